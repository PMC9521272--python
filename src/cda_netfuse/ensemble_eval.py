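"""Soft-voting ensemble, per-disease ranking and cross-validated AUC.

The ensemble score is the additive blend ``Ypre = P + theta * F`` of the
random-walk matrix P and the LRLS matrix F.  Evaluation is repeated
k-fold cross-validation over the known positive *pairs*: each fold's test
positives are masked to 0 in Y, every similarity channel is recomputed
from the masked matrix (so no test label leaks into the model), and the
fold AUC ranks the held-out positives against all pairs that are unknown
in the full data.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field

import numpy as np

from cda_netfuse.core_data import (
    AssociationMatrix,
    HyperParams,
    ScoreMatrix,
    SimilarityMatrix,
)
from cda_netfuse.lrls import lrls_score_matrix
from cda_netfuse.rwr import rwr_score_matrix
from cda_netfuse.similarity import build_similarities

logger = logging.getLogger(__name__)

MODELS = ("rwr", "lrls", "ensemble")


@dataclass
class CVResult:
    """Repeated k-fold cross-validation outcome.

    ``fold_aucs`` is a repeats x k array (NaN marks a skipped fold);
    ``mean_auc`` is the mean over all computed folds; ``fold_assignment``
    maps each known association (i, j) to its fold index in every repeat.
    """

    fold_aucs: np.ndarray
    mean_auc: float
    fold_assignment: dict[tuple[int, int], list[int]]
    seed: int
    model: str
    params: HyperParams = field(repr=False, default=HyperParams())

    def __post_init__(self) -> None:
        self.fold_aucs = np.asarray(self.fold_aucs, dtype=float)


def ensemble_combine(P: ScoreMatrix, F: ScoreMatrix, theta: float) -> ScoreMatrix:
    """Soft-voting blend ``Ypre = P + theta * F`` (elementwise)."""
    if P.circrna_ids != F.circrna_ids or P.disease_ids != F.disease_ids:
        raise ValueError("score matrices have mismatched identifiers")
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    return ScoreMatrix(P.circrna_ids, P.disease_ids, P.values + theta * F.values)


def rank_for_disease(
    Ypre: ScoreMatrix,
    Y: AssociationMatrix,
    disease_id: str,
    top: int | None = None,
    include_known: bool = True,
) -> list[tuple[str, float, bool]]:
    """Rank circRNAs for one disease by descending score.

    Ties break by circRNA identifier (lexicographic), so output is
    deterministic.  Known associations are flagged and, by default,
    ranked alongside the candidates; with ``include_known=False`` they
    are dropped before truncation to ``top``.
    """
    if Ypre.circrna_ids != Y.circrna_ids or Ypre.disease_ids != Y.disease_ids:
        raise ValueError("score and association matrices have mismatched identifiers")
    if disease_id not in Ypre.disease_ids:
        near = difflib.get_close_matches(disease_id, Ypre.disease_ids, n=3)
        hint = f"; closest matches: {near}" if near else ""
        raise KeyError(f"unknown disease {disease_id!r}{hint}")
    j = Ypre.disease_ids.index(disease_id)
    col = Ypre.values[:, j]
    known = Y.values[:, j] > 0
    order = sorted(range(len(col)), key=lambda i: (-col[i], Ypre.circrna_ids[i]))
    out = [
        (Ypre.circrna_ids[i], float(col[i]), bool(known[i]))
        for i in order
        if include_known or not known[i]
    ]
    return out if top is None else out[:top]


def auc_ranked(
    scores: ScoreMatrix,
    test_positives: set[tuple[int, int]],
    train_positives: set[tuple[int, int]],
) -> float:
    """Rank-based AUC of test positives against all unknown pairs.

    The pair population is every (circRNA, disease) cell excluding the
    training positives; positives are the held-out test pairs, negatives
    everything else.  Ties contribute 1/2, making this the Mann-Whitney U
    statistic normalized by |pos| * |neg|.  Ranking is done in-house with
    midranks; no external AUC routine is called.
    """
    if test_positives & train_positives:
        raise ValueError("test and train positive sets overlap")
    m, n = scores.values.shape
    mask = np.ones((m, n), dtype=bool)
    for i, j in train_positives:
        mask[i, j] = False
    pos_mask = np.zeros((m, n), dtype=bool)
    for i, j in test_positives:
        if not mask[i, j]:
            raise ValueError(f"test positive {(i, j)} collides with a train positive")
        pos_mask[i, j] = True
    vals = scores.values[mask]
    is_pos = pos_mask[mask]
    n_pos = int(is_pos.sum())
    n_neg = int(len(vals) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    # midranks by hand: average rank over each tie group
    order = np.argsort(vals, kind="mergesort")
    ranks = np.empty(len(vals))
    sorted_vals = vals[order]
    i = 0
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    rank_sum = ranks[is_pos].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def predict_scores(
    Y: AssociationMatrix,
    sem: SimilarityMatrix,
    params: HyperParams,
    model: str = "ensemble",
) -> ScoreMatrix:
    """Fit the requested model on the full data and return its score matrix."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    SC, SD = build_similarities(Y, sem, params)
    if model == "rwr":
        return rwr_score_matrix(SC, SD, Y, params)
    if model == "lrls":
        return lrls_score_matrix(SC, SD, Y, params)
    P = rwr_score_matrix(SC, SD, Y, params)
    F = lrls_score_matrix(SC, SD, Y, params)
    return ensemble_combine(P, F, params.theta)


def _fold_splits(
    Y: AssociationMatrix, k: int, repeats: int, seed: int
) -> tuple[list[list[list[tuple[int, int]]]], dict[tuple[int, int], list[int]]]:
    """Shuffle the positive pairs per repeat and cut them into k folds.

    Repeat r draws from seed + r, so a fixed master seed reproduces the
    exact fold assignment.
    """
    positives = Y.positive_pairs()
    if len(positives) < k:
        raise ValueError(f"need at least k={k} positives, have {len(positives)}")
    all_folds: list[list[list[tuple[int, int]]]] = []
    assignment: dict[tuple[int, int], list[int]] = {p: [] for p in positives}
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(len(positives))
        folds = [
            [positives[idx] for idx in chunk] for chunk in np.array_split(perm, k)
        ]
        for f, fold in enumerate(folds):
            for pair in fold:
                assignment[pair].append(f)
        all_folds.append(folds)
    return all_folds, assignment


def _fold_model_scores(
    Y: AssociationMatrix,
    sem: SimilarityMatrix,
    params: HyperParams,
    test_pairs: list[tuple[int, int]],
) -> tuple[ScoreMatrix, ScoreMatrix, set[tuple[int, int]], set[tuple[int, int]]]:
    """Mask a fold's test positives and fit both models on the masked Y."""
    masked = Y.values.copy()
    for i, j in test_pairs:
        masked[i, j] = 0.0
    Y_masked = Y.with_values(masked)
    SC, SD = build_similarities(Y_masked, sem, params)
    P = rwr_score_matrix(SC, SD, Y_masked, params)
    F = lrls_score_matrix(SC, SD, Y_masked, params)
    test = set(test_pairs)
    train = set(Y.positive_pairs()) - test
    return P, F, test, train


def cross_validate(
    Y: AssociationMatrix,
    sem: SimilarityMatrix,
    params: HyperParams,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    model: str = "ensemble",
) -> CVResult:
    """Repeated k-fold cross-validation of one model, AUC per fold.

    Per repeat the positive pairs are shuffled (seed + repeat index) and
    split into k folds; per fold the test positives are zeroed in Y, the
    similarity channels and the model are recomputed from the masked
    matrix, and AUC ranks the held-out positives against all unknown
    pairs.  A fold whose masking leaves no test positive is skipped with
    a warning and recorded as NaN.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if k < 2:
        raise ValueError("k must be at least 2")
    all_folds, assignment = _fold_splits(Y, k, repeats, seed)
    fold_aucs = np.full((repeats, k), np.nan)
    for r, folds in enumerate(all_folds):
        for f, test_pairs in enumerate(folds):
            if not test_pairs:
                logger.warning("repeat %d fold %d has no test positives; skipped", r, f)
                continue
            P, F, test, train = _fold_model_scores(Y, sem, params, test_pairs)
            if model == "rwr":
                scores = P
            elif model == "lrls":
                scores = F
            else:
                scores = ensemble_combine(P, F, params.theta)
            fold_aucs[r, f] = auc_ranked(scores, test, train)
    mean_auc = float(np.nanmean(fold_aucs))
    return CVResult(fold_aucs, mean_auc, assignment, seed, model, params)


def theta_sweep(
    Y: AssociationMatrix,
    sem: SimilarityMatrix,
    params: HyperParams,
    thetas: list[float],
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Mean ensemble AUC as a function of the soft-voting weight theta.

    Every theta is evaluated on the identical fold assignment (same
    seed), and P and F are fitted once per fold and recombined per theta,
    so the resulting curve isolates the effect of theta.
    """
    if not thetas:
        raise ValueError("thetas must be non-empty")
    all_folds, _ = _fold_splits(Y, k, repeats, seed)
    sums = {t: 0.0 for t in thetas}
    counts = {t: 0 for t in thetas}
    for folds in all_folds:
        for test_pairs in folds:
            if not test_pairs:
                continue
            P, F, test, train = _fold_model_scores(Y, sem, params, test_pairs)
            for t in thetas:
                sums[t] += auc_ranked(ensemble_combine(P, F, t), test, train)
                counts[t] += 1
    return [(t, sums[t] / counts[t]) for t in thetas]
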