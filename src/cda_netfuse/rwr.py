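"""Random walk with restart on the heterogeneous circRNA-disease network.

The walker lives on the (m + n)-node graph whose 2 x 2 block transition
matrix routes probability within the circRNA similarity network (W_cc),
within the disease similarity network (W_dd), and across the bipartite
association edges (W_cd, W_dc) with jump probability ``mu``.  For a seed
disease the stationary restart distribution scores every circRNA's
proximity to that disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from cda_netfuse.core_data import (
    AssociationMatrix,
    HyperParams,
    ScoreMatrix,
    SimilarityMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    """(m + n) x (m + n) row-stochastic transition matrix.

    Rows index the *source* node: ``values[i, j]`` is the probability of
    moving from node i to node j.  circRNAs occupy indices [0, m),
    diseases [m, m + n).  A row may be all-zero only for a fully isolated
    node (zero similarity to all others and zero associations).
    """

    m: int
    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        size = self.m + self.n
        if self.values.shape != (size, size):
            raise ValueError(f"transition matrix must be {size} x {size}")
        if self.values.min() < 0 or self.values.max() > 1.0 + 1e-12:
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-10) | np.isclose(sums, 0.0, atol=1e-10)
        if not ok.all():
            bad = int(np.nonzero(~ok)[0][0])
            raise ValueError(f"row {bad} sums to {sums[bad]!r}, expected 0 or 1")


def _row_normalize(mat: np.ndarray) -> np.ndarray:
    sums = mat.sum(axis=1, keepdims=True)
    out = np.zeros_like(mat)
    np.divide(mat, sums, out=out, where=sums > 0)
    return out


def build_transition_matrix(
    SC: SimilarityMatrix, SD: SimilarityMatrix, Y: AssociationMatrix, mu: float
) -> TransitionMatrix:
    """Assemble the block transition matrix from SC, SD and Y.

    A node with at least one association splits its outgoing mass
    ``(1 - mu)`` within its own similarity network and ``mu`` across the
    association edges (proportionally to its associations); a node with no
    associations keeps all its mass within its similarity network.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu={mu} outside (0, 1)")
    if SC.values.min() < 0 or SD.values.min() < 0:
        raise ValueError("similarity matrices must be nonnegative")
    m, n = Y.m, Y.n
    if SC.k != m or SD.k != n:
        raise ValueError("similarity matrix sizes do not match the association matrix")

    circ_deg = Y.values.sum(axis=1)  # associations per circRNA
    dis_deg = Y.values.sum(axis=0)  # associations per disease

    Wcc = _row_normalize(SC.values)
    Wcc[circ_deg > 0] *= 1.0 - mu
    Wcd = mu * _row_normalize(Y.values)

    Wdd = _row_normalize(SD.values)
    Wdd[dis_deg > 0] *= 1.0 - mu
    Wdc = mu * _row_normalize(Y.values.T)

    W = np.block([[Wcc, Wcd], [Wdc, Wdd]])
    return TransitionMatrix(m, n, W)


def initial_probability(seed_disease_index: int, m: int, n: int, lambda_: float) -> np.ndarray:
    """Restart distribution for one seed disease.

    Mass ``lambda_`` is spread uniformly over the m circRNAs and
    ``1 - lambda_`` sits on the seed disease; all other diseases get 0.
    """
    if m == 0:
        raise ValueError("m must be positive")
    if not 0 <= seed_disease_index < n:
        raise ValueError(f"seed disease index {seed_disease_index} outside [0, {n})")
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError(f"lambda_={lambda_} outside [0, 1]")
    p0 = np.zeros(m + n)
    p0[:m] = lambda_ / m
    p0[m + seed_disease_index] = 1.0 - lambda_
    return p0


def propagate(
    W: TransitionMatrix,
    p0: np.ndarray,
    beta: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, bool]:
    """Iterate ``p <- beta * W^T p + (1 - beta) * p0`` to its fixed point.

    The transpose keeps ``p`` a vector of node-occupancy mass, so a fully
    row-stochastic W conserves total probability.  Iteration stops when
    the l1 change drops below ``tol``; on hitting ``max_iter`` first a
    warning is logged and the current iterate is returned with the
    converged flag set to False.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta={beta} outside (0, 1)")
    p0 = np.asarray(p0, dtype=float)
    WT = W.values.T
    p = p0.copy()
    for _ in range(max_iter):
        p_next = beta * (WT @ p) + (1.0 - beta) * p0
        if np.abs(p_next - p).sum() < tol:
            return p_next, True
        p = p_next
    logger.warning("propagation did not converge in %d iterations", max_iter)
    return p, False


def rwr_score_matrix(
    SC: SimilarityMatrix,
    SD: SimilarityMatrix,
    Y: AssociationMatrix,
    params: HyperParams,
) -> ScoreMatrix:
    """Score matrix P: one restart-walk per disease, circRNA block per column.

    Disease j is seeded, the walk is run to its fixed point, and column j
    of P collects the circRNA entries of the stationary vector; the
    disease block is discarded since only circRNAs are ranked.
    """
    W = build_transition_matrix(SC, SD, Y, params.mu)
    m, n = Y.m, Y.n
    P = np.empty((m, n))
    for j in range(n):
        p0 = initial_probability(j, m, n, params.lambda_)
        p_star, _converged = propagate(W, p0, params.beta, params.rwr_tol, params.rwr_max_iter)
        P[:, j] = p_star[:m]
    return ScoreMatrix(Y.circrna_ids, Y.disease_ids, P)
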