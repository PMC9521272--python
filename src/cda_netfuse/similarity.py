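"""Similarity computation and fusion.

Three similarity channels feed the predictors:

* a Gaussian kernel on binary association profiles (rows of Y for
  circRNAs, columns for diseases), with the bandwidth scaled by the mean
  squared profile norm;
* circRNA functional similarity: best-match averaging of disease semantic
  similarity over the two circRNAs' associated disease sets;
* the precomputed disease semantic similarity itself.

The final matrices are convex blends:
``SC = alpha_c * S_fun + (1 - alpha_c) * S_ap_c`` and
``SD = alpha_d * S_sem + (1 - alpha_d) * S_ap_d``.
"""

from __future__ import annotations

import logging

import numpy as np

from cda_netfuse.core_data import AssociationMatrix, HyperParams, SimilarityMatrix

logger = logging.getLogger(__name__)


def profile_similarity(
    profiles: np.ndarray, ids: list[str], gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian kernel on binary association profiles, taken row-wise.

    ``S(i, j) = exp(-gamma * ||row_i - row_j||^2)`` with
    ``gamma = gamma_prime / mean_k ||row_k||^2``.  Apply to ``Y`` for
    circRNAs and to ``Y.T`` for diseases.  If every profile is all-zero
    the bandwidth is undefined; the identity matrix is returned (only
    self-similarity remains) with a logged warning.

    The bandwidth actually used is exposed as ``meta["gamma"]``
    (``None`` in the all-zero case).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise ValueError("profiles must be a k x p matrix with k >= 1")
    if not np.isin(profiles, (0.0, 1.0)).all():
        raise ValueError("profiles must be binary")
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    k = profiles.shape[0]
    mean_sq_norm = float((profiles**2).sum() / k)
    if mean_sq_norm == 0.0:
        logger.warning("all profiles are empty; returning identity similarity")
        return SimilarityMatrix(ids, np.eye(k), meta={"gamma": None})
    gamma = gamma_prime / mean_sq_norm
    # squared Euclidean distance between binary rows via the Gram matrix
    sq_norms = (profiles**2).sum(axis=1)
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-gamma * d2)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids, values, meta={"gamma": gamma})


def functional_similarity(Y: AssociationMatrix, sem: SimilarityMatrix) -> SimilarityMatrix:
    """circRNA functional similarity induced by disease semantic similarity.

    For circRNAs with associated disease sets ``D_i`` and ``D_j``::

        score(i, j) = [ sum_{d in D_i} max_{t in D_j} sem(d, t)
                      + sum_{d in D_j} max_{t in D_i} sem(d, t) ]
                      / (|D_i| + |D_j|)

    The max over an empty set is 0, so a pair where one set is empty
    scores 0; a pair where both are empty also scores 0 off-diagonal.
    The diagonal is forced to 1 in every case, keeping the fused circRNA
    similarity positive-diagonal for the Laplacian downstream.
    """
    missing = [d for d in Y.disease_ids if d not in set(sem.ids)]
    if missing:
        raise ValueError(f"semantic similarity does not cover disease(s): {missing[:5]}")
    sem_idx = [sem.ids.index(d) for d in Y.disease_ids]
    S = sem.values[np.ix_(sem_idx, sem_idx)]
    m = Y.m
    disease_sets = [np.nonzero(Y.values[i])[0] for i in range(m)]
    values = np.zeros((m, m))
    for i in range(m):
        Di = disease_sets[i]
        for j in range(i + 1, m):
            Dj = disease_sets[j]
            tot = len(Di) + len(Dj)
            if tot == 0 or len(Di) == 0 or len(Dj) == 0:
                continue
            cross = S[np.ix_(Di, Dj)]
            score = (cross.max(axis=1).sum() + cross.max(axis=0).sum()) / tot
            values[i, j] = values[j, i] = score
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(Y.circrna_ids, values)


def fuse(bio: SimilarityMatrix, ap: SimilarityMatrix, alpha: float) -> SimilarityMatrix:
    """Convex blend ``alpha * bio + (1 - alpha) * ap`` of two channels."""
    if bio.ids != ap.ids:
        raise ValueError("cannot fuse similarity matrices with mismatched identifiers")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    return SimilarityMatrix(bio.ids, alpha * bio.values + (1.0 - alpha) * ap.values)


def build_similarities(
    Y: AssociationMatrix, sem: SimilarityMatrix, params: HyperParams
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Compute the fused circRNA and disease similarity matrices (SC, SD).

    All profile-derived channels (the Gaussian profile kernels and the
    functional similarity) are recomputed from the Y that is passed in, so
    calling this on a fold-masked Y never sees test labels.
    """
    ap_c = profile_similarity(Y.values, Y.circrna_ids, params.gamma_c_band)
    ap_d = profile_similarity(Y.values.T, Y.disease_ids, params.gamma_d_band)
    fun_c = functional_similarity(Y, sem)
    sem_d = SimilarityMatrix(Y.disease_ids, sem.values[
        np.ix_([sem.ids.index(d) for d in Y.disease_ids],
               [sem.ids.index(d) for d in Y.disease_ids])
    ]) if sem.ids != Y.disease_ids else sem
    SC = fuse(fun_c, ap_c, params.alpha_c)
    SD = fuse(sem_d, ap_d, params.alpha_d)
    return SC, SD
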