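"""Laplacian regularized least squares (LRLS) link scoring.

Labels are reconstructed smoothly over the similarity graph: the score
matrix in circRNA space minimizes ``||Y - F||_F^2 + gamma * tr(F^T L F)``
with L the normalized Laplacian of the fused circRNA similarity, whose
stationarity condition yields the closed form
``F_c = S (S + gamma * L * S)^{-1} Y``.  The mirror problem in disease
space acts on ``Y^T``, and the final matrix averages the two views:
``F = (F_c + F_d^T) / 2``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.linalg

from cda_netfuse.core_data import (
    AssociationMatrix,
    HyperParams,
    ScoreMatrix,
    SimilarityMatrix,
)

logger = logging.getLogger(__name__)


def normalized_laplacian(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian ``D^{-1/2} (D - S) D^{-1/2}``.

    D is the diagonal matrix of row sums of S. The result is symmetric
    PSD with eigenvalues in [0, 2]. Zero row sums are an error; upstream
    the unit similarity diagonal precludes them.
    """
    values = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("similarity must be symmetric")
    if values.min() < 0:
        raise ValueError("similarity must be nonnegative")
    deg = values.sum(axis=1)
    if (deg <= 0).any():
        raise ValueError("zero row sum: Laplacian normalization undefined")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = -values * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(L, np.diag(L) + 1.0)
    return (L + L.T) / 2.0


def lrls_solve(
    S: SimilarityMatrix | np.ndarray,
    L: np.ndarray,
    target: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Closed-form LRLS solution ``S (S + gamma * L * S)^{-1} target``.

    Solved as a linear system, never by explicit inversion; a singular
    system falls back to least squares with a logged warning.  With
    ``gamma = 0`` and invertible S the target is returned unchanged, and
    ``S = I`` gives ``L = 0`` so the target passes through for any gamma.
    """
    Sv = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    target = np.asarray(target, dtype=float)
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    A = Sv + gamma * (L @ Sv)
    try:
        with warnings.catch_warnings():
            # near-singular systems (e.g. duplicated profiles) go to lstsq
            warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
            X = scipy.linalg.solve(A, target)
    except (scipy.linalg.LinAlgError, scipy.linalg.LinAlgWarning, ValueError):
        logger.warning("LRLS system singular or ill-conditioned; using least squares")
        X = scipy.linalg.lstsq(A, target)[0]
    return Sv @ X


def lrls_score_matrix(
    SC: SimilarityMatrix,
    SD: SimilarityMatrix,
    Y: AssociationMatrix,
    params: HyperParams,
) -> ScoreMatrix:
    """Average of the circRNA-space and disease-space LRLS reconstructions.

    ``F_c`` (m x n) smooths Y over the circRNA graph with weight
    ``gamma_c_reg``; ``F_d`` (n x m) smooths ``Y^T`` over the disease
    graph with weight ``gamma_d_reg``; ``F = (F_c + F_d^T) / 2``.
    """
    if SC.k != Y.m or SD.k != Y.n:
        raise ValueError("similarity matrix sizes do not match the association matrix")
    Lc = normalized_laplacian(SC)
    Ld = normalized_laplacian(SD)
    Fc = lrls_solve(SC, Lc, Y.values, params.gamma_c_reg)
    Fd = lrls_solve(SD, Ld, Y.values.T, params.gamma_d_reg)
    F = 0.5 * (Fc + Fd.T)
    return ScoreMatrix(Y.circrna_ids, Y.disease_ids, F)
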