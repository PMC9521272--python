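"""Synthetic planted-cluster benchmark generator.

Emulates the two inputs the pipeline needs — a bipartite circRNA-disease
association matrix and a disease semantic-similarity matrix — with signal
planted in *both* channels the method fuses: circRNAs and diseases are
grouped into matched clusters, associations are dense within matched
cluster pairs (``p_in``) and sparse elsewhere (``p_out``), and the
semantic matrix is block-structured over the same disease clusters
(``sem_in`` within, ``sem_out`` across, plus symmetric uniform jitter).
A random 10% of the generated within-cluster associations is withheld
from Y as recoverable ground-truth missing links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cda_netfuse.core_data import AssociationMatrix, SimilarityMatrix

HOLDOUT_FRACTION = 0.1


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted-cluster benchmark parameters.

    ``m`` circRNAs and ``n`` diseases are assigned round-robin to
    ``n_circ_clusters`` / ``n_disease_clusters`` clusters; cluster pairs
    are matched bijectively (cluster c of circRNAs with cluster c of
    diseases, modulo the smaller count).
    """

    m: int = 60
    n: int = 20
    n_disease_clusters: int = 4
    n_circ_clusters: int = 4
    p_in: float = 0.5
    p_out: float = 0.02
    sem_in: float = 0.8
    sem_out: float = 0.1
    sem_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be positive")
        if self.n_circ_clusters < 1 or self.n_disease_clusters < 1:
            raise ValueError("cluster counts must be positive")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if not 0.0 <= self.sem_out < self.sem_in <= 1.0:
            raise ValueError("require 0 <= sem_out < sem_in <= 1")
        if self.sem_noise < 0:
            raise ValueError("sem_noise must be nonnegative")
        if self.sem_in + self.sem_noise > 1.0:
            raise ValueError("sem_in + sem_noise must not exceed 1")
        if self.sem_out - self.sem_noise < 0.0:
            raise ValueError("sem_out - sem_noise must be nonnegative")


def small_preset(seed: int = 0) -> SyntheticConfig:
    """Default fixture: 60 circRNAs x 20 diseases, 4 matched clusters."""
    return SyntheticConfig(seed=seed)


def paper_shaped_preset(seed: int = 0) -> SyntheticConfig:
    """Scale fixture shaped like the curated human association extract.

    585 circRNAs x 88 diseases at overall density ~0.0126 (650 known
    pairs); meant for scale testing, not for matching published AUC.
    """
    # p_in / p_out chosen so expected density ~= 650 / (585 * 88)
    return SyntheticConfig(
        m=585,
        n=88,
        n_disease_clusters=8,
        n_circ_clusters=8,
        p_in=0.09,
        p_out=0.0015,
        seed=seed,
    )


def _round_robin(count: int, n_clusters: int) -> np.ndarray:
    return np.arange(count) % n_clusters


def generate(
    config: SyntheticConfig,
) -> tuple[AssociationMatrix, SimilarityMatrix, set[tuple[str, str]]]:
    """Draw one benchmark instance: (Y, disease semantic matrix, held-out truth).

    The held-out pairs are within-cluster associations that were drawn
    but removed from Y; they are the "missing links" a good predictor
    should rank highly.  Output is bitwise-reproducible for a fixed
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    m, n = config.m, config.n
    circ_ids = [f"circ{str(i + 1).zfill(len(str(m)))}" for i in range(m)]
    dis_ids = [f"disease{str(j + 1).zfill(len(str(n)))}" for j in range(n)]
    circ_cl = _round_robin(m, config.n_circ_clusters)
    dis_cl = _round_robin(n, config.n_disease_clusters)
    n_matched = min(config.n_circ_clusters, config.n_disease_clusters)
    matched = (circ_cl[:, None] % n_matched) == (dis_cl[None, :] % n_matched)

    prob = np.where(matched, config.p_in, config.p_out)
    Y_full = (rng.random((m, n)) < prob).astype(float)

    # withhold 10% of the within-cluster hits as recoverable missing links
    in_hits = np.argwhere((Y_full > 0) & matched)
    n_hold = int(round(HOLDOUT_FRACTION * len(in_hits)))
    held_idx = rng.choice(len(in_hits), size=n_hold, replace=False) if n_hold else []
    Y = Y_full.copy()
    ground_truth: set[tuple[str, str]] = set()
    for idx in held_idx:
        i, j = in_hits[idx]
        Y[i, j] = 0.0
        ground_truth.add((circ_ids[i], dis_ids[j]))

    sem = np.where(
        dis_cl[:, None] == dis_cl[None, :], config.sem_in, config.sem_out
    ).astype(float)
    if config.sem_noise > 0:
        jitter = rng.uniform(-config.sem_noise, config.sem_noise, size=(n, n))
        sem = sem + np.triu(jitter, 1) + np.triu(jitter, 1).T
    np.fill_diagonal(sem, 1.0)
    sem = np.clip(sem, 0.0, 1.0)

    assoc = AssociationMatrix(circ_ids, dis_ids, Y)
    sem_matrix = SimilarityMatrix(dis_ids, sem)
    return assoc, sem_matrix, ground_truth
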