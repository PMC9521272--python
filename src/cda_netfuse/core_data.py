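"""Domain types, file I/O and configuration.

The in-memory containers keep a stable mapping between string identifiers
and matrix positions: every downstream matrix (similarity, transition,
score) indexes by the identifier order fixed when the association edge
list is read, never by position in external files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-10
_READ_SYMMETRY_TOL = 1e-6
_CLIP_TOL = 1e-9


class MatrixFormatError(ValueError):
    """Raised when an input file violates the matrix/edge-list contracts."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class AssociationMatrix:
    """Binary m x n circRNA-by-disease incidence matrix Y.

    Rows are circRNAs, columns diseases; ``values[i, j] == 1`` iff circRNA
    ``circrna_ids[i]`` is known to associate with disease ``disease_ids[j]``.
    """

    circrna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.circrna_ids = list(self.circrna_ids)
        self.disease_ids = list(self.disease_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.circrna_ids, "circRNA")
        _check_unique(self.disease_ids, "disease")
        if self.values.shape != (len(self.circrna_ids), len(self.disease_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.circrna_ids)} circRNAs x {len(self.disease_ids)} diseases"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix must be binary (0/1)")

    @property
    def m(self) -> int:
        return len(self.circrna_ids)

    @property
    def n(self) -> int:
        return len(self.disease_ids)

    def circrna_index(self, circrna_id: str) -> int:
        return self.circrna_ids.index(circrna_id)

    def disease_index(self, disease_id: str) -> int:
        return self.disease_ids.index(disease_id)

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) of all known associations, row-major order."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        return AssociationMatrix(self.circrna_ids, self.disease_ids, values)


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one node type.

    Values lie in [0, 1] and the diagonal is 1 (self-similarity); the
    profile kernel forces the diagonal to 1 even for empty profiles.
    ``meta`` carries computation by-products such as the Gaussian kernel
    bandwidth actually used.
    """

    ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.ids, "node")
        k = len(self.ids)
        if self.values.shape != (k, k):
            raise ValueError(f"shape {self.values.shape} does not match {k} ids")
        if not np.allclose(self.values, self.values.T, rtol=0.0, atol=_SYMMETRY_TOL):
            raise ValueError("similarity matrix is not symmetric within 1e-10")
        if self.values.min() < -_SYMMETRY_TOL or self.values.max() > 1.0 + _SYMMETRY_TOL:
            raise ValueError("similarity values must lie in [0, 1]")
        if k and not np.allclose(np.diag(self.values), 1.0, atol=_SYMMETRY_TOL):
            raise ValueError("similarity diagonal must equal 1")

    @property
    def k(self) -> int:
        return len(self.ids)


@dataclass
class ScoreMatrix:
    """Real-valued m x n matrix of circRNA-disease association scores."""

    circrna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.circrna_ids = list(self.circrna_ids)
        self.disease_ids = list(self.disease_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.circrna_ids), len(self.disease_ids)):
            raise ValueError("score matrix shape does not match identifier counts")
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite values")


@dataclass(frozen=True)
class HyperParams:
    """Model hyperparameters.

    Defaults are the published operating point of the method: equal fusion
    weights, walk weight ``beta = 0.2`` (the restart term carries
    ``1 - beta``), initial-probability split ``lambda_ = 0.1`` toward the
    circRNA layer, inter-network jump probability ``mu = 0.6``, LRLS
    trade-offs 0.95 (circRNA space) and 0.2 (disease space), and soft-voting
    weight ``theta = 0.3``.

    ``gamma_c_band`` / ``gamma_d_band`` scale the Gaussian profile-kernel
    bandwidths and are distinct parameters from the LRLS regularization
    weights ``gamma_c_reg`` / ``gamma_d_reg``.
    """

    alpha_c: float = 0.5
    alpha_d: float = 0.5
    gamma_c_band: float = 1.0
    gamma_d_band: float = 1.0
    beta: float = 0.2
    lambda_: float = 0.1
    mu: float = 0.6
    gamma_c_reg: float = 0.95
    gamma_d_reg: float = 0.2
    theta: float = 0.3
    rwr_tol: float = 1e-6
    rwr_max_iter: int = 1000

    def __post_init__(self) -> None:
        for name in ("alpha_c", "alpha_d", "lambda_"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("beta", "mu"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        for name in ("gamma_c_band", "gamma_d_band", "rwr_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gamma_c_reg", "gamma_d_reg", "theta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rwr_max_iter < 1:
            raise ValueError("rwr_max_iter must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "HyperParams":
        """Load from a flat key/value YAML document; overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise MatrixFormatError(f"{path}: config must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MatrixFormatError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def replace(self, **changes) -> "HyperParams":
        return replace(self, **changes)


def read_association_edgelist(path: str | Path, delimiter: str = "\t") -> AssociationMatrix:
    """Read a two-column (circRNA, disease) edge list into a binary matrix.

    Identifiers are ordered by first appearance; duplicate edges collapse
    to a single 1 (with a logged warning). Lines starting with ``#`` and
    blank lines are ignored.
    """
    path = Path(path)
    circ_order: dict[str, int] = {}
    dis_order: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    n_dup = 0
    seen: set[tuple[int, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected at least 2 fields "
                    f"(circRNA id, disease id), got {line!r}"
                )
            c, d = parts[0].strip(), parts[1].strip()
            ci = circ_order.setdefault(c, len(circ_order))
            di = dis_order.setdefault(d, len(dis_order))
            if (ci, di) in seen:
                n_dup += 1
                continue
            seen.add((ci, di))
            edges.append((ci, di))
    if not edges:
        raise MatrixFormatError(f"{path}: no associations found")
    if n_dup:
        logger.warning("%s: collapsed %d duplicate association line(s) to 1", path, n_dup)
    values = np.zeros((len(circ_order), len(dis_order)))
    for ci, di in edges:
        values[ci, di] = 1.0
    return AssociationMatrix(list(circ_order), list(dis_order), values)


def write_association_edgelist(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the known associations back out as a two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# circRNA_id\tdisease_id\n")
        for i, j in assoc.positive_pairs():
            fh.write(f"{assoc.circrna_ids[i]}\t{assoc.disease_ids[j]}\n")


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a labelled square similarity table (TSV, labels in row 1/col 1).

    Row and column labels must match in order. Mild asymmetry (at most
    1e-6) is repaired by averaging ``(V + V^T) / 2``; anything larger is an
    error. Values are clipped into [0, 1] only for violations below 1e-9.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise MatrixFormatError(f"{path}: empty similarity table")
    header = lines[0].split("\t")
    col_labels = [h.strip() for h in header[1:]]
    row_labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(col_labels) + 1:
            raise MatrixFormatError(
                f"{path}:{lineno}: expected {len(col_labels) + 1} fields, got {len(parts)}"
            )
        row_labels.append(parts[0].strip())
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise MatrixFormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if len(row_labels) != len(col_labels):
        raise MatrixFormatError(
            f"{path}: non-square table ({len(row_labels)} rows x {len(col_labels)} columns)"
        )
    if row_labels != col_labels:
        raise MatrixFormatError(f"{path}: row labels do not match column labels in order")
    values = np.array(rows)
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > _READ_SYMMETRY_TOL:
        raise MatrixFormatError(f"{path}: asymmetry {asym:.3g} exceeds tolerance 1e-06")
    values = (values + values.T) / 2.0
    low, high = values.min(initial=0.0), values.max(initial=1.0)
    if low < -_CLIP_TOL or high > 1.0 + _CLIP_TOL:
        raise MatrixFormatError(f"{path}: values outside [0, 1] (range [{low:.3g}, {high:.3g}])")
    values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(row_labels, values)


def _fmt(x: float) -> str:
    # 17 significant digits round-trips any IEEE double exactly
    return format(float(x), ".17g")


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a labelled square similarity table readable by read_similarity_matrix."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for label, row in zip(sim.ids, sim.values):
            fh.write(label + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def write_score_table(scores: ScoreMatrix, known: AssociationMatrix, path: str | Path) -> None:
    """Write scores as a long-format TSV with per-disease dense ranks.

    Columns: circRNA_id, disease_id, score, known (0/1),
    rank_within_disease.  Rows are ordered disease-by-disease with
    circRNAs sorted by descending score, ties broken by identifier;
    tied scores share a dense rank.
    """
    if scores.circrna_ids != known.circrna_ids or scores.disease_ids != known.disease_ids:
        raise ValueError("score and association matrices have mismatched identifiers")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("circRNA_id\tdisease_id\tscore\tknown\trank_within_disease\n")
        for j, disease in enumerate(scores.disease_ids):
            col = scores.values[:, j]
            order = sorted(range(len(col)), key=lambda i: (-col[i], scores.circrna_ids[i]))
            rank, prev = 0, None
            for i in order:
                if prev is None or col[i] != prev:
                    rank += 1
                    prev = col[i]
                fh.write(
                    f"{scores.circrna_ids[i]}\t{disease}\t{_fmt(col[i])}\t"
                    f"{int(known.values[i, j])}\t{rank}\n"
                )


def read_score_table(path: str | Path) -> ScoreMatrix:
    """Re-read a score table written by write_score_table (exact round trip)."""
    entries: dict[tuple[str, str], float] = {}
    circ_order: dict[str, None] = {}
    dis_order: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("circRNA_id\t"):
            raise MatrixFormatError(f"{path}: not a score table")
        for line in fh:
            c, d, s, _known, _rank = line.rstrip("\n").split("\t")
            circ_order.setdefault(c)
            dis_order.setdefault(d)
            entries[(c, d)] = float(s)
    circ_ids, dis_ids = list(circ_order), list(dis_order)
    values = np.empty((len(circ_ids), len(dis_ids)))
    for i, c in enumerate(circ_ids):
        for j, d in enumerate(dis_ids):
            values[i, j] = entries[(c, d)]
    return ScoreMatrix(circ_ids, dis_ids, values)


def align_semantic_similarity(sem: SimilarityMatrix, disease_ids: Sequence[str]) -> SimilarityMatrix:
    """Restrict/extend a semantic-similarity matrix to a disease id list.

    Diseases absent from ``sem`` — e.g. diseases with no ontology terms —
    get similarity 0 to all others and 1 to themselves (logged); this is
    exactly the gap the association-profile channel is meant to fill.
    """
    index = {d: i for i, d in enumerate(sem.ids)}
    missing = [d for d in disease_ids if d not in index]
    if missing:
        logger.warning(
            "%d disease(s) absent from the semantic-similarity matrix get "
            "self-similarity only: %s",
            len(missing),
            ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""),
        )
    k = len(disease_ids)
    values = np.eye(k)
    for a, da in enumerate(disease_ids):
        ia = index.get(da)
        if ia is None:
            continue
        for b, db in enumerate(disease_ids):
            ib = index.get(db)
            if ib is not None:
                values[a, b] = sem.values[ia, ib]
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(disease_ids), values)
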