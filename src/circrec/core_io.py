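"""Domain containers and plain-text I/O for the association-prediction pipeline.

The pipeline operates on a bipartite disease x circRNA association network
plus several per-entity side data sources (sequences, annotation-term sets,
gene sets, an imported semantic-similarity matrix).  Every external format is
delimited text or FASTA; matrices are written dense with a header row and a
header column of identifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ParseError",
    "ValidationError",
    "AssociationMatrix",
    "SimilarityMatrix",
    "TermMap",
    "SequenceSet",
    "ScoreMatrix",
    "PipelineConfig",
    "EvaluationResult",
    "read_associations",
    "read_fasta",
    "read_term_map",
    "read_matrix",
    "write_matrix",
    "write_scores",
    "write_ranked_predictions",
]

_SYMMETRY_TOL = 1e-6
_RANGE_TOL = 1e-9
_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A structurally invalid input file."""


class ValidationError(ValueError):
    """A container invariant was violated."""


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what} identifiers")


@dataclass
class AssociationMatrix:
    """Binary disease x circRNA association matrix.

    Rows are diseases, columns are circRNAs.  ``values[i, j] == 1`` records a
    known association between disease ``disease_ids[i]`` and circRNA
    ``circ_ids[j]``.  Row vectors are the disease interaction profiles and
    column vectors the circRNA interaction profiles used by the Gaussian
    interaction-profile kernel.
    """

    disease_ids: list[str]
    circ_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.disease_ids, "disease")
        _check_unique(self.circ_ids, "circRNA")
        if self.values.shape != (len(self.disease_ids), len(self.circ_ids)):
            raise ValidationError("matrix shape does not match identifier lists")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValidationError("association entries must be 0 or 1")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.disease_ids), list(self.circ_ids), self.values.copy()
        )

    def positives(self) -> list[tuple[int, int]]:
        """Index pairs (row, col) of all known associations."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass
class SimilarityMatrix:
    """Square symmetric entity-similarity matrix with entries in [0, 1]."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.ids, "entity")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("similarity matrix is not square with matching ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite similarity entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-9:
            raise ValidationError("similarity matrix is not symmetric")
        if self.values.min(initial=1.0) < -_RANGE_TOL or self.values.max(initial=0.0) > 1 + _RANGE_TOL:
            raise ValidationError("similarity entries outside [0, 1]")
        if n and np.abs(np.diag(self.values) - 1.0).max() > _RANGE_TOL:
            raise ValidationError("similarity diagonal must be 1")


@dataclass
class TermMap:
    """Entity -> set of annotation identifiers, with the corpus term count.

    Used both for circRNA GO-style annotation sets and for disease gene sets.
    ``universe_size`` is the number of distinct terms in the whole corpus and
    is the denominator of the information-content probabilities.
    """

    mapping: dict[str, frozenset[str]]
    universe_size: int

    def __post_init__(self) -> None:
        self.mapping = {k: frozenset(v) for k, v in self.mapping.items()}
        observed = set().union(*self.mapping.values()) if self.mapping else set()
        if self.universe_size < len(observed):
            raise ValidationError(
                f"universe_size {self.universe_size} smaller than "
                f"{len(observed)} observed distinct terms"
            )

    def get(self, entity: str) -> frozenset[str]:
        return self.mapping.get(entity, frozenset())


@dataclass
class SequenceSet:
    """circRNA id -> nucleotide sequence over {A, C, G, T, N}."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.mapping.items():
            if not seq:
                raise ValidationError(f"empty sequence for {name!r}")
            if set(seq) - set("ACGTN"):
                raise ValidationError(f"invalid characters in sequence {name!r}")

    def get(self, entity: str) -> str | None:
        return self.mapping.get(entity)


@dataclass
class ScoreMatrix:
    """Real-valued disease x circRNA recommendation scores."""

    disease_ids: list[str]
    circ_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (len(self.disease_ids), len(self.circ_ids)):
            raise ValidationError("score matrix shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite scores")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("negative scores")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline.

    alpha      weight of annotation similarity vs sequence similarity in the
               circRNA fallback fusion (0..1)
    beta       weight of gene-set Jaccard vs imported semantic similarity in
               the disease fallback fusion (0..1)
    gamma      balance between disease-based and circRNA-based recommendation
               scores; the string "auto" resolves to N_c / (N_d + N_c)
    k_fraction fraction of entities kept as nearest neighbors on each side
    gamma_hat_c, gamma_hat_d
               bandwidth bases of the Gaussian interaction-profile kernels
    match, mismatch, gap_open, gap_extend
               global-alignment scoring (gap_open is charged on a gap's first
               position, gap_extend on each subsequent position)
    strict_fcod
               use the strict co-dedication count in the importance
               coefficient (diseases associated with exactly the two
               circRNAs) instead of the plain co-association count
    cold_start enable the importance-weighted cold-start scorer
    threshold  fixed classification threshold for the confusion metrics;
               None picks the threshold maximizing the f-measure
    """

    alpha: float = 0.5
    beta: float = 0.5
    gamma: float | str = "auto"
    k_fraction: float = 0.04
    gamma_hat_c: float = 1.0
    gamma_hat_d: float = 1.0
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5
    strict_fcod: bool = False
    cold_start: bool = True
    threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.gamma != "auto" and not 0.0 <= float(self.gamma) <= 1.0:
            raise ValidationError(f"gamma must be in [0, 1] or 'auto', got {self.gamma}")
        if not 0.0 < self.k_fraction <= 1.0:
            raise ValidationError("k_fraction must be in (0, 1]")
        if self.gamma_hat_c <= 0 or self.gamma_hat_d <= 0:
            raise ValidationError("GIP bandwidth bases must be positive")

    def resolve_gamma(self, n_diseases: int, n_circ: int) -> float:
        """Resolve the recommendation balance factor.

        "auto" yields N_c / (N_d + N_c) so that neither side's score scale
        biases the fusion.
        """
        if self.gamma == "auto":
            return n_circ / (n_diseases + n_circ)
        return float(self.gamma)


@dataclass
class EvaluationResult:
    """ROC points, AUC, threshold metrics and top-k hit counts."""

    roc_points: np.ndarray
    auc: float
    precision: float
    recall: float
    f_measure: float
    accuracy: float
    hits_at_k: dict[int, int] = field(default_factory=dict)
    threshold: float = float("nan")

    def validate(self) -> None:
        pts = np.asarray(self.roc_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("roc_points must be an (m, 2) array")
        if np.any(np.diff(pts, axis=0) < -1e-12):
            raise ValidationError("roc_points must be monotone non-decreasing")
        if not (np.allclose(pts[0], (0, 0)) and np.allclose(pts[-1], (1, 1))):
            raise ValidationError("roc_points must run from (0,0) to (1,1)")
        area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
        if abs(area - self.auc) > 1e-9:
            raise ValidationError("auc does not equal the trapezoidal ROC area")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            lines.append((lineno, line))
    return lines


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a two-column (disease id, circRNA id) association list.

    Tab or comma delimited, auto-detected from the first data line.  Lines
    starting with ``#`` are comments.  Label order is first-appearance order;
    duplicate pairs collapse.
    """
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: no association records")
    delim = _detect_delimiter(lines[0][1])
    diseases: dict[str, int] = {}
    circs: dict[str, int] = {}
    pairs: list[tuple[str, str]] = []
    for lineno, line in lines:
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected two delimited fields")
        d, c = fields[0], fields[1]
        diseases.setdefault(d, len(diseases))
        circs.setdefault(c, len(circs))
        pairs.append((d, c))
    values = np.zeros((len(diseases), len(circs)))
    for d, c in pairs:
        values[diseases[d], circs[c]] = 1.0
    return AssociationMatrix(list(diseases), list(circs), values)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read circRNA sequences; uppercases and maps U to T.

    The record id is the first whitespace-delimited token of the header.
    Duplicate ids, empty sequences and characters outside {A,C,G,T,U,N} are
    rejected.
    """
    mapping: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if record.id in mapping:
            raise ParseError(f"{path}: duplicate sequence id {record.id!r}")
        if not seq:
            raise ParseError(f"{path}: empty sequence for {record.id!r}")
        bad = set(seq) - set("ACGTUN")
        if bad:
            raise ParseError(
                f"{path}: invalid characters {sorted(bad)} in {record.id!r}"
            )
        mapping[record.id] = seq.replace("U", "T")
    return SequenceSet(mapping)


def read_term_map(path: str | Path, universe_size: int | None = None) -> TermMap:
    """Read a two-column (entity id, term id) file into per-entity term sets.

    ``universe_size`` overrides the corpus size; by default it is the number
    of distinct terms observed in the file.
    """
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: no term records")
    delim = _detect_delimiter(lines[0][1])
    mapping: dict[str, set[str]] = {}
    terms: set[str] = set()
    for lineno, line in lines:
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"{path}:{lineno}: expected two delimited fields")
        mapping.setdefault(fields[0], set()).add(fields[1])
        terms.add(fields[1])
    size = len(terms) if universe_size is None else universe_size
    return TermMap({k: frozenset(v) for k, v in mapping.items()}, size)


def _read_frame(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    return pd.read_csv(path, sep=_detect_delimiter(first), index_col=0)


def read_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a dense labeled similarity matrix.

    Row and column labels must match.  Asymmetries below 1e-6 are averaged
    away; anything larger is an error, as are entries outside [0, 1].
    """
    frame = _read_frame(path)
    ids = [str(i) for i in frame.index]
    cols = [str(c) for c in frame.columns]
    if ids != cols:
        raise ParseError(f"{path}: row and column labels differ")
    values = frame.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ParseError(f"{path}: matrix is not square")
    asym = np.abs(values - values.T).max(initial=0.0)
    if asym >= _SYMMETRY_TOL:
        raise ParseError(f"{path}: asymmetry {asym:.3g} exceeds tolerance")
    values = (values + values.T) / 2.0
    if values.min(initial=1.0) < -_RANGE_TOL or values.max(initial=0.0) > 1 + _RANGE_TOL:
        raise ParseError(f"{path}: entries outside [0, 1]")
    values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(ids, values)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write a labeled dense similarity matrix as TSV (17 significant digits,
    so that a write/read round trip is exact to 1e-12)."""
    frame = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    """Write a labeled dense disease x circRNA score matrix as TSV."""
    frame = pd.DataFrame(
        scores.values, index=scores.disease_ids, columns=scores.circ_ids
    )
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_scores(path: str | Path) -> ScoreMatrix:
    frame = _read_frame(path)
    return ScoreMatrix(
        [str(i) for i in frame.index],
        [str(c) for c in frame.columns],
        frame.to_numpy(dtype=float),
    )


def rank_candidate_pairs(
    scores: ScoreMatrix, associations: AssociationMatrix
) -> list[tuple[str, str, float, int]]:
    """Rank all candidate (unknown) pairs by descending score.

    Only cells with no known association are candidates.  Ties break by
    (disease id, circRNA id) lexicographic order so the ranking is
    deterministic.  Ranks are 1-based.
    """
    if (
        scores.disease_ids != associations.disease_ids
        or scores.circ_ids != associations.circ_ids
    ):
        raise ValidationError("score and association labels differ")
    rows, cols = np.nonzero(associations.values == 0)
    records = [
        (scores.disease_ids[r], scores.circ_ids[c], float(scores.values[r, c]))
        for r, c in zip(rows.tolist(), cols.tolist())
    ]
    records.sort(key=lambda rec: (-rec[2], rec[0], rec[1]))
    return [(d, c, s, rank) for rank, (d, c, s) in enumerate(records, start=1)]


def write_ranked_predictions(
    scores: ScoreMatrix, associations: AssociationMatrix, path: str | Path
) -> None:
    """Write (disease_id, circ_id, score, rank) for all unknown pairs."""
    ranked = rank_candidate_pairs(scores, associations)
    with open(path, "w") as fh:
        fh.write("disease_id\tcirc_id\tscore\trank\n")
        for d, c, s, rank in ranked:
            fh.write(f"{d}\t{c}\t{_FLOAT_FMT % s}\t{rank}\n")
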