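"""Neighborhood collaborative filtering with importance-weighted cold start.

Scoring a candidate disease-circRNA pair proceeds in five steps: pick the
top-k most similar neighbors of every circRNA and of every disease, average
each side's neighbor evidence into a circRNA-based (CRS) and a disease-based
(DRS) score matrix, and fuse the two with a balance factor gamma.  circRNAs
with at most one known association carry too little profile information for
plain neighborhood averaging ("cold start"); their circRNA-side scores are
replaced by an importance-weighted sum over co-associated circRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import (
    AssociationMatrix,
    PipelineConfig,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
)

__all__ = [
    "NeighborTable",
    "resolve_k",
    "top_k_neighbors",
    "circ_based_scores",
    "disease_based_scores",
    "importance",
    "importance_matrix",
    "cold_start_scores",
    "integrate_scores",
    "predict",
]

COLD_DEGREE = 1  # training degree at or below which a circRNA counts as cold


@dataclass
class NeighborTable:
    """Per-entity top-k neighbor lists.

    ``indices[i]`` holds the k most similar neighbors of entity i in
    descending-similarity order (ties broken by ascending index, self
    excluded); ``similarities`` the matching similarity values.
    """

    indices: np.ndarray
    similarities: np.ndarray

    def __post_init__(self) -> None:
        if self.indices.shape != self.similarities.shape or self.indices.ndim != 2:
            raise ValidationError("neighbor index/similarity shapes differ")
        if self.indices.shape[1] < 1:
            raise ValidationError("neighbor lists must have k >= 1")
        if np.any(self.indices == np.arange(len(self.indices))[:, None]):
            raise ValidationError("an entity cannot be its own neighbor")
        if np.any(np.diff(self.similarities, axis=1) > 1e-12):
            raise ValidationError("neighbor similarities must be non-increasing")

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def resolve_k(n: int, k_fraction: float) -> int:
    """Neighborhood size as a fraction of the entity count.

    k = ceil(k_fraction * n), at least 1 and at most n - 1.
    """
    if n < 2:
        raise ValidationError("need at least two entities to pick neighbors")
    if not 0.0 < k_fraction <= 1.0:
        raise ValidationError("k_fraction must be in (0, 1]")
    return min(max(1, math.ceil(k_fraction * n)), n - 1)


def top_k_neighbors(S: SimilarityMatrix, k: int) -> NeighborTable:
    """The k most similar neighbors of every entity, self excluded."""
    n = len(S.ids)
    if not 1 <= k <= n - 1:
        raise ValidationError(f"k={k} out of range for {n} entities")
    masked = S.values.copy()
    np.fill_diagonal(masked, -np.inf)
    # stable sort on -sim preserves ascending index order among ties
    order = np.argsort(-masked, axis=1, kind="stable")[:, :k]
    sims = np.take_along_axis(S.values, order, axis=1)
    return NeighborTable(order, sims)


def _neighbor_weight_matrix(S: SimilarityMatrix, k: int) -> np.ndarray:
    """W[n, j] = S(n, j) if n is a top-k neighbor of j, else 0."""
    table = top_k_neighbors(S, k)
    n = len(S.ids)
    W = np.zeros((n, n))
    cols = np.repeat(np.arange(n), k)
    W[table.indices.ravel(), cols] = table.similarities.ravel()
    return W


def circ_based_scores(
    A: AssociationMatrix, CS: SimilarityMatrix, k: int
) -> ScoreMatrix:
    """circRNA-side neighborhood scores.

    CRS(i, j) = (1/k) * sum over the top-k neighbors n of circRNA j of
    A(i, n) * CS(n, j): the average similarity-weighted association evidence
    that disease i has with j's neighborhood.
    """
    if CS.ids != A.circ_ids:
        raise ValidationError("circRNA similarity ids differ from association ids")
    W = _neighbor_weight_matrix(CS, k)
    values = (A.values @ W) / k
    return ScoreMatrix(list(A.disease_ids), list(A.circ_ids), values)


def disease_based_scores(
    A: AssociationMatrix, DS: SimilarityMatrix, k: int
) -> ScoreMatrix:
    """Disease-side neighborhood scores.

    DRS(i, j) = (1/k) * sum over the top-k neighbors m of disease i of
    DS(i, m) * A(m, j).
    """
    if DS.ids != A.disease_ids:
        raise ValidationError("disease similarity ids differ from association ids")
    W = _neighbor_weight_matrix(DS, k)
    values = (W.T @ A.values) / k
    return ScoreMatrix(list(A.disease_ids), list(A.circ_ids), values)


def importance_matrix(A: AssociationMatrix, strict: bool = False) -> np.ndarray:
    """IMP[t, i]: importance of circRNA i as a recommender for circRNA t.

    IMP(t, i) = f_exp(t) * f_ns(i) * n_cod(t, i) where

    * f_exp(t) = 1 / |D(t)| rewards sparsely associated query circRNAs
      (0 when t has no associations at all),
    * f_ns(i) = 1 / (|D(i)| - |I(t, i)| + 1) discounts neighbors whose
      associations mostly lie outside the shared set,
    * n_cod(t, i) = |I(t, i)|, the number of diseases associated with both
      circRNAs -- or, with ``strict=True``, only diseases associated with
      exactly those two circRNAs.

    The diagonal is zero; the coefficient is only defined between distinct
    circRNAs.
    """
    deg = A.values.sum(axis=0)
    inter = A.values.T @ A.values  # |D(t) & D(i)|
    if strict:
        pair_rows = A.values[A.values.sum(axis=1) == 2]
        n_cod = pair_rows.T @ pair_rows if len(pair_rows) else np.zeros_like(inter)
    else:
        n_cod = inter
    with np.errstate(divide="ignore"):
        f_exp = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    f_ns = 1.0 / (deg[None, :] - inter + 1.0)
    imp = f_exp[:, None] * f_ns * n_cod
    np.fill_diagonal(imp, 0.0)
    return imp


def importance(
    A: AssociationMatrix, i: int, j: int, strict: bool = False
) -> float:
    """Importance coefficient between circRNAs i (query) and j (neighbor)."""
    if i == j:
        raise ValidationError("importance is undefined for a circRNA with itself")
    return float(importance_matrix(A, strict=strict)[i, j])


def cold_start_scores(
    A: AssociationMatrix, CS: SimilarityMatrix, strict: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Importance-weighted scores for cold circRNA columns.

    A circRNA is cold when its training degree is at most ``COLD_DEGREE``.
    For a cold circRNA t and disease d the score is

        sum over circRNAs i != t with A(d, i) = 1 of IMP(t, i) * CS(t, i)

    i.e. every circRNA co-associated with d recommends t in proportion to
    its importance and similarity.  Returns (scores, cold_mask) where
    ``scores`` is a full disease x circRNA array that is zero outside cold
    columns.
    """
    if CS.ids != A.circ_ids:
        raise ValidationError("circRNA similarity ids differ from association ids")
    deg = A.values.sum(axis=0)
    cold = deg <= COLD_DEGREE
    scores = np.zeros_like(A.values, dtype=float)
    if cold.any():
        imp = importance_matrix(A, strict=strict)
        weights = imp[cold] * CS.values[cold]  # (n_cold, n_circ)
        scores[:, cold] = A.values @ weights.T
    return scores, cold


def integrate_scores(
    CRS: ScoreMatrix, DRS: ScoreMatrix, gamma: float
) -> ScoreMatrix:
    """Fuse the two score channels: IRS = gamma * DRS + (1 - gamma) * CRS."""
    if CRS.values.shape != DRS.values.shape:
        raise ValidationError("score matrices have mismatched shapes")
    if not 0.0 <= gamma <= 1.0:
        raise ValidationError("gamma must be in [0, 1]")
    values = gamma * DRS.values + (1.0 - gamma) * CRS.values
    return ScoreMatrix(list(CRS.disease_ids), list(CRS.circ_ids), values)


def predict(
    A: AssociationMatrix,
    CS: SimilarityMatrix,
    DS: SimilarityMatrix,
    config: PipelineConfig | None = None,
) -> ScoreMatrix:
    """Full recommendation pipeline for one training matrix.

    Resolves a neighborhood size per side, computes both score channels,
    substitutes the cold-start scores on cold circRNA columns of the circRNA
    channel, and fuses with the (possibly auto-resolved) balance factor.
    Known-association cells keep their computed scores; masking them is the
    evaluator's concern.
    """
    config = config or PipelineConfig()
    k_c = resolve_k(A.n_circ, config.k_fraction)
    k_d = resolve_k(A.n_diseases, config.k_fraction)
    CRS = circ_based_scores(A, CS, k_c)
    DRS = disease_based_scores(A, DS, k_d)
    if config.cold_start:
        cold_values, cold = cold_start_scores(A, CS, strict=config.strict_fcod)
        crs_values = CRS.values.copy()
        crs_values[:, cold] = cold_values[:, cold]
        CRS = ScoreMatrix(list(CRS.disease_ids), list(CRS.circ_ids), crs_values)
    gamma = config.resolve_gamma(A.n_diseases, A.n_circ)
    return integrate_scores(CRS, DRS, gamma)
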