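"""circRNA similarity networks: annotation-based, sequence-based, kernel-based.

Three complementary similarity matrices are computed for the circRNA side of
the bipartite network and fused into a single matrix CS:

* information-content semantic similarity over annotation-term sets,
* normalized Needleman-Wunsch global-alignment similarity over sequences,
* Gaussian interaction-profile (GIP) kernel similarity over association
  profiles.

The GIP kernel is only informative for circRNAs that have at least one known
association, so the fusion uses it where both profiles are non-empty and
falls back to a convex combination of the other two matrices elsewhere.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from Bio import Align

from .core_io import (
    AssociationMatrix,
    PipelineConfig,
    SequenceSet,
    SimilarityMatrix,
    TermMap,
    ValidationError,
)

__all__ = [
    "functional_annotation_similarity",
    "make_aligner",
    "align_global",
    "sequence_similarity",
    "gip_kernel",
    "circ_gip",
    "integrate_circ",
]


def functional_annotation_similarity(
    annotations: TermMap, ids: Sequence[str]
) -> SimilarityMatrix:
    """Information-content similarity between annotation-term sets.

    For term sets C_i, C_j with occurrence probabilities P(S) = |S| / universe:

        CFS(i, j) = 2 * log P(C_i | C_j) / (log P(C_i) + log P(C_j))

    where the numerator uses the union of the two sets.  The value is
    invariant to the log base and lies in [0, 1] because the union is never
    rarer than either set.  Pairs where either set is empty score 0; the
    degenerate case P(C_i) = P(C_j) = 1 (both sets cover the whole corpus,
    0/0) is defined as 1 by the identical-set limit.  The diagonal is 1.
    """
    if annotations.universe_size < 1:
        raise ValidationError("annotation universe must contain at least one term")
    n = len(ids)
    sets = [annotations.get(i) for i in ids]
    logp = [
        math.log(len(s) / annotations.universe_size) if s else 0.0 for s in sets
    ]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = sets[i], sets[j]
            if not si or not sj:
                continue
            denom = logp[i] + logp[j]
            if denom == 0.0:  # both sets are the full corpus
                values[i, j] = 1.0
                continue
            union = len(si | sj) / annotations.universe_size
            values[i, j] = 2.0 * math.log(union) / denom
    values += values.T
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(ids), values)


def make_aligner(config: PipelineConfig | None = None) -> Align.PairwiseAligner:
    """Global (Needleman-Wunsch) aligner with affine gaps.

    The gap-open score is charged on a gap's first position and the extend
    score on each subsequent position.  N is a wildcard scoring 0 against
    any base.
    """
    config = config or PipelineConfig()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    aligner.wildcard = "N"
    return aligner


def align_global(
    a: str, b: str, config: PipelineConfig | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Optimal global-alignment score of two sequences over {A,C,G,T,N}."""
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner(config)
    return float(aligner.score(a, b))


def sequence_similarity(
    seqs: SequenceSet, ids: Sequence[str], config: PipelineConfig | None = None
) -> SimilarityMatrix:
    """Normalized global-alignment similarity matrix.

        CSS(i, j) = NW(i, j) / sqrt(NW(i, i) * NW(j, j))

    clamped to [0, 1] (arbitrary scoring schemes can push the ratio outside
    that range).  Self-similarity is exactly 1.  Ids without a sequence get 0
    off-diagonal: the fusion then relies on the remaining evidence.
    """
    config = config or PipelineConfig()
    aligner = make_aligner(config)
    n = len(ids)
    present = [i for i in range(n) if seqs.get(ids[i]) is not None]
    self_scores = np.zeros(n)
    for i in present:
        seq = seqs.get(ids[i])
        self_scores[i] = aligner.score(seq, seq)
        if self_scores[i] <= 0:
            raise ValidationError(
                f"degenerate scoring: self-alignment of {ids[i]!r} is not positive"
            )
    values = np.zeros((n, n))
    for ii, i in enumerate(present):
        si = seqs.get(ids[i])
        for j in present[ii + 1 :]:
            raw = aligner.score(si, seqs.get(ids[j]))
            values[i, j] = raw / math.sqrt(self_scores[i] * self_scores[j])
    values += values.T
    np.clip(values, 0.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(ids), values)


def gip_kernel(profiles: np.ndarray, gamma_hat: float) -> np.ndarray:
    """Gaussian interaction-profile kernel over binary profile vectors.

    With profiles V_1..V_N as the rows of ``profiles``:

        gamma = gamma_hat / ((1/N) * sum_i ||V_i||^2)
        K(i, j) = exp(-gamma * ||V_i - V_j||^2)

    The bandwidth is normalized by the mean squared profile norm so the
    kernel scale is invariant to the overall association density.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValidationError("profiles must be a 2-D array")
    if gamma_hat <= 0:
        raise ValidationError("gamma_hat must be positive")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValidationError("all profiles are zero; kernel bandwidth undefined")
    gamma = gamma_hat / mean_sq
    gram = profiles @ profiles.T
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * gram
    np.clip(sq_dist, 0.0, None, out=sq_dist)
    kernel = np.exp(-gamma * sq_dist)
    kernel = (kernel + kernel.T) / 2.0
    np.fill_diagonal(kernel, 1.0)
    return kernel


def circ_gip(A: AssociationMatrix, gamma_hat: float = 1.0) -> SimilarityMatrix:
    """GIP kernel similarity between circRNAs.

    A circRNA's interaction profile is its column of the association matrix
    (which diseases it is linked to).
    """
    kernel = gip_kernel(A.values.T, gamma_hat)
    return SimilarityMatrix(list(A.circ_ids), kernel)


def integrate_circ(
    CGS: SimilarityMatrix,
    CFS: SimilarityMatrix,
    CSS: SimilarityMatrix,
    alpha: float,
    A: AssociationMatrix,
) -> SimilarityMatrix:
    """Fuse the three circRNA similarity matrices into CS.

    Where both circRNAs have at least one known association their kernel
    similarity is used directly; otherwise the kernel carries no signal and
    the fused value is ``alpha * CFS + (1 - alpha) * CSS``.
    """
    if not (CGS.ids == CFS.ids == CSS.ids == A.circ_ids):
        raise ValidationError("circRNA similarity inputs have mismatched ids")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    informative = A.values.sum(axis=0) > 0
    use_gip = informative[:, None] & informative[None, :]
    fallback = alpha * CFS.values + (1.0 - alpha) * CSS.values
    values = np.where(use_gip, CGS.values, fallback)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(CGS.ids), values)
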