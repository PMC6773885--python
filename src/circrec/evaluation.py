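"""Leave-one-out cross validation and performance metrics.

Each known association is withheld in turn; the association-dependent parts
of the model (both GIP kernels and the similarity fusions) are recomputed on
the training matrix so no information about the held-out edge leaks into the
similarity networks, and the pipeline scores the withheld pair.  All unknown
pairs are scored once from the full-data model and serve as the negative set.
A threshold sweep over the pooled scores yields the ROC curve; ties are
handled in the Mann-Whitney convention (tied pairs count one half), which the
tie-grouped threshold sweep with trapezoidal integration realizes exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .circ_similarity import circ_gip, integrate_circ
from .core_io import (
    AssociationMatrix,
    EvaluationResult,
    PipelineConfig,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
)
from .disease_similarity import disease_gip, integrate_disease
from .recommender import predict

__all__ = [
    "SideData",
    "PairScore",
    "LoocvResult",
    "fold_similarities",
    "roc_auc",
    "confusion_metrics",
    "best_f_threshold",
    "hits_at_k",
    "loocv_global",
    "loocv_per_disease",
    "per_disease_aucs",
]

DEFAULT_HIT_KS = (10, 20, 50, 100, 200)


@dataclass
class SideData:
    """Fold-invariant similarity inputs.

    Annotation-, sequence-, gene-set- and semantic-similarity matrices do not
    depend on the association matrix, so they are computed once and reused
    across folds; only the GIP kernels and the fusions are fold-specific.
    """

    CFS: SimilarityMatrix
    CSS: SimilarityMatrix
    DS1: SimilarityMatrix
    DS2: SimilarityMatrix | None = None


@dataclass
class PairScore:
    disease_id: str
    circ_id: str
    score: float


@dataclass
class LoocvResult:
    positives: list[PairScore]
    negatives: list[PairScore]
    evaluation: EvaluationResult
    full_scores: ScoreMatrix
    positive_index: list[tuple[int, int]] = field(default_factory=list)


def fold_similarities(
    A: AssociationMatrix, side: SideData, config: PipelineConfig
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Recompute the association-dependent similarity fusions for one fold.

    If the training matrix has no associations at all (a degenerate fold of a
    single-association network) the kernel bandwidth is undefined and every
    entity falls back to the association-independent similarities, so the
    kernel step is skipped entirely.
    """
    if A.values.any():
        CGS = circ_gip(A, config.gamma_hat_c)
        DGS = disease_gip(A, config.gamma_hat_d)
    else:
        CGS = SimilarityMatrix(list(A.circ_ids), np.eye(A.n_circ))
        DGS = SimilarityMatrix(list(A.disease_ids), np.eye(A.n_diseases))
    CS = integrate_circ(CGS, side.CFS, side.CSS, config.alpha, A)
    DS = integrate_disease(DGS, side.DS1, side.DS2, config.beta, A)
    return CS, DS


def _model_scores(
    A: AssociationMatrix,
    side: SideData | None,
    config: PipelineConfig,
    fixed: tuple[SimilarityMatrix, SimilarityMatrix] | None = None,
) -> ScoreMatrix:
    CS, DS = fixed if fixed is not None else fold_similarities(A, side, config)
    return predict(A, CS, DS, config)


def roc_auc(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[np.ndarray, float]:
    """ROC curve and trapezoidal AUC from positive and negative score lists.

    Every observed score acts as a threshold; equal scores are processed as a
    single threshold step, making the area identical to the Mann-Whitney
    statistic with ties counted one half.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("need at least one positive and one negative score")
    labels = np.r_[np.ones(pos.size), np.zeros(neg.size)]
    scores = np.r_[pos, neg]
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))


def confusion_metrics(
    pos_scores: Sequence[float],
    neg_scores: Sequence[float],
    threshold: float,
) -> tuple[float, float, float, float]:
    """(precision, recall, accuracy, f_measure) at a score threshold.

    Scores at or above the threshold are classified positive.  With no
    predicted positives the precision is reported as 0 with a warning.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("need at least one positive and one negative score")
    tp = int((pos >= threshold).sum())
    fn = pos.size - tp
    fp = int((neg >= threshold).sum())
    tn = neg.size - fp
    if tp + fp == 0:
        warnings.warn("no predicted positives at this threshold; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    f_measure = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, accuracy, f_measure


def best_f_threshold(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> float:
    """The observed score maximizing the f-measure (highest such score on ties)."""
    candidates = np.unique(np.r_[pos_scores, neg_scores])[::-1]
    best_t, best_f = float(candidates[0]), -1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in candidates:
            _, _, _, f = confusion_metrics(pos_scores, neg_scores, float(t))
            if f > best_f:
                best_t, best_f = float(t), f
    return best_t


def hits_at_k(
    scored_pairs: Sequence[PairScore],
    withheld: set[tuple[str, str]],
    ks: Sequence[int],
) -> dict[int, int]:
    """Withheld positives found in the top k of the pooled ranking.

    ``scored_pairs`` is the pooled candidate list (withheld positives at
    their fold scores plus all unknown pairs at their full-model scores);
    ranking is by descending score with (disease id, circRNA id) tie-breaks.
    """
    if any(k <= 0 for k in ks):
        raise ValidationError("hit counts require k > 0")
    ranked = sorted(
        scored_pairs, key=lambda p: (-p.score, p.disease_id, p.circ_id)
    )
    flags = np.array(
        [(p.disease_id, p.circ_id) in withheld for p in ranked], dtype=int
    )
    cum = np.cumsum(flags)
    return {int(k): int(cum[min(k, len(cum)) - 1]) if len(cum) else 0 for k in ks}


def _loocv_fold(
    A_work: AssociationMatrix,
    row: int,
    col: int,
    side: SideData | None,
    config: PipelineConfig,
    fixed: tuple[SimilarityMatrix, SimilarityMatrix] | None = None,
) -> float:
    """Score one withheld association, restoring the matrix afterwards."""
    if A_work.values[row, col] != 1.0:
        raise ValidationError("fold target is not a known association")
    A_work.values[row, col] = 0.0
    try:
        scores = _model_scores(A_work, side, config, fixed)
        return float(scores.values[row, col])
    finally:
        A_work.values[row, col] = 1.0


def loocv_global(
    A: AssociationMatrix,
    side: SideData | None = None,
    config: PipelineConfig | None = None,
    hit_ks: Sequence[int] = DEFAULT_HIT_KS,
    fixed_similarities: tuple[SimilarityMatrix, SimilarityMatrix] | None = None,
) -> LoocvResult:
    """Leave-one-out cross validation over every known association.

    ``fixed_similarities`` replaces the per-fold similarity recomputation
    with a constant (CS, DS) pair; it exists for null experiments with
    association-independent similarities and skips ``side`` entirely.
    """
    config = config or PipelineConfig()
    if side is None and fixed_similarities is None:
        raise ValidationError("either side data or fixed similarities required")
    positive_index = A.positives()
    if not positive_index:
        raise ValidationError("cross validation requires at least one association")
    full = _model_scores(A, side, config, fixed_similarities)
    neg_rows, neg_cols = np.nonzero(A.values == 0)
    negatives = [
        PairScore(A.disease_ids[r], A.circ_ids[c], float(full.values[r, c]))
        for r, c in zip(neg_rows.tolist(), neg_cols.tolist())
    ]
    work = A.copy()
    positives = []
    for r, c in positive_index:
        score = _loocv_fold(work, r, c, side, config, fixed_similarities)
        positives.append(PairScore(A.disease_ids[r], A.circ_ids[c], score))
    if not np.array_equal(work.values, A.values):
        raise ValidationError("association matrix was not restored after folds")
    pos_scores = [p.score for p in positives]
    neg_scores = [p.score for p in negatives]
    points, auc = roc_auc(pos_scores, neg_scores)
    threshold = (
        best_f_threshold(pos_scores, neg_scores)
        if config.threshold is None
        else config.threshold
    )
    precision, recall, accuracy, f_measure = confusion_metrics(
        pos_scores, neg_scores, threshold
    )
    withheld = {(p.disease_id, p.circ_id) for p in positives}
    hits = hits_at_k(positives + negatives, withheld, hit_ks)
    evaluation = EvaluationResult(
        roc_points=points,
        auc=auc,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        accuracy=accuracy,
        hits_at_k=hits,
        threshold=threshold,
    )
    return LoocvResult(positives, negatives, evaluation, full, positive_index)


def loocv_per_disease(
    A: AssociationMatrix,
    side: SideData,
    config: PipelineConfig | None = None,
    disease: str | None = None,
) -> EvaluationResult:
    """LOOCV restricted to one disease's row.

    Positives are that disease's known associations (scored by withheld
    folds); negatives are the unknown cells of the same row from the
    full-data model.
    """
    config = config or PipelineConfig()
    if disease not in A.disease_ids:
        raise ValidationError(f"unknown disease {disease!r}")
    row = A.disease_ids.index(disease)
    cols = np.nonzero(A.values[row] == 1)[0]
    if cols.size == 0:
        raise ValidationError(f"disease {disease!r} has no known associations")
    full = _model_scores(A, side, config)
    neg_scores = full.values[row, A.values[row] == 0].tolist()
    work = A.copy()
    pos_scores = [
        _loocv_fold(work, row, int(c), side, config) for c in cols
    ]
    points, auc = roc_auc(pos_scores, neg_scores)
    threshold = (
        best_f_threshold(pos_scores, neg_scores)
        if config.threshold is None
        else config.threshold
    )
    precision, recall, accuracy, f_measure = confusion_metrics(
        pos_scores, neg_scores, threshold
    )
    return EvaluationResult(
        roc_points=points,
        auc=auc,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        accuracy=accuracy,
        threshold=threshold,
    )


def per_disease_aucs(result: LoocvResult, A: AssociationMatrix) -> dict[str, float]:
    """Per-disease AUCs derived from a completed global LOOCV run.

    Fold scores do not depend on the evaluation grouping, so each disease's
    AUC can be computed from its own row's withheld-positive and
    unknown-pair scores.  Diseases whose row has no positives or no unknown
    cells are omitted.
    """
    by_disease_pos: dict[str, list[float]] = {}
    for p in result.positives:
        by_disease_pos.setdefault(p.disease_id, []).append(p.score)
    by_disease_neg: dict[str, list[float]] = {}
    for p in result.negatives:
        by_disease_neg.setdefault(p.disease_id, []).append(p.score)
    aucs = {}
    for d in A.disease_ids:
        if d in by_disease_pos and d in by_disease_neg:
            _, auc = roc_auc(by_disease_pos[d], by_disease_neg[d])
            aucs[d] = auc
    return aucs
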