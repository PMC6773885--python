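"""Disease similarity networks: gene-set Jaccard, GIP kernel, imported semantic.

The disease side mirrors the circRNA side: a Gaussian interaction-profile
kernel over association profiles is used wherever both diseases have known
associations, with a convex combination of gene-set Jaccard similarity and an
externally computed ontology semantic-similarity matrix as the fallback.
The semantic matrix (e.g. produced by a Disease-Ontology tool) is consumed
as-is; its computation is outside this package.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .circ_similarity import gip_kernel
from .core_io import AssociationMatrix, SimilarityMatrix, TermMap, ValidationError

__all__ = ["jaccard_functional", "disease_gip", "integrate_disease"]


def jaccard_functional(gene_map: TermMap, ids: Sequence[str]) -> SimilarityMatrix:
    """Jaccard similarity between disease gene sets.

    DS1(i, j) = |DG(i) & DG(j)| / |DG(i) | DG(j)|; pairs where both sets are
    empty score 0 off-diagonal, and the diagonal is 1.
    """
    n = len(ids)
    sets = [gene_map.get(i) for i in ids]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            if union:
                values[i, j] = len(sets[i] & sets[j]) / len(union)
    values += values.T
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(ids), values)


def disease_gip(A: AssociationMatrix, gamma_hat: float = 1.0) -> SimilarityMatrix:
    """GIP kernel similarity between diseases (row profiles of A)."""
    kernel = gip_kernel(A.values, gamma_hat)
    return SimilarityMatrix(list(A.disease_ids), kernel)


def integrate_disease(
    DGS: SimilarityMatrix,
    DS1: SimilarityMatrix,
    DS2: SimilarityMatrix | None,
    beta: float,
    A: AssociationMatrix,
) -> SimilarityMatrix:
    """Fuse the disease similarity matrices into DS.

    Kernel similarity where both diseases have at least one known
    association, otherwise ``beta * DS1 + (1 - beta) * DS2``.  If no semantic
    matrix is supplied the fallback is DS1 alone regardless of beta.
    """
    if DGS.ids != A.disease_ids or DS1.ids != A.disease_ids:
        raise ValidationError("disease similarity inputs have mismatched ids")
    if DS2 is not None and DS2.ids != A.disease_ids:
        raise ValidationError("semantic similarity ids differ from association ids")
    if not 0.0 <= beta <= 1.0:
        raise ValidationError("beta must be in [0, 1]")
    informative = A.values.sum(axis=1) > 0
    use_gip = informative[:, None] & informative[None, :]
    if DS2 is None:
        fallback = DS1.values
    else:
        fallback = beta * DS1.values + (1.0 - beta) * DS2.values
    values = np.where(use_gip, DGS.values, fallback)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(DGS.ids), values)
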