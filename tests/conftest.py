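import numpy as np
import pytest

from circrec.circ_similarity import (
    functional_annotation_similarity,
    sequence_similarity,
)
from circrec.core_io import AssociationMatrix, PipelineConfig, SimilarityMatrix
from circrec.disease_similarity import jaccard_functional
from circrec.evaluation import SideData
from circrec.synthetic import PlantedDesign, generate_dataset


def build_side_data(data, config=None):
    """Fold-invariant similarity matrices for a synthetic dataset."""
    config = config or PipelineConfig()
    A = data.associations
    return SideData(
        CFS=functional_annotation_similarity(data.circ_annotations, A.circ_ids),
        CSS=sequence_similarity(data.sequences, A.circ_ids, config),
        DS1=jaccard_functional(data.disease_genes, A.disease_ids),
        DS2=data.semantic,
    )


def random_similarity(rng, ids):
    """A valid but arbitrary similarity matrix (for null experiments)."""
    n = len(ids)
    values = rng.random((n, n))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(ids), values)


@pytest.fixture
def tiny_A():
    """2 diseases x 3 circRNAs with hand-checkable structure."""
    return AssociationMatrix(
        ["d1", "d2"], ["c1", "c2", "c3"], np.array([[1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
    )


@pytest.fixture(scope="session")
def small_design():
    """A small planted design that keeps end-to-end tests fast."""
    return PlantedDesign(
        n_diseases=10,
        n_circ=30,
        n_blocks=2,
        p_in=0.5,
        p_out=0.03,
        seq_length=60,
        n_terms=60,
        terms_per_entity=6,
        n_genes=60,
        genes_per_entity=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return generate_dataset(small_design)


@pytest.fixture(scope="session")
def small_side(small_dataset):
    return build_side_data(small_dataset)


@pytest.fixture(scope="session")
def planted_dataset():
    """The default planted benchmark (seed 1), shared across expensive tests."""
    return generate_dataset(PlantedDesign(seed=1))


@pytest.fixture(scope="session")
def planted_side(planted_dataset):
    return build_side_data(planted_dataset)
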