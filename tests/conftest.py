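import numpy as np
import pytest

from phenoaug import ExpressionDataset, FixtureSpec, SignatureSet, simulate_cohort


@pytest.fixture(scope="session")
def cms_fixture():
    """Small 4-class signature-structured count cohort (CMS-style panel)."""
    spec = FixtureSpec(
        n_classes=4, genes_per_signature=10, class_sizes=(30, 50, 20, 40),
        rng_seed=7,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def overlap_fixture():
    """3-class cohort where the first two signatures share two genes."""
    spec = FixtureSpec(
        n_classes=3, genes_per_signature=10, class_sizes=(40, 50, 60),
        overlap_genes=2, rng_seed=13,
    )
    return simulate_cohort(spec)


@pytest.fixture
def two_class_dataset():
    """Deterministic 2-class, 2-blocks-of-2-genes count dataset.

    Values are distinct across cells so block donors can be identified from
    values alone.
    """
    matrix = np.array([
        [1, 2, 3, 4],
        [5, 6, 7, 8],
        [9, 10, 11, 12],
        [13, 14, 15, 16],
        [17, 18, 19, 20],
        [21, 22, 23, 24],
    ], dtype=float)
    ds = ExpressionDataset(
        matrix=matrix,
        sample_ids=[f"s{i}" for i in range(6)],
        gene_ids=["a1", "a2", "b1", "b2"],
        labels=["A", "A", "A", "B", "B", "B"],
        scale="counts",
    )
    sigs = SignatureSet(classes=["A", "B"], blocks={"A": ["a1", "a2"], "B": ["b1", "b2"]})
    return ds, sigs
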