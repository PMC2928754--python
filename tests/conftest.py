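import numpy as np
import pandas as pd
import pytest

from popvar.containers import ExpressionMatrix
from popvar.outliers import reciprocal_outliers
from popvar.simulate import SimulationConfig, generate_all
from popvar.variability import (
    build_profile,
    filter_low_expression,
    median_normalize,
)


@pytest.fixture(scope="session")
def dataset():
    """One medium synthetic study shared by planted-signal tests."""
    return generate_all(SimulationConfig(n_genes=2000, seed=11))


@pytest.fixture(scope="session")
def profile(dataset):
    mats = median_normalize(
        filter_low_expression([dataset.matrix_a, dataset.matrix_b])
    )
    return build_profile(mats)


@pytest.fixture(scope="session")
def partition(profile):
    return reciprocal_outliers(profile, "popA", "popB")


@pytest.fixture()
def tiny_matrix_pair():
    """3 genes x 2+2 samples with exactly known values."""
    genes = pd.Index(["g1", "g2", "g3"], name="gene_id")
    a = ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 3.0], [10.0, 10.0], [2.0, 6.0]],
            index=genes,
            columns=["a1", "a2"],
        ),
        "popA",
    )
    b = ExpressionMatrix(
        pd.DataFrame(
            [[2.0, 2.0], [8.0, 12.0], [4.0, 4.0]],
            index=genes,
            columns=["b1", "b2"],
        ),
        "popB",
    )
    return a, b
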