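import numpy as np
import pytest

from craft.core_io import ExpressionMatrix, SampleTable


def make_expr(values, gene_prefix="G", sample_prefix="S") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(1, values.shape[0] + 1)]
    samples = [f"{sample_prefix}{j}" for j in range(1, values.shape[1] + 1)]
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expr(rng) -> ExpressionMatrix:
    """12 genes x 10 samples of noise, no structure."""
    return make_expr(rng.normal(size=(12, 10)))


@pytest.fixture
def case_control_samples() -> SampleTable:
    ids = [f"case_{i}" for i in range(1, 7)] + [f"ctrl_{i}" for i in range(1, 7)]
    conditions = ["case"] * 6 + ["control"] * 6
    traits = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0] + [np.nan] * 6)
    return SampleTable(ids, conditions, traits)
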