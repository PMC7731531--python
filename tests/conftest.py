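import numpy as np
import pandas as pd
import pytest

from smtransfer.features import ExpressionMatrix
from smtransfer.synth import SynthConfig, generate_world

FAST_GRID = {"n_estimators": [50], "max_depth": [None], "max_features": ["sqrt"]}


@pytest.fixture(scope="session")
def small_world():
    """A small but signal-rich two-species world reused across tests."""
    cfg = SynthConfig(
        n_genes_source=600,
        n_genes_target=600,
        n_informative_shared=30,
        benchmark_n=40,
        seed=42,
    )
    return generate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def expr_matrix(rng):
    """Random 12-gene x 9-sample expression matrix in three dataset groups."""
    genes = [f"g{i}" for i in range(12)]
    samples = [f"s{j}" for j in range(9)]
    values = pd.DataFrame(
        rng.gamma(shape=2.0, scale=5.0, size=(12, 9)), index=genes, columns=samples
    )
    groups = pd.Series(
        ["dev"] * 3 + ["hormone"] * 3 + ["stress"] * 3, index=samples
    )
    return ExpressionMatrix(values=values, groups=groups)
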