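import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from regmodnet import ExpressionMatrix, NetworkParams
from regmodnet.simulate import generate_planted_network

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ds():
    """A small planted network reused across test modules (3 modules × 10
    genes, 16 conditions, depth-2 trees)."""
    return generate_planted_network(
        n_modules=3, genes_per_module=10, n_background_genes=6,
        n_conditions=16, n_tfs=8, depth=2, seed=11,
    )


@pytest.fixture(scope="session")
def fit_params():
    """Fitting knobs matched to the planted generator (depth-2 trees)."""
    return NetworkParams(max_depth=2)


@pytest.fixture
def log_matrix():
    """Tiny deterministic log-scale matrix for formula-level tests."""
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        rng.normal(0, 1, size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"c{j}" for j in range(8)],
    )
    return ExpressionMatrix(df, "log")
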