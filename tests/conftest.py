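import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cdome.expression import ExpressionMatrix, Status

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 cells x 3 molecules with every status represented."""
    grid = pd.DataFrame(
        [
            [Status.POSITIVE, Status.NEGATIVE, Status.UNKNOWN],
            [Status.POSITIVE, Status.POSITIVE, Status.NEGATIVE],
            [Status.UNKNOWN, Status.NEGATIVE, Status.POSITIVE],
        ],
        index=["cellA", "cellB", "cellC"],
        columns=["CD1", "CD2", "CD3"],
        dtype=np.int8,
    )
    return ExpressionMatrix(grid)


def random_ternary_matrix(rng, n_cells, n_mols):
    grid = rng.choice([-1, 0, 1], size=(n_cells, n_mols))
    return ExpressionMatrix(
        pd.DataFrame(
            grid.astype(np.int8),
            index=[f"cell{i}" for i in range(n_cells)],
            columns=[f"CD{j}" for j in range(n_mols)],
        )
    )
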