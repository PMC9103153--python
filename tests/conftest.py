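import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cernet import ExpressionMatrix, SpongeSimConfig, simulate_cerna_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def small_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples with exact linear relations to the lncRNA row."""
    lnc = np.array([1.0, 2.0, 0.5, 3.0, 2.5, 1.5])
    data = pd.DataFrame(
        {
            f"S{i + 1}": col
            for i, col in enumerate(
                np.vstack(
                    [
                        lnc,
                        lnc + 5.0,          # shifted copy, r = 1
                        -lnc,               # negated, r = -1
                        [0.3, -1.2, 0.7, 2.1, -0.4, 0.9],
                    ]
                ).T
            )
        },
        index=["LNC", "SHIFT", "NEG", "NOISE"],
    )
    return ExpressionMatrix(data=data, lnc_id="LNC")


@pytest.fixture(scope="session")
def default_sponge_dataset():
    """One dataset at the default planted-sponge conditions (seed 0)."""
    return simulate_cerna_dataset(SpongeSimConfig())
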