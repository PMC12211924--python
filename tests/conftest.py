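import numpy as np
import pandas as pd
import pytest

from airses import cohort as sc


@pytest.fixture(scope="session")
def panel_20k() -> pd.DataFrame:
    """Default-parameter pollutant panel shared across tests."""
    return sc.generate_pollutants(20000, seed=101)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest full cohort with a known high-risk effect on AMD."""
    cfg = sc.CohortConfig(
        n=6000,
        seed=202,
        log_hr={"T3xlow": [np.log(1.5), 0.0, 0.0, 0.0, 0.0]},
        tie_fraction=0.05,
    )
    return sc.generate_cohort(cfg)


def two_block_panel(n: int = 4000, seed: int = 0) -> pd.DataFrame:
    """Panel with a particulate block and a nitrogen-oxide block driven by
    two independent latent factors (used for varimax recovery checks)."""
    rng = np.random.default_rng(seed)
    f1 = rng.normal(size=n)
    f2 = rng.normal(size=n)
    noise = rng.normal(scale=0.35, size=(n, 5))
    X = np.column_stack(
        [
            10 + 1.0 * f1 + noise[:, 0],
            16 + 1.8 * f1 + noise[:, 1],
            6.4 + 0.9 * f1 + noise[:, 2],
            26 + 7.0 * f2 + noise[:, 3],
            44 + 15.0 * f2 + noise[:, 4],
        ]
    )
    return pd.DataFrame(X, columns=sc.POLLUTANTS)
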