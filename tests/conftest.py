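import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leanbone.ingest import ingest_cohort
from leanbone.simulate import SyntheticConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ENDO_COLS = [f"{v}_leg_{m}" for v in ("V0", "V3", "V5") for m in ("LM", "BMD")]


def clean_leg_config(n: int, seed: int, **overrides) -> SyntheticConfig:
    """Config with no covariate effects, dropout or flags: the pure CLPM."""
    kwargs = dict(
        n_participants=n,
        seed=seed,
        covariate_effects={},
        dropout=(0.0, 0.0, 0.0),
        side_flag_p=0.0,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-configuration cohort draw (covariates, dropout, flags on)."""
    return simulate_cohort(SyntheticConfig(n_participants=600, seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return ingest_cohort(small_cohort)


@pytest.fixture(scope="session")
def clean_leg_data():
    """Complete-case leg LM/BMD panel from the pure-CLPM generator."""
    df = simulate_cohort(clean_leg_config(3000, seed=5))
    return ingest_cohort(df, required=ENDO_COLS).data


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
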