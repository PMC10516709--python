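import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from starr_audit import ScenarioConfig, generate_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# shared scenario sizes: a mid-size bundle exercising every planted effect,
# and a small one for faster per-module checks
SMALL = dict(n_chroms=2, chrom_length=300_000, crm_count=300, peak_count=250, n_genes=150)
# calibration scenarios: large enough that category gene sets reach the
# asymptotic branch of the rank tests
CALIB = dict(
    n_chroms=1,
    chrom_length=250_000,
    crm_count=50,
    peak_count=30,
    n_genes=150,
    with_sequence=False,
    out_of_region_fraction=0.0,
)
TINY = dict(
    n_chroms=1,
    chrom_length=100_000,
    crm_count=20,
    peak_count=12,
    n_genes=60,
    with_sequence=False,
    out_of_region_fraction=0.0,
)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-size scenario at the study's default conditions."""
    return generate_scenario(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    return generate_scenario(ScenarioConfig(seed=11, **SMALL))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
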