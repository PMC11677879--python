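import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from akstage.pipeline import build_hfus_table
from akstage.synthetic import PhantomParams, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the SLEB/dermis LEP/HEP ratios of SLEB-bearing phantoms are routinely
# undefined (no low/high echogenic dermis pixels); that warning is expected
warnings.filterwarnings("ignore", message="dermis .* is zero")
warnings.filterwarnings("ignore", message=".*constant feature.*")


@pytest.fixture(scope="session")
def params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def small_cohort(params):
    """10 patients, 20 HFUS phantoms — enough for fold/feature tests."""
    return generate_cohort(
        10, (8, 6, 6), params, seed=123, with_dermoscopy=False
    )


@pytest.fixture(scope="session")
def staging_cohort(params):
    """The parameter-recovery cohort: 30 patients, 90 lesions, 30 per stage."""
    return generate_cohort(
        30, (30, 30, 30), params, seed=11, with_dermoscopy=False
    )


@pytest.fixture(scope="session")
def staging_table(staging_cohort):
    """HFUS handcrafted feature table of the parameter-recovery cohort,
    extracted from the ground-truth masks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_hfus_table(staging_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
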