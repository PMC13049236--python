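import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cvrkit.synthetic import GroundTruth, ProtocolSpec, gen_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def noiseless_params(**overrides) -> GroundTruth:
    """Generator parameters with every stochastic component switched off."""
    base = dict(
        capno_noise_sd=0.0,
        drift_amplitude=0.0,
        noise_sd={"asl": 0.0, "ge": 0.0, "se": 0.0},
        voxel_noise_sd=0.0,
        asl_sd=0.0,
        ge_sd=0.0,
        se_sd=0.0,
        petco2_rest_sd=0.0,
        petco2_modulation_sd=0.0,
        tau_ge=0.0,
        macro_subject_sd=0.0,
    )
    base.update(overrides)
    return GroundTruth(**base)


@pytest.fixture(scope="session")
def protocol() -> ProtocolSpec:
    return ProtocolSpec()


@pytest.fixture(scope="session")
def noiseless_subject(protocol):
    """One fully deterministic subject plus its cohort truth."""
    subjects, cohort = gen_cohort(1, protocol, noiseless_params(), seed=3)
    return subjects[0], cohort


@pytest.fixture(scope="session")
def default_cohort(protocol):
    """A small default-noise cohort shared across tests (read-only)."""
    subjects, cohort = gen_cohort(6, protocol, GroundTruth(), seed=11)
    return subjects, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
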