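import numpy as np
import pytest

import pahkin as pk


@pytest.fixture(scope="session")
def study_params() -> pk.KineticParams:
    """Fitted study-condition truth: k_tot=0.142, k_a=0.063 (f=0.4437), k2=0.150, S0=60."""
    return pk.STUDY_PARAMS


@pytest.fixture(scope="session")
def noiseless_design() -> pk.DesignSpec:
    return pk.DesignSpec(
        noise_sigma_parent=0.0, noise_sigma_intermediate=0.0, lod_parent=0.0, lod_intermediate=0.0
    )


@pytest.fixture(scope="session")
def noiseless_data(study_params, noiseless_design) -> pk.TimeCourseData:
    return pk.simulate_timecourse(study_params, noiseless_design)


@pytest.fixture()
def noisy_data(study_params) -> pk.TimeCourseData:
    return pk.simulate_timecourse(study_params, pk.DesignSpec(seed=42))


def random_valid_params(rng: np.random.Generator) -> pk.KineticParams:
    """A random admissible parameter vector, occasionally near the equal-rate limit."""
    k_tot = float(rng.uniform(0.02, 1.5))
    if rng.random() < 0.2:
        k2 = k_tot * (1.0 + rng.choice([-1, 1]) * 10.0 ** rng.uniform(-12, -6))
    else:
        k2 = float(rng.uniform(0.0, 1.5))
    return pk.KineticParams(
        k_tot=k_tot,
        f=float(rng.uniform(0.0, 1.0)),
        k2=k2,
        S0=float(rng.uniform(5.0, 300.0)),
        P0=float(rng.choice([0.0, rng.uniform(0.0, 5.0)])),
    )
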