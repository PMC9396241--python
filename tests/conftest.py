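import numpy as np
import pytest

from tnepredict import CohortConfig, generate_cohort
from tnepredict.synthetic_data import EyeState


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-eye default-condition cohort shared by cheap tests."""
    return generate_cohort(CohortConfig(n_eyes=40, seed=7))


def make_eye(
    eye_id="eye_test",
    baseline_volumes=None,
    decay_rate=None,
    recurrence_hazard=0.0,
    bcva_coeffs=(60.0, 0.0, 0.0),
    random_intercept=0.0,
    noise_sd=0.0,
    seed=123,
    **kwargs,
) -> EyeState:
    """Hand-built eye state with deterministic defaults for worked examples."""
    return EyeState(
        eye_id=eye_id,
        latent_class=1,
        baseline_bcva=bcva_coeffs[0],
        bcva_coeffs=bcva_coeffs,
        random_intercept=random_intercept,
        baseline_volumes=baseline_volumes
        or {"IRF": 0.0, "SRF": 0.0, "PED": 0.0, "HRF": 0.0},
        pr_baseline_thickness=45.0,
        decay_rate=decay_rate or {"IRF": 0.1, "SRF": 0.4, "PED": 0.9, "HRF": 0.5},
        recurrence_hazard=recurrence_hazard,
        age=75.0,
        sex="female",
        seed=seed,
        noise_sd=noise_sd,
        zone_weights={
            "IRF": (0.5, 0.35, 0.15),
            "SRF": (0.12, 0.43, 0.45),
            "PED": (0.25, 0.45, 0.30),
            "HRF": (0.3, 0.4, 0.3),
        },
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
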