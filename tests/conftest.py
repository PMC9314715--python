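import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from jawkin import pipeline, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

logging.getLogger("jawkin").setLevel(logging.WARNING)


@pytest.fixture
def skeleton():
    """Default three-body shark skeleton configuration."""
    return synthetic.default_skeleton()


@pytest.fixture(scope="session")
def default_tables():
    return synthetic.default_magnitudes(), synthetic.default_timings()


@pytest.fixture(scope="session")
def noisy_study():
    """The reference 12-trial synthetic study: 3 individuals x 4 trials,
    0.1 mm marker noise, base seed 1, 2 s at 320 Hz."""
    config, trials = synthetic.generate_study(base_seed=1, sigma_mm=0.1)
    return config, trials


@pytest.fixture(scope="session")
def noisy_study_results(noisy_study):
    """Pipeline results for every trial of the reference study."""
    config, trials = noisy_study
    return [pipeline.analyze_trial(config, t.trajectories) for t in trials]


@pytest.fixture(scope="session")
def noise_free_trial():
    """One noise-free trial with its ground truth (seed 7)."""
    mag, tim = synthetic.default_magnitudes(), synthetic.default_timings()
    config = synthetic.default_skeleton()
    d_up = synthetic.calibrate_upper_depression_duration(config, mag, tim)
    trial = synthetic.generate_trial(
        config, 7, magnitudes=mag, timings=tim, d_up=d_up, sigma_mm=0.0, trial_id="clean"
    )
    return config, trial


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
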