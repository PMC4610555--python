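import numpy as np
import pytest

from gaitphase import CohortDataset, GaitTemplate
from gaitphase.simulate import CohortSpec, generate_cohort, generate_trial


@pytest.fixture(scope="session")
def template() -> GaitTemplate:
    return GaitTemplate()


@pytest.fixture(scope="session")
def clean_trial(template):
    """Noise-free, jitter-free 30 s trial plus its 6P phase script."""
    rng = np.random.default_rng(7)
    return generate_trial(template, "S01", "TD", "L1.0", 1, 30.0, rng,
                          intra_sd=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_pair(template):
    """Two repetitions of one synthetic TD subject (default variability)."""
    t1, _ = generate_trial(template, "S01", "TD", "L1.0", 1, 30.0,
                           np.random.default_rng(11), intra_sd=0.03,
                           noise_sd=12.0)
    t2, _ = generate_trial(template, "S01", "TD", "L1.0", 2, 30.0,
                           np.random.default_rng(12), intra_sd=0.03,
                           noise_sd=12.0)
    return t1, t2


@pytest.fixture(scope="session")
def small_cohort() -> CohortDataset:
    """4 TD subjects, one condition, both repetitions, 20 s trials."""
    spec = CohortSpec(n_subjects=4, group="TD", conditions=("L1.0",),
                      duration_s=20.0, seed=3)
    return generate_cohort(spec)
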