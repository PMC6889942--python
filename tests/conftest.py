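import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from redoxwound.synthetic import CohortParams, CohortSimulator

settings.register_profile(
    "suite", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def small_params(**overrides) -> CohortParams:
    """A fast cohort: 96x96 frames (quarter-scale geometry), small stacks."""
    defaults = dict(seed=3, frame_shape=(96, 96), stack_shape=(10, 32, 32),
                    n_per_group=2, days=(0, 2))
    defaults.update(overrides)
    return CohortParams(**defaults)


def noise_free_params(**overrides) -> CohortParams:
    """Deterministic world: no camera noise, no lamp drift, no subject spread."""
    defaults = dict(noise_gain=0.0, read_noise_sd=0.0, lamp_drift_sigma=0.0,
                    subject_sd=0.0, coupling_slope_b=0.0, coupling_noise_sd=0.0)
    defaults.update(overrides)
    return small_params(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """One small cohort written to disk, shared by I/O and pipeline tests."""
    outdir = tmp_path_factory.mktemp("cohort")
    params = small_params()
    manifest = CohortSimulator(params).write_cohort(outdir)
    return params, manifest
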