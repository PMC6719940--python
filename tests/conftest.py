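import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# deterministic, CI-friendly hypothesis runs
settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_phantom():
    from mwdetect.phantom import make_reference_phantom
    return make_reference_phantom()


@pytest.fixture(scope="session")
def toy_cohort():
    """Small surrogate cohort with a clear class effect (toy feature size)."""
    from mwdetect.surrogate import TOY_PROFILE, CohortSpec, generate_cohort
    spec = CohortSpec(n_subjects=60, effect_amplitude=3.0, seed=11,
                      **TOY_PROFILE)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
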