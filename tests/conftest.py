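import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel136():
    from nbscreen.genomic_profiling import default_panel

    return default_panel()


@pytest.fixture(scope="session")
def panel131(panel136):
    from nbscreen.genomic_profiling import core_panel

    return core_panel(panel136)


@pytest.fixture(scope="session")
def small_config(panel136):
    """Full panel, reduced drug count: fast but structurally complete."""
    from nbscreen.synthetic_cohort import CohortConfig

    return CohortConfig(panel=tuple(panel136), n_drugs=60)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    from nbscreen.synthetic_cohort import generate_cohort

    return generate_cohort(small_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
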