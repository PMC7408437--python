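import numpy as np
import pytest

from biclustsurv import CohortSpec, PanCancerSpec, simulate_cohort, simulate_pan_cancer


@pytest.fixture(scope="session")
def small_cohort():
    """A well-separated 60-sample cohort with the default planted structure."""
    spec = CohortSpec(n_samples=60, n_genes=45, noise_sd=0.2, seed=11)
    expr, clinical, truth = simulate_cohort(spec)
    return spec, expr, clinical, truth


@pytest.fixture(scope="session")
def pan_cancer():
    spec = PanCancerSpec(seed=3)
    return (spec, *simulate_pan_cancer(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
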