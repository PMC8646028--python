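import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from icgpbpk import (  # noqa: E402
    CohortGeneratorConfig,
    ModelParameters,
    R15Surface,
    fit_map_coefficients,
    generate,
    run_scan,
    standard_bolus,
)


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def cirrhosis_scan(base_params):
    """Standard-bolus scan of the composite cirrhosis degree, step 0.05."""
    return run_scan("f_cirrhosis", np.round(np.arange(0.0, 0.91, 0.05), 10),
                    base_params, standard_bolus())


@pytest.fixture(scope="session")
def map_coeffs(cirrhosis_scan):
    return fit_map_coefficients(cirrhosis_scan)


@pytest.fixture(scope="session")
def r15_surface():
    """Shared R15(f_cirrhosis, resection_rate) interpolation surface."""
    return R15Surface.compute(step=0.05)


@pytest.fixture(scope="session")
def default_cohort(r15_surface):
    cohort, truth = generate(CohortGeneratorConfig(seed=20260923), r15_surface)
    return cohort, truth
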