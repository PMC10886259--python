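import numpy as np
import pytest
from hypothesis import settings

from y90ici import CohortSpec, ModelParameters, sample_cohort_arrays

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def small_cohort():
    """Column view of a small reproducible cohort."""
    return sample_cohort_arrays(CohortSpec(n=200, seed=42))


def init_from_arrays(arrays) -> np.ndarray:
    n = len(arrays["T0"])
    return np.stack([arrays["T0"], arrays["TNI0"], np.zeros(n), arrays["L0"]])
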