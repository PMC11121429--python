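import numpy as np
import pytest

from viewfeat.synthetic import CohortSpec, simulate_cohort


def solid(rgb, shape=(16, 16)):
    """Uniform RGB image of the given colour."""
    return np.full((*shape, 3), rgb, dtype=np.uint8)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but complete cohort exercising every injection rule."""
    spec = CohortSpec(
        n_participants=8,
        image_size=(64, 64),
        n_missing_negative_affect=1,
        n_missing_auc=1,
        seed=42,
    )
    return simulate_cohort(spec)
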