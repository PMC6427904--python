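import numpy as np
import pytest

from tumorvox.preprocess_io import MODALITIES, ModalityStack
from tumorvox.synthetic_phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_stack(rng):
    """A small random 4-modality stack with values in [0, 1]."""
    return ModalityStack(
        subject_id="rand",
        **{m: rng.random((9, 9, 9)) for m in MODALITIES},
    )


def small_phantom_spec(seed=0, cohort="HGG"):
    """A 32-cube phantom spec scaled down for fast unit tests."""
    return PhantomSpec(
        shape=(32, 32, 32),
        seed=seed,
        cohort=cohort,
        radii={
            "brain": (14.0, 14.0, 14.0),
            "edema": (10.0, 10.0, 9.5),
            "core": (7.0, 7.0, 7.0),
            "enhancing": (5.0, 5.0, 5.0),
            "necrosis": (2.5, 2.5, 2.5),
        },
    )


@pytest.fixture
def small_phantom():
    return generate_phantom(small_phantom_spec(seed=11))
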