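import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tspopet import (
    SubjectRecord,
    build_frame_schedule,
    build_phantom,
    default_phantom_spec,
)
from tspopet.pipeline import build_affinity_class_sets
from tspopet.synthetic import DEFAULT_FRAME_SPEC


@pytest.fixture(scope="session")
def schedule32():
    """The 60-min, 32-frame acquisition schedule."""
    return build_frame_schedule(DEFAULT_FRAME_SPEC)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default noiseless phantom: (image, label_map, true params)."""
    return build_phantom(default_phantom_spec())


@pytest.fixture(scope="session")
def noiseless_class_sets(noiseless_phantom):
    """SVCA class sets built from four identical noiseless controls."""
    img, lm, _ = noiseless_phantom
    controls = [
        (
            SubjectRecord(
                id=f"c{i}",
                group="control",
                genotype="HAB" if i < 2 else "MAB",
                crs_r=23,
                state="EMCS",
            ),
            img,
        )
        for i in range(4)
    ]
    return build_affinity_class_sets(controls, lm)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
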