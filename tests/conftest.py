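import numpy as np
import pytest

from dermaqx.synthgen import generate_dataset, symmetric_profile
from dermaqx.taxonomy import EXPLANATIONS, QUALITY_CLASSES

UNIFORM_MIX = {e: 0.35 for e in EXPLANATIONS}


@pytest.fixture(scope="session")
def small_dataset():
    """40 images, 10 per class, strong degradations; shared read-only."""
    return generate_dataset(
        {c: 10 for c in QUALITY_CLASSES}, UNIFORM_MIX, seed=11,
        image_size=(64, 64), severity_range=(0.6, 1.0),
    )


@pytest.fixture(scope="session")
def rater_panel():
    return [symmetric_profile(f"derm{i:02d}", accuracy=0.8, sensitivity=0.8,
                              false_alarm=0.05) for i in range(5)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
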