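import numpy as np
import pytest

from ascseg.phantom import PhantomSpec, generate_phantom
from ascseg.segmenter import ReferenceUNetConfig, reference_unet, Segmenter


@pytest.fixture(scope="session")
def level2_phantom():
    """One fixed poorly-contrasted phantom case (64x64x8)."""
    return generate_phantom(PhantomSpec(level=2, seed=42))


@pytest.fixture(scope="session")
def tiny_net():
    """A small, fast reference net for structural tests (inputs % 4 == 0)."""
    return reference_unet(ReferenceUNetConfig(channel_width=4, depth=2), seed=0)


class ConstantSegmenter(Segmenter):
    """Stub: ignores the input, returns a constant probability map."""

    channel_width = 1

    def __init__(self, value: float):
        self.value = value
        self.calls = 0
        self.inputs: list[np.ndarray] = []

    def predict(self, image):
        self.calls += 1
        self.inputs.append(np.array(image, copy=True))
        return np.full(np.asarray(image).shape[-2:], self.value)

    @property
    def trainable_parameter_count(self):
        return 0


@pytest.fixture
def constant_segmenter():
    return ConstantSegmenter
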