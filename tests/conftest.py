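import numpy as np
import pytest

from octaquant import AnalysisConfig, EnfaceImage


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def center_faz():
    """A small square FAZ mask factory for threshold bookkeeping in tests."""

    def _make(shape, half=10):
        m = np.zeros(shape, dtype=bool)
        r, c = shape[0] // 2, shape[1] // 2
        m[r - half:r + half, c - half:c + half] = True
        return m

    return _make


def image_from(mask_or_pixels, field_width_mm=3.0, plexus="SCP"):
    px = np.asarray(mask_or_pixels, dtype=float)
    return EnfaceImage(px, field_width_mm, plexus)
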