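import numpy as np
import pytest

from pmbdose.maps import DoseMap2D
from pmbdose.synthetic import MinibeamFieldSpec, generate_minibeam_map


@pytest.fixture(scope="session")
def mono_spec():
    """Default mono-energetic field spec (2.0 cm WED conditions)."""
    return MinibeamFieldSpec()


@pytest.fixture(scope="session")
def sobp_spec(mono_spec):
    """SOBP-depth variant (10.0 cm WED): broader beamlets, stronger valley."""
    return mono_spec.sobp()


@pytest.fixture(scope="session")
def mono_map(mono_spec):
    """Noiseless mono-energetic map at 600 dpi scanner resolution."""
    return generate_minibeam_map(mono_spec)


@pytest.fixture(scope="session")
def sobp_map(sobp_spec):
    return generate_minibeam_map(sobp_spec)


@pytest.fixture(scope="session")
def mono_map_padded(mono_spec):
    """Coarser mono map with a 20 mm zero-dose margin so the largest
    (40.8 mm radius) aperture fits at (0, -11) mm."""
    return generate_minibeam_map(mono_spec, pixel_spacing=0.15, pad_mm=20.0)


@pytest.fixture()
def uniform_map():
    """Uniform 2 Gy map, 40 x 40 mm at 0.1 mm spacing."""
    return DoseMap2D(np.full((400, 400), 2.0), 0.1)
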