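import numpy as np
import pytest
from hypothesis import settings

from mapskin.geometry import NeedleGeometry, SkinStack

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def study_geometry() -> NeedleGeometry:
    """25-needle pyramidal array, 500 μm needles, ~70 % insertion, 0.5 mg."""
    return NeedleGeometry(height_um=500.0, base_width_um=333.0, n_needles=25,
                          array_area_cm2=1.0, dose_mg=0.5, penetration_fraction=0.7)


@pytest.fixture
def porcine_skin() -> SkinStack:
    """Porcine-ear layer thicknesses with the default 4 x 10 grid."""
    return SkinStack(h_sc_um=21.0, h_ed_um=72.0, h_de_um=1500.0)


@pytest.fixture
def t_day() -> np.ndarray:
    return np.linspace(0.0, 24.0, 25)
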