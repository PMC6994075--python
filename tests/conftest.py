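import numpy as np
import pytest

from wormetrics.cli_io import MeasureConfig, measure_mask
from wormetrics.synthetic import WormSpec, preset, render


@pytest.fixture(scope="session")
def straight_tube():
    """Clean horizontal straight tube, blunt ends (no tip taper)."""
    spec = WormSpec(kind="straight", length_px=400, radius_px=10, taper_frac=0.0)
    mask, gt = render(spec)
    return spec, mask, gt


@pytest.fixture(scope="session")
def straight_worm():
    """Straight worm with tapered tips at realistic proportions."""
    spec = WormSpec(kind="straight", length_px=600, radius_px=12)
    mask, gt = render(spec)
    return spec, mask, gt


@pytest.fixture(scope="session")
def sine_worm():
    spec = preset("sine", length_px=800, sine_amplitude_px=60, sine_wavelength_px=500,
                  radius_px=15)
    mask, gt = render(spec)
    return spec, mask, gt


@pytest.fixture(scope="session")
def arc_worm():
    spec = WormSpec(kind="arc", length_px=600, radius_px=12, arc_radius_px=200)
    mask, gt = render(spec)
    return spec, mask, gt


@pytest.fixture(scope="session")
def measured_sine(sine_worm):
    """Full pipeline output for the sine worm (scale 1: pixel units)."""
    spec, mask, gt = sine_worm
    morph, wp, path, oriented = measure_mask(mask, MeasureConfig(scale=1.0))
    return dict(spec=spec, mask=mask, gt=gt, morph=morph, wp=wp, path=path,
                oriented=oriented)


@pytest.fixture(scope="session")
def measured_straight(straight_worm):
    spec, mask, gt = straight_worm
    morph, wp, path, oriented = measure_mask(mask, MeasureConfig(scale=1.0))
    return dict(spec=spec, mask=mask, gt=gt, morph=morph, wp=wp, path=path,
                oriented=oriented)


@pytest.fixture(scope="session")
def measured_arc(arc_worm):
    spec, mask, gt = arc_worm
    morph, wp, path, oriented = measure_mask(mask, MeasureConfig(scale=1.0))
    return dict(spec=spec, mask=mask, gt=gt, morph=morph, wp=wp, path=path,
                oriented=oriented)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
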