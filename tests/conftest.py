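import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_phantom():
    """64x64x32 phantom with one B0-aligned vein at OEF 0.45."""
    from qsmoef import add_vein, make_phantom

    ph = make_phantom((64, 64, 32), tissue_chi_ppm=0.02)
    add_vein(ph, ((32, 32, 0), (0, 0, 1)), 2.5, 0.45)
    return ph


@pytest.fixture(scope="session")
def smooth_bump_phase():
    """Smooth 6*pi-peak phase on a 64^3 grid with its wrapped version and mask."""
    from qsmoef._spectral import wrap_phase

    n = 64
    ax = np.linspace(-1, 1, n)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = x**2 + y**2 + z**2
    truth = 6 * np.pi * np.exp(-r2 / (2 * 0.35**2))
    return truth, wrap_phase(truth), r2 < 0.7**2
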