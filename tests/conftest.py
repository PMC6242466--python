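import numpy as np
import pytest

from hdscreen.quant import GridSpec
from hdscreen.simulate import BasalDrugCurve, ScreenSimParams, simulate_screen
from hdscreen.tables import DensityTable


@pytest.fixture(scope="session")
def small_screen():
    """A modest spiked screen shared by read-only tests."""
    params = ScreenSimParams(
        n_strains=500, days=(1, 2, 3), spike_fraction=0.05, seed=42
    )
    return params, *simulate_screen(params)


@pytest.fixture(scope="session")
def clean_screen():
    """A noise-free screen: no spikes, no noise, flat basal curve."""
    params = ScreenSimParams(
        n_strains=200,
        days=(1, 3),
        spike_fraction=0.0,
        noise_sd_log2=0.0,
        plate_effect_sd=0.0,
        basal_drug_curve=BasalDrugCurve(amplitude=0.0),
        seed=1,
    )
    return params, *simulate_screen(params)


@pytest.fixture
def grid384():
    return GridSpec(16, 24, (20.0, 20.0), angle=0.0, pitch_x=20.0, pitch_y=20.0)


@pytest.fixture
def plate_and_truth(grid384):
    """One rendered noiseless 384-format plate plus its input densities."""
    from hdscreen.simulate import render_plates

    params = ScreenSimParams(
        n_strains=384, n_replicates=2, days=(3,), plate_format=384,
        spike_fraction=0.0, seed=7,
    )
    _, table = simulate_screen(params)
    sub = table.data[
        (table.data.plate_id == "control_r1_p1") & (table.data.day == 3)
    ].reset_index(drop=True)
    images, layout = render_plates(DensityTable(sub), grid384)
    return images[("control_r1_p1", 3)], layout, sub


def make_disc(shape=(60, 60), center=(30, 30), radius=5.0, intensity=200.0,
              background=10.0):
    """Uniform disc on flat background (oracle-friendly test image)."""
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img[(xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2] = intensity
    return img
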