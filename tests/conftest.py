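"""Shared fixtures: default optics, fingerprint matrix, and small
rendered scenes reused across test modules (session-scoped; everything
is generated programmatically and seeded)."""

import numpy as np
import pytest

import pentaplex as px


@pytest.fixture(scope="session")
def optics():
    return px.load_default_optics()


@pytest.fixture(scope="session")
def A(optics):
    return px.fingerprint_from_optics(optics)


@pytest.fixture(scope="session")
def panel():
    return px.default_panel()


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise-free camera with a dark offset: isolates model identities."""
    return px.NoiseModel(
        read_noise_sd=0.0, shot_noise=False, quench_residual_fraction=0.0,
        dark_offset=50.0, seed=0,
    )


@pytest.fixture(scope="session")
def small_scene(panel):
    """100-cell tumor/immune scene shared by forward-model tests."""
    return px.generate_scene(100, seed=3, markers=panel.markers())


@pytest.fixture(scope="session")
def registration_scene(panel):
    """Mid-density scene for alignment-recovery tests."""
    return px.generate_scene(200, seed=5, markers=panel.markers())


@pytest.fixture(scope="session")
def reference_dapi(registration_scene, panel, A):
    """A rendered reference-cycle DAPI-window image (with noise)."""
    stack = px.render_acquisition(
        registration_scene, panel, 1, A, px.NoiseModel(seed=2), px.RigidTransform()
    )
    return stack.dapi_window_image()


def delta_curve(center, grid=None, width=2.0, name="delta"):
    """Narrow triangular spike usable as an idealized spectrum."""
    if grid is None:
        grid = np.arange(300.0, 1001.0, 1.0)
    vals = np.clip(1.0 - np.abs(grid - center) / width, 0.0, None)
    return px.SpectralCurve(grid, vals, name=name)


@pytest.fixture(scope="session")
def toy_optics():
    """Idealized non-overlapping optics: one LED at 400 nm, one at
    600 nm; penta windows at 450 and 650; R sensor sees only 650,
    B only 450. Fingerprints are analytically predictable."""
    grid = np.arange(300.0, 1001.0, 1.0)
    flat = px.SpectralCurve(grid, np.full(grid.size, 0.9), name="flat")
    led1 = px.LEDChannel("L400", delta_curve(400), flat)
    led2 = px.LEDChannel("L600", delta_curve(600), flat)
    penta = px.PentaFilter(
        passbands=((440.0, 460.0), (640.0, 660.0)),
        transmission=px.SpectralCurve(
            grid,
            0.9 * (((grid >= 440) & (grid <= 460)) | ((grid >= 640) & (grid <= 660))),
            name="penta2",
        ),
    )
    sensor = px.SensorResponse(
        r=delta_curve(650, width=5.0, name="r"),
        g=delta_curve(550, width=5.0, name="g"),
        b=delta_curve(450, width=5.0, name="b"),
    )
    blue_dye = px.Fluorochrome("BLUE", delta_curve(400), delta_curve(450), brightness=1.0)
    red_dye = px.Fluorochrome("RED", delta_curve(600), delta_curve(650), brightness=1.0)
    return px.OpticsConfig(
        leds=(led1, led2),
        fluors=(blue_dye, red_dye),
        penta=penta,
        sensor=sensor,
        nominal_windows={"BLUE": 0, "RED": 1},
    )
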