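import numpy as np
import pytest

from wingshear.synthetic import simulate_scene


@pytest.fixture(scope="session")
def uniform_scene():
    """Small uniform-flow scene with painted channels (no coupling)."""
    return simulate_scene(preset="uniform", rows=8, cols=8, n_frames=3, seed=11,
                          polarity_magnitude=0.4, polarity_angle_deg=0.0)


@pytest.fixture(scope="session")
def shear_scene():
    """Noise-free linear-shear scene, gamma = 0.01 / min."""
    return simulate_scene(preset="shear", rows=14, cols=14, gamma=0.01,
                          n_frames=3, seed=12)


def rotate_cells(cells, alpha_deg):
    """Rigidly rotate a cells table by alpha (mathematical convention)."""
    out = cells.copy()
    a = np.radians(alpha_deg)
    x = cells["x_um"].to_numpy()
    y = -cells["y_um"].to_numpy()
    out["x_um"] = np.cos(a) * x - np.sin(a) * y
    out["y_um"] = -(np.sin(a) * x + np.cos(a) * y)
    return out
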