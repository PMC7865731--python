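import numpy as np
import pytest

import punctakit as pk


@pytest.fixture(scope="session")
def sparse_scene():
    """Two-channel frame with 25 well-resolved spots (detection benchmark)."""
    params = pk.SceneParams(
        field_size_px=(80, 80),
        amplitude=200.0,
        membrane_background=50.0,
        offcell_background=10.0,
        n_spots=25,
        seed=7,
    )
    stack, masks, gt = pk.gen_two_channel_frame(params)
    return params, stack, masks, gt


@pytest.fixture(scope="session")
def internalization_movie():
    """Time-lapse in which half the puncta internalize after frame 15."""
    params = pk.SceneParams(field_size_px=(128, 128), density_per_um2=0.4, seed=5)
    stack, masks, gt = pk.gen_timelapse(
        params,
        n_frames=40,
        stim_frame=15,
        internalized_fraction=0.5,
        loss_frames=1,
        frame_interval_s=0.1,
    )
    return params, stack, masks, gt


def gaussian_spot_frame(shape=(41, 41), center=(20.0, 20.0), amplitude=120.0,
                        sigma=1.2, cell_level=40.0, bg_level=8.0, bg_cols=3):
    """One synthetic spot on a uniform cell with an off-cell background strip."""
    img = np.full(shape, cell_level, dtype=float)
    img[:, :bg_cols] = bg_level
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    img += amplitude * np.exp(
        -((rows - center[0]) ** 2 + (cols - center[1]) ** 2) / (2 * sigma**2)
    )
    bg_mask = np.zeros(shape, dtype=bool)
    bg_mask[:, :bg_cols] = True
    return img, bg_mask
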