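import numpy as np
import pytest

import punctakit as pk
from punctakit.dynamics import site_delta_f_trace
from punctakit.errors import ParameterError


def constant_movie(value=10.0, bg_value=2.0, n_frames=20, shape=(40, 40)):
    cell = np.zeros(shape, bool)
    cell[10:30, 10:30] = True
    bg = np.zeros(shape, bool)
    bg[:, :4] = True
    frames = np.where(cell, value, bg_value)[None, None].repeat(n_frames, axis=1)
    stack = pk.ImageStack(frames.astype(float), pixel_size_nm=160.0,
                          frame_interval_s=0.1)
    return stack, cell, bg


class TestCellTrace:
    def test_constant_stack_normalizes_to_one(self):
        stack, cell, bg = constant_movie()
        tr = pk.cell_trace(stack, cell, bg, stim_frame=8)
        np.testing.assert_allclose(tr.f_norm, 1.0)
        assert tr.f_norm[:8].mean() == pytest.approx(1.0, abs=1e-9)
        assert tr.time_s[8] == 0.0

    def test_cell_equal_to_background_flags_undefined(self):
        stack, cell, bg = constant_movie(value=2.0, bg_value=2.0)
        tr = pk.cell_trace(stack, cell, bg, stim_frame=8)
        np.testing.assert_allclose(tr.f_raw, 0.0, atol=1e-12)
        assert not tr.normalization_defined and tr.f_norm is None

    def test_gain_and_offset_invariances(self):
        params = pk.SceneParams(field_size_px=(96, 96), density_per_um2=0.4, seed=2)
        stack, masks, _ = pk.gen_timelapse(params, n_frames=20, stim_frame=8,
                                           internalized_fraction=0.5)
        tr = pk.cell_trace(stack, masks["cell"], masks["background"], 8)
        gained = pk.ImageStack(stack.data * 3.0, 160.0, 0.1)
        tr_g = pk.cell_trace(gained, masks["cell"], masks["background"], 8)
        np.testing.assert_allclose(tr_g.f_norm, tr.f_norm, rtol=1e-12)
        offset = pk.ImageStack(stack.data + 50.0, 160.0, 0.1)
        tr_o = pk.cell_trace(offset, masks["cell"], masks["background"], 8)
        np.testing.assert_allclose(tr_o.f_raw, tr.f_raw, atol=1e-9)

    def test_plateau_matches_scene_expectation(self, internalization_movie):
        params, stack, masks, gt = internalization_movie
        tr = pk.cell_trace(stack, masks["cell"], masks["background"], 15)
        plateau = tr.f_norm[-8:].mean()
        n = len(gt.event_times)
        n_events = sum(e is not None for e in gt.event_times)
        flux = n * params.amplitude * 2 * np.pi * params.psf_sigma_px**2
        flux /= masks["cell"].mask.sum()
        delta = params.membrane_background - params.offcell_background
        expected = (delta + flux * (1 - n_events / n)) / (delta + flux)
        assert plateau == pytest.approx(expected, rel=0.05)

    def test_too_few_baseline_frames_rejected(self):
        stack, cell, bg = constant_movie()
        with pytest.raises(ParameterError):
            pk.cell_trace(stack, cell, bg, stim_frame=2)


class TestEndocytosisEvents:
    def test_constant_site_has_no_events(self):
        stack, cell, bg = constant_movie(n_frames=30)
        events = pk.detect_endocytosis_events(stack, [(20.0, 20.0)], bg)
        assert events == []

    def test_forced_step_drop_yields_one_event_at_that_frame(self):
        stack, cell, bg = constant_movie(value=2.0, n_frames=30)
        data = stack.data.copy()
        rows = np.arange(40)[:, None]
        cols = np.arange(40)[None, :]
        spot = 100 * np.exp(-((rows - 20) ** 2 + (cols - 20) ** 2) / (2 * 1.2**2))
        for t in range(30):
            data[0, t] += spot * (0.2 if t >= 12 else 1.0)  # 80% drop at frame 12
        movie = pk.ImageStack(data, 160.0, 0.1)
        events = pk.detect_endocytosis_events(movie, [(20.0, 20.0)], bg)
        assert len(events) == 1
        assert events[0].event_frame == 12
        assert events[0].frames_to_loss == 1
        assert events[0].drop_fraction == pytest.approx(0.8, abs=0.05)

    def test_slow_decline_is_not_an_event(self):
        stack, cell, bg = constant_movie(value=2.0, n_frames=40)
        data = stack.data.copy()
        rows = np.arange(40)[:, None]
        cols = np.arange(40)[None, :]
        spot = 100 * np.exp(-((rows - 20) ** 2 + (cols - 20) ** 2) / (2 * 1.2**2))
        ramp = np.clip(1 - np.arange(40) / 39, 0, None)  # linear fade over 40 frames
        for t in range(40):
            data[0, t] += spot * ramp[t]
        movie = pk.ImageStack(data, 160.0, 0.1)
        assert pk.detect_endocytosis_events(movie, [(20.0, 20.0)], bg) == []

    def test_event_count_monotone_in_threshold(self, internalization_movie):
        _, stack, masks, gt = internalization_movie
        sites = gt.positions_array(0)[:30]
        n_low = len(pk.detect_endocytosis_events(
            stack, sites, masks["background"], drop_threshold=0.3))
        n_high = len(pk.detect_endocytosis_events(
            stack, sites, masks["background"], drop_threshold=0.7))
        assert n_high <= n_low

    def test_recovers_programmed_events(self, internalization_movie):
        _, stack, masks, gt = internalization_movie
        sites = gt.positions_array(0)
        events = pk.detect_endocytosis_events(stack, sites, masks["background"])
        truth = {i: e for i, e in enumerate(gt.event_times) if e is not None}
        hits = {e.punctum_id: e.event_frame for e in events}
        matched = [i for i in truth if i in hits and abs(hits[i] - truth[i]) <= 1]
        assert len(matched) / len(truth) >= 0.9
        assert len(matched) / max(len(events), 1) >= 0.9

    def test_site_delta_f_accepts_per_frame_positions(self):
        stack, cell, bg = constant_movie(n_frames=10)
        path = np.column_stack([np.full(10, 20.0), np.linspace(15, 24, 10)])
        trace = site_delta_f_trace(stack, path, bg)
        assert trace.shape == (10,)


class TestDensityBeforeAfter:
    def test_no_internalization_ratio_near_one(self):
        params = pk.SceneParams(field_size_px=(128, 128), density_per_um2=0.4, seed=9)
        stack, masks, _ = pk.gen_timelapse(params, n_frames=30, stim_frame=10,
                                           internalized_fraction=0.0)
        _, _, ratio = pk.density_before_after(stack, masks["cell"], 10,
                                              tolerance=30.0)
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_half_internalization_halves_density(self, internalization_movie):
        _, stack, masks, _ = internalization_movie
        pre, post, ratio = pk.density_before_after(stack, masks["cell"], 15,
                                                   tolerance=30.0)
        assert ratio == pytest.approx(0.5, abs=0.1)
        assert pre > post

    def test_full_internalization_leaves_detector_floor(self):
        params = pk.SceneParams(field_size_px=(128, 128), density_per_um2=0.4, seed=10)
        stack, masks, _ = pk.gen_timelapse(params, n_frames=30, stim_frame=10,
                                           internalized_fraction=1.0,
                                           event_delay_range=(1, 5))
        _, post, _ = pk.density_before_after(stack, masks["cell"], 10,
                                             tolerance=30.0)
        # false-positive floor: detections on pure background frames
        blank = pk.SceneParams(field_size_px=(128, 128), density_per_um2=0.0, seed=10)
        bstack, bmasks, _ = pk.gen_timelapse(blank, n_frames=10, stim_frame=5,
                                             internalized_fraction=0.0)
        floors = [
            pk.cluster_density(
                pk.find_maxima(bstack.frame(0, t), 30.0, within=bmasks["cell"]),
                bmasks["cell"], 160.0)
            for t in range(10)
        ]
        assert post <= max(np.mean(floors), 0.005) + 0.01

    def test_insufficient_frames_rejected(self):
        stack, cell, bg = constant_movie(n_frames=6)
        with pytest.raises(ParameterError):
            pk.density_before_after(stack, cell, 1, tolerance=5.0)
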