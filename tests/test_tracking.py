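import numpy as np
import pytest

import punctakit as pk
from punctakit.errors import CalibrationError, ParameterError


class TestLinkTracks:
    def test_stationary_spot_gives_one_track_with_zero_steps(self):
        frames = [[(10.0, 10.0)] for _ in range(10)]
        tracks = pk.link_tracks(frames)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10
        np.testing.assert_allclose(tracks[0].step_lengths_px, 0.0)

    def test_distant_spots_never_cross_link(self):
        frames = [
            [(10.0, 10.0 + t), (10.0, 30.0 - t)] for t in range(5)
        ]
        tracks = pk.link_tracks(frames, max_step_px=5.0)
        assert len(tracks) == 2
        for t in tracks:
            assert np.all(t.step_lengths_px <= 5.0)
        cols = sorted(t.positions[0, 1] for t in tracks)
        assert cols == [10.0, 30.0]

    def test_every_detection_used_at_most_once(self):
        rng = np.random.default_rng(0)
        frames = [rng.uniform(0, 50, size=(8, 2)) for _ in range(6)]
        tracks = pk.link_tracks(frames, max_step_px=50.0, min_length=1)
        seen = set()
        for t in tracks:
            for f, r, c in t.points:
                key = (f, round(r, 9), round(c, 9))
                assert key not in seen
                seen.add(key)
        assert len(seen) == 48

    def test_raising_cutoff_never_loses_steps(self):
        rng = np.random.default_rng(1)
        frames = [rng.uniform(0, 40, size=(10, 2)) for _ in range(8)]
        def total_steps(cutoff):
            return sum(
                len(t) - 1 for t in pk.link_tracks(frames, cutoff, min_length=1)
            )
        steps = [total_steps(c) for c in (1.0, 3.0, 6.0, 12.0)]
        assert steps == sorted(steps)

    def test_brownian_links_follow_ground_truth_identity(self):
        params = pk.SceneParams(field_size_px=(200, 200), n_spots=40,
                                amplitude=1000, membrane_background=10,
                                offcell_background=2, noise_gaussian_sd=1, seed=3)
        stack, masks, gt = pk.gen_timelapse(params, n_frames=30, stim_frame=10,
                                            internalized_fraction=0.0,
                                            diffusion_coeff_um2s=0.01,
                                            frame_interval_s=0.1)
        det = [pk.find_maxima(stack.frame(0, t), 50.0, within=masks["cell"])
               for t in range(30)]
        tracks = pk.link_tracks(det, max_step_px=5.0)
        traj = gt.trajectories
        good = bad = 0
        for t in tracks:
            for k in range(len(t) - 1):
                f0 = t.frames[k]
                ids = []
                for f, pos in ((f0, t.positions[k]), (f0 + 1, t.positions[k + 1])):
                    d2 = ((traj[:, f, :] - pos) ** 2).sum(axis=1)
                    ids.append(int(np.argmin(d2)))
                if ids[0] == ids[1]:
                    good += 1
                else:
                    bad += 1
        assert good / (good + bad) >= 0.95


class TestDisplacementHistogram:
    def test_stationary_tracks_all_in_lowest_bin(self):
        frames = [[(5.0, 5.0), (20.0, 20.0)] for _ in range(6)]
        tracks = pk.link_tracks(frames)
        hist = pk.displacement_histogram(tracks, bin_width_px=1.0)
        assert hist.step_hist["count"].iloc[0] == 10
        assert hist.step_hist["count"].iloc[1:].sum() == 0
        assert hist.n_min_displacement_tracks == 2

    def test_hand_computed_bins(self):
        track = pk.Track(id=0, frames=[0, 1, 2, 3],
                         positions=[(0, 0), (0, 1), (0, 2), (0, 4)])
        hist = pk.displacement_histogram([track], bin_width_px=1.0)
        # steps are {1, 1, 2}: two in [1,2), one in [2,3)
        counts = dict(zip(hist.step_hist["bin_left"], hist.step_hist["count"]))
        assert counts[1.0] == 2 and counts[2.0] == 1

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ParameterError):
            pk.displacement_histogram(
                [pk.Track(id=0, frames=[0, 1], positions=[(0, 0), (1, 1)])], 0.0
            )

    def test_brownian_steps_pass_rayleigh_gof(self):
        from scipy import stats

        d, dt = 0.01, 0.1
        params = pk.SceneParams(field_size_px=(240, 240), n_spots=60, seed=12)
        _, _, gt = pk.gen_timelapse(params, n_frames=60, stim_frame=30,
                                    internalized_fraction=0.0,
                                    diffusion_coeff_um2s=d, frame_interval_s=dt)
        frames = [gt.trajectories[:, t, :] for t in range(60)]
        tracks = pk.link_tracks(frames, max_step_px=5.0)
        steps = pk.displacement_histogram(tracks, 0.1).step_lengths_px
        sigma = np.sqrt(2 * d * dt) * 1000 / 160  # analytic, px
        edges = np.quantile(steps, np.linspace(0, 1, 16))
        edges[0], edges[-1] = 0.0, np.inf
        obs, _ = np.histogram(steps, bins=edges)
        expected = steps.size * np.diff(1 - np.exp(-(edges**2) / (2 * sigma**2)))
        chi2 = ((obs - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, len(obs) - 1) > 0.01


class TestAverageSpeed:
    def test_straight_motion_arithmetic(self):
        track = pk.Track(id=0, frames=range(5),
                         positions=[(10.0, 10.0 + k) for k in range(5)])
        speed = track.avg_speed_um_s(160.0, 0.1)
        assert speed == pytest.approx(1.6)

    def test_stationary_is_zero(self):
        track = pk.Track(id=0, frames=range(5), positions=[(3.0, 3.0)] * 5)
        summary = pk.average_speed([track], 160.0, 0.1)
        assert summary.pooled_mean_um_s == 0.0

    def test_missing_frame_interval_raises(self):
        track = pk.Track(id=0, frames=[0, 1], positions=[(0, 0), (1, 1)])
        with pytest.raises(CalibrationError):
            pk.average_speed([track], 160.0, None)

    def test_brownian_pooled_speed_matches_rayleigh_mean(self):
        d, dt = 0.01, 0.1
        params = pk.SceneParams(field_size_px=(240, 240), n_spots=50, seed=13)
        _, _, gt = pk.gen_timelapse(params, n_frames=50, stim_frame=25,
                                    internalized_fraction=0.0,
                                    diffusion_coeff_um2s=d, frame_interval_s=dt)
        frames = [gt.trajectories[:, t, :] for t in range(50)]
        tracks = pk.link_tracks(frames, max_step_px=5.0)
        summary = pk.average_speed(tracks, 160.0, dt)
        expected = np.sqrt(np.pi * d * dt) / dt
        assert abs(summary.pooled_mean_um_s - expected) / expected < 0.10

    def test_speed_invariant_under_global_translation(self):
        rng = np.random.default_rng(4)
        frames = [rng.uniform(10, 40, size=(5, 2))]
        for _ in range(9):
            frames.append(frames[-1] + rng.normal(0, 0.3, size=(5, 2)))
        shifted = [f + np.array([100.0, -7.0]) for f in frames]
        s0 = pk.average_speed(pk.link_tracks(frames, 5.0), 160.0, 0.1)
        s1 = pk.average_speed(pk.link_tracks(shifted, 5.0), 160.0, 0.1)
        assert s1.pooled_mean_um_s == pytest.approx(s0.pooled_mean_um_s, rel=1e-12)
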