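"""Whole-cell fluorescence traces, endocytosis events, density ratios.

Trace analysis follows the membrane-trafficking convention: the mean cell
fluorescence is background-corrected with an off-cell region, normalized
to the pre-stimulation baseline, and plotted on a time axis with the
stimulation at t = 0. Endocytosis events are the characteristic rapid loss
of a punctum's site-specific fluorescence (dF) within one or two frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binding import measure_site
from .errors import BorderError, MaskError, ParameterError
from .imgio import ImageStack, RegionMask, check_disjoint
from .puncta import auto_tolerance, cluster_density, find_maxima, positions_of


@dataclass
class FluorescenceTrace:
    """Background-corrected, baseline-normalized whole-cell trace."""

    time_s: np.ndarray  # per-frame timestamps, stimulation at t = 0
    f_raw: np.ndarray  # mean cell fluorescence minus mean background
    f_norm: np.ndarray | None  # f_raw / pre-stimulation baseline
    stim_frame: int
    baseline: float
    normalization_defined: bool = True


@dataclass
class EndocytosisEvent:
    """A rapid step loss of site fluorescence."""

    punctum_id: int
    event_frame: int
    drop_fraction: float
    frames_to_loss: int  # 1 or 2


def cell_trace(
    stack: ImageStack,
    cell_mask: RegionMask | np.ndarray,
    bg_mask: RegionMask | np.ndarray,
    stim_frame: int,
    channel: int = 0,
    min_baseline_frames: int = 5,
) -> FluorescenceTrace:
    """Whole-cell fluorescence around a stimulation.

    Per frame, the mean intensity inside the cell mask minus the mean in
    the off-cell background mask; normalized to the mean over all
    pre-stimulation frames (at least ``min_baseline_frames`` required) and
    put on a time axis with stimulation at t = 0. A baseline at or below
    zero leaves ``f_norm`` undefined (flagged, not raised).
    """
    stack.require_time_axis()
    cm = cell_mask if isinstance(cell_mask, RegionMask) else RegionMask("cell", cell_mask)
    bm = bg_mask if isinstance(bg_mask, RegionMask) else RegionMask("background", bg_mask)
    cm.require_nonempty()
    bm.require_nonempty()
    check_disjoint(cm, bm)
    if not 0 <= stim_frame < stack.n_frames:
        raise ParameterError("stim_frame outside the movie")
    if stim_frame < min_baseline_frames:
        raise ParameterError(
            f"need >= {min_baseline_frames} pre-stimulation frames for the baseline"
        )
    frames = stack.data[channel]
    f_raw = frames[:, cm.mask].mean(axis=1) - frames[:, bm.mask].mean(axis=1)
    baseline = float(f_raw[:stim_frame].mean())
    time_s = (np.arange(stack.n_frames) - stim_frame) * stack.frame_interval_s
    if baseline > 0:
        return FluorescenceTrace(time_s, f_raw, f_raw / baseline, stim_frame, baseline)
    return FluorescenceTrace(
        time_s, f_raw, None, stim_frame, baseline, normalization_defined=False
    )


def site_delta_f_trace(
    stack: ImageStack,
    site,
    bg_mask: RegionMask | np.ndarray,
    channel: int = 0,
    circle_diam_px: float = 3.0,
    annulus_outer_diam_px: float = 5.0,
) -> np.ndarray:
    """Per-frame dF at one site (static (row, col) or per-frame positions)."""
    n = stack.n_frames
    pos = np.asarray(site, dtype=float)
    if pos.ndim == 1:
        pos = np.tile(pos, (n, 1))
    if pos.shape != (n, 2):
        raise ParameterError("site must be (row, col) or per-frame (n_frames, 2)")
    out = np.empty(n)
    for t in range(n):
        m = measure_site(
            stack.data[channel, t], tuple(pos[t]), bg_mask,
            circle_diam_px=circle_diam_px,
            annulus_outer_diam_px=annulus_outer_diam_px,
        )
        out[t] = m.delta_f
    return out


def detect_endocytosis_events(
    stack: ImageStack,
    sites,
    bg_mask: RegionMask | np.ndarray,
    drop_threshold: float = 0.5,
    max_frames: int = 2,
    persist_frames: int = 3,
    baseline_window: int = 5,
    min_baseline_fraction: float = 0.2,
    channel: int = 0,
) -> list[EndocytosisEvent]:
    """Detect rapid per-punctum fluorescence losses.

    An event is called at the first frame where the site's dF falls by at
    least ``drop_threshold`` of its trailing ``baseline_window``-frame
    median, the fall from baseline takes at most ``max_frames`` frames, and
    dF stays below the threshold level for at least ``persist_frames``
    frames (rejecting blinking). The baseline median must additionally
    retain at least ``min_baseline_fraction`` of the trace's bright level
    (95th percentile), so the relative-drop rule cannot fire on the faint
    tail of a slow decline. At most one event is reported per site. Sites
    whose trace is too short or too close to the border are skipped with a
    warning.
    """
    if not 0 < drop_threshold <= 1:
        raise ParameterError("drop_threshold must be in (0, 1]")
    events: list[EndocytosisEvent] = []
    for i, site in enumerate(_iter_sites(sites)):
        try:
            trace = site_delta_f_trace(stack, site, bg_mask, channel=channel)
        except BorderError:
            warnings.warn(f"site {i} too close to the border; skipped")
            continue
        n = len(trace)
        if n < baseline_window + persist_frames:
            warnings.warn(f"site {i} trace shorter than the detection window")
            continue
        min_baseline = min_baseline_fraction * float(np.percentile(trace, 95))
        for t in range(baseline_window, n - persist_frames + 1):
            med = float(np.median(trace[t - baseline_window : t]))
            if med <= max(min_baseline, 0.0):
                continue
            floor = (1.0 - drop_threshold) * med
            if trace[t] > floor:
                continue
            if not np.all(trace[t : t + persist_frames] <= floor):
                continue
            # rapid: the last frame still above the floor is close behind
            above = np.nonzero(trace[:t] > floor)[0]
            if len(above) == 0 or t - above[-1] > max_frames:
                continue
            events.append(
                EndocytosisEvent(
                    punctum_id=i,
                    event_frame=t,
                    drop_fraction=float(1.0 - trace[t] / med),
                    frames_to_loss=int(min(t - above[-1], 2)),
                )
            )
            break
    return events


def _iter_sites(sites):
    from .tracking import Track

    for s in sites:
        if isinstance(s, Track):
            yield s.positions
        elif hasattr(s, "position"):
            yield np.asarray(s.position, dtype=float)
        else:
            yield np.asarray(s, dtype=float)


def density_before_after(
    stack: ImageStack,
    cell_mask: RegionMask | np.ndarray,
    stim_frame: int,
    tolerance: float | None = None,
    pre_window: int = 5,
    post_window: int = 5,
    channel: int = 0,
    bg_mask: RegionMask | np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Cluster density before and after stimulation, and their ratio.

    The pre window is the ``pre_window`` frames immediately before the
    stimulation; the post window is the last ``post_window`` frames of the
    movie, leaving the loss transition out of both. At least 3 frames are
    required on each side. ``tolerance=None`` derives the detection
    tolerance from the background region of the first frame.
    """
    stack.require_time_axis()
    n = stack.n_frames
    pre_idx = range(max(0, stim_frame - pre_window), stim_frame)
    post_idx = range(max(stim_frame, n - post_window), n)
    if len(pre_idx) < 3 or len(post_idx) < 3:
        raise ParameterError("need >= 3 frames on each side of the stimulation")
    if tolerance is None:
        tolerance = auto_tolerance(stack.data[channel, 0], bg_mask)
    cm = cell_mask if isinstance(cell_mask, RegionMask) else RegionMask("cell", cell_mask)

    def window_density(idx) -> float:
        dens = []
        for t in idx:
            pts = find_maxima(stack.data[channel, t], tolerance, within=cm)
            dens.append(cluster_density(pts, cm, stack.pixel_size_nm))
        return float(np.mean(dens))

    pre = window_density(pre_idx)
    post = window_density(post_idx)
    ratio = post / pre if pre > 0 else float("nan")
    return pre, post, ratio
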