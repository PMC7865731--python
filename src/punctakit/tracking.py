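"""Frame-to-frame punctum linking and displacement statistics.

Linking gates candidate assignments at a maximum frame-to-frame
displacement (default 5 px, the tracking-plugin pixel cutoff) and resolves
conflicts greedily by ascending distance, so each detection joins at most
one track and no track ever jumps farther than the cutoff. There is no gap
closing: consecutive track points differ by exactly one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, ParameterError
from .puncta import positions_of


@dataclass
class Track:
    """One linked trajectory."""

    id: int
    frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    positions: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.positions):
            raise ParameterError("frames and positions length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) == 1):
            raise ParameterError("track frames must be consecutive (no gaps)")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> list[tuple[int, float, float]]:
        return [
            (int(f), float(r), float(c))
            for f, (r, c) in zip(self.frames, self.positions)
        ]

    @property
    def step_lengths_px(self) -> np.ndarray:
        return np.sqrt((np.diff(self.positions, axis=0) ** 2).sum(axis=1))

    @property
    def total_displacement_px(self) -> float:
        """Path length: sum of per-frame step lengths."""
        return float(self.step_lengths_px.sum())

    def avg_speed_um_s(self, pixel_size_nm: float, frame_interval_s: float) -> float:
        if not frame_interval_s or frame_interval_s <= 0:
            raise CalibrationError("frame interval required for speeds")
        if len(self) < 2:
            return 0.0
        mean_step_um = self.step_lengths_px.mean() * pixel_size_nm / 1000.0
        return float(mean_step_um / frame_interval_s)


def link_tracks(
    puncta_by_frame,
    max_step_px: float = 5.0,
    min_length: int = 3,
) -> list[Track]:
    """Link per-frame detections into gap-free trajectories.

    Between consecutive frames, all candidate pairs within ``max_step_px``
    are sorted by ascending distance and accepted greedily, each end point
    at most once. Unmatched detections start new tracks; tracks shorter
    than ``min_length`` points are discarded.
    """
    if max_step_px <= 0:
        raise ParameterError("max_step_px must be > 0")
    frames = [positions_of(p) for p in puncta_by_frame]
    if len(frames) < 2:
        raise ParameterError("need detections from at least two frames")

    tracks: list[dict] = []
    active: dict[int, int] = {}  # detection index in current frame -> track index
    for i, _ in enumerate(frames[0]):
        tracks.append({"frames": [0], "positions": [frames[0][i]]})
        active[i] = len(tracks) - 1

    for t in range(1, len(frames)):
        prev, cur = frames[t - 1], frames[t]
        pairs = []
        if len(prev) and len(cur):
            d2 = ((prev[:, None, :] - cur[None, :, :]) ** 2).sum(axis=2)
            ok = np.argwhere(d2 <= max_step_px**2)
            pairs = sorted(
                ((d2[i, j], int(i), int(j)) for i, j in ok), key=lambda x: x[0]
            )
        used_prev: set[int] = set()
        used_cur: set[int] = set()
        new_active: dict[int, int] = {}
        for _, i, j in pairs:
            if i in used_prev or j in used_cur or i not in active:
                continue
            used_prev.add(i)
            used_cur.add(j)
            k = active[i]
            tracks[k]["frames"].append(t)
            tracks[k]["positions"].append(cur[j])
            new_active[j] = k
        for j in range(len(cur)):
            if j not in used_cur:
                tracks.append({"frames": [t], "positions": [cur[j]]})
                new_active[j] = len(tracks) - 1
        active = new_active

    out = []
    for rec in tracks:
        if len(rec["frames"]) >= min_length:
            out.append(
                Track(
                    id=len(out),
                    frames=np.asarray(rec["frames"]),
                    positions=np.asarray(rec["positions"]),
                )
            )
    return out


@dataclass
class DisplacementHistogram:
    """Per-step and per-track displacement histograms."""

    step_hist: pd.DataFrame  # bin_left, bin_right, count (per-step lengths)
    track_hist: pd.DataFrame  # same bins over per-track total displacement
    n_min_displacement_tracks: int  # tracks whose total falls in the lowest bin
    step_lengths_px: np.ndarray


def displacement_histogram(
    tracks: list[Track], bin_width_px: float
) -> DisplacementHistogram:
    """Histogram per-step displacements (and per-track totals) of tracks.

    Whether published displacement histograms pool per-step lengths or
    per-track totals is ambiguous; both are computed and labelled. The
    count of minimum-displacement tracks is the number of tracks whose
    total displacement falls in the lowest bin.
    """
    if bin_width_px <= 0:
        raise ParameterError("bin width must be > 0")
    if not tracks:
        raise ParameterError("need at least one track")
    steps = np.concatenate([t.step_lengths_px for t in tracks])
    totals = np.asarray([t.total_displacement_px for t in tracks])

    def hist(values: np.ndarray) -> pd.DataFrame:
        top = max(values.max(initial=0), bin_width_px)
        edges = np.arange(0.0, top + bin_width_px, bin_width_px)
        if edges[-1] <= values.max(initial=0):
            edges = np.append(edges, edges[-1] + bin_width_px)
        counts, _ = np.histogram(values, bins=edges)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )

    th = hist(totals)
    return DisplacementHistogram(
        step_hist=hist(steps),
        track_hist=th,
        n_min_displacement_tracks=int(th["count"].iloc[0]),
        step_lengths_px=steps,
    )


@dataclass
class SpeedSummary:
    per_track_um_s: np.ndarray
    pooled_mean_um_s: float
    sem_um_s: float


def average_speed(
    tracks: list[Track], pixel_size_nm: float, frame_interval_s: float
) -> SpeedSummary:
    """Per-track mean speeds (um/s) with pooled mean +/- SEM across tracks."""
    if not frame_interval_s or frame_interval_s <= 0:
        raise CalibrationError("frame interval required for speeds")
    if not tracks:
        raise ParameterError("need at least one track")
    speeds = np.asarray(
        [t.avg_speed_um_s(pixel_size_nm, frame_interval_s) for t in tracks]
    )
    sem = float(speeds.std(ddof=1) / np.sqrt(len(speeds))) if len(speeds) > 1 else 0.0
    return SpeedSummary(
        per_track_um_s=speeds,
        pooled_mean_um_s=float(speeds.mean()),
        sem_um_s=sem,
    )


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format (track_id, frame, row, col) table."""
    rows = [
        {"track_id": t.id, "frame": f, "row": r, "col": c}
        for t in tracks
        for f, r, c in t.points
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "row", "col"])
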