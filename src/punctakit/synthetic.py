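"""Synthetic fluorescence scenes with known ground truth.

Every input the quantification pipeline consumes can be generated here:
two-channel punctate TIRF-like fields with a controllable co-localized
fraction, time-lapses with step-wise punctum internalization after a
stimulation frame, Brownian punctum motion at a set diffusion coefficient,
PLA scenes (nuclei plus bright dot signals) and replicate Cq tables with
set true fold changes.

Spots are rendered as isotropic Gaussians (default sigma 1.2 px, about
190 nm at the 160 nm/px calibration — diffraction-limited). The default
noise model is Poisson shot noise on signal + background plus Gaussian read
noise (sd 2). All randomness is driven by a single seed; equal seeds give
bit-identical outputs.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PackingError, ParameterError
from .imgio import ImageStack, RegionMask

DEFAULT_PIXEL_SIZE_NM = 160.0


# ---------------------------------------------------------------------------
# Parameter / ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class SceneParams:
    """Parameters of a simulated punctate field.

    ``density_per_um2`` is the punctum density inside the elliptical cell
    mask; the expected spot count is density times the cell-mask area.
    ``coloc_fraction`` of channel-1 spots are duplicated into channel 2 at
    the same centers; the remainder of channel 2 is filled with independent
    spots so both channels carry the same density. ``exclusion_radius_px``
    > 0 keeps independent channel-2 spots at least that far from every
    channel-1 spot (anti-localized scenes).
    """

    field_size_px: tuple[int, int] = (80, 80)
    density_per_um2: float = 0.4
    psf_sigma_px: float = 1.2
    amplitude: float = 200.0
    membrane_background: float = 40.0
    offcell_background: float = 8.0
    noise_poisson: bool = True
    noise_gaussian_sd: float = 2.0
    coloc_fraction: float = 0.0
    exclusion_radius_px: float = 0.0
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    n_spots: int | None = None  # overrides the Poisson draw when set
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.field_size_px, int):
            self.field_size_px = (self.field_size_px, self.field_size_px)
        if self.density_per_um2 < 0:
            raise ParameterError("density_per_um2 must be >= 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ParameterError("coloc_fraction must be in [0, 1]")
        if self.psf_sigma_px <= 0:
            raise ParameterError("psf_sigma_px must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually put into a scene."""

    spot_positions: list[tuple[int, float, float]] = field(default_factory=list)
    coloc_flags: list[bool] | None = None
    event_times: list[int | None] | None = None
    diffusion_coeff_um2s: float | None = None
    pla_counts: list[int] | None = None
    qpcr_true_fold: dict[str, float] | None = None
    # extras beyond the minimum contract
    spot_positions_ch2: list[tuple[int, float, float]] | None = None
    trajectories: np.ndarray | None = None  # (n_spots, n_frames, 2) row/col
    nucleus_centers: list[tuple[float, float]] | None = None
    warnings: list[str] = field(default_factory=list)

    def positions_array(self, frame: int | None = None) -> np.ndarray:
        """Spot (row, col) positions, optionally restricted to one frame."""
        pos = [
            (r, c)
            for (f, r, c) in self.spot_positions
            if frame is None or f == frame
        ]
        return np.asarray(pos, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# Scene geometry and rendering helpers
# ---------------------------------------------------------------------------

def _cell_geometry(shape: tuple[int, int], margin: int = 5):
    """Elliptical cell mask centred in the field plus off-cell background."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h / 2.0 - margin, w / 2.0 - margin
    if ry <= 2 or rx <= 2:
        raise ParameterError("field too small for a cell mask")
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    rho2 = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2
    cell = rho2 <= 1.0
    background = rho2 >= 1.25  # annular guard band keeps the regions disjoint
    return cell, background, (cy, cx, ry, rx)


def _sample_in_cell(rng, n, geom, shape):
    """Uniform subpixel positions inside the ellipse, >= 3 px from borders.

    Positions are accepted only when their nearest pixel also lies inside
    the ellipse, so rounded ground-truth coordinates stay in the cell mask.
    """
    cy, cx, ry, rx = geom
    h, w = shape
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 16)
        r = rng.uniform(2.0, h - 3.0, size=m)
        c = rng.uniform(2.0, w - 3.0, size=m)
        ok = ((r - cy) / ry) ** 2 + ((c - cx) / rx) ** 2 <= 1.0
        ok &= ((np.round(r) - cy) / ry) ** 2 + ((np.round(c) - cx) / rx) ** 2 <= 1.0
        take = min(n - got, int(ok.sum()))
        out[got : got + take] = np.column_stack([r[ok][:take], c[ok][:take]])
        got += take
    return out


def render_spots(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray | float,
    sigma_px: float,
) -> np.ndarray:
    """Additively render isotropic Gaussian spots into a zero image."""
    img = np.zeros(shape, dtype=np.float64)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return img
    amps = np.broadcast_to(
        np.asarray(amplitudes, dtype=float), (positions.shape[0],)
    )
    half = int(np.ceil(4 * sigma_px))
    h, w = shape
    for (r, c), a in zip(positions, amps):
        if a == 0:
            continue
        r0, r1 = max(0, int(r) - half), min(h, int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(w, int(c) + half + 1)
        rr = np.arange(r0, r1)[:, None]
        cc = np.arange(c0, c1)[None, :]
        img[r0:r1, c0:c1] += a * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sigma_px**2)
        )
    return img


def _apply_noise(img: np.ndarray, rng, poisson: bool, gauss_sd: float) -> np.ndarray:
    out = rng.poisson(np.clip(img, 0, None)).astype(np.float64) if poisson else img
    if gauss_sd > 0:
        out = out + rng.normal(0.0, gauss_sd, size=img.shape)
    return np.clip(out, 0, None)


def _masks(cell: np.ndarray, background: np.ndarray) -> dict[str, RegionMask]:
    return {
        "cell": RegionMask(kind="cell", mask=cell),
        "background": RegionMask(kind="background", mask=background),
    }


def cell_area_um2(params: SceneParams) -> float:
    """Area of the simulated cell mask in square microns."""
    cell, _, _ = _cell_geometry(params.field_size_px)
    return float(cell.sum()) * (params.pixel_size_nm / 1000.0) ** 2


# ---------------------------------------------------------------------------
# Two-channel punctate frame
# ---------------------------------------------------------------------------

def gen_two_channel_frame(
    params: SceneParams,
) -> tuple[ImageStack, dict[str, RegionMask], GroundTruth]:
    """Simulate a two-channel punctate membrane field.

    Channel 1 carries ``n`` spots (Poisson draw at the stated in-cell
    density unless ``params.n_spots`` fixes the count). A ``coloc_fraction``
    subset is duplicated into channel 2 at identical centers; channel 2 is
    topped up with independent spots to the same total, optionally excluded
    from channel-1 positions by ``exclusion_radius_px``.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.field_size_px
    cell, background, geom = _cell_geometry(shape)
    area_um2 = cell.sum() * (params.pixel_size_nm / 1000.0) ** 2

    if params.n_spots is not None:
        n1 = int(params.n_spots)
    else:
        n1 = int(rng.poisson(params.density_per_um2 * area_um2))

    gt = GroundTruth()
    density_px = n1 / max(cell.sum(), 1)
    if n1 > 1 and 0.5 / np.sqrt(density_px) < 2 * params.psf_sigma_px:
        gt.warnings.append(
            "overcrowded: expected spot spacing below 2 x psf_sigma"
        )

    pos1 = _sample_in_cell(rng, n1, geom, shape)
    n_coloc = int(round(params.coloc_fraction * n1))
    coloc_idx = rng.choice(n1, size=n_coloc, replace=False) if n1 else np.array([], int)
    flags = np.zeros(n1, dtype=bool)
    flags[coloc_idx] = True

    # independent channel-2 spots, optionally excluded from channel-1 sites
    n_indep = n1 - n_coloc
    indep = np.empty((0, 2))
    if n_indep > 0:
        keep: list[np.ndarray] = []
        got = 0
        for _ in range(200):
            cand = _sample_in_cell(rng, n_indep - got, geom, shape)
            if params.exclusion_radius_px > 0 and n1 > 0:
                d2 = ((cand[:, None, :] - pos1[None, :, :]) ** 2).sum(-1)
                cand = cand[d2.min(axis=1) >= params.exclusion_radius_px**2]
            if len(cand):
                keep.append(cand)
                got += len(cand)
            if got >= n_indep:
                break
        else:
            raise PackingError(
                "cannot place independent channel-2 spots under exclusion"
            )
        indep = np.concatenate(keep)[:n_indep]
    pos2 = (
        np.concatenate([pos1[flags], indep])
        if n1 or len(indep)
        else np.empty((0, 2))
    )

    base = np.where(cell, params.membrane_background, params.offcell_background)
    ch1 = base + render_spots(shape, pos1, params.amplitude, params.psf_sigma_px)
    ch2 = base + render_spots(shape, pos2, params.amplitude, params.psf_sigma_px)
    ch1 = _apply_noise(ch1, rng, params.noise_poisson, params.noise_gaussian_sd)
    ch2 = _apply_noise(ch2, rng, params.noise_poisson, params.noise_gaussian_sd)

    stack = ImageStack(
        data=np.stack([ch1, ch2])[:, np.newaxis],
        pixel_size_nm=params.pixel_size_nm,
        channel_names=["ch1", "ch2"],
    )
    gt.spot_positions = [(0, float(r), float(c)) for r, c in pos1]
    gt.coloc_flags = flags.tolist()
    gt.spot_positions_ch2 = [(0, float(r), float(c)) for r, c in pos2]
    return stack, _masks(cell, background), gt


# ---------------------------------------------------------------------------
# Time-lapse with internalization events and Brownian motion
# ---------------------------------------------------------------------------

def gen_timelapse(
    params: SceneParams,
    n_frames: int,
    stim_frame: int,
    internalized_fraction: float,
    loss_frames: int = 1,
    diffusion_coeff_um2s: float = 0.0,
    frame_interval_s: float = 0.1,
    event_delay_range: tuple[int, int] = (1, 8),
) -> tuple[ImageStack, dict[str, RegionMask], GroundTruth]:
    """Simulate a single-channel time-lapse of mobile, internalizing puncta.

    Puncta take independent per-axis Gaussian Brownian steps of variance
    ``2 D dt`` (converted to pixels). After ``stim_frame`` a round(fraction
    x n) subset loses its amplitude to zero linearly over ``loss_frames``
    (1 or 2) frames, starting at a per-spot event frame drawn uniformly from
    ``stim_frame + event_delay_range``. The event frame recorded in the
    ground truth is the first frame with reduced amplitude.
    """
    if diffusion_coeff_um2s < 0:
        raise ParameterError("diffusion coefficient must be >= 0")
    if not 0.0 <= internalized_fraction <= 1.0:
        raise ParameterError("internalized_fraction must be in [0, 1]")
    if loss_frames not in (1, 2):
        raise ParameterError("loss_frames must be 1 or 2")
    if not 0 <= stim_frame < n_frames:
        raise ParameterError("stim_frame must fall inside the movie")

    rng = np.random.default_rng(params.seed)
    shape = params.field_size_px
    cell, background, geom = _cell_geometry(shape)
    area_um2 = cell.sum() * (params.pixel_size_nm / 1000.0) ** 2
    n = (
        int(params.n_spots)
        if params.n_spots is not None
        else int(rng.poisson(params.density_per_um2 * area_um2))
    )

    pos0 = _sample_in_cell(rng, n, geom, shape)
    step_sd_px = (
        np.sqrt(2.0 * diffusion_coeff_um2s * frame_interval_s)
        * 1000.0
        / params.pixel_size_nm
    )

    cy, cx, ry, rx = geom
    traj = np.empty((n, n_frames, 2))
    if n:
        traj[:, 0] = pos0
    for t in range(1, n_frames):
        prev = traj[:, t - 1]
        step = rng.normal(0.0, step_sd_px, size=(n, 2)) if step_sd_px else 0.0
        nxt = prev + step
        if step_sd_px:
            # stay inside the cell: re-draw escaping steps, else hold still
            for _ in range(20):
                bad = ((nxt[:, 0] - cy) / ry) ** 2 + ((nxt[:, 1] - cx) / rx) ** 2 > 1.0
                if not bad.any():
                    break
                nxt[bad] = prev[bad] + rng.normal(
                    0.0, step_sd_px, size=(int(bad.sum()), 2)
                )
            bad = ((nxt[:, 0] - cy) / ry) ** 2 + ((nxt[:, 1] - cx) / rx) ** 2 > 1.0
            nxt[bad] = prev[bad]
        traj[:, t] = nxt

    n_events = int(round(internalized_fraction * n))
    event_idx = rng.choice(n, size=n_events, replace=False) if n else np.array([], int)
    event_times: list[int | None] = [None] * n
    lo, hi = event_delay_range
    for i in event_idx:
        event_times[i] = int(stim_frame + rng.integers(lo, hi + 1))

    # amplitude profile per spot per frame
    amps = np.full((n, n_frames), params.amplitude)
    for i, e in enumerate(event_times):
        if e is None:
            continue
        if loss_frames == 1:
            amps[i, e:] = 0.0
        else:
            if e < n_frames:
                amps[i, e] = params.amplitude / 2.0
            amps[i, e + 1 :] = 0.0

    base = np.where(cell, params.membrane_background, params.offcell_background)
    frames = np.empty((1, n_frames) + shape)
    for t in range(n_frames):
        img = base + render_spots(
            shape, traj[:, t] if n else np.empty((0, 2)), amps[:, t], params.psf_sigma_px
        )
        frames[0, t] = _apply_noise(
            img, rng, params.noise_poisson, params.noise_gaussian_sd
        )

    stack = ImageStack(
        data=frames,
        pixel_size_nm=params.pixel_size_nm,
        frame_interval_s=frame_interval_s,
        channel_names=["ch1"],
    )
    gt = GroundTruth(
        spot_positions=[(0, float(r), float(c)) for r, c in (pos0 if n else [])],
        event_times=event_times,
        diffusion_coeff_um2s=diffusion_coeff_um2s,
        trajectories=traj,
    )
    return stack, _masks(cell, background), gt


# ---------------------------------------------------------------------------
# PLA scenes
# ---------------------------------------------------------------------------

def gen_pla_scene(
    n_cells: int,
    mean_signals_per_cell: float,
    nucleus_radius_px: float = 12.0,
    dot_amplitude: float = 200.0,
    seed: int = 0,
    field_size_px: tuple[int, int] | None = None,
    expand_px: float = 65.0,
    dot_sigma_px: float = 0.8,
    min_dot_separation_px: float = 5.0,
    dapi_amplitude: float = 150.0,
    background: float = 2.0,
    noise_gaussian_sd: float = 1.0,
    forced_counts: Sequence[int] | None = None,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a DAPI + PLA two-channel scene.

    Nuclei are non-overlapping discs on a jittered grid; each cell receives
    Poisson(``mean_signals_per_cell``) dot signals (or ``forced_counts``)
    placed within ``expand_px`` of its nucleus. Dots are dart-thrown with a
    minimum mutual separation so that every programmed signal is a
    resolvable connected component — the ground-truth count is the number
    of countable amplified signals.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if mean_signals_per_cell < 0:
        raise ParameterError("mean_signals_per_cell must be >= 0")
    rng = np.random.default_rng(seed)

    pitch = 2.0 * (nucleus_radius_px + expand_px) * 0.8
    ncols = int(np.ceil(np.sqrt(n_cells)))
    nrows = int(np.ceil(n_cells / ncols))
    if field_size_px is None:
        field_size_px = (
            int(nrows * pitch + 2 * nucleus_radius_px + 20),
            int(ncols * pitch + 2 * nucleus_radius_px + 20),
        )
    h, w = field_size_px
    if (
        nrows * pitch + 2 * nucleus_radius_px > h
        or ncols * pitch + 2 * nucleus_radius_px > w
    ):
        raise PackingError(f"cannot place {n_cells} cells in a {h}x{w} field")

    centers = []
    jit = max(pitch / 2 - 2 * nucleus_radius_px, 0.0)
    for k in range(n_cells):
        gr, gc = divmod(k, ncols)
        cy = nucleus_radius_px + 10 + (gr + 0.5) * pitch + rng.uniform(-jit, jit) * 0.3
        cx = nucleus_radius_px + 10 + (gc + 0.5) * pitch + rng.uniform(-jit, jit) * 0.3
        centers.append((cy, cx))
    centers_arr = np.asarray(centers)

    if forced_counts is not None:
        if len(forced_counts) != n_cells:
            raise ParameterError("forced_counts length must equal n_cells")
        counts = np.asarray(forced_counts, dtype=int)
    else:
        counts = rng.poisson(mean_signals_per_cell, size=n_cells)

    all_dots: list[np.ndarray] = []
    placed = np.empty((0, 2))
    max_r = nucleus_radius_px + expand_px
    for (cy, cx), m in zip(centers, counts):
        for _ in range(int(m)):
            ok = False
            for _try in range(80):
                rho = max_r * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                r = cy + rho * np.sin(theta)
                c = cx + rho * np.cos(theta)
                if not (3 <= r < h - 3 and 3 <= c < w - 3):
                    continue
                if len(placed) and (
                    ((placed - [r, c]) ** 2).sum(axis=1).min()
                    < min_dot_separation_px**2
                ):
                    continue
                ok = True
                break
            if not ok:
                _warnings.warn("dot placed without minimum separation")
            placed = np.vstack([placed, [r, c]])
            all_dots.append(np.array([r, c]))

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    dapi = np.full((h, w), background)
    for cy, cx in centers:
        dapi += dapi_amplitude * (
            (rows - cy) ** 2 + (cols - cx) ** 2 <= nucleus_radius_px**2
        )
    pla = background + render_spots(
        (h, w),
        np.asarray(all_dots).reshape(-1, 2),
        dot_amplitude,
        dot_sigma_px,
    )
    dapi = _apply_noise(dapi, rng, True, noise_gaussian_sd)
    pla = _apply_noise(pla, rng, True, noise_gaussian_sd)

    stack = ImageStack(
        data=np.stack([dapi, pla])[:, np.newaxis],
        pixel_size_nm=pixel_size_nm,
        channel_names=["DAPI", "PLA"],
    )
    gt = GroundTruth(
        spot_positions=[(0, float(r), float(c)) for r, c in all_dots],
        pla_counts=[int(c) for c in counts],
        nucleus_centers=[(float(r), float(c)) for r, c in centers],
    )
    return stack, gt


# ---------------------------------------------------------------------------
# qPCR tables
# ---------------------------------------------------------------------------

def gen_qpcr_table(
    genes: Sequence[str],
    true_fold: dict[str, float] | float,
    reference_genes: Sequence[str],
    cq_noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
    base_cq_range: tuple[float, float] = (20.0, 28.0),
):
    """Simulate a replicate Cq table with known true fold changes.

    The treated-condition Cq of each target gene is shifted by
    ``-log2(true_fold)`` relative to untreated (one cycle fewer per
    two-fold up-regulation); reference genes are unshifted. Gaussian
    replicate noise of sd ``cq_noise_sd`` is added to every reaction.
    """
    from .qpcr import CqTable  # local import to avoid a cycle

    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    folds = (
        {g: float(true_fold) for g in genes}
        if np.isscalar(true_fold)
        else dict(true_fold)
    )
    all_genes = list(dict.fromkeys(list(genes) + list(reference_genes)))
    for g in all_genes:
        f = folds.get(g, 1.0)
        if f <= 0:
            raise ParameterError(f"true fold for {g} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for g in all_genes:
        base = rng.uniform(*base_cq_range)
        fold = 1.0 if g in reference_genes else folds.get(g, 1.0)
        for cond, shift in (("untreated", 0.0), ("treated", -np.log2(fold))):
            for rep in range(replicates):
                noise = rng.normal(0.0, cq_noise_sd) if cq_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": g,
                        "condition": cond,
                        "replicate": rep,
                        "cq": base + shift + noise,
                    }
                )
    df = pd.DataFrame(rows)
    table = CqTable(df=df, reference_genes=list(reference_genes))
    return table


# ---------------------------------------------------------------------------
# Detection scoring against ground truth
# ---------------------------------------------------------------------------

def detection_performance(
    true_positions: np.ndarray,
    detected_positions: np.ndarray,
    radius_px: float = 2.0,
) -> tuple[float, float]:
    """(recall, precision) of detections against ground-truth positions.

    Neighborhood matching: a true spot counts as recovered when any
    detection lies within ``radius_px`` of it, and a detection counts as
    correct when any true spot lies within ``radius_px`` of it.
    """
    true_positions = np.asarray(true_positions, float).reshape(-1, 2)
    detected_positions = np.asarray(detected_positions, float).reshape(-1, 2)
    if len(true_positions) == 0:
        return (1.0, 1.0 if len(detected_positions) == 0 else 0.0)
    if len(detected_positions) == 0:
        return (0.0, 1.0)
    d2 = ((true_positions[:, None, :] - detected_positions[None, :, :]) ** 2).sum(-1)
    r2 = radius_px**2
    recall = float((d2.min(axis=1) <= r2).mean())
    precision = float((d2.min(axis=0) <= r2).mean())
    return recall, precision
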