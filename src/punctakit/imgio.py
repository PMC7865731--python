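"""Calibrated image-stack I/O, region masks and two-channel alignment.

The in-memory substrate for every imaging stage is :class:`ImageStack`, a
float array indexed ``(channel, frame, row, col)`` carrying its spatial
calibration (pixel pitch in nm, e.g. 160 nm/px for the TIRF data this
package targets) and, for time-lapses, the frame interval in seconds.

Conventions used throughout the package: coordinates are 0-based
``(row, col)`` with the origin at the top-left and pixel centers at integer
coordinates.

Stacks are stored as multi-page TIFF with a JSON calibration sidecar
``{pixel_size_nm, frame_interval_s, channel_names}``; masks as single-page
label TIFF or run-length JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

from .errors import (
    AlignmentError,
    CalibrationError,
    MaskError,
    TimeAxisError,
)

MASK_KINDS = ("cell", "background", "nucleus-label")


@dataclass
class ImageStack:
    """A calibrated fluorescence image stack.

    Parameters
    ----------
    data:
        Intensity array indexed ``(channel, frame, row, col)``. Stored as
        float64; all values must be finite and non-negative.
    pixel_size_nm:
        Physical pixel pitch in nanometres (> 0).
    frame_interval_s:
        Seconds between frames; ``None`` for single-frame data.
    channel_names:
        Ordered channel labels, one per channel.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"ImageStack data must be 4-D (channel, frame, row, col); "
                f"got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageStack intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("ImageStack intensities must be >= 0")
        if not self.pixel_size_nm or self.pixel_size_nm <= 0:
            raise CalibrationError("pixel_size_nm must be > 0")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise CalibrationError("frame_interval_s must be > 0 when given")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must equal channel count")

    # -- geometry helpers -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def frame(self, channel: int = 0, frame: int = 0) -> np.ndarray:
        """A single 2-D frame view."""
        return self.data[channel, frame]

    def require_time_axis(self) -> None:
        """Raise unless this stack is a calibrated time-lapse."""
        if self.n_frames < 2 or self.frame_interval_s is None:
            raise TimeAxisError(
                "operation requires a time-lapse stack with a frame interval"
            )


@dataclass
class RegionMask:
    """A per-pixel region: boolean cell/background mask or integer labels."""

    kind: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in MASK_KINDS:
            raise MaskError(f"mask kind must be one of {MASK_KINDS}")
        self.mask = np.asarray(self.mask)
        if self.kind == "nucleus-label":
            self.mask = self.mask.astype(np.int32)
        else:
            self.mask = self.mask.astype(bool)
        if self.mask.ndim != 2:
            raise MaskError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        if self.kind == "nucleus-label":
            return int(np.count_nonzero(self.mask))
        return int(self.mask.sum())

    def area_um2(self, pixel_size_nm: float) -> float:
        return self.area_px * (pixel_size_nm / 1000.0) ** 2

    def require_nonempty(self) -> None:
        if self.area_px == 0:
            raise MaskError(f"{self.kind} mask is empty")


def check_disjoint(cell: RegionMask, background: RegionMask) -> None:
    """Cell and off-cell background regions must not overlap."""
    if cell.mask.shape != background.mask.shape:
        raise MaskError("cell and background masks have different shapes")
    if np.any(cell.mask & background.mask):
        raise MaskError("cell and background masks overlap")


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stack(stack: ImageStack, path: str | Path, dtype=None) -> None:
    """Write a stack as multi-page TIFF plus a JSON calibration sidecar.

    Integer dtypes round-trip bit-exactly; float data is written as float32
    unless ``dtype`` says otherwise.
    """
    path = Path(path)
    data = stack.data
    if dtype is not None:
        data = data.astype(dtype)
    elif np.allclose(data, np.round(data)) and data.max(initial=0) < 2**16:
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack", metadata={"axes": "CTYX"})
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "frame_interval_s": stack.frame_interval_s,
        "channel_names": stack.channel_names,
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def load_stack(
    path: str | Path,
    pixel_size_nm: float | None = None,
    frame_interval_s: float | None = None,
    channel_names: Sequence[str] | None = None,
    n_channels: int | None = None,
) -> ImageStack:
    """Read a single- or multi-page TIFF into a normalized ImageStack.

    Axis order is normalized to ``(channel, frame, row, col)``: 2-D input
    becomes a single-channel single-frame stack; 3-D input is interpreted as
    ``(channel, row, col)`` when the leading axis matches ``n_channels`` or
    the sidecar's channel list, and as ``(frame, row, col)`` otherwise.

    Explicit calibration arguments override sidecar metadata. A stack with
    neither raises :class:`CalibrationError`.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    names = list(channel_names) if channel_names else meta.get("channel_names")
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis, np.newaxis]
    elif data.ndim == 3:
        expect = n_channels if n_channels else (len(names) if names else None)
        if expect is not None and data.shape[0] == expect:
            data = data[:, np.newaxis]
        else:
            data = data[np.newaxis]
    elif data.ndim != 4:
        raise ValueError(f"unsupported TIFF dimensionality {data.ndim}")

    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise CalibrationError(
            f"no pixel size for {path}: pass pixel_size_nm or provide a sidecar"
        )
    dt = (
        frame_interval_s
        if frame_interval_s is not None
        else meta.get("frame_interval_s")
    )
    if names is not None and len(names) != data.shape[0]:
        names = None
    return ImageStack(
        data=data,
        pixel_size_nm=float(px),
        frame_interval_s=dt,
        channel_names=names or [],
    )


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------

def save_mask(mask: RegionMask, path: str | Path) -> None:
    """Write a mask as uint16 label TIFF or as run-length JSON (.json)."""
    path = Path(path)
    if path.suffix == ".json":
        arr = mask.mask.astype(np.int32)
        runs = []
        flat = arr.ravel()
        changes = np.flatnonzero(np.diff(flat)) + 1
        starts = np.concatenate([[0], changes])
        ends = np.concatenate([changes, [flat.size]])
        for s, e in zip(starts, ends):
            if flat[s]:
                runs.append([int(s), int(e - s), int(flat[s])])
        path.write_text(
            json.dumps({"kind": mask.kind, "shape": list(arr.shape), "runs": runs})
        )
    else:
        tifffile.imwrite(path, mask.mask.astype(np.uint16))


def load_mask(path: str | Path, kind: str) -> RegionMask:
    """Read a mask written by :func:`save_mask`."""
    path = Path(path)
    if path.suffix == ".json":
        obj = json.loads(path.read_text())
        flat = np.zeros(int(np.prod(obj["shape"])), dtype=np.int32)
        for start, length, label in obj["runs"]:
            flat[start : start + length] = label
        arr = flat.reshape(obj["shape"])
    else:
        arr = tifffile.imread(path)
    return RegionMask(kind=kind, mask=arr)


# ---------------------------------------------------------------------------
# Two-channel alignment
# ---------------------------------------------------------------------------

def _quadratic_offset(cm: float, c0: float, cp: float) -> float:
    """Subpixel offset of a parabola through three equidistant samples."""
    denom = cm - 2.0 * c0 + cp
    if denom == 0:
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_shift(reference: np.ndarray, moving: np.ndarray) -> tuple[float, float]:
    """Displacement ``(drow, dcol)`` of ``moving`` relative to ``reference``.

    A positive ``drow`` means the moving channel's content sits ``drow``
    pixels further down than the reference. Estimated as the peak of the
    circular cross-correlation of the mean-subtracted images, refined to
    subpixel precision by a separable quadratic fit around the integer peak.
    Translating the moving channel by the negated displacement aligns it.
    """
    a = np.asarray(reference, dtype=np.float64)
    b = np.asarray(moving, dtype=np.float64)
    if a.shape != b.shape:
        raise AlignmentError("channels must have identical shape")
    a = a - a.mean()
    b = b - b.mean()
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise AlignmentError("alignment undetermined: featureless channel")
    corr = np.real(np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b))))
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = []
    for axis, idx in enumerate(peak):
        n = corr.shape[axis]
        cm = corr[_index(peak, axis, idx - 1, n)]
        cp = corr[_index(peak, axis, idx + 1, n)]
        c0 = corr[peak]
        sub = _quadratic_offset(cm, c0, cp)
        val = idx + sub
        if val > n / 2:
            val -= n
        shift.append(-val)
    return float(shift[0]), float(shift[1])


def _index(peak: tuple[int, ...], axis: int, value: int, n: int):
    idx = list(peak)
    idx[axis] = value % n
    return tuple(idx)


def align_channels(
    stack: ImageStack, reference_channel: int = 0, channel: int | None = None
) -> tuple[ImageStack, tuple[float, float]]:
    """Correct the misalignment between two colour channels.

    The non-reference channel is translated by the (subpixel) shift that
    maximizes its cross-correlation with the reference channel; the shift
    ``(drow, dcol)`` applied is returned alongside the corrected stack.
    Rotation and scale changes are out of scope: only translation is
    corrected.
    """
    if stack.n_channels < 2:
        raise AlignmentError("need at least two channels to align")
    if channel is None:
        channel = next(
            c for c in range(stack.n_channels) if c != reference_channel
        )
    ref = stack.data[reference_channel].mean(axis=0)
    mov = stack.data[channel].mean(axis=0)
    shift = estimate_shift(ref, mov)
    correction = (-shift[0], -shift[1])
    data = stack.data.copy()
    for t in range(stack.n_frames):
        data[channel, t] = ndimage.shift(
            stack.data[channel, t], correction, order=1, mode="nearest"
        )
    data = np.clip(data, 0, None)
    aligned = ImageStack(
        data=data,
        pixel_size_nm=stack.pixel_size_nm,
        frame_interval_s=stack.frame_interval_s,
        channel_names=list(stack.channel_names),
    )
    return aligned, shift
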