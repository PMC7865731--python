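"""Punctate-spot detection ("find maxima") and cluster density.

The detector reimplements the ImageJ find-maxima semantics: starting from
the brightest pixel, regions are grown downhill level by level; when two
regions meet at a saddle, the weaker peak's prominence is its height above
that saddle, and only peaks whose prominence exceeds the noise tolerance
are reported. Plateau maxima are merged to their centroid and positions
are refined to subpixel precision by a 3x3 quadratic fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MaskError, ParameterError
from .imgio import RegionMask


@dataclass
class Punctum:
    """A detected diffraction-limited cluster."""

    frame: int
    position: tuple[float, float]  # (row, col), subpixel
    peak_intensity: float
    prominence: float

    @property
    def row(self) -> float:
        return self.position[0]

    @property
    def col(self) -> float:
        return self.position[1]


def positions_of(puncta) -> np.ndarray:
    """(n, 2) array of (row, col) positions from puncta or coordinate pairs."""
    out = []
    for p in puncta:
        if isinstance(p, Punctum):
            out.append(p.position)
        else:
            out.append((float(p[0]), float(p[1])))
    return np.asarray(out, dtype=float).reshape(-1, 2)


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _peak_persistence(image: np.ndarray):
    """All candidate maxima of ``image`` with their prominence.

    Pixels are processed in descending intensity order and merged with a
    union-find structure (descending flood-fill region growing). A region's
    peak dies when it first touches a region with a higher peak; its
    prominence is peak height minus the saddle level. The globally highest
    peak's prominence is its height above the image minimum.

    Returns a list of ``(row, col, peak_value, prominence)``.
    """
    h, w = image.shape
    flat = image.ravel()
    n = flat.size
    # stable descending order; ties broken by pixel index (deterministic)
    order = np.argsort(-flat, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    parent = np.full(n, -1, dtype=np.int64)  # -1: unprocessed
    peak_val = {}
    peak_idx = {}
    results = []

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    flat_list = flat  # local alias
    rank_l = rank
    for p in order:
        p = int(p)
        r, c = divmod(p, w)
        v = flat_list[p]
        roots = []
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                q = rr * w + cc
                if rank_l[q] < rank_l[p]:
                    root = find(q)
                    if root not in roots:
                        roots.append(root)
        if not roots:
            parent[p] = p
            peak_val[p] = v
            peak_idx[p] = p
            continue
        # merge into the component with the highest peak
        best = max(roots, key=lambda t: (peak_val[t], -peak_idx[t]))
        for root in roots:
            if root is not best and root != best:
                pers = peak_val[root] - v
                pk = peak_idx[root]
                results.append((pk // w, pk % w, peak_val[root], pers))
                parent[root] = best
        parent[p] = best

    # surviving components: prominence above the global minimum
    vmin = flat.min()
    seen = set()
    for root in list(peak_val):
        top = find(root)
        if top in seen:
            continue
        seen.add(top)
        pk = peak_idx[top]
        results.append((pk // w, pk % w, peak_val[top], peak_val[top] - vmin))
    return results


def _plateau_centroid(image: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Centroid of the connected plateau of equal-valued pixels at (r, c)."""
    h, w = image.shape
    v = image[r, c]
    # quick exit: isolated peak pixel
    if not any(
        0 <= r + dr < h and 0 <= c + dc < w and image[r + dr, c + dc] == v
        for dr, dc in _NEIGHBORS
    ):
        return float(r), float(c)
    stack = [(r, c)]
    seen = {(r, c)}
    while stack:
        rr, cc = stack.pop()
        for dr, dc in _NEIGHBORS:
            nr, nc = rr + dr, cc + dc
            if 0 <= nr < h and 0 <= nc < w and (nr, nc) not in seen:
                if image[nr, nc] == v:
                    seen.add((nr, nc))
                    stack.append((nr, nc))
    pts = np.asarray(list(seen), dtype=float)
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def _subpixel_refine(image: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Separable 3x3 quadratic refinement of an interior integer maximum."""
    h, w = image.shape
    if not (1 <= r < h - 1 and 1 <= c < w - 1):
        return float(r), float(c)
    out = [float(r), float(c)]
    for axis, (m, z, p) in enumerate(
        [
            (image[r - 1, c], image[r, c], image[r + 1, c]),
            (image[r, c - 1], image[r, c], image[r, c + 1]),
        ]
    ):
        denom = m - 2 * z + p
        if denom < 0:  # proper curvature
            out[axis] += float(np.clip(0.5 * (m - p) / denom, -0.5, 0.5))
    return out[0], out[1]


def find_maxima(
    image: np.ndarray,
    noise_tolerance: float,
    within: RegionMask | np.ndarray | None = None,
    edge_exclusion_px: int = 3,
    subpixel: bool = True,
    frame: int = 0,
) -> list[Punctum]:
    """Detect punctate local maxima with prominence above ``noise_tolerance``.

    A maximum is reported when its height above the highest saddle
    connecting it to any stronger maximum strictly exceeds the tolerance
    (ImageJ noise-tolerance semantics). Maxima within ``edge_exclusion_px``
    of the image border are dropped, and ``within`` restricts detections to
    a region mask. Raising the tolerance can never increase the number of
    detections. An empty list is a valid result.
    """
    if noise_tolerance < 0:
        raise ParameterError("noise_tolerance must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ParameterError("find_maxima expects a single 2-D frame")
    h, w = image.shape
    mask = None
    if within is not None:
        mask = within.mask if isinstance(within, RegionMask) else np.asarray(within)
        mask = mask.astype(bool)
        if mask.shape != image.shape:
            raise MaskError("within mask shape does not match image")

    out: list[Punctum] = []
    for r, c, peak, prom in _peak_persistence(image):
        if prom <= noise_tolerance:
            continue
        pr, pc = _plateau_centroid(image, int(r), int(c))
        if subpixel and (pr, pc) == (float(r), float(c)):
            pr, pc = _subpixel_refine(image, int(r), int(c))
        ir, ic = int(round(pr)), int(round(pc))
        if not (
            edge_exclusion_px <= pr <= h - 1 - edge_exclusion_px
            and edge_exclusion_px <= pc <= w - 1 - edge_exclusion_px
        ):
            continue
        if mask is not None and not mask[min(max(ir, 0), h - 1), min(max(ic, 0), w - 1)]:
            continue
        out.append(
            Punctum(
                frame=frame,
                position=(pr, pc),
                peak_intensity=float(peak),
                prominence=float(prom),
            )
        )
    out.sort(key=lambda p: (-p.peak_intensity, p.position))
    return out


def auto_tolerance(
    image: np.ndarray, bg_mask: RegionMask | np.ndarray | None = None, k: float = 5.0
) -> float:
    """Scale-free default noise tolerance: ``k`` x robust background sd.

    The robust sd is the median absolute deviation times 1.4826, computed
    over the background region when one is given, else the whole frame.
    """
    image = np.asarray(image, dtype=float)
    if bg_mask is not None:
        m = bg_mask.mask if isinstance(bg_mask, RegionMask) else np.asarray(bg_mask)
        vals = image[m.astype(bool)]
    else:
        vals = image.ravel()
    if vals.size == 0:
        raise MaskError("empty region for tolerance estimation")
    mad = np.median(np.abs(vals - np.median(vals)))
    return float(k * 1.4826 * mad)


def cluster_density(
    puncta, cell_mask: RegionMask | np.ndarray, pixel_size_nm: float
) -> float:
    """Puncta per square micron of cell area.

    Counts the puncta whose (rounded) position lies inside the cell mask
    and divides by the mask area in um^2.
    """
    mask = cell_mask.mask if isinstance(cell_mask, RegionMask) else np.asarray(cell_mask)
    mask = mask.astype(bool)
    area_px = int(mask.sum())
    if area_px == 0:
        raise MaskError("cluster density undefined for an empty cell mask")
    area_um2 = area_px * (pixel_size_nm / 1000.0) ** 2
    pos = positions_of(puncta)
    if len(pos) == 0:
        return 0.0
    rows = np.clip(np.round(pos[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round(pos[:, 1]).astype(int), 0, mask.shape[1] - 1)
    inside = mask[rows, cols].sum()
    return float(inside) / area_um2
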