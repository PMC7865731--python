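"""Circle-annulus binding score (dF/S) and co-localization percentage.

At each punctum site the mean fluorescence is read in a central circle
(default 3 px diameter, ~0.5 um at 160 nm/px), a surrounding contiguous
annulus (outer diameter 5 px, ~0.8 um) and an off-cell background region.
The site-specific fluorescence is dF = circle - annulus; the local unbound
fluorescence is S = annulus - background. Their ratio dF/S measures binding
at the site independently of expression level: positive values indicate
binding, negative values exclusion. Pixel membership is decided by the
pixel-center distance from the (possibly subpixel) site center, so the
circle covers r <= 1.5 px and the annulus 1.5 < r <= 2.5 px by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BorderError, InsufficientSitesError, MaskError, ParameterError
from .imgio import RegionMask
from .puncta import positions_of


@dataclass
class SiteMeasurement:
    """Fluorescence triple at one site and the derived binding score."""

    center: tuple[float, float]
    c: float  # mean in central circle
    a: float  # mean in annulus
    bg: float  # mean in off-cell background
    delta_f: float  # c - a
    s: float  # a - bg
    score: float | None  # delta_f / s, None when s <= 0

    @property
    def defined(self) -> bool:
        return self.score is not None


def _region_means(
    image: np.ndarray,
    center: tuple[float, float],
    r_circle: float,
    r_annulus: float,
) -> tuple[float, float]:
    """Means over pixels whose centers fall in the circle and the annulus."""
    h, w = image.shape
    cr, cc = center
    r0 = int(np.floor(cr - r_annulus))
    r1 = int(np.ceil(cr + r_annulus))
    c0 = int(np.floor(cc - r_annulus))
    c1 = int(np.ceil(cc + r_annulus))
    if r0 < 0 or c0 < 0 or r1 > h - 1 or c1 > w - 1:
        raise BorderError(
            f"site {center} closer than the annulus radius to the border"
        )
    rows = np.arange(r0, r1 + 1)[:, None]
    cols = np.arange(c0, c1 + 1)[None, :]
    d = np.sqrt((rows - cr) ** 2 + (cols - cc) ** 2)
    window = image[r0 : r1 + 1, c0 : c1 + 1]
    in_circle = d <= r_circle
    in_annulus = (d > r_circle) & (d <= r_annulus)
    return float(window[in_circle].mean()), float(window[in_annulus].mean())


def measure_site(
    image: np.ndarray,
    center: tuple[float, float],
    bg_mask: RegionMask | np.ndarray,
    circle_diam_px: float = 3.0,
    annulus_outer_diam_px: float = 5.0,
) -> SiteMeasurement:
    """Measure c, a, bg and the dF/S score at one site.

    ``s <= 0`` flags the score undefined (``None``) rather than raising;
    a site closer than the annulus radius to the border raises
    :class:`BorderError`.
    """
    if circle_diam_px <= 0 or annulus_outer_diam_px <= circle_diam_px:
        raise ParameterError("need 0 < circle diameter < annulus outer diameter")
    image = np.asarray(image, dtype=np.float64)
    mask = bg_mask.mask if isinstance(bg_mask, RegionMask) else np.asarray(bg_mask)
    mask = mask.astype(bool)
    if mask.shape != image.shape:
        raise MaskError("background mask shape does not match image")
    if not mask.any():
        raise MaskError("background mask is empty")
    c, a = _region_means(
        image, (float(center[0]), float(center[1])), circle_diam_px / 2.0,
        annulus_outer_diam_px / 2.0,
    )
    bg = float(image[mask].mean())
    delta_f = c - a
    s = a - bg
    score = (delta_f / s) if s > 0 else None
    return SiteMeasurement(
        center=(float(center[0]), float(center[1])),
        c=c, a=a, bg=bg, delta_f=delta_f, s=s, score=score,
    )


@dataclass
class CellBindingResult:
    """Per-cell mean dF/S with the underlying per-site table."""

    mean_score: float
    n_sites: int
    n_undefined: int
    table: pd.DataFrame


def cell_binding_score(
    image: np.ndarray,
    sites,
    bg_mask: RegionMask | np.ndarray,
    min_sites: int = 7,
    allow_fewer: bool = False,
    circle_diam_px: float = 3.0,
    annulus_outer_diam_px: float = 5.0,
) -> CellBindingResult:
    """Mean dF/S over well-separated sites of one cell.

    Sites whose score is undefined (S <= 0) or that fall too close to the
    border are excluded and counted, never imputed. Fewer than ``min_sites``
    valid sites raises :class:`InsufficientSitesError` unless
    ``allow_fewer`` overrides the minimum.
    """
    rows = []
    for r, c in positions_of(sites):
        try:
            m = measure_site(
                image, (r, c), bg_mask,
                circle_diam_px=circle_diam_px,
                annulus_outer_diam_px=annulus_outer_diam_px,
            )
        except BorderError:
            rows.append(
                {"row": r, "col": c, "c": np.nan, "a": np.nan, "bg": np.nan,
                 "delta_f": np.nan, "s": np.nan, "score": np.nan,
                 "status": "border"}
            )
            continue
        rows.append(
            {"row": r, "col": c, "c": m.c, "a": m.a, "bg": m.bg,
             "delta_f": m.delta_f, "s": m.s,
             "score": m.score if m.defined else np.nan,
             "status": "ok" if m.defined else "undefined"}
        )
    table = pd.DataFrame(
        rows,
        columns=["row", "col", "c", "a", "bg", "delta_f", "s", "score", "status"],
    )
    valid = table["score"].dropna()
    if len(valid) < min_sites and not allow_fewer:
        raise InsufficientSitesError(
            f"{len(valid)} valid sites < required minimum {min_sites}"
        )
    if len(valid) == 0:
        raise InsufficientSitesError("no valid sites at all")
    return CellBindingResult(
        mean_score=float(valid.mean()),
        n_sites=len(table),
        n_undefined=int((table["status"] != "ok").sum()),
        table=table,
    )


def colocalization_percent(
    reference_puncta,
    query_puncta,
    match_radius_px: float = 1.0,
    cutout_um2: float = 11.0,
    pixel_size_nm: float = 160.0,
) -> float:
    """Percentage of reference puncta with a query punctum within radius.

    Automates the observer call: a reference punctum counts as co-localized
    when the nearest query punctum center lies within ``match_radius_px``
    (one pixel by default) of its center. The square cutout area (default
    11 um^2, a 21x21 px window at 160 nm/px) bounds the search
    neighbourhood around each reference punctum.
    """
    ref = positions_of(reference_puncta)
    if len(ref) == 0:
        raise ParameterError("co-localization undefined for empty reference")
    qry = positions_of(query_puncta)
    if len(qry) == 0:
        return 0.0
    half_window = (np.sqrt(cutout_um2) * 1000.0 / pixel_size_nm) / 2.0
    d = np.abs(ref[:, None, :] - qry[None, :, :])
    in_cutout = (d <= half_window).all(axis=2)
    d2 = (d**2).sum(axis=2)
    hit = (in_cutout & (d2 <= match_radius_px**2)).any(axis=1)
    return float(100.0 * hit.mean())
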