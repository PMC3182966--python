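"""Regional background correction and dust detection/removal.

Slide fluorescence is not uniform, so each spot's background is estimated
*locally*: the median intensity of an annulus around the spot's actual
boundary, excluding its own and its neighbors' masks.  Net volume is then
``raw volume - background level * area``, the quantity fed to the
SuperCurve.  Compact high-intensity contaminants (dust) inside a spot are
found as connected runs of mask pixels far above the spot's own robust
level and in-painted with the spot median before the volume is recomputed;
a spot that is mostly dust is excluded outright.  All estimators are
medians/MADs: robustness is the point of regional correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gridding import SpotMeasurement
from .images import ArrayImage

MIN_BACKGROUND_PIXELS = 20


@dataclass
class BackgroundEstimate:
    level: float  # intensity per pixel
    inner_radius: float
    outer_radius: float
    n_pixels: int
    low_confidence: bool = False


@dataclass
class DustRecord:
    address: tuple[int, int, int]
    pixels: np.ndarray  # (n, 2) image coordinates of dusty pixels
    contaminating_intensity: float  # estimated excess counts, >= 0
    action: str  # "removed" | "spot_excluded"


def regional_background(
    image: ArrayImage,
    spot: SpotMeasurement,
    neighbor_masks=None,
    occupancy: np.ndarray | None = None,
    inner_margin: float = 2.0,
    width: float = 6.0,
    max_growth: float = 14.0,
) -> BackgroundEstimate:
    """Median intensity of an annulus around the spot's actual boundary.

    The annulus starts ``inner_margin`` px outside the spot's equivalent
    radius and is ``width`` px wide; pixels inside any spot mask (own or
    neighbors', via ``occupancy`` or ``neighbor_masks``) are ineligible.
    If fewer than 20 eligible pixels remain the outer radius grows in 2 px
    steps up to ``max_growth`` extra; failing that the estimate is flagged
    low-confidence, never an exception.
    """
    h, w = image.shape
    if occupancy is None:
        occupancy = spot.full_mask((h, w))
        for m in neighbor_masks or []:
            occupancy = occupancy | (m.full_mask((h, w)) if isinstance(m, SpotMeasurement) else m)
    cy, cx = spot.center
    r_eq = float(np.sqrt(max(spot.area, 1) / np.pi))
    inner = r_eq + inner_margin
    outer = inner + width
    grow = 0.0
    while True:
        ro = outer + grow
        y0 = max(0, int(np.floor(cy - ro)))
        y1 = min(h, int(np.ceil(cy + ro)) + 1)
        x0 = max(0, int(np.floor(cx - ro)))
        x1 = min(w, int(np.ceil(cx + ro)) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r = np.hypot(yy - cy, xx - cx)
        ann = (r >= inner) & (r <= ro) & ~occupancy[y0:y1, x0:x1]
        n = int(ann.sum())
        if n >= MIN_BACKGROUND_PIXELS or grow >= max_growth:
            break
        grow += 2.0
    if n == 0:
        return BackgroundEstimate(level=0.0, inner_radius=inner,
                                  outer_radius=ro, n_pixels=0,
                                  low_confidence=True)
    level = float(np.median(image.pixels[y0:y1, x0:x1][ann]))
    return BackgroundEstimate(
        level=level, inner_radius=inner, outer_radius=ro, n_pixels=n,
        low_confidence=n < MIN_BACKGROUND_PIXELS,
    )


def net_volume(spot: SpotMeasurement, bg: BackgroundEstimate) -> float:
    """Background-corrected volume, floored at zero.

    ``net = raw_volume - level * area``; a negative result is clipped to 0
    and the spot flagged ``negative_net``.
    """
    net = spot.raw_volume - bg.level * spot.area
    if net < 0:
        spot.flags.add("negative_net")
        return 0.0
    return float(net)


def detect_dust(
    image: ArrayImage,
    spot: SpotMeasurement,
    k_d: float = 5.0,
    area_cap: float = 0.25,
    min_dust_area: int = 3,
) -> DustRecord | None:
    """Find compact high-intensity contaminants inside a spot's mask.

    Dusty pixels exceed ``median + k_d * MAD`` of the spot's own mask
    pixels; connected components of at least ``min_dust_area`` pixels and
    at most ``area_cap`` of the spot area count as dust.  When dusty
    pixels exceed ``area_cap`` of the spot area the whole spot is excluded
    (``action="spot_excluded"``).  Returns ``None`` for a clean spot.
    """
    if "missing" in spot.flags:
        raise ValueError("dust detection requires a segmented (non-missing) spot")
    y0, x0 = spot.bbox
    vals = image.pixels[y0:y0 + spot.mask.shape[0],
                        x0:x0 + spot.mask.shape[1]].astype(float)
    inmask = vals[spot.mask]
    med = float(np.median(inmask))
    mad = float(np.median(np.abs(inmask - med)))
    thr = med + k_d * max(mad, 1e-9)
    hot = (vals > thr) & spot.mask
    lab, n = ndimage.label(hot)
    if n == 0:
        return None
    dust_local = np.zeros_like(hot)
    total_hot = 0
    for li in range(1, n + 1):
        comp = lab == li
        a = int(comp.sum())
        if a < min_dust_area:
            continue
        total_hot += a
        dust_local |= comp
    if total_hot == 0:
        return None
    ys, xs = np.nonzero(dust_local)
    excess = float(np.sum(vals[dust_local] - med))
    action = "spot_excluded" if total_hot > area_cap * spot.area else "removed"
    return DustRecord(
        address=spot.address,
        pixels=np.stack([ys + y0, xs + x0], axis=1),
        contaminating_intensity=max(excess, 0.0),
        action=action,
    )


def dust_report(records) -> "pd.DataFrame":
    """QC table with one row per dust record (write with ``to_csv``)."""
    import pandas as pd
    rows = [{
        "block": r.address[0], "row": r.address[1], "col": r.address[2],
        "n_dust_pixels": int(len(r.pixels)),
        "contaminating_intensity": r.contaminating_intensity,
        "action": r.action,
    } for r in records]
    return pd.DataFrame(rows, columns=["block", "row", "col", "n_dust_pixels",
                                       "contaminating_intensity", "action"])


def remove_dust(
    image: ArrayImage,
    spot: SpotMeasurement,
    dust: DustRecord,
) -> SpotMeasurement:
    """In-paint dust pixels with the spot's clean median and re-measure.

    Dust pixels take the median of the spot's non-dust mask pixels; the
    raw volume is recomputed over the unchanged mask and the measurement
    flagged ``dust_corrected``.  Only valid for ``action="removed"``.
    """
    if dust.action != "removed":
        raise ValueError(
            f"spot {spot.address} was excluded for dust; nothing to remove"
        )
    y0, x0 = spot.bbox
    vals = image.pixels[y0:y0 + spot.mask.shape[0],
                        x0:x0 + spot.mask.shape[1]].astype(float)
    dust_local = np.zeros_like(spot.mask)
    if len(dust.pixels):
        dust_local[dust.pixels[:, 0] - y0, dust.pixels[:, 1] - x0] = True
    dust_local &= spot.mask
    if not dust_local.any():
        return spot
    clean = spot.mask & ~dust_local
    fill = float(np.median(vals[clean])) if clean.any() else 0.0
    vals = vals.copy()
    vals[dust_local] = fill
    raw = float(vals[spot.mask].sum())
    return SpotMeasurement(
        address=spot.address, center=spot.center, bbox=spot.bbox,
        mask=spot.mask, area=spot.area, raw_volume=raw,
        flags=set(spot.flags) | {"dust_corrected"},
    )
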