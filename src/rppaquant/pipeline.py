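"""End-to-end quantification: image + layout -> per-series readout table.

The batch pipeline chains grid location, actual-boundary segmentation,
regional background correction, dust detection/removal, joint SuperCurve
fitting with one outlier-flagging pass, and the EC50-style per-series
readouts; optionally a companion total-protein (Sypro Ruby) image of the
same layout normalizes for loading.  The result is a spreadsheet-shaped
table, one row per dilution series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import (BackgroundEstimate, DustRecord, detect_dust,
                         net_volume, regional_background, remove_dust)
from .gridding import GridEstimate, locate_grid, segment_array
from .images import ArrayImage
from .layout import ArrayLayout
from .supercurve import (DilutionObservation, FitConfig, SuperCurveFit,
                         fit_supercurve, flag_outliers, series_readouts)

log = logging.getLogger(__name__)

QUANT_COLUMNS = ["array_id", "antibody", "sample_id", "ec50_readout", "se",
                 "normalized_readout", "n_spots_used", "flags"]


@dataclass
class PipelineConfig:
    segmentation_k: float = 3.0
    min_area: int = 9
    dust_removal: bool = True
    outlier_threshold: float = 3.0
    fit: FitConfig = field(default_factory=FitConfig)


@dataclass
class ArrayQuantResult:
    """Everything the pipeline produced for one array."""

    grid: GridEstimate
    measurements: list
    backgrounds: list[BackgroundEstimate]
    dust_records: list[DustRecord]
    observations: list[DilutionObservation]
    fit: SuperCurveFit
    readouts: dict[str, object]  # series_id -> SeriesReadout


def measure_array(image: ArrayImage, layout: ArrayLayout,
                  config: PipelineConfig | None = None):
    """Segment + background-correct + de-dust every spot.

    Returns ``(measurements, backgrounds, dust_records, observations)``
    where observations carry each sample spot's net volume at its
    dilution factor, ready for SuperCurve fitting.
    """
    config = config or PipelineConfig()
    grid = locate_grid(image, layout)
    measurements = segment_array(image, layout, grid,
                                 k=config.segmentation_k,
                                 min_area=config.min_area)
    occupancy = np.zeros(image.shape, dtype=bool)
    for m in measurements:
        y0, x0 = m.bbox
        occupancy[y0:y0 + m.mask.shape[0], x0:x0 + m.mask.shape[1]] |= m.mask

    backgrounds, dust_records, observations = [], [], []
    for i, (ann, m) in enumerate(zip(layout.spots, measurements)):
        if config.dust_removal and "missing" not in m.flags:
            rec = detect_dust(image, m)
            if rec is not None:
                dust_records.append(rec)
                if rec.action == "removed":
                    m = remove_dust(image, m, rec)
                    measurements[i] = m
                else:
                    m.flags.add("spot_excluded")
        bg = regional_background(image, m, occupancy=occupancy)
        backgrounds.append(bg)
        net = net_volume(m, bg)
        if ann.role == "sample":
            observations.append(DilutionObservation(
                series_id=ann.series_id, x=ann.dilution_factor, y=net,
                flags=set(m.flags)))
    return grid, measurements, backgrounds, dust_records, observations


def quantify_array(
    image: ArrayImage,
    layout: ArrayLayout,
    sypro_image: ArrayImage | None = None,
    array_id: str = "array",
    antibody: str = "",
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, ArrayQuantResult]:
    """Run the full pipeline on one array (and optional Sypro companion).

    Returns the quantification table (one row per dilution series) and
    the detailed :class:`ArrayQuantResult`.
    """
    config = config or PipelineConfig()
    grid, measurements, backgrounds, dust_records, observations = \
        measure_array(image, layout, config)
    fit = fit_supercurve(observations, config.fit)
    fit = flag_outliers(fit, config.outlier_threshold, config.fit)
    readouts = {r.series_id: r for r in series_readouts(fit, config.fit)}

    sypro_readouts = None
    if sypro_image is not None:
        *_, sypro_obs = measure_array(sypro_image, layout, config)
        sfit = fit_supercurve(sypro_obs, config.fit)
        sfit = flag_outliers(sfit, config.outlier_threshold, config.fit)
        sypro_readouts = {r.series_id: r for r in series_readouts(sfit, config.fit)}

    flags_by_series: dict[str, set] = {}
    for m, ann in zip(measurements, layout.spots):
        if ann.role == "sample":
            flags_by_series.setdefault(ann.series_id, set()).update(m.flags)

    rows = []
    for sid, r in readouts.items():
        normalized = np.nan
        if sypro_readouts is not None:
            if sid in sypro_readouts and sypro_readouts[sid].ec50_readout > 0:
                normalized = r.ec50_readout / sypro_readouts[sid].ec50_readout
            else:
                log.warning("no total-protein readout for series %s", sid)
        rows.append({
            "array_id": array_id, "antibody": antibody, "sample_id": sid,
            "ec50_readout": r.ec50_readout, "se": r.se,
            "normalized_readout": normalized,
            "n_spots_used": r.n_spots_used,
            "flags": ";".join(sorted(flags_by_series.get(sid, set()))),
        })
    table = pd.DataFrame(rows, columns=QUANT_COLUMNS)
    result = ArrayQuantResult(grid=grid, measurements=measurements,
                              backgrounds=backgrounds,
                              dust_records=dust_records,
                              observations=observations, fit=fit,
                              readouts=readouts)
    return table, result


def write_quant_table(table: pd.DataFrame, path, allow_empty: bool = False):
    """Write the quantification spreadsheet as CSV (>= 6 significant digits)."""
    if table.empty and not allow_empty:
        raise ValueError("refusing to write an empty quantification table "
                         "(pass allow_empty=True to override)")
    table.to_csv(path, index=False, float_format="%.8g")
    return path


def read_quant_table(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=True,
                       dtype={"flags": str}).fillna({"flags": ""})


def write_overlay(image: ArrayImage, measurements, path):
    """QC overlay for manual review: spot boundaries drawn on the image.

    Boundaries are painted in green (missing spots in red) on a
    contrast-stretched RGB rendering, written as an 8-bit TIFF.
    """
    import tifffile
    from skimage.segmentation import find_boundaries

    lo, hi = np.percentile(image.pixels, [1, 99.5])
    base = np.clip((image.pixels.astype(float) - lo) / max(hi - lo, 1), 0, 1)
    rgb = np.stack([base] * 3, axis=-1)
    for m in measurements:
        edge = find_boundaries(m.mask, mode="inner")
        y0, x0 = m.bbox
        ys, xs = np.nonzero(edge)
        color = (1.0, 0.1, 0.1) if "missing" in m.flags else (0.1, 1.0, 0.1)
        rgb[ys + y0, xs + x0] = color
    tifffile.imwrite(path, (rgb * 255).astype(np.uint8), photometric="rgb")
    return path
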