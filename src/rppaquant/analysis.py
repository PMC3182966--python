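"""Downstream analyses on series readouts.

Total-protein (Sypro Ruby) normalization, non-specific-signal subtraction
for mixture-gradient experiments, gradient linearity, time-course fold
changes relative to a baseline condition, and between-array
reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def normalize_total_protein(readout: float, sypro_readout: float) -> float:
    """Loading-corrected readout: antibody / total-protein-stain readout."""
    if sypro_readout is None or not np.isfinite(sypro_readout) or sypro_readout <= 0:
        raise ValueError(
            f"total-protein readout must be > 0, got {sypro_readout}"
        )
    return float(readout) / float(sypro_readout)


@dataclass
class GradientExperiment:
    """A mixture-gradient titration: readouts per % of target-positive lysate.

    ``calibrated`` holds per-level readouts after subtracting the 0% level
    (the antibody's non-specific signal), so 0% maps to 0 by construction.
    """

    levels: list[float]  # percent, includes 0
    calibrated: dict[float, np.ndarray]
    raw: dict[float, np.ndarray] = field(default_factory=dict)
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None


def subtract_nonspecific(readouts_by_level: dict) -> GradientExperiment:
    """Calibrate gradient readouts against the 0% (non-specific) level.

    The mean readout at 0% target fraction is treated as non-specific
    antibody signal and subtracted from every level; the 0% entry itself
    is re-centered (its residuals around 0 are kept so replicate scatter
    remains visible).
    """
    levels = sorted(float(k) for k in readouts_by_level)
    if 0.0 not in levels:
        raise ValueError("gradient calibration requires a 0% level")
    raw = {lv: np.atleast_1d(np.asarray(readouts_by_level[lv], dtype=float))
           for lv in levels}
    floor = float(np.mean(raw[0.0]))
    calibrated = {lv: raw[lv] - floor for lv in levels}
    return GradientExperiment(levels=levels, calibrated=calibrated, raw=raw)


def gradient_linearity(exp: GradientExperiment):
    """OLS of calibrated readout on mixture fraction.

    Returns ``(slope, intercept, r_squared)`` and stores them (plus
    per-level replicate mean/SD) on the experiment.  A zero-variance
    response has ``r_squared`` defined as 0.
    """
    if len(exp.levels) < 3:
        raise ValueError("need >= 3 distinct gradient levels")
    xs, ys = [], []
    for lv in exp.levels:
        for v in exp.calibrated[lv]:
            xs.append(lv)
            ys.append(v)
    xs, ys = np.asarray(xs), np.asarray(ys)
    if np.ptp(ys) == 0:
        slope, intercept = 0.0, float(ys[0])
        r2 = 0.0
    else:
        res = stats.linregress(xs, ys)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue ** 2)
    exp.slope, exp.intercept, exp.r_squared = slope, intercept, r2
    return slope, intercept, r2


def level_statistics(exp: GradientExperiment, estimator: str = "sd") -> pd.DataFrame:
    """Per-level replicate mean and spread (SD by default, SEM optional)."""
    rows = []
    for lv in exp.levels:
        v = exp.calibrated[lv]
        spread = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        if estimator == "sem" and len(v) > 1:
            spread /= np.sqrt(len(v))
        rows.append({"level": lv, "mean": float(np.mean(v)),
                     "spread": spread, "n": len(v)})
    return pd.DataFrame(rows)


def fold_change(readouts_by_condition: dict, baseline) -> pd.DataFrame:
    """Fold change of each analyte relative to the baseline condition.

    ``readouts_by_condition`` maps condition -> {analyte: normalized
    readout}.  Returns a conditions x analytes table with the baseline
    row identically 1; values are kept at full precision (round only at
    serialization, conventionally 2 decimals).
    """
    if baseline not in readouts_by_condition:
        raise ValueError(f"baseline condition {baseline!r} absent")
    base = readouts_by_condition[baseline]
    analytes = list(base)
    for an, v in base.items():
        if v is None or not np.isfinite(v) or v <= 0:
            raise ValueError(f"baseline readout for {an!r} must be > 0, got {v}")
    rows = {}
    for cond, vals in readouts_by_condition.items():
        rows[cond] = {an: float(vals[an]) / float(base[an])
                      for an in analytes if an in vals}
    df = pd.DataFrame.from_dict(rows, orient="index")[analytes]
    return df


def write_fold_change(df: pd.DataFrame, path, decimals: int = 2):
    """Serialize a fold-change table (2 decimals, matching convention)."""
    df.round(decimals).to_csv(path, float_format=f"%.{decimals}f")
    return path


def reproducibility(readouts_a: dict, readouts_b: dict):
    """Pearson correlation of two arrays' readouts over shared series.

    Returns ``(r, paired_table, n_unmatched)``; series present in only
    one array are excluded and counted.
    """
    shared = [k for k in readouts_a if k in readouts_b]
    n_unmatched = (len(readouts_a) - len(shared)) + (len(readouts_b) - len(shared))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared series, got {len(shared)}")
    a = np.array([readouts_a[k] for k in shared], dtype=float)
    b = np.array([readouts_b[k] for k in shared], dtype=float)
    r = float(stats.pearsonr(a, b).statistic)
    table = pd.DataFrame({"series_id": shared, "readout_a": a, "readout_b": b})
    return r, table, n_unmatched
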