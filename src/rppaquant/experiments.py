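"""Reproducible simulation experiments over the full pipeline.

Each function here simulates arrays with the synthetic generator under
the platform's study conditions (5-step 1:2 dilutions in triplicate,
350 µm pitch, 10% spot-to-spot CV), runs the complete
segmentation + background + SuperCurve pipeline on the rendered images,
and measures a property of scientific interest: the smallest mixture
gradient the readouts can distinguish, segmentation accuracy under grid
and spot shifts, dust detection performance, time-course fold recovery,
and between-array reproducibility.  All are pure functions of their
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .analysis import (fold_change, gradient_linearity, reproducibility,
                       subtract_nonspecific)
from .background import detect_dust
from .gridding import dice, locate_grid, segment_array
from .layout import make_dilution_layout
from .pipeline import PipelineConfig, measure_array
from .simulate import NoiseSpec, inject_dust, render_array
from .supercurve import (SuperCurveParams, fit_supercurve, flag_outliers,
                         invert_concentration, series_readouts)

# Default response curve for simulations: small lower asymptote, 1.5e7
# upper plateau (spots stay well clear of the 16-bit ceiling yet far above
# read noise), and a location putting the 1..1/16 dilution range of unit
# concentration on the informative lower shoulder of the sigmoid, so
# multiplicative printing noise maps to roughly constant log-concentration
# noise (~CV/c) everywhere on the array.
DEFAULT_PARAMS = SuperCurveParams(a=500.0, b=1.5e7, c=0.9, d=0.5)

GRADIENT_LEVELS = (0.0, 25.0, 50.0, 75.0, 100.0)
NONSPECIFIC_FRACTION = 0.08  # antibody floor, relative concentration units


POSITIVE_CONTROL_ID = "POS"
POSITIVE_CONTROL_CONC = 8.0


def _seed_stream(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def _study_layout(sample_ids, conc: dict, **kwargs):
    """Standard study layout: the samples plus a bright positive-control
    series that spans the upper bend of the response curve, as printed
    control lysates do on real arrays; without it every spot would sit on
    the lower shoulder and the curve's asymptote/slope would be poorly
    identified."""
    ids = list(sample_ids) + [POSITIVE_CONTROL_ID]
    conc = dict(conc)
    conc[POSITIVE_CONTROL_ID] = POSITIVE_CONTROL_CONC
    return make_dilution_layout(ids, **kwargs), conc


# -- gradient discrimination (mixture titration) ----------------------------

@dataclass
class GradientReplicate:
    readouts_by_level: dict[float, np.ndarray]  # per-spot concentration estimates
    calibrated_by_level: dict[float, np.ndarray]
    adjacent_p: dict[tuple[float, float], float]
    r_squared: float


def simulate_gradient_replicate(
    seed: int,
    levels=GRADIENT_LEVELS,
    cv: float = 0.10,
    params: SuperCurveParams = DEFAULT_PARAMS,
    nonspecific: float = NONSPECIFIC_FRACTION,
    config: PipelineConfig | None = None,
) -> GradientReplicate:
    """One simulated mixture-gradient array through the full pipeline.

    Five samples (one per mixture level) are printed as standard 15-spot
    dilution series and rendered with the stated multiplicative CV.  The
    per-spot readout is the relative concentration implied by inverting
    the jointly fitted SuperCurve at the spot's net volume; readouts are
    calibrated by subtracting the mean 0%-level readout (non-specific
    signal).  Welch tests compare adjacent levels; linearity is assessed
    on the per-level replicate means.
    """
    config = config or PipelineConfig()
    sample_ids = [f"L{int(lv)}" for lv in levels]
    layout, conc = _study_layout(
        sample_ids, {f"L{int(lv)}": nonspecific + lv / 100.0 for lv in levels})
    noise = NoiseSpec(multiplicative_cv=cv)
    image, _ = render_array(layout, params, conc, noise, seed=seed)

    *_, observations = measure_array(image, layout, config)
    fit = fit_supercurve(observations, config.fit)
    fit = flag_outliers(fit, config.outlier_threshold, config.fit)

    by_level: dict[float, np.ndarray] = {}
    for lv in levels:
        sid = f"L{int(lv)}"
        obs = [o for o in fit.observations
               if o.series_id == sid
               and not ({"missing", "spot_excluded"} & o.flags)]
        est = invert_concentration(
            fit.params, np.array([o.y for o in obs]),
            np.array([o.x for o in obs]))
        by_level[float(lv)] = np.asarray(est, dtype=float)

    floor = float(np.mean(by_level[0.0]))
    calibrated = {lv: v - floor for lv, v in by_level.items()}

    adjacent_p = {}
    lvs = sorted(by_level)
    for lo, hi in zip(lvs[:-1], lvs[1:]):
        t = stats.ttest_ind(calibrated[hi], calibrated[lo], equal_var=False)
        adjacent_p[(lo, hi)] = float(t.pvalue)

    exp = subtract_nonspecific({lv: np.mean(by_level[lv]) for lv in lvs})
    _, _, r2 = gradient_linearity(exp)
    return GradientReplicate(readouts_by_level=by_level,
                             calibrated_by_level=calibrated,
                             adjacent_p=adjacent_p, r_squared=r2)


@dataclass
class GradientStudy:
    n_replicates: int
    detection_rate: dict[tuple[float, float], float]  # adjacent pair -> rate
    detection_rate_by_spacing: dict[float, float]
    smallest_distinguishable_step: float  # percent
    median_r_squared: float


def gradient_discrimination_study(
    seed: int,
    n_replicates: int = 100,
    levels=GRADIENT_LEVELS,
    cv: float = 0.10,
    alpha: float = 0.05,
    required_rate: float = 0.8,
) -> GradientStudy:
    """Monte-Carlo estimate of the smallest distinguishable gradient step.

    Runs ``n_replicates`` independent gradient arrays; an adjacent level
    pair is called distinguishable when its two-sided Welch test reaches
    ``p < alpha`` in at least ``required_rate`` of replicates.  The
    smallest level spacing whose pairs are all distinguishable is the
    study's headline number (the design's spacing is 25%).
    """
    seeds = _seed_stream(seed, n_replicates)
    pair_hits: dict[tuple[float, float], int] = {}
    r2s = []
    for s in seeds:
        rep = simulate_gradient_replicate(s, levels=levels, cv=cv)
        for pair, p in rep.adjacent_p.items():
            pair_hits[pair] = pair_hits.get(pair, 0) + (p < alpha)
        r2s.append(rep.r_squared)
    rates = {pair: hits / n_replicates for pair, hits in pair_hits.items()}

    # group by spacing, then find the smallest spacing with every pair
    # at or above the required detection rate
    by_spacing: dict[float, list[float]] = {}
    for (lo, hi), rate in rates.items():
        by_spacing.setdefault(hi - lo, []).append(rate)
    spacing_rate = {sp: min(v) for sp, v in by_spacing.items()}
    ok = sorted(sp for sp, r in spacing_rate.items() if r >= required_rate)
    smallest = ok[0] if ok else float("inf")
    return GradientStudy(
        n_replicates=n_replicates, detection_rate=rates,
        detection_rate_by_spacing=spacing_rate,
        smallest_distinguishable_step=float(smallest),
        median_r_squared=float(np.median(r2s)),
    )


# -- segmentation under shift ----------------------------------------------

@dataclass
class SegmentationStudy:
    mean_dice: float
    dice_per_spot: np.ndarray
    recovered_shift: tuple[float, float]
    true_shift: tuple[float, float]


def segmentation_shift_study(
    seed: int,
    n_samples: int = 40,
    jitter_frac: float = 0.30,
    global_shift_frac: float = 0.40,
    params: SuperCurveParams = DEFAULT_PARAMS,
) -> SegmentationStudy:
    """Mean Dice overlap vs truth masks on a shifted, jittered array.

    ``n_samples`` standard series (600 spots by default) with per-spot
    jitter up to ``jitter_frac`` of the pitch and a global image shift of
    ``global_shift_frac`` of the pitch along each axis.
    """
    rng = np.random.default_rng(seed)
    pitch = 350.0
    pitch_px = pitch / 10.0
    # extra margin so the shifted, jittered grid stays inside the frame
    layout = make_dilution_layout([f"s{i}" for i in range(n_samples)],
                                  origin=(2 * pitch_px, 2 * pitch_px))
    conc = {f"s{i}": float(10 ** rng.uniform(-0.9, 0)) for i in range(n_samples)}
    noise = NoiseSpec(
        spot_jitter_sd=jitter_frac * pitch / 2.0,
        spot_jitter_max=jitter_frac * pitch,
        global_shift=(global_shift_frac * pitch, -global_shift_frac * pitch),
    )
    image, truth = render_array(layout, params, conc, noise, seed=seed,
                                image_shape=layout.frame_shape(2.0))
    grid = locate_grid(image, layout)
    measurements = segment_array(image, layout, grid)
    dices = []
    for i, (ann, m) in enumerate(zip(layout.spots, measurements)):
        truth_mask = truth.labels == i + 1
        dices.append(dice(truth_mask, m.full_mask(image.shape)))
    gshift_px = tuple(np.array(noise.global_shift) / layout.pixel_size)
    return SegmentationStudy(
        mean_dice=float(np.mean(dices)), dice_per_spot=np.array(dices),
        recovered_shift=grid.shift, true_shift=gshift_px,
    )


# -- dust detection performance --------------------------------------------

@dataclass
class DustStudy:
    recall: float
    false_positive_rate: float
    n_specks: int
    n_clean_spots: int


def dust_detection_study(
    seed: int,
    n_arrays: int = 4,
    specks_per_array: int = 50,
    n_samples: int = 10,
    volume_fraction_range: tuple[float, float] = (0.2, 0.5),
    params: SuperCurveParams = DEFAULT_PARAMS,
) -> DustStudy:
    """Recall on injected specks and false-positive rate on clean spots.

    Specks are injected onto random spots, each adding 20-50% of the host
    spot's true volume within a compact footprint; a speck counts as
    recalled when the host spot's dust record covers at least one of its
    pixels.  Clean spots with any dust record count as false positives.
    """
    seeds = _seed_stream(seed, n_arrays)
    rng = np.random.default_rng(seed + 1)
    hits = total = fp = clean = 0
    for s in seeds:
        layout = make_dilution_layout([f"s{i}" for i in range(n_samples)])
        conc = {f"s{i}": float(10 ** rng.uniform(-0.9, 0))
                for i in range(n_samples)}
        image, truth = render_array(layout, params, conc, NoiseSpec(), seed=s)
        image, truth = inject_dust(
            image, truth, specks_per_array, seed=s + 7,
            on_spot_fraction=1.0,
            volume_fraction_range=volume_fraction_range)
        grid = locate_grid(image, layout)
        measurements = segment_array(image, layout, grid)
        by_addr = {m.address: m for m in measurements}
        dusted = {}
        for m in measurements:
            if "missing" in m.flags:
                continue
            rec = detect_dust(image, m)
            if rec is not None:
                dusted[m.address] = {tuple(p) for p in rec.pixels}
        speck_addrs = set()
        for speck in truth.dust:
            if speck.on_spot is None:
                continue
            speck_addrs.add(speck.on_spot)
            total += 1
            found = dusted.get(speck.on_spot, set())
            if found & {tuple(p) for p in speck.pixels}:
                hits += 1
        for m in measurements:
            if m.address in speck_addrs or "missing" in m.flags:
                continue
            clean += 1
            if m.address in dusted:
                fp += 1
    return DustStudy(
        recall=hits / total if total else float("nan"),
        false_positive_rate=fp / clean if clean else float("nan"),
        n_specks=total, n_clean_spots=clean,
    )


# -- time-course fold change (end to end) -----------------------------------

@dataclass
class TimecourseStudy:
    folds: dict  # condition -> measured fold
    programmed: dict  # condition -> programmed fold
    max_relative_error: float


def timecourse_study(
    seed: int,
    conditions=(0, 6, 24, 48),
    programmed_folds=(1.0, 1.0, 2.0, 2.0),
    baseline_conc: float = 0.25,
    n_arrays: int = 3,
    params: SuperCurveParams = DEFAULT_PARAMS,
) -> TimecourseStudy:
    """A programmed 2-fold activation step recovered through the pipeline.

    All time points are printed together (shared SuperCurve per array) on
    ``n_arrays`` replicate arrays, as a real time-course panel would be;
    per-condition folds relative to time 0 are averaged over the
    replicate arrays and compared with the programmed folds.
    """
    layout, conc = _study_layout(
        [f"t{c}" for c in conditions],
        {f"t{c}": baseline_conc * f
         for c, f in zip(conditions, programmed_folds)})
    config = PipelineConfig()
    folds_acc = {c: [] for c in conditions}
    for s in _seed_stream(seed, n_arrays):
        image, _ = render_array(layout, params, conc, NoiseSpec(), seed=s)
        *_, observations = measure_array(image, layout, config)
        fit = fit_supercurve(observations, config.fit)
        fit = flag_outliers(fit, config.outlier_threshold, config.fit)
        readouts = {r.series_id: r.ec50_readout
                    for r in series_readouts(fit, config.fit)}
        table = fold_change(
            {c: {"analyte": readouts[f"t{c}"]} for c in conditions},
            baseline=conditions[0])
        for c in conditions:
            folds_acc[c].append(float(table.loc[c, "analyte"]))
    folds = {c: float(np.mean(v)) for c, v in folds_acc.items()}
    programmed = dict(zip(conditions, programmed_folds))
    err = max(abs(folds[c] / programmed[c] - 1.0) for c in conditions)
    return TimecourseStudy(folds=folds, programmed=programmed,
                           max_relative_error=float(err))


# -- between-array reproducibility ------------------------------------------

def reproducibility_study(
    seed: int,
    n_samples: int = 10,
    params: SuperCurveParams = DEFAULT_PARAMS,
):
    """Pearson R of readouts from two independently rendered replicates."""
    rng = np.random.default_rng(seed)
    layout, conc = _study_layout(
        [f"s{i}" for i in range(n_samples)],
        {f"s{i}": float(10 ** rng.uniform(-1.0, 0))
         for i in range(n_samples)})
    s1, s2 = _seed_stream(seed, 2)
    readouts = []
    config = PipelineConfig()
    for s in (s1, s2):
        image, _ = render_array(layout, params, conc, NoiseSpec(), seed=s)
        *_, obs = measure_array(image, layout, config)
        fit = fit_supercurve(obs, config.fit)
        fit = flag_outliers(fit, config.outlier_threshold, config.fit)
        readouts.append({r.series_id: r.ec50_readout
                         for r in series_readouts(fit, config.fit)
                         if r.series_id != POSITIVE_CONTROL_ID})
    r, table, _ = reproducibility(readouts[0], readouts[1])
    return r, table
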