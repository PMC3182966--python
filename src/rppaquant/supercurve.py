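"""Joint SuperCurve fitting for dilution-series arrays.

Every spot on an array probes the same antigen–antibody reaction, so all
spots are pooled to fit one shared four-parameter logistic-log response

    Y = a + (b - a) / (1 + exp(c * (d - v))),      v = ln(x) + delta_j,

where ``x`` is the spot's dilution factor (relative concentration within
its series: 1, 1/2, 1/4, ...), ``Y`` its background-corrected net volume,
and ``delta_j`` the log-concentration offset of dilution series ``j``.
``a``/``b`` are the lower/upper intensity asymptotes, ``c`` the slope and
``d`` the location in log-dilution units.  With ``b > a`` and ``c > 0``
the curve is strictly increasing in concentration.

Because the shared parameters are estimated from all spots, the fit is
robust to individual outliers or missing spots in any one series.  Each
series differs only by its horizontal offset ``delta_j``; the readout of a
series is the relative concentration ``exp(delta_j)`` — the horizontal
displacement of its half-maximum (EC50) crossing — identified by the
constraint ``mean(delta) = 0`` and rescaled so the array median readout
is 1.

The optimizer alternates (i) bounded nonlinear least squares on
``(a, b, c, d)`` with the offsets fixed, using the transforms
``b = a + exp(beta)``, ``c = exp(gamma)`` to enforce orientation, and
(ii) independent 1-D refinements of each ``delta_j`` with the shared
parameters fixed.  The loss is non-increasing across outer iterations by
construction (a 1-D update is only accepted if it improves the loss).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import FlatFitError, InsufficientDataError

log = logging.getLogger(__name__)

_EXCLUDE_FLAGS = frozenset({"missing", "spot_excluded"})


@dataclass(frozen=True)
class SuperCurveParams:
    """Shared 4PL parameters (orientation: b > a, c > 0)."""

    a: float  # lower asymptote (intensity)
    b: float  # upper asymptote (intensity)
    c: float  # slope, per log-unit
    d: float  # location, log-dilution units

    def __post_init__(self):
        vals = (self.a, self.b, self.c, self.d)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite SuperCurve parameters {vals}")
        if self.b <= self.a:
            raise ValueError(f"upper asymptote must exceed lower (a={self.a}, b={self.b})")
        if self.c <= 0:
            raise ValueError(f"slope must be positive, got c={self.c}")


@dataclass
class DilutionObservation:
    """One spot's contribution to the joint fit."""

    series_id: str
    x: float  # dilution factor (relative concentration), > 0
    y: float  # net volume (intensity), >= 0
    weight: float = 1.0
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.x <= 0:
            raise ValueError(f"dilution factor must be > 0, got {self.x}")


@dataclass
class SuperCurveFit:
    """Result of a joint fit: shared parameters plus per-series offsets."""

    params: SuperCurveParams
    series_ids: list[str]
    delta: np.ndarray  # per-series log-concentration offset, mean 0
    observations: list[DilutionObservation]
    residuals: np.ndarray  # y - fitted, one per observation (0 for excluded)
    loss: float
    converged: bool
    n_iterations: int
    loss_trace: list[float] = field(default_factory=list)

    def delta_of(self, series_id: str) -> float:
        return float(self.delta[self.series_ids.index(series_id)])


@dataclass
class SeriesReadout:
    """Per-series EC50-style readout on the relative-concentration scale."""

    series_id: str
    ec50_readout: float
    se: float
    n_spots_used: int


# -- model ------------------------------------------------------------------

def evaluate(params: SuperCurveParams, x, delta=0.0):
    """Evaluate the response curve at dilution factor ``x`` and offset ``delta``.

    ``Y = a + (b-a) / (1 + exp(c (d - (ln x + delta))))``.  ``x`` may be a
    scalar or array and must be positive.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("dilution factor must be > 0")
    v = np.log(x) + delta
    return _eval_v(params.a, params.b, params.c, params.d, v)


def _eval_v(a, b, c, d, v):
    z = np.clip(c * (d - v), -700.0, 700.0)
    return a + (b - a) / (1.0 + np.exp(z))


def invert_concentration(params: SuperCurveParams, y, x, margin: float = 1e-9):
    """Per-spot relative concentration implied by response ``y`` at dilution ``x``.

    Inverts the 4PL for ``v`` and removes the dilution factor:
    ``exp(v - ln x)``.  Responses at or beyond the asymptotes are clamped a
    relative ``margin`` inside ``(a, b)`` so the inverse stays finite.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    span = params.b - params.a
    yc = np.clip(y, params.a + margin * span, params.b - margin * span)
    v = params.d - np.log(span / (yc - params.a) - 1.0) / params.c
    return np.exp(v - np.log(x))


# -- fitting ----------------------------------------------------------------

@dataclass
class FitConfig:
    """Optimizer settings.

    ``weighting="proportional"`` (default) minimizes *relative* squared
    residuals, i.e. weights each observation by ``1/max(y, floor)^2``
    with ``floor`` 0.1% of the largest response — the efficient choice
    when spot noise is multiplicative (constant CV), and what keeps dim
    series from being drowned out by bright ones.  ``"constant"`` gives
    plain unweighted least squares.
    """

    max_outer_iterations: int = 200
    rel_loss_tol: float = 1e-8
    delta_halfrange: float = 6.0  # search range for each 1-D offset update
    multistart: bool = False  # extra (c, d) starts for the shared update
    weighting: str = "proportional"

    def __post_init__(self):
        if self.max_outer_iterations < 1:
            raise ValueError("max_outer_iterations must be >= 1")
        if self.weighting not in ("proportional", "constant"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


def _usable(observations):
    return [o for o in observations
            if not (_EXCLUDE_FLAGS & o.flags) and o.weight > 0]


def _effective_weights(ys, user_weights, weighting: str) -> np.ndarray:
    """User weights times the variance-model weight (1 or 1/y^2)."""
    if weighting == "constant":
        return np.asarray(user_weights, dtype=float)
    floor = 1e-3 * max(float(np.max(ys)), 1e-300)
    return np.asarray(user_weights, dtype=float) / np.maximum(ys, floor) ** 2


def fit_supercurve(observations, config: FitConfig | None = None,
                   initial: SuperCurveFit | None = None) -> SuperCurveFit:
    """Fit the shared curve and per-series offsets from all usable spots.

    Requires at least 3 series, 3 distinct dilution factors and 12 usable
    observations; raises :class:`InsufficientDataError` otherwise, and
    :class:`FlatFitError` when all responses are identical.  ``initial``
    warm-starts from a previous fit (used by the outlier refit pass).

    The shared-parameter step is bounded: the span ``b - a`` may exceed
    the observed response range by at most a factor 50 and the slope must
    lie in [0.05, 20] per log-unit.  When every spot sits on the lower
    shoulder of the sigmoid the upper asymptote is only weakly
    identified; the bound keeps the exponential-regime ridge finite
    without constraining the per-series offsets, which remain identified.
    """
    config = config or FitConfig()
    usable = _usable(observations)
    series_ids = list(dict.fromkeys(o.series_id for o in usable))
    n_series = len(series_ids)
    xs = np.array([o.x for o in usable], dtype=float)
    ys = np.array([o.y for o in usable], dtype=float)
    ws = np.array([o.weight for o in usable], dtype=float)
    if n_series < 3 or len(np.unique(xs)) < 3 or len(usable) < 12:
        raise InsufficientDataError(
            f"need >= 3 series, >= 3 distinct dilution factors and >= 12 usable "
            f"observations; got {n_series} series, {len(np.unique(xs))} factors, "
            f"{len(usable)} observations"
        )
    if np.ptp(ys) == 0:
        raise FlatFitError("all responses identical; slope unidentifiable")

    sidx = np.array([series_ids.index(o.series_id) for o in usable])
    lx = np.log(xs)
    ws = _effective_weights(ys, ws, config.weighting)
    sw = np.sqrt(ws)

    # initialization: asymptotes from response percentiles, location at the
    # median log dilution, unit slope, zero offsets — or a previous fit
    span_y = float(np.ptp(ys))
    if initial is not None:
        p0 = initial.params
        theta = np.array([p0.a, np.log(p0.b - p0.a), np.log(p0.c), p0.d])
        delta = np.array([initial.delta_of(s) if s in initial.series_ids else 0.0
                          for s in series_ids])
        delta -= delta.mean()
    else:
        a = float(np.percentile(ys, 5))
        b = float(np.percentile(ys, 95))
        if b <= a:
            b = a + max(1.0, abs(a) * 1e-3)
        theta = np.array([a, np.log(b - a), 0.0, float(np.median(lx))])
        delta = np.zeros(n_series)

    lo = np.array([ys.min() - 2 * span_y, np.log(span_y * 1e-3),
                   np.log(0.05), lx.min() - 12.0])
    hi = np.array([ys.max(), np.log(span_y * 50.0),
                   np.log(20.0), lx.max() + 12.0])
    theta = np.clip(theta, lo + 1e-9, hi - 1e-9)

    def unpack(th):
        return th[0], th[0] + np.exp(np.clip(th[1], -700, 700)), \
            np.exp(np.clip(th[2], -700, 700)), th[3]

    def loss_of(th, dl):
        a_, b_, c_, d_ = unpack(th)
        r = ys - _eval_v(a_, b_, c_, d_, lx + dl[sidx])
        return float(np.sum(ws * r * r))

    def shared_residuals(th, dl):
        a_, b_, c_, d_ = unpack(th)
        return sw * (ys - _eval_v(a_, b_, c_, d_, lx + dl[sidx]))

    loss = loss_of(theta, delta)
    trace = [loss]
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_outer_iterations + 1):
        # (i) shared parameters by bounded nonlinear least squares
        theta = np.clip(theta, lo + 1e-9, hi - 1e-9)
        sol = least_squares(shared_residuals, theta, args=(delta,),
                            method="trf", bounds=(lo, hi),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12,
                            max_nfev=400)
        cand = [sol.x]
        if config.multistart:
            for c0 in (np.log(0.5), np.log(2.0)):
                th0 = theta.copy()
                th0[2] = c0
                cand.append(least_squares(shared_residuals, th0, args=(delta,),
                                          method="trf", bounds=(lo, hi),
                                          xtol=1e-12, ftol=1e-12,
                                          gtol=1e-12, max_nfev=400).x)
        best = min(cand, key=lambda th: loss_of(th, delta))
        if loss_of(best, delta) <= loss:
            theta = best

        # (ii) per-series 1-D offset refinements, accepted only on improvement
        a_, b_, c_, d_ = unpack(theta)
        for j in range(n_series):
            m = sidx == j
            yj, lj, wj = ys[m], lx[m], ws[m]

            def g(dj):
                r = yj - _eval_v(a_, b_, c_, d_, lj + dj)
                return float(np.sum(wj * r * r))

            res = minimize_scalar(
                g, bounds=(delta[j] - config.delta_halfrange,
                           delta[j] + config.delta_halfrange),
                method="bounded", options={"xatol": 1e-12},
            )
            if res.fun <= g(delta[j]):
                delta[j] = res.x

        # re-center offsets; shifting d in step keeps every prediction,
        # hence the loss, exactly unchanged
        shift = float(np.mean(delta))
        delta -= shift
        theta[3] -= shift

        new_loss = loss_of(theta, delta)
        if new_loss > loss * (1 + 1e-12) + 1e-12:  # pragma: no cover
            raise AssertionError("loss increased across an outer iteration")
        trace.append(new_loss)
        if abs(loss - new_loss) <= config.rel_loss_tol * max(loss, 1e-30):
            loss = new_loss
            converged = True
            break
        loss = new_loss
    else:  # pragma: no cover - only on non-convergence
        log.warning("SuperCurve fit did not converge in %d outer iterations",
                    config.max_outer_iterations)

    a_, b_, c_, d_ = unpack(theta)
    params = SuperCurveParams(a=a_, b=b_, c=c_, d=d_)
    # residuals for every non-excluded observation (weight-0 included, so
    # outlier refits still report their deviation)
    residuals = np.zeros(len(observations))
    for i, o in enumerate(observations):
        if _EXCLUDE_FLAGS & o.flags:
            residuals[i] = 0.0
            continue
        if o.series_id in series_ids:
            dj = delta[series_ids.index(o.series_id)]
            residuals[i] = o.y - float(evaluate(params, o.x, dj))
        else:  # pragma: no cover - series entirely excluded
            residuals[i] = 0.0

    return SuperCurveFit(
        params=params, series_ids=series_ids, delta=delta.copy(),
        observations=list(observations), residuals=residuals, loss=loss,
        converged=converged, n_iterations=n_iter, loss_trace=trace,
    )


def flag_outliers(fit: SuperCurveFit, threshold: float = 3.0,
                  config: FitConfig | None = None) -> SuperCurveFit:
    """Flag large-residual spots and refit once with them down-weighted.

    An observation is an outlier when ``|residual| > threshold * s`` with
    ``s = 1.4826 * MAD`` of the usable residuals (a robust SD); residuals
    are taken on the fit's weighting scale (relative residuals under the
    default proportional weighting).  Flags are frozen after the single
    refit pass: no iterative re-flagging.  ``threshold=inf`` flags
    nothing and returns the fit unchanged.
    """
    if not fit.converged:
        raise ValueError("outlier flagging requires a converged fit")
    if not np.isfinite(threshold):
        return fit
    weighting = (config or FitConfig()).weighting
    usable_idx = [i for i, o in enumerate(fit.observations)
                  if not (_EXCLUDE_FLAGS & o.flags) and o.weight > 0]
    ys = np.array([fit.observations[i].y for i in usable_idx])
    wu = np.array([fit.observations[i].weight for i in usable_idx])
    sw = np.sqrt(_effective_weights(ys, wu, weighting))
    u = sw * fit.residuals[usable_idx]
    s = 1.4826 * float(np.median(np.abs(u - np.median(u))))
    if s == 0:
        return fit
    flagged = [i for i, ui in zip(usable_idx, u)
               if abs(ui) > threshold * s]
    if not flagged:
        return fit
    refit_obs = []
    for i, o in enumerate(fit.observations):
        flags = set(o.flags)
        w = o.weight
        if i in flagged:
            flags.add("outlier")
            w = 0.0
        refit_obs.append(DilutionObservation(
            series_id=o.series_id, x=o.x, y=o.y, weight=w, flags=flags))
    out = fit_supercurve(refit_obs, config, initial=fit)
    # propagate flags onto the caller's observation objects
    for i in flagged:
        fit.observations[i].flags.add("outlier")
    out.observations = fit.observations
    return out


def series_readouts(fit: SuperCurveFit,
                    config: FitConfig | None = None) -> list[SeriesReadout]:
    """EC50-style readouts: relative concentration per series, median 1.

    The fitted curve of series ``j`` crosses its half-maximum at
    ``ln x = d - delta_j``; the readout is ``exp(delta_j)`` rescaled so the
    array-median readout equals 1.  The standard error comes from the
    Gauss–Newton curvature of the loss in ``delta_j`` with the robust
    residual scale.
    """
    if not fit.converged:
        raise ValueError("readouts require a converged fit")
    weighting = (config or FitConfig()).weighting
    usable = [(o, r) for o, r in zip(fit.observations, fit.residuals)
              if not (_EXCLUDE_FLAGS & o.flags) and o.weight > 0]
    ys_all = np.array([o.y for o, _ in usable])
    w_all = _effective_weights(ys_all, [o.weight for o, _ in usable],
                               weighting) if len(usable) else np.empty(0)
    u = np.sqrt(w_all) * np.array([r for _, r in usable])
    sigma = 1.4826 * float(np.median(np.abs(u - np.median(u)))) if len(u) else 0.0
    p = fit.params
    raw = np.exp(fit.delta)
    med = float(np.median(raw))
    readouts = []
    for j, sid in enumerate(fit.series_ids):
        sel = [k for k, (o, _) in enumerate(usable) if o.series_id == sid]
        obs_j = [usable[k][0] for k in sel]
        if not obs_j:
            log.warning("series %s has no usable observations; omitted", sid)
            continue
        v = np.log([o.x for o in obs_j]) + fit.delta[j]
        # df/dv of the 4PL at each usable point of the series
        y = _eval_v(p.a, p.b, p.c, p.d, v)
        dfdv = p.c * (y - p.a) * (p.b - y) / (p.b - p.a)
        curv = float(np.sum(w_all[sel] * dfdv ** 2))
        se_delta = sigma / np.sqrt(curv) if curv > 0 else np.inf
        scaled = raw[j] / med
        readouts.append(SeriesReadout(
            series_id=sid,
            ec50_readout=float(scaled),
            se=float(scaled * se_delta),  # delta-method on exp(delta)/median
            n_spots_used=len(obs_j),
        ))
    return readouts
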