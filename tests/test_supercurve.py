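import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from rppaquant import (DilutionObservation, FitConfig, FlatFitError,
                       InsufficientDataError, SuperCurveParams, evaluate,
                       fit_supercurve, flag_outliers, invert_concentration,
                       series_readouts)


def curve_oracle(a, b, c, d, x, delta):
    """Independent transcription of the logistic-log response."""
    v = math.log(x) + delta
    return a + (b - a) / (1.0 + math.exp(c * (d - v)))


def make_observations(params, deltas, n_reps=3, n_steps=5, noise_cv=0.0,
                      rng=None):
    obs = []
    for j, dj in enumerate(deltas):
        for _ in range(n_reps):
            for k in range(n_steps):
                x = 2.0 ** -k
                y = float(evaluate(params, x, dj))
                if noise_cv:
                    sig = math.sqrt(math.log(1 + noise_cv ** 2))
                    y *= float(np.exp(rng.normal(-sig ** 2 / 2, sig)))
                obs.append(DilutionObservation(f"s{j}", x, y))
    return obs


class TestEvaluate:
    def test_midpoint_is_half_maximum(self):
        p = SuperCurveParams(a=0, b=100, c=1, d=0)
        assert evaluate(p, 1.0, 0.0) == pytest.approx(50.0)

    def test_asymptotes(self):
        p = SuperCurveParams(a=10, b=200, c=2, d=0)
        assert evaluate(p, 1e-9, -20.0) == pytest.approx(10.0, abs=1e-6)
        assert evaluate(p, 1.0, 40.0) == pytest.approx(200.0, abs=1e-6)

    def test_offset_equivalent_to_dilution_shift(self):
        p = SuperCurveParams(a=5, b=500, c=1.3, d=-0.4)
        t = 0.7
        assert evaluate(p, 1.0, t) == pytest.approx(
            evaluate(p, math.exp(t), 0.0))

    @given(a=st.floats(0, 1e3), span=st.floats(1, 1e6),
           c=st.floats(0.1, 5), d=st.floats(-3, 3),
           x=st.floats(1e-3, 10), delta=st.floats(-3, 3))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_independent_formula(self, a, span, c, d, x, delta):
        p = SuperCurveParams(a=a, b=a + span, c=c, d=d)
        assert evaluate(p, x, delta) == pytest.approx(
            curve_oracle(a, a + span, c, d, x, delta), rel=1e-12, abs=1e-10)

    @given(c=st.floats(0.2, 3), d=st.floats(-2, 2),
           x1=st.floats(0.01, 0.99), x2=st.floats(1.0, 10.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_strictly_increasing_in_dilution_factor(self, c, d, x1, x2):
        p = SuperCurveParams(a=1, b=1000, c=c, d=d)
        assert evaluate(p, x1, 0.0) < evaluate(p, x2, 0.0)

    def test_nonpositive_dilution_rejected(self):
        p = SuperCurveParams(a=0, b=1, c=1, d=0)
        with pytest.raises(ValueError):
            evaluate(p, 0.0, 0.0)

    def test_param_invariants_enforced(self):
        with pytest.raises(ValueError):
            SuperCurveParams(a=10, b=5, c=1, d=0)
        with pytest.raises(ValueError):
            SuperCurveParams(a=0, b=5, c=-1, d=0)
        with pytest.raises(ValueError):
            SuperCurveParams(a=0, b=np.inf, c=1, d=0)


class TestFit:
    def test_noiseless_recovery(self, params):
        deltas = np.array([0.9, 0.2, -0.3, -0.8])
        deltas = deltas - deltas.mean()
        fit = fit_supercurve(make_observations(params, deltas))
        assert fit.converged
        assert fit.params.a == pytest.approx(params.a, rel=1e-4, abs=1e-2)
        assert fit.params.b == pytest.approx(params.b, rel=1e-4)
        assert fit.params.c == pytest.approx(params.c, rel=1e-4)
        assert fit.params.d == pytest.approx(params.d, rel=1e-4)
        np.testing.assert_allclose(fit.delta, deltas, atol=1e-4)

    def test_delta_mean_zero_and_loss_monotone(self, params, rng):
        deltas = [0.5, 0.0, -0.5, 1.0, -1.0]
        obs = make_observations(params, deltas, noise_cv=0.08, rng=rng)
        fit = fit_supercurve(obs)
        assert abs(float(np.mean(fit.delta))) < 1e-9
        trace = np.array(fit.loss_trace)
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1))

    def test_single_dilution_step_unidentifiable(self, params):
        obs = [DilutionObservation(f"s{j}", 1.0, 100.0 + j)
               for j in range(10) for _ in range(3)]
        with pytest.raises(InsufficientDataError):
            fit_supercurve(obs)

    def test_too_few_series(self, params):
        obs = make_observations(params, [0.1, -0.1])
        with pytest.raises(InsufficientDataError):
            fit_supercurve(obs)

    def test_flat_responses_rejected(self):
        obs = [DilutionObservation(f"s{j}", 2.0 ** -k, 42.0)
               for j in range(4) for k in range(5)]
        with pytest.raises(FlatFitError):
            fit_supercurve(obs)

    def test_flagged_observations_excluded(self, params):
        deltas = [0.4, 0.0, -0.4]
        obs = make_observations(params, deltas)
        # corrupt one observation but mark it excluded: fit must ignore it
        obs[0].y *= 100
        obs[0].flags.add("spot_excluded")
        fit = fit_supercurve(obs)
        np.testing.assert_allclose(fit.delta, deltas, atol=1e-3)
        assert fit.residuals[0] == 0.0

    def test_stochastic_delta_recovery(self, params, rng):
        errs = []
        for _ in range(5):
            deltas = rng.normal(0, 0.7, 8)
            deltas -= deltas.mean()
            obs = make_observations(params, deltas, noise_cv=0.05, rng=rng)
            fit = fit_supercurve(obs)
            errs.extend(np.abs(fit.delta - deltas))
        assert np.median(errs) < 0.05

    def test_matches_brute_force_on_small_instance(self, rng):
        """Alternating fit reaches the jointly optimized loss (<=3 series)."""
        p = SuperCurveParams(a=50, b=5e4, c=1.1, d=-1.0)
        deltas = [0.6, -0.1, -0.5]
        obs = make_observations(p, deltas, n_reps=1, n_steps=5,
                                noise_cv=0.05, rng=rng)
        cfg = FitConfig(weighting="constant")
        fit = fit_supercurve(obs, cfg)

        ys = np.array([o.y for o in obs])
        xs = np.array([o.x for o in obs])
        sidx = np.array([int(o.series_id[1]) for o in obs])

        def joint_resid(th):
            a, b, c, d = th[0], th[0] + np.exp(th[1]), np.exp(th[2]), th[3]
            d1, d2 = th[4], th[5]
            dl = np.array([d1, d2, -d1 - d2])
            v = np.log(xs) + dl[sidx]
            return ys - (a + (b - a) / (1 + np.exp(np.clip(c * (d - v),
                                                           -700, 700))))

        best = np.inf
        for c0 in (0.5, 1.0, 2.0):
            for d0 in (-2.0, -1.0, 0.0):
                th0 = [ys.min(), np.log(np.ptp(ys)), np.log(c0), d0, 0.0, 0.0]
                sol = least_squares(joint_resid, th0, method="lm",
                                    max_nfev=20000)
                best = min(best, float(np.sum(sol.fun ** 2)))
        assert fit.loss <= best * (1 + 1e-3)


class TestOutliers:
    def test_infinite_threshold_is_identity(self, params):
        fit = fit_supercurve(make_observations(params, [0.3, 0.0, -0.3]))
        assert flag_outliers(fit, float("inf")) is fit

    def test_inflated_spot_flagged_and_downweighted(self, params, rng):
        obs = make_observations(params, [0.3, 0.0, -0.3, 0.6, -0.6],
                                noise_cv=0.03, rng=rng)
        obs[7].y *= 3.0
        fit = flag_outliers(fit_supercurve(obs), 3.0)
        assert "outlier" in obs[7].flags
        # refit is clean: its residual scale is unaffected by the outlier
        np.testing.assert_allclose(
            fit.delta, [0.3, 0.0, -0.3, 0.6, -0.6], atol=0.05)

    def test_clean_fit_rarely_flags(self, params, rng):
        obs = make_observations(params, np.linspace(-0.8, 0.8, 10),
                                noise_cv=0.05, rng=rng)
        flag_outliers(fit_supercurve(obs), 3.0)
        frac = np.mean([("outlier" in o.flags) for o in obs])
        assert frac <= 0.01


class TestReadouts:
    def test_equal_series_read_one(self, params):
        fit = fit_supercurve(make_observations(params, [0.0, 0.0, 0.0, 0.0]))
        for r in series_readouts(fit):
            assert r.ec50_readout == pytest.approx(1.0, abs=1e-6)
            assert r.n_spots_used == 15

    def test_ratio_matches_concentration_ratio(self, params):
        fit = fit_supercurve(
            make_observations(params, [np.log(2), 0.0, 0.0, -np.log(2)]))
        ro = {r.series_id: r.ec50_readout for r in series_readouts(fit)}
        assert ro["s0"] / ro["s1"] == pytest.approx(2.0, rel=1e-4)
        assert ro["s1"] / ro["s3"] == pytest.approx(2.0, rel=1e-4)

    def test_global_concentration_scale_cancels(self, params):
        base = [0.5, 0.1, -0.2, -0.4]
        ro1 = {r.series_id: r.ec50_readout for r in series_readouts(
            fit_supercurve(make_observations(params, base)))}
        shifted = [b + np.log(2) for b in base]
        ro2 = {r.series_id: r.ec50_readout for r in series_readouts(
            fit_supercurve(make_observations(params, shifted)))}
        for sid in ro1:
            assert ro1[sid] == pytest.approx(ro2[sid], rel=1e-4)


class TestInversion:
    def test_inverts_evaluate(self, params):
        for x in (1.0, 0.25, 0.0625):
            for conc in (0.05, 0.3, 1.0):
                y = evaluate(params, x, np.log(conc))
                assert invert_concentration(params, y, x) == pytest.approx(
                    conc, rel=1e-9)

    def test_clamps_out_of_range_responses(self, params):
        est = invert_concentration(params, params.b * 2, 1.0)
        assert np.isfinite(est)
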