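"""Dwell MLEs, Bell fits, rupture-distribution MLE, p_fold fitting."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from g4pull.estimators import (
    BellRateFit,
    ExponentialDwellMLE,
    PfoldKineticsFit,
    RuptureForceMLE,
)
from g4pull.inference import (
    estimate_pfold,
    fit_bell,
    fit_exponential,
    fit_pfold,
    fit_rupture_distribution,
    peak_force,
    pfold_curve_model,
    select_model,
)
from g4pull.kinetic_model import BellEdge, sequential_model
from g4pull.presets import FOLDING_BELL, RAMP_UNFOLDING, alpha_rate_set
from g4pull.trace_synthesis import (
    PfoldCurve,
    synthesize_pfold_curve,
    synthesize_rupture_forces,
)


class TestExponentialMLE:
    def test_uncensored_single_component_is_sample_mean(self, rng):
        t = rng.exponential(12.0, 500)
        fit = fit_exponential(t, 1)
        assert fit.lifetimes[0] == pytest.approx(t.mean(), rel=1e-12)
        assert fit.se_lifetimes[0] == pytest.approx(t.mean() / np.sqrt(500), rel=1e-9)

    @given(st.floats(0.1, 100.0))
    def test_scale_equivariance(self, c):
        t = np.random.default_rng(3).exponential(5.0, 200)
        tau1 = fit_exponential(t, 1).lifetimes[0]
        tau2 = fit_exponential(c * t, 1).lifetimes[0]
        assert tau2 == pytest.approx(c * tau1, rel=1e-9)

    def test_censoring_terms_remove_bias(self, rng):
        # right-censor everything above 8 s; naive mean is badly biased
        t = rng.exponential(10.0, 4000)
        cens = t > 8.0
        t_obs = np.minimum(t, 8.0)
        fit = fit_exponential((t_obs, cens), 1)
        assert fit.lifetimes[0] == pytest.approx(10.0, rel=0.1)
        naive = fit_exponential(t_obs[~cens], 1)
        assert naive.lifetimes[0] < 4.0

    def test_dead_time_truncation(self, rng):
        t = rng.exponential(3.0, 3000)
        t_obs = t[t >= 0.5]
        fit = fit_exponential(t_obs, 1, dead_time=0.5)
        assert fit.lifetimes[0] == pytest.approx(3.0, rel=0.1)

    def test_unfolded_dwell_fit_at_683_events(self, rng):
        t = rng.exponential(15.8, 683)
        fit = fit_exponential(t, 1)
        assert abs(fit.lifetimes[0] - 15.8) < 3 * fit.se_lifetimes[0]
        assert 0.35 < fit.se_lifetimes[0] < 0.75

    def test_mixture_recovery_at_684_events(self):
        rng = np.random.default_rng(8)
        n = 684
        z = rng.random(n) < 0.5
        t = np.where(z, rng.exponential(3.0, n), rng.exponential(45.0, n))
        fit = fit_exponential(t, 2)
        assert abs(fit.lifetimes[0] - 3.0) < 3 * max(fit.se_lifetimes[0], 0.15)
        assert abs(fit.lifetimes[1] - 45.0) < 3 * max(fit.se_lifetimes[1], 2.0)
        assert fit.amplitudes[0] + fit.amplitudes[1] == pytest.approx(1.0)
        assert fit.lifetimes[0] < fit.lifetimes[1]

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(np.ones(5), 1)


class TestSelectModel:
    def test_single_exponential_prefers_one_component(self):
        hits = 0
        for seed in range(20):
            t = np.random.default_rng(seed).exponential(10.0, 500)
            k, _, _ = select_model(t)
            hits += k == 1
        assert hits >= 19

    def test_mixture_prefers_two_components(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            z = rng.random(500) < 0.5
            t = np.where(z, rng.exponential(3.0, 500), rng.exponential(45.0, 500))
            k, _, _ = select_model(t)
            hits += k == 2
        assert hits >= 19

    def test_underpowered_guard(self):
        t = np.random.default_rng(1).exponential(5.0, 10)
        with pytest.warns(UserWarning, match="defaulting to 1"):
            k, _, fit2 = select_model(t)
        assert k == 1 and fit2 is None


class TestBellFit:
    def test_two_noiseless_points_interpolated_exactly(self, kbt):
        f = np.array([2.0, 6.0])
        k = 1.5 * np.exp(-2.5 * f / kbt)
        res = fit_bell(f, k)
        assert res.k0 == pytest.approx(1.5, rel=1e-9)
        assert res.dx == pytest.approx(-2.5, rel=1e-9)

    def test_noiseless_many_points_exact(self, kbt):
        f = np.arange(1.0, 8.0)
        k = FOLDING_BELL.rate(f)
        res = fit_bell(f, k)
        assert res.dx == pytest.approx(FOLDING_BELL.dx, rel=1e-9)

    def test_sign_preserved_for_folding_rates(self):
        f = np.arange(1.0, 8.0)
        res = fit_bell(f, FOLDING_BELL.rate(f))
        assert res.dx < 0

    def test_noisy_recovery_of_folding_distance(self):
        # 20% lognormal noise on k12 over 1-7 pN, 200 replicates
        from g4pull.pipeline import bell_recovery

        out = bell_recovery(seed=1234, n_replicates=200)
        assert out["dx_mean"] == pytest.approx(3.0, abs=0.2)
        assert 1.6 <= out["k0_geomean"] <= 6.7

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            fit_bell([5.0, 5.0], [1.0, 2.0])


class TestRuptureFit:
    def test_self_consistency_large_n(self):
        f = synthesize_rupture_forces(RAMP_UNFOLDING, 2.0, 100_000, seed=2)
        res = fit_rupture_distribution(f, 2.0)
        assert res.dx == pytest.approx(0.8, abs=0.02)
        assert res.k0 == pytest.approx(0.009, rel=0.1)

    def test_consistency_error_decreases_with_n(self):
        errs = []
        for n in (1_000, 10_000, 100_000):
            f = synthesize_rupture_forces(RAMP_UNFOLDING, 2.0, n, seed=4)
            errs.append(abs(fit_rupture_distribution(f, 2.0).dx - 0.8))
        assert errs[2] < errs[0]
        assert errs[2] < 0.02

    def test_likelihood_peaks_at_truth_not_double_dx(self):
        from g4pull.inference import _rupture_nll

        f = synthesize_rupture_forces(RAMP_UNFOLDING, 2.0, 50_000, seed=9)
        nll_true = _rupture_nll(np.log([0.009, 0.8]), f, 2.0, 4.0729175)
        nll_wrong = _rupture_nll(np.log([0.009, 1.6]), f, 2.0, 4.0729175)
        assert nll_true < nll_wrong

    def test_experiment_scale_spread(self):
        from g4pull.pipeline import rupture_recovery

        out = rupture_recovery(seed=5, n_per_replicate=60, n_replicates=100)
        assert out["dx_mean"] == pytest.approx(0.8, abs=0.08)
        assert 0.08 <= out["dx_sd"] <= 0.35

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_rupture_distribution(np.full(30, 17.0), 2.0)


class TestPeakForce:
    def test_closed_form_value(self, kbt):
        expected = kbt / 0.8 * np.log(0.8 * 2.0 / (kbt * 0.009))
        assert peak_force(RAMP_UNFOLDING, 2.0) == pytest.approx(expected, rel=1e-12)
        assert peak_force(RAMP_UNFOLDING, 2.0) == pytest.approx(19.2, abs=0.1)

    def test_matches_numerical_argmax(self):
        from g4pull.trace_synthesis import rupture_force_pdf

        f = np.linspace(0.01, 60, 600_000)
        num = f[np.argmax(rupture_force_pdf(f, RAMP_UNFOLDING, 2.0))]
        assert num == pytest.approx(peak_force(RAMP_UNFOLDING, 2.0), abs=0.01)

    def test_no_interior_peak_flagged(self):
        with pytest.raises(ValueError, match="no interior"):
            peak_force(BellEdge("F", "U", 10.0, 0.1), 0.001)


class TestEstimatePfold:
    def test_all_successes(self):
        c = PfoldCurve(5.0, [60.0], [100], [100])
        out = estimate_pfold(c)
        assert out["p"][0] == 1.0

    def test_wilson_interval_80_of_100(self):
        c = PfoldCurve(5.0, [60.0], [80], [100])
        out = estimate_pfold(c)
        assert out["ci_low"][0] == pytest.approx(0.71, abs=0.01)
        assert out["ci_high"][0] == pytest.approx(0.87, abs=0.01)

    def test_zero_successes_upper_bound_positive(self):
        out = estimate_pfold(PfoldCurve(5.0, [5.0], [0], [100]))
        assert out["p"][0] == 0.0
        assert out["ci_high"][0] > 0.0


class TestFitPfold:
    def test_recovery_over_replicates(self):
        from g4pull.pipeline import pfold_recovery

        ratios = np.array(
            [
                [r["k12_fit"] / r["k12_true"], r["k32_fit"] / r["k32_true"]]
                for r in (pfold_recovery(seed) for seed in range(25))
            ]
        )
        means = ratios.mean(axis=0)
        assert abs(means[0] - 1.0) < 0.2
        assert abs(means[1] - 1.0) < 0.2

    def test_insensitive_to_alpha_above_5(self):
        rs = alpha_rate_set(5.0, 10.0)
        model = sequential_model(rs, include_ul=False)
        curve = synthesize_pfold_curve(
            model, 5.0, [5, 10, 20, 40, 60, 120], 2000, seed=3, method="exact"
        )
        fits = {a: fit_pfold(curve, alpha=a) for a in (5.0, 10.0, 20.0)}
        # doubling/halving alpha moves the fitted rates by ~±10% on data
        # whose statistical error is ~1%: the constraint choice does not
        # drive the conclusions
        for a in (5.0, 20.0):
            assert abs(fits[a].k12 - fits[10.0].k12) / fits[10.0].k12 < 0.15
            assert abs(fits[a].k32 - fits[10.0].k32) / fits[10.0].k32 < 0.15

    def test_sequential_beats_parallel_on_sequential_data(self):
        rs = alpha_rate_set(5.0, 10.0)
        times = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 60.0, 120.0])
        p_true = pfold_curve_model(times, rs.k12, rs.k32, 10.0, "sequential")
        n = 1000
        curve = PfoldCurve(5.0, times, np.round(n * p_true).astype(int),
                           np.full(len(times), n))
        seq = fit_pfold(curve, alpha=10.0, topology="sequential")
        par = fit_pfold(curve, alpha=10.0, topology="parallel")
        assert seq.nll < par.nll

    def test_alpha_below_5_rejected(self):
        c = PfoldCurve(5.0, [5.0, 10.0, 20.0], [10, 20, 30], [50, 50, 50])
        with pytest.raises(ValueError):
            fit_pfold(c, alpha=2.0)

    def test_eigen_model_matches_rk4_master(self):
        rs = alpha_rate_set(5.0, 10.0)
        model = sequential_model(rs, include_ul=False)
        from g4pull.kinetic_model import pfold_predict

        t = np.array([1.0, 10.0, 60.0, 120.0])
        eig = pfold_curve_model(t, rs.k12, rs.k32, 10.0)
        rk4 = pfold_predict(model, 5.0, t)
        assert np.allclose(eig, rk4, atol=1e-7)


class TestEstimatorProtocol:
    @pytest.mark.parametrize(
        "est",
        [
            ExponentialDwellMLE(n_components=2),
            BellRateFit(),
            RuptureForceMLE(loading_rate=2.0),
            PfoldKineticsFit(alpha=10.0),
        ],
        ids=["dwell-mle", "bell", "rupture", "pfold"],
    )
    def test_clone_and_params_roundtrip(self, est):
        c = clone(est)
        assert c.get_params() == est.get_params()

    def test_dwell_estimator_fit(self, rng):
        t = rng.exponential(7.0, 300)
        est = ExponentialDwellMLE(n_components=1).fit(t)
        assert est.lifetimes_[0] == pytest.approx(t.mean(), rel=1e-12)

    def test_bell_estimator_predict(self):
        f = np.arange(1.0, 8.0)
        est = BellRateFit().fit(f, FOLDING_BELL.rate(f))
        assert np.allclose(est.predict(f), FOLDING_BELL.rate(f), rtol=1e-8)

    def test_rupture_estimator(self):
        f = synthesize_rupture_forces(RAMP_UNFOLDING, 2.0, 5000, seed=12)
        est = RuptureForceMLE(loading_rate=2.0).fit(f)
        assert est.dx_ == pytest.approx(0.8, abs=0.1)
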