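import numpy as np
import pytest

from oligoring import kinetics as kin
from oligoring.simulate import (
    AssemblyParams,
    McrCCoupling,
    make_standard_curve_data,
    simulate_assembly,
    simulate_pi_trace,
    simulate_trp_trace,
)


class TestStandardCurve:
    def test_perfect_line_full_range(self):
        data = make_standard_curve_data(2.0, 0.1, [0, 5, 10, 20, 40])
        curve = kin.fit_standard_curve(data[:, 0], data[:, 1])
        assert curve.slope == pytest.approx(2.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.1, abs=1e-10)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert curve.n_levels_used == 5

    def test_saturating_levels_excluded(self):
        # linear to 20 uM then a hard plateau: the knee is known by
        # construction, so the retained range must stop at or below it
        conc = np.array([0, 2, 5, 10, 15, 20, 40, 80.0])
        resp = np.where(conc <= 20, 3.0 * conc, 60.0)
        curve = kin.fit_standard_curve(conc, resp)
        assert curve.linear_range[1] <= 20.0
        assert curve.slope == pytest.approx(3.0, rel=0.02)

    def test_two_levels_insufficient(self):
        with pytest.raises(ValueError, match="insufficient"):
            kin.fit_standard_curve([0.0, 10.0], [0.1, 5.0])

    def test_noisy_slope_within_three_se(self):
        hits = 0
        for seed in range(100):
            data = make_standard_curve_data(
                1.5, 0.05, np.linspace(0, 35, 8), noise_sd=0.2, seed=seed
            )
            x, y = data[:, 0], data[:, 1]
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            se = np.sqrt(np.sum(resid**2) / (len(x) - 2) / np.sum((x - x.mean()) ** 2))
            if abs(slope - 1.5) <= 3 * se:
                hits += 1
        assert hits >= 95


class TestCalibrateTrace:
    def test_intercept_maps_to_zero(self):
        curve = kin.StandardCurve(2.0, 0.3, (0.0, 50.0), 0.0, 5)
        raw = kin.KineticTrace(np.arange(30.0), np.full(30, 0.3))
        cal = kin.calibrate_trace(raw, curve)
        assert np.allclose(cal.signal, 0.0)
        assert cal.calibrated

    def test_round_trip_with_generator_line(self):
        data = make_standard_curve_data(1.7, 0.2, [0, 10, 20, 40])
        curve = kin.fit_standard_curve(data[:, 0], data[:, 1])
        t = np.arange(40.0)
        pi_true = 0.5 * t
        raw = kin.KineticTrace(t, 1.7 * pi_true + 0.2)
        cal = kin.calibrate_trace(raw, curve)
        assert np.allclose(cal.signal, pi_true, atol=1e-9)

    def test_out_of_range_points_flagged(self):
        curve = kin.StandardCurve(1.0, 0.0, (0.0, 10.0), 0.0, 4)
        raw = kin.KineticTrace(np.arange(30.0), np.linspace(0, 20, 30))
        cal = kin.calibrate_trace(raw, curve)
        assert cal.out_of_range.sum() > 0


class TestLagFit:
    def test_piecewise_linear_geometry_exact(self):
        """Flat-then-linear trace: rate 2, lag 5 s, initiation 0.2 /s."""
        t = np.arange(0, 20.01, 0.25)
        y = np.where(t < 5, 0.0, 2.0 * (t - 5.0))
        trace = kin.KineticTrace(t, y, calibrated=True, mcrB_conc_um=0.5)
        fit = kin.lag_fit(trace)
        assert fit.steady_state_rate == pytest.approx(2.0, abs=1e-12)
        assert fit.relaxation_time == pytest.approx(5.0, abs=1e-10)
        assert fit.initiation_rate == pytest.approx(0.2, abs=1e-10)
        assert fit.per_enzyme_rate == pytest.approx(4.0, abs=1e-10)

    @pytest.mark.parametrize("tail_fraction", [0.3, 0.4, 0.6])
    def test_affine_tail_exact_for_any_window_policy(self, tail_fraction):
        t = np.linspace(0, 30, 90)
        y = np.where(t < 8, 0.0, 1.3 * (t - 8.0))
        trace = kin.KineticTrace(t, y, calibrated=True)
        fit = kin.lag_fit(trace, tail_fraction=tail_fraction)
        assert fit.steady_state_rate == pytest.approx(1.3, abs=1e-10)
        assert fit.relaxation_time == pytest.approx(8.0, abs=1e-8)

    def test_line_through_origin_flags_infinite_initiation(self):
        t = np.linspace(0, 10, 50)
        trace = kin.KineticTrace(t, 2.0 * t, calibrated=True)
        fit = kin.lag_fit(trace)
        assert fit.relaxation_time == 0.0
        assert np.isinf(fit.initiation_rate)
        assert fit.steady_state_rate == pytest.approx(2.0, rel=1e-9)

    def test_burst_trace_clamped_with_warning(self):
        t = np.linspace(0, 10, 60)
        y = 2.0 * t + 1.0  # positive intercept -> negative x-intercept
        trace = kin.KineticTrace(t, y, calibrated=True)
        with pytest.warns(UserWarning, match="clamp"):
            fit = kin.lag_fit(trace)
        assert fit.relaxation_time == 0.0

    def test_flat_trace_has_no_steady_state(self):
        t = np.linspace(0, 10, 40)
        trace = kin.KineticTrace(t, np.zeros_like(t), calibrated=True)
        with pytest.raises(ValueError, match="no steady state"):
            kin.lag_fit(trace)

    def test_ode_trace_rate_matches_simulator_end_state(self):
        """Per-enzyme rate ~ k_cat x assembled fraction from the simulator."""
        params = AssemblyParams(k_bind=50, k_assoc=100, k_dissoc=1, k_cat=1.0)
        state = simulate_assembly(params, 0.5, t_end=120, n_points=500)
        fit = kin.lag_fit(simulate_pi_trace(state))
        oracle = params.k_cat * state.assembled_fraction()[-1]
        assert fit.per_enzyme_rate == pytest.approx(oracle, rel=0.05)


class TestAnalyzeSeries:
    @staticmethod
    def ladder(concs, noise=0.0, seed=1):
        traces = []
        for c in concs:
            params = AssemblyParams(mcrC_coupling=McrCCoupling())
            state = simulate_assembly(params, c, total_mcrC=c / 4, t_end=120,
                                      n_points=500)
            sd = noise * state.pi[-1]
            traces.append(simulate_pi_trace(state, noise_sd_um=sd, seed=seed))
        return traces

    def test_concentration_ladder_signature(self):
        """Constant per-enzyme rate, rising initiation rate: assembly first.

        The 4:1 ladder at 1% noise reproduces the mechanistic signature
        that the hydrolysing unit is the same at every concentration while
        assembly obeys mass action.
        """
        res = kin.analyze_series(self.ladder([0.25, 0.5, 1.0, 2.0], noise=0.01))
        assert res.per_enzyme_rate_cv < 0.10
        assert res.initiation_strictly_increasing

    def test_per_enzyme_rate_invariant_when_assembly_instant(self):
        traces = []
        for c in (0.25, 0.5, 1.0, 2.0):
            params = AssemblyParams(k_bind=1000, k_unbind=0, k_assoc=1e4,
                                    k_dissoc=10)
            state = simulate_assembly(params, c, t_end=120, n_points=300)
            traces.append(simulate_pi_trace(state))
        res = kin.analyze_series(traces)
        rates = [f.per_enzyme_rate for f in res.fits]
        assert (max(rates) - min(rates)) / min(rates) < 0.02

    def test_identical_traces_not_flagged_increasing(self):
        base = self.ladder([0.5])[0]
        traces = []
        for c in (0.25, 0.5, 1.0):
            tr = kin.KineticTrace(base.time_s.copy(), base.signal.copy(),
                                  calibrated=True, mcrB_conc_um=c,
                                  mcrC_conc_um=c / 4)
            traces.append(tr)
        res = kin.analyze_series(traces)
        assert not res.initiation_strictly_increasing

    def test_two_concentrations_rejected(self):
        traces = self.ladder([0.5, 1.0])
        with pytest.raises(ValueError, match=">= 3"):
            kin.analyze_series(traces)

    def test_wrong_subunit_ratio_rejected(self):
        traces = self.ladder([0.25, 0.5, 1.0])
        traces[0].mcrC_conc_um = traces[0].mcrB_conc_um  # 1:1, not 4:1
        with pytest.raises(ValueError, match="ratio"):
            kin.analyze_series(traces)


class TestSingleExponential:
    def test_exact_model_recovered_and_runs_test_passes(self):
        t = np.linspace(0, 30, 120)
        rng = np.random.default_rng(3)
        y = 0.5 + 1.2 * (1 - np.exp(-0.3 * t)) + rng.normal(0, 0.01, t.shape)
        fit = kin.fit_single_exponential(kin.KineticTrace(t, y))
        assert fit.amplitude == pytest.approx(1.2, rel=0.05)
        assert fit.rate == pytest.approx(0.3, rel=0.05)
        assert fit.baseline == pytest.approx(0.5, abs=0.02)
        assert fit.runs_p > 0.05

    def test_multistep_signal_rejects_single_exponential(self):
        """Sequential-assembly fluorescence misfits an exponential.

        The sigmoidal loading signal from the multi-step scheme leaves
        structured residuals: the runs test fails at alpha = 0.05 in at
        least 80% of noisy repeats.
        """
        # weak monomer loading (fast pre-equilibrium) followed by slow
        # assembly that pulls further loading: clearly biphasic signal
        params = AssemblyParams(k_bind=0.5, k_unbind=2.0, k_assoc=10)
        state = simulate_assembly(params, 0.5, t_end=120, n_points=200)
        failures = 0
        for seed in range(50):
            trace = simulate_trp_trace(state, noise_sd=0.002, seed=seed)
            fit = kin.fit_single_exponential(trace)
            if fit.runs_p < 0.05:
                failures += 1
        assert failures >= 40

    def test_constant_trace_unidentifiable(self):
        t = np.linspace(0, 10, 30)
        fit = kin.fit_single_exponential(kin.KineticTrace(t, np.full(30, 2.0)))
        assert not fit.identifiable
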