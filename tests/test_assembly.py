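import numpy as np
import pytest

from oligoring.kinetics import lag_fit
from oligoring.simulate import (
    AssemblyParams,
    McrCCoupling,
    simulate_assembly,
    simulate_pi_trace,
    simulate_trp_trace,
)


def terminal_rate(state):
    return (state.pi[-1] - state.pi[-2]) / (state.time_s[-1] - state.time_s[-2])


class TestSimulateAssembly:
    def test_no_hydrolysis_without_kcat(self):
        params = AssemblyParams(k_cat=0.0)
        state = simulate_assembly(params, 0.5, t_end=30)
        assert np.all(state.pi == 0.0)

    def test_subunit_conservation(self):
        """Total subunits (free + oligomeric + McrC-bound) stay constant."""
        params = AssemblyParams(mcrC_coupling=McrCCoupling())
        state = simulate_assembly(params, 0.8, total_mcrC=0.2, t_end=120)
        total = state.subunit_total()
        assert np.max(np.abs(total - 0.8)) / 0.8 < 1e-6

    def test_phosphate_monotone_nondecreasing(self):
        state = simulate_assembly(AssemblyParams(), 0.5, t_end=120, n_points=400)
        assert np.all(np.diff(state.pi) >= -1e-9)

    def test_all_assembled_limit_rate_is_kcat(self):
        """Fast, strongly forward assembly: terminal rate/monomer -> k_cat.

        Needs reversible intermediate steps so the system can anneal out of
        kinetically trapped partial oligomers into the stabilised ring.
        """
        params = AssemblyParams(
            k_bind=1000, k_unbind=0, k_assoc=1e4, k_dissoc=10, k_cat=1.0
        )
        state = simulate_assembly(params, 0.5, t_end=200, n_points=150)
        assert terminal_rate(state) / 0.5 == pytest.approx(1.0, rel=0.01)

    def test_moderate_assembly_convex_then_linear_with_lag(self):
        """Against a 10x finer integration grid and lag-fit positivity."""
        params = AssemblyParams(k_bind=5, k_assoc=10, k_cat=1.0)
        coarse = simulate_assembly(params, 0.5, t_end=120, n_points=301)
        fine = simulate_assembly(params, 0.5, t_end=120, n_points=3001)
        # grid-independence oracle: every 10th fine point shares a time stamp
        assert np.allclose(coarse.time_s, fine.time_s[::10])
        assert np.allclose(coarse.pi, fine.pi[::10], rtol=1e-5, atol=1e-7)
        # early convexity: the mean early slope is below the terminal slope
        n = len(coarse.time_s)
        early = (coarse.pi[n // 10] - coarse.pi[0]) / (
            coarse.time_s[n // 10] - coarse.time_s[0]
        )
        assert early < terminal_rate(coarse)
        fit = lag_fit(simulate_pi_trace(coarse))
        assert fit.relaxation_time > 0

    def test_lag_shrinks_as_association_speeds_up(self):
        taus = []
        for k_assoc in (1.0, 10.0, 100.0):
            state = simulate_assembly(
                AssemblyParams(k_assoc=k_assoc), 0.5, t_end=120, n_points=600
            )
            taus.append(lag_fit(simulate_pi_trace(state)).relaxation_time)
        assert taus[0] > taus[1] > taus[2]

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            simulate_assembly(AssemblyParams(), -1.0)
        with pytest.raises(ValueError):
            simulate_assembly(AssemblyParams(), 0.5, t_end=-5)
        with pytest.raises(ValueError):
            AssemblyParams(k_cat=-1.0)
        with pytest.raises(ValueError):
            AssemblyParams(n_ring=1)
        with pytest.raises(ValueError):
            McrCCoupling(stimulation_factor=0.5)

    def test_mcrc_stimulation_increases_rate(self):
        base = simulate_assembly(AssemblyParams(), 0.5, t_end=120)
        coupled = simulate_assembly(
            AssemblyParams(mcrC_coupling=McrCCoupling()), 0.5,
            total_mcrC=0.125, t_end=120,
        )
        assert terminal_rate(coupled) > 2 * terminal_rate(base)


class TestPiTrace:
    def test_noiseless_equals_model(self):
        state = simulate_assembly(AssemblyParams(), 0.5, t_end=60)
        trace = simulate_pi_trace(state, noise_sd_um=0.0)
        assert np.array_equal(trace.signal, state.pi)
        assert trace.calibrated

    def test_seed_determinism(self):
        state = simulate_assembly(AssemblyParams(), 0.5, t_end=60)
        a = simulate_pi_trace(state, noise_sd_um=0.05, seed=123)
        b = simulate_pi_trace(state, noise_sd_um=0.05, seed=123)
        assert np.array_equal(a.signal, b.signal)
        c = simulate_pi_trace(state, noise_sd_um=0.05, seed=124)
        assert not np.array_equal(a.signal, c.signal)

    def test_noise_amplitude_calibrated(self):
        state = simulate_assembly(AssemblyParams(), 0.5, t_end=60, n_points=200)
        trace = simulate_pi_trace(state, noise_sd_um=0.01, seed=5)
        resid_sd = np.std(trace.signal - state.pi)
        assert abs(resid_sd - 0.01) / 0.01 < 0.20


class TestTrpTrace:
    def test_zero_enhancement_is_flat(self):
        state = simulate_assembly(AssemblyParams(), 0.5, t_end=60)
        trace = simulate_trp_trace(state, enhancement=0.0, baseline=2.0)
        assert np.allclose(trace.signal, 2.0)

    def test_saturated_binding_plateau_twenty_percent(self):
        """All-bound end state with 20% enhancement plateaus at 1.20x."""
        params = AssemblyParams(k_unbind=0.0)
        state = simulate_assembly(params, 0.5, t_end=200, n_points=300)
        trace = simulate_trp_trace(state, enhancement=0.20, baseline=1.0)
        assert trace.signal[-1] == pytest.approx(1.20, abs=1e-3)

    def test_monotone_when_binding_irreversible(self):
        params = AssemblyParams(k_unbind=0.0)
        state = simulate_assembly(params, 0.5, t_end=120, n_points=300)
        trace = simulate_trp_trace(state)
        assert np.all(np.diff(trace.signal) >= -1e-9)


class TestGeneratorDeterminism:
    def test_chromatogram_and_mals_and_saxs_repeatable(self):
        from oligoring.simulate import (
            make_mals_run,
            make_saxs_sphere,
            make_sec_chromatogram,
        )

        c1 = make_sec_chromatogram([(12.0, 1.0, 0.3)], noise_sd=0.01, seed=9)
        c2 = make_sec_chromatogram([(12.0, 1.0, 0.3)], noise_sd=0.01, seed=9)
        assert np.array_equal(c1.signal, c2.signal)

        m1 = make_mals_run(320.0, noise_frac=0.01, seed=9)
        m2 = make_mals_run(320.0, noise_frac=0.01, seed=9)
        assert np.array_equal(m1.ls_intensity, m2.ls_intensity)

        s1 = make_saxs_sphere(50.0, noise_floor=1e-5, seed=9)
        s2 = make_saxs_sphere(50.0, noise_floor=1e-5, seed=9)
        assert np.array_equal(s1.intensity, s2.intensity)
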