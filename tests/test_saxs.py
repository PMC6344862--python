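import math

import numpy as np
import pytest

from oligoring import saxs
from oligoring.simulate import make_saxs_sphere
from oligoring.simulate.detectors import sphere_form_factor


class TestGuinierFit:
    @pytest.mark.parametrize(
        "radius, rg_expected, tol",
        [(51.51, 39.90, 0.1), (75.69, 58.63, 0.15)],
    )
    def test_sphere_rg_recovery(self, radius, rg_expected, tol):
        """Guinier Rg of a sphere equals sqrt(3/5) R (analytic)."""
        assert rg_expected == pytest.approx(math.sqrt(3 / 5) * radius, abs=0.01)
        curve = make_saxs_sphere(radius)
        res = saxs.guinier_fit(curve)
        assert res.rg == pytest.approx(rg_expected, abs=tol)

    @pytest.mark.parametrize("radius", [20, 35, 51.51, 65, 80, 100])
    def test_one_percent_recovery_across_radii(self, radius):
        curve = make_saxs_sphere(radius)
        res = saxs.guinier_fit(curve)
        assert res.rg == pytest.approx(math.sqrt(3 / 5) * radius, rel=0.01)
        assert res.i0 == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("radius", [30, 51.51, 90])
    def test_qrg_bound_enforced(self, radius):
        res = saxs.guinier_fit(make_saxs_sphere(radius))
        assert res.q_rg_max <= 1.3 + 1e-9

    def test_qrg_product_consistency(self):
        res = saxs.guinier_fit(make_saxs_sphere(51.51))
        assert res.q_rg_max == pytest.approx(res.q_max * res.rg, abs=1e-12)

    def test_weighted_fit_with_sigma(self):
        curve = make_saxs_sphere(51.51, noise_floor=1e-5, noise_frac=0.005, seed=7)
        res = saxs.guinier_fit(curve)
        assert res.rg == pytest.approx(math.sqrt(3 / 5) * 51.51, rel=0.03)

    def test_rising_curve_rejected(self):
        q = np.linspace(0.005, 0.1, 100)
        with pytest.raises(ValueError, match="Guinier"):
            saxs.guinier_fit(saxs.SaxsCurve(q=q, intensity=np.exp(+50 * q**2)))


class TestTruncation:
    def test_threshold_ratio_on_sphere(self):
        """Returned q has I(0)/I(q) within 5% of 10^2.25 (bisection oracle)."""
        curve = make_saxs_sphere(51.51, q_grid=np.linspace(0.002, 0.12, 4000))
        qm = saxs.truncation_qmax(curve, i0=1.0)
        # oracle: bisect the analytic sphere factor on its monotone stretch
        lo, hi = 1e-4, 4.49 / 51.51
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if sphere_form_factor(np.array([mid]), 51.51)[0] > 10**-2.25:
                lo = mid
            else:
                hi = mid
        assert qm == pytest.approx(0.5 * (lo + hi), rel=0.02)
        ratio = 1.0 / sphere_form_factor(np.array([qm]), 51.51)[0]
        assert ratio == pytest.approx(10**2.25, rel=0.05)

    def test_flat_curve_warns_and_returns_end(self):
        q = np.linspace(0.01, 0.3, 50)
        curve = saxs.SaxsCurve(q=q, intensity=np.ones_like(q))
        with pytest.warns(UserWarning):
            qm = saxs.truncation_qmax(curve, i0=1.0)
        assert qm == pytest.approx(q[-1])

    def test_zero_ratio_returns_first_point(self):
        curve = make_saxs_sphere(51.51)
        qm = saxs.truncation_qmax(curve, i0=1.0, ratio_log10=0.0)
        assert qm == pytest.approx(curve.q[0])


class TestPorodVolume:
    def test_sphere_volume_within_five_percent(self):
        """Porod volume of a noiseless sphere matches (4/3) pi R^3."""
        curve = make_saxs_sphere(51.51)
        gui = saxs.guinier_fit(curve)
        res = saxs.porod_volume(curve, gui)
        analytic = 4.0 / 3.0 * math.pi * 51.51**3
        assert analytic == pytest.approx(5.72e5, rel=0.001)
        assert res.apparent_volume_a3 == pytest.approx(analytic, rel=0.05)

    def test_matches_fine_grid_quadrature_oracle(self):
        curve = make_saxs_sphere(40.0)
        gui = saxs.guinier_fit(curve)
        res = saxs.porod_volume(curve, gui)
        # oracle: same invariant on a 10x finer analytic grid
        q_fine = np.linspace(1e-5, curve.q[-1], 20001)
        i_fine = sphere_form_factor(q_fine, 40.0)
        q_fine = np.concatenate([[0.0], q_fine])
        i_fine = np.concatenate([[1.0], i_fine])
        invariant = np.trapezoid(q_fine**2 * i_fine, q_fine)
        v_oracle = 2 * math.pi**2 * 1.0 / invariant
        assert res.apparent_volume_a3 == pytest.approx(v_oracle, rel=0.005)

    def test_intensity_scale_invariance(self):
        curve = make_saxs_sphere(51.51)
        scaled = saxs.SaxsCurve(q=curve.q, intensity=10.0 * curve.intensity)
        g1 = saxs.guinier_fit(curve)
        g2 = saxs.guinier_fit(scaled)
        v1 = saxs.porod_volume(curve, g1)
        v2 = saxs.porod_volume(scaled, g2)
        assert v2.apparent_volume_a3 == pytest.approx(v1.apparent_volume_a3, rel=1e-6)
        assert v2.mass_kda == pytest.approx(v1.mass_kda, rel=1e-6)

    def test_truncated_curve_underestimates_and_mass_grows_with_qmax(self):
        curve = make_saxs_sphere(51.51, q_grid=np.linspace(0.004, 0.6, 1200))
        gui = saxs.guinier_fit(curve)
        qm = saxs.truncation_qmax(curve, gui.i0)
        res_short = saxs.porod_volume(curve, gui, q_max=qm)
        analytic = 4.0 / 3.0 * math.pi * 51.51**3
        assert res_short.apparent_volume_a3 > analytic  # truncation inflates V
        masses = [
            saxs.porod_volume(curve, gui, q_max=q).mass_kda
            for q in (qm, 0.2, 0.4, 0.6)
        ]
        assert all(b < a for a, b in zip(masses, masses[1:]))


class TestPercentMassDifference:
    @pytest.mark.parametrize(
        "measured, calculated, expected",
        [(197.5, 214.0, 7.7), (476.4, 500.0, 4.7), (214.0, 214.0, 0.0)],
    )
    def test_printed_arithmetic(self, measured, calculated, expected):
        """Percent shortfall of scattering-derived vs sequence mass."""
        assert saxs.percent_mass_difference(measured, calculated) == expected

    def test_sign_convention(self):
        # measured above calculated gives a negative difference
        assert saxs.percent_mass_difference(220.0, 200.0) == -10.0
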