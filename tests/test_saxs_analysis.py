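"""Power-law regimes, cross-section Guinier analysis and model refits."""

import numpy as np
import pytest

from peptide_nanoform import (
    DEFAULT_LOW_Q_WINDOW,
    EllipticalCylinderParams,
    ScatteringCurve,
    SaxsScenario,
    circular_cylinder_intensity,
    elliptical_cylinder_intensity,
    fit_elliptical_cylinder,
    gen_saxs,
    guinier_cross_section,
    power_law_fit,
    regime_report,
)


class TestPowerLawFit:
    @pytest.mark.parametrize("exponent", [-2.0, -5.0 / 3.0, -1.0])
    def test_exact_power_law_recovered(self, exponent):
        q = np.geomspace(0.05, 1.0, 60)
        curve = ScatteringCurve(q=q, i=3.7 * q**exponent)
        fit = power_law_fit(curve, (0.05, 1.0))
        assert fit.exponent == pytest.approx(exponent, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exponent_invariant_under_rescaling(self):
        q = np.geomspace(0.05, 1.0, 60)
        curve = ScatteringCurve(q=q, i=q**-1.7)
        scaled = ScatteringCurve(q=q, i=1e4 * q**-1.7)
        a = power_law_fit(curve, (0.05, 1.0))
        b = power_law_fit(scaled, (0.05, 1.0))
        assert a.exponent == pytest.approx(b.exponent, abs=1e-12)

    def test_too_few_points_is_an_error(self):
        q = np.geomspace(0.05, 1.0, 60)
        curve = ScatteringCurve(q=q, i=q**-2.0)
        with pytest.raises(ValueError):
            power_law_fit(curve, (0.05, 0.055))

    def test_twisted_fibre_curve_shows_flat_particle_law(self, epk_model_curve):
        """The wide-ellipse geometry scatters as q⁻² at the low-q edge."""
        fit = power_law_fit(epk_model_curve, DEFAULT_LOW_Q_WINDOW)
        assert fit.exponent == pytest.approx(-2.0, abs=0.15)

    def test_ribbon_curve_shows_shallower_low_q_law(self, kpe_params):
        """The narrower-ellipse geometry fits close to the q^-5/3 reading."""
        curve = gen_saxs(SaxsScenario(params=kpe_params, noise="none", noise_level=0))
        fit = power_law_fit(curve, (0.086, 0.15))
        assert fit.exponent == pytest.approx(-5.0 / 3.0, abs=0.1)


class TestGuinierCrossSection:
    def test_pure_gaussian_round_trip_exact(self):
        """qI = exp(−q²Rσ²/2) with Rσ² = 8 inverts to Rσ = 2.828…"""
        q = np.linspace(0.05, 0.4, 50)
        curve = ScatteringCurve(q=q, i=np.exp(-4.0 * q**2) / q)
        fit = guinier_cross_section(curve, (0.05, 0.4))
        assert fit.r_sigma == pytest.approx(np.sqrt(8.0), abs=1e-10)

    def test_round_trip_with_prefactor(self):
        rs = 3.3
        q = np.linspace(0.04, 0.35, 40)
        curve = ScatteringCurve(q=q, i=5.0 * np.exp(-0.5 * rs**2 * q**2) / q)
        fit = guinier_cross_section(curve, (0.04, 0.35))
        assert fit.r_sigma == pytest.approx(rs, abs=1e-10)

    def test_circular_cylinder_r_over_sqrt2_law(self):
        q = np.geomspace(0.05, 0.26, 40)
        i = circular_cylinder_intensity(q, 5.0, 1000.0)
        curve = ScatteringCurve(q=q, i=np.atleast_1d(i))
        fit = guinier_cross_section(curve, (0.05, 0.26))
        assert fit.valid
        assert fit.r_sigma == pytest.approx(5.0 / np.sqrt(2), rel=0.02)

    def test_increasing_curve_flagged_invalid(self):
        q = np.linspace(0.05, 0.4, 30)
        fit = guinier_cross_section(ScatteringCurve(q=q, i=q**2 + 1), (0.05, 0.4))
        assert not fit.valid
        assert fit.r_sigma is None

    def test_validity_requires_qr_below_limit(self):
        rs = 10.0
        q = np.linspace(0.05, 0.4, 40)
        curve = ScatteringCurve(q=q, i=np.exp(-0.5 * rs**2 * q**2) / q)
        fit = guinier_cross_section(curve, (0.05, 0.4))
        assert fit.r_sigma == pytest.approx(rs, abs=1e-8)
        assert not fit.valid  # q·Rσ = 4 at the window top


@pytest.fixture(scope="module")
def kpe_model_curve(kpe_params):
    q = np.geomspace(0.1, 7.0, 200)
    return elliptical_cylinder_intensity(q, kpe_params)


def perturbed_init(truth, factor=1.3):
    return EllipticalCylinderParams(
        r_minor=truth.r_minor * factor,
        axis_ratio=max(1.0, truth.axis_ratio * factor),
        length=truth.length,
        scale=truth.scale,
        background=truth.background + 1e-4,
    )


class TestFitEllipticalCylinder:
    def test_noiseless_self_fit_recovers_cross_section(self, kpe_params, kpe_model_curve):
        fit = fit_elliptical_cylinder(
            kpe_model_curve, perturbed_init(kpe_params), fixed=("length", "scale")
        )
        assert fit.status == "converged"
        assert fit.params.r_minor == pytest.approx(kpe_params.r_minor, rel=5e-3)
        assert fit.params.axis_ratio == pytest.approx(kpe_params.axis_ratio, rel=5e-3)

    def test_init_at_truth_leaves_zero_residual(self, kpe_params, kpe_model_curve):
        fit = fit_elliptical_cylinder(
            kpe_model_curve, kpe_params, fixed=("length", "scale")
        )
        assert fit.reduced_chi2 == pytest.approx(0.0, abs=1e-20)
        assert fit.params.r_minor == pytest.approx(kpe_params.r_minor, rel=1e-9)

    def test_random_inits_converge_to_truth(self, kpe_params, kpe_model_curve):
        """±30% random perturbations of the free parameters all recover."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            f_r, f_nu = 1.0 + rng.uniform(-0.3, 0.3, size=2)
            init = EllipticalCylinderParams(
                r_minor=kpe_params.r_minor * f_r,
                axis_ratio=max(1.0, kpe_params.axis_ratio * f_nu),
                length=kpe_params.length,
                scale=kpe_params.scale,
                background=1e-4,
            )
            fit = fit_elliptical_cylinder(
                kpe_model_curve, init, fixed=("length", "scale")
            )
            assert fit.params.r_minor == pytest.approx(kpe_params.r_minor, rel=5e-3)
            assert fit.params.axis_ratio == pytest.approx(
                kpe_params.axis_ratio, rel=5e-3
            )

    def test_noisy_replicates_recover_on_average(self, kpe_params):
        """1% multiplicative noise: mean fitted minor radius within 2%."""
        recovered = []
        for seed in range(20):
            curve = gen_saxs(
                SaxsScenario(
                    params=kpe_params,
                    q_min=0.1,
                    q_max=7.0,
                    noise="multiplicative",
                    noise_level=0.01,
                    seed=seed,
                )
            )
            fit = fit_elliptical_cylinder(
                curve, perturbed_init(kpe_params), fixed=("length", "scale")
            )
            recovered.append(fit.params.r_minor)
        assert np.mean(recovered) == pytest.approx(kpe_params.r_minor, rel=0.02)

    def test_fit_is_deterministic(self, kpe_params, kpe_model_curve):
        init = perturbed_init(kpe_params)
        a = fit_elliptical_cylinder(kpe_model_curve, init, fixed=("length", "scale"))
        b = fit_elliptical_cylinder(kpe_model_curve, init, fixed=("length", "scale"))
        assert a.params == b.params
        assert a.reduced_chi2 == b.reduced_chi2

    def test_unknown_fixed_name_rejected(self, kpe_params, kpe_model_curve):
        with pytest.raises(ValueError):
            fit_elliptical_cylinder(kpe_model_curve, kpe_params, fixed=("radius",))


class TestRegimeReport:
    def test_pure_power_law_is_one_regime(self):
        q = np.geomspace(0.05, 5.0, 120)
        report = regime_report(ScatteringCurve(q=q, i=q**-2.0))
        assert len(report) == 1
        assert report[0][1] == pytest.approx(-2.0, abs=1e-6)

    def test_piecewise_breakpoint_located(self):
        q = np.geomspace(0.05, 5.0, 200)
        q_break = 0.7
        i = np.where(q < q_break, q**-1.0, q_break**3.0 * q**-4.0)
        report = regime_report(ScatteringCurve(q=q, i=i))
        assert len(report) >= 2
        (w1, e1), (w2, e2) = report[0], report[1]
        assert e1 == pytest.approx(-1.0, abs=0.05)
        assert e2 == pytest.approx(-4.0, abs=0.05)
        step = np.log(q[1] / q[0])
        assert abs(np.log(w1[1] / q_break)) <= 2.5 * step
        assert abs(np.log(w2[0] / q_break)) <= 2.5 * step

    def test_twisted_fibre_first_regime_matches_windowed_oracle(self, epk_model_curve):
        """Segmentation's lowest-q regime agrees with a direct refit of its window."""
        report = regime_report(epk_model_curve)
        (w, e) = report[0]
        direct = power_law_fit(epk_model_curve, w)
        assert e == pytest.approx(direct.exponent, abs=0.05)
        assert e == pytest.approx(-2.29, abs=0.1)  # frozen from the model-curve oracle

    def test_short_curve_rejected(self):
        q = np.geomspace(0.1, 1.0, 20)
        with pytest.raises(ValueError):
            regime_report(ScatteringCurve(q=q, i=q**-2.0))
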