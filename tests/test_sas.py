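import numpy as np
import pytest

import gqmelt as g
from gqmelt import synthetic as syn
from gqmelt.sas import QUAD_ORDER, SASFitResult
from gqmelt.spectra_io import SASCurve, ValidationError

BOX = g.BoxModel(15.0, None, 27.0)
Q = np.geomspace(0.02, 1.0, 120)


class TestFormFactors:
    def test_normalization_at_zero(self):
        assert g.parallelepiped_form_factor(0.0, BOX) == pytest.approx(1.0, abs=1e-12)
        assert g.dimer_form_factor(0.0, BOX) == pytest.approx(1.0, abs=1e-12)

    def test_bounded_and_positive(self):
        P = g.parallelepiped_form_factor(Q, BOX)
        assert np.all(P > 0)
        assert np.all(P <= 1.0 + 1e-12)

    def test_guinier_rg_matches_analytic_box(self, box_curve):
        curve, box = box_curve
        _, rg, _, _ = g.guinier_fit(curve)
        assert rg == pytest.approx(box.rg, rel=0.02)  # sqrt(99/4...) = 9.91 A

    def test_quadrature_order_doubling_converges(self):
        Pa = g.parallelepiped_form_factor(Q, BOX, order=QUAD_ORDER)
        Pb = g.parallelepiped_form_factor(Q, BOX, order=2 * QUAD_ORDER)
        np.testing.assert_allclose(Pa, Pb, rtol=1e-8)
        Da = g.dimer_form_factor(Q, BOX, order=QUAD_ORDER)
        Db = g.dimer_form_factor(Q, BOX, order=2 * QUAD_ORDER)
        np.testing.assert_allclose(Da, Db, rtol=1e-8)

    def test_gap_zero_axial_dimer_is_double_height_box(self):
        tall = g.BoxModel(15.0, None, 54.0)
        D = g.dimer_form_factor(Q, BOX, "axial_stack", gap=0.0)
        P = g.parallelepiped_form_factor(Q, tall)
        np.testing.assert_allclose(D, P, rtol=1e-6)

    def test_gap_zero_axial_dimer_guinier_rg(self):
        q = np.geomspace(0.005, 0.2, 100)
        I = g.dimer_form_factor(q, BOX, "axial_stack", gap=0.0)
        curve = SASCurve(q, I, 0.01 * I)
        # elongated particle: the Guinier law bends early, so restrict
        # the window to q Rg <= 1.0 as standard for anisotropic shapes
        _, rg, _, _ = g.guinier_fit(curve, qrg_max=1.0)
        rg_true = np.sqrt((15.0**2 + 15.0**2 + 54.0**2) / 12.0)
        assert rg == pytest.approx(rg_true, rel=0.02)

    def test_side_by_side_differs_from_axial(self):
        ax = g.dimer_form_factor(Q, BOX, "axial_stack", gap=0.0)
        sbs = g.dimer_form_factor(Q, BOX, "side_by_side", gap=0.0)
        assert np.max(np.abs(ax - sbs)) > 0.01


class TestMixtureIntensity:
    def test_pure_monomer(self):
        model = g.MixtureModel(monomer=BOX, dimer_fraction=0.0, scale=2.0, background=0.1)
        I = g.mixture_intensity(Q, model)
        np.testing.assert_allclose(
            I, 2.0 * g.parallelepiped_form_factor(Q, BOX) + 0.1, rtol=1e-12
        )

    def test_pure_dimer(self):
        model = g.MixtureModel(monomer=BOX, dimer_fraction=1.0, scale=1.5)
        I = g.mixture_intensity(Q, model)
        np.testing.assert_allclose(
            I, 1.5 * 2.0 * g.dimer_form_factor(Q, BOX), rtol=1e-12
        )

    def test_forward_intensity_weighting_at_half(self):
        # I(0) = scale * [(1 - f) + 2 f] = 1.5 scale at f = 0.5
        model = g.MixtureModel(monomer=BOX, dimer_fraction=0.5, scale=2.0, background=0.25)
        tiny = g.mixture_intensity(np.array([1e-6]), model)[0]
        assert tiny == pytest.approx(2.0 * 1.5 + 0.25, rel=1e-9)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            g.MixtureModel(monomer=BOX, dimer_fraction=1.2)


class TestFitSASModel:
    def test_noiseless_monomer_round_trip(self):
        truth = g.MixtureModel(monomer=BOX, dimer_fraction=0.0)
        curve = syn.generate_sas_curve(truth, noise_frac=0.0, seed=0)
        start = g.MixtureModel(monomer=g.BoxModel(14.0, None, 30.0))
        res = g.fit_sas_model(
            curve, start, fix={"dimer_fraction", "gap", "background", "scale"}
        )
        assert res.model.monomer.side_a == pytest.approx(15.0, abs=1e-4)
        assert res.model.monomer.height_c == pytest.approx(27.0, abs=1e-4)

    def test_mixture_recovery_over_seeds(self):
        truth = g.MixtureModel(monomer=BOX, dimer_fraction=0.5)
        fds, sides = [], []
        for seed in range(10):
            curve = syn.generate_sas_curve(truth, noise_frac=0.01, seed=seed)
            start = g.MixtureModel(monomer=g.BoxModel(13.0, None, 30.0), dimer_fraction=0.3)
            res = g.fit_sas_model(curve, start, fix={"gap", "background"})
            fds.append(res.model.dimer_fraction)
            sides.append(res.model.monomer.side_a)
        assert abs(np.median(fds) - 0.5) < 0.1
        assert abs(np.median(sides) - 15.0) < 1.0

    def test_all_fixed_returns_model_chi2(self):
        truth = g.MixtureModel(monomer=BOX, dimer_fraction=0.0)
        curve = syn.generate_sas_curve(truth, noise_frac=0.0, seed=0)
        res = g.fit_sas_model(
            curve,
            truth,
            fix={"side_a", "side_b", "height_c", "gap", "dimer_fraction", "scale", "background"},
        )
        assert isinstance(res, SASFitResult)
        assert res.chi2_reduced < 1e-12
        assert res.model == truth

    def test_unknown_fix_name_rejected(self):
        curve = syn.generate_sas_curve(
            g.MixtureModel(monomer=BOX), noise_frac=0.0, seed=0
        )
        with pytest.raises(ValidationError, match="unknown"):
            g.fit_sas_model(curve, g.MixtureModel(monomer=BOX), fix={"bogus"})


class TestGuinier:
    def test_exact_gaussian_curve(self):
        q = np.linspace(0.01, 0.2, 100)
        I = 5.0 * np.exp(-(q**2) * 100.0 / 3.0)
        i0, rg, _, _ = g.guinier_fit(SASCurve(q, I, 0.01 * I))
        assert i0 == pytest.approx(5.0, rel=1e-8)
        assert rg == pytest.approx(10.0, rel=1e-8)

    def test_window_respects_qrg_limit(self, box_curve):
        curve, _ = box_curve
        _, rg, (qlo, qhi), _ = g.guinier_fit(curve, qrg_max=1.3)
        assert qhi * rg <= 1.3 + 1e-9

    def test_flat_curve_rejected(self):
        q = np.linspace(0.01, 0.2, 50)
        I = np.ones_like(q)
        with pytest.raises(ValidationError):
            g.guinier_fit(SASCurve(q, I, 0.01 * I))


class TestPorodVolume:
    def test_sphere_volume(self, sphere_curve):
        curve, R = sphere_curve
        out = g.porod_volume(curve)
        v_true = 4.0 / 3.0 * np.pi * R**3
        assert out["volume"] == pytest.approx(v_true, rel=0.03)

    def test_box_volume(self, box_curve):
        curve, box = box_curve
        out = g.porod_volume(curve)
        assert out["volume"] == pytest.approx(box.volume, rel=0.10)

    def test_scale_invariance(self, sphere_curve):
        curve, _ = sphere_curve
        scaled = SASCurve(curve.q, 7.5 * curve.intensity, 7.5 * curve.sigma)
        v1 = g.porod_volume(curve)["volume"]
        v2 = g.porod_volume(scaled)["volume"]
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_negative_intensity_rejected(self, sphere_curve):
        curve, _ = sphere_curve
        with pytest.raises(ValidationError):
            g.porod_volume(curve, background=float(curve.intensity.max()))


class TestIFT:
    def test_sphere_pr_matches_closed_form(self, sphere_curve):
        curve, R = sphere_curve
        res = g.ift_pr(curve, Dmax=2 * R)
        r = res.r
        p_true = r**2 * (1.0 - 0.75 * (r / R) + (r / R) ** 3 / 16.0)
        p_true[r > 2 * R] = 0.0
        p_true *= np.trapezoid(res.p, r) / np.trapezoid(p_true, r)
        assert np.max(np.abs(res.p - p_true)) < 0.03 * p_true.max()

    def test_sphere_rg_from_moments(self, sphere_curve):
        curve, R = sphere_curve
        res = g.ift_pr(curve, Dmax=2 * R)
        assert res.Rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.02)

    def test_forward_model_i0_consistency(self, sphere_curve):
        curve, R = sphere_curve
        res = g.ift_pr(curve, Dmax=2 * R)
        i0_fwd = 4.0 * np.pi * np.trapezoid(res.p, res.r)
        assert res.I0 == pytest.approx(i0_fwd, rel=1e-8)

    def test_boundary_zeros(self, sphere_curve):
        curve, R = sphere_curve
        res = g.ift_pr(curve, Dmax=2 * R)
        assert res.p[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p[-1] == pytest.approx(0.0, abs=1e-12)

    def test_too_small_dmax_flagged(self, sphere_curve):
        curve, R = sphere_curve
        tight = SASCurve(curve.q, curve.intensity, 0.001 * curve.intensity)
        res = g.ift_pr(tight, Dmax=1.1 * R)
        assert res.dmax_warning

    def test_refit_chi2_near_one_on_matched_noise(self):
        R = 20.0
        q = np.geomspace(0.02, 1.0, 120)
        x = q * R
        I = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
        rng = np.random.default_rng(4)
        noisy = I * (1.0 + rng.normal(0.0, 0.01, q.size))
        res = g.ift_pr(SASCurve(q, noisy, 0.01 * I), Dmax=2 * R)
        assert 0.5 < res.chi2_reduced < 2.0


class TestKratky:
    def test_constant_intensity_parabola(self):
        q = np.linspace(0.01, 1.0, 50)
        c = SASCurve(q, np.full_like(q, 3.0), np.full_like(q, 0.1))
        out = g.kratky_transform(c)
        np.testing.assert_allclose(out[:, 1], 3.0 * q**2, rtol=1e-12)

    def test_guinier_curve_peak_position(self):
        rg = 10.0
        q = np.linspace(0.005, 0.6, 2000)
        I = np.exp(-(q**2) * rg**2 / 3.0)
        out = g.kratky_transform(SASCurve(q, I, 0.01 * I))
        qpeak = out[np.argmax(out[:, 1]), 0]
        assert qpeak == pytest.approx(np.sqrt(3.0) / rg, rel=1e-3)

    def test_empty_curve(self):
        c = SASCurve(np.array([]), np.array([]), np.array([]))
        assert g.kratky_transform(c).size == 0


class TestScalarModels:
    def test_saw_rg_values(self):
        assert g.saw_rg(22) == pytest.approx(20.39, abs=0.01)
        assert g.saw_rg(1) == pytest.approx(3.0)
        assert g.saw_rg(100) == pytest.approx(3.0 * 100**0.62, rel=1e-12)
        assert g.saw_rg(100) == pytest.approx(52.1, abs=0.1)

    def test_saw_rg_invalid_n(self):
        with pytest.raises(ValidationError):
            g.saw_rg(0)

    def test_tel22_molecular_weight(self):
        mw, _ = g.molecular_weight_volume(g.TEL22_SEQUENCE)
        # independent residue-mass summation: 4 A + 12 G + 6 T - 61.96
        expected = 4 * 313.21 + 12 * 329.21 + 6 * 304.20 - 61.96
        assert mw == pytest.approx(expected, rel=1e-12)
        assert mw == pytest.approx(6.97e3, rel=0.005)

    def test_tel22_volume_near_reference(self):
        _, vol = g.molecular_weight_volume(g.TEL22_SEQUENCE, vbar=0.55)
        assert vol == pytest.approx(6400.0, rel=0.02)

    def test_single_nucleotide(self):
        mw, _ = g.molecular_weight_volume("A")
        assert mw == pytest.approx(313.21 - 61.96, rel=1e-12)

    def test_invalid_base_rejected(self):
        with pytest.raises(ValidationError):
            g.molecular_weight_volume("AGGU")

    def test_forward_scattering_linearity_and_dimer(self):
        base = g.forward_scattering_absolute(450e-6, 6966.6, 0.55, 3.2e10)
        assert g.forward_scattering_absolute(900e-6, 6966.6, 0.55, 3.2e10) == pytest.approx(
            2.0 * base, rel=1e-12
        )
        assert g.forward_scattering_absolute(
            450e-6, 6966.6, 0.55, 3.2e10, dimer=True
        ) == pytest.approx(2.0 * base, rel=1e-12)

    def test_forward_scattering_hand_evaluation(self):
        from scipy.constants import Avogadro

        conc, mw, vbar, drho = 450e-6, 6966.6, 0.55, 3.2e10
        n_p = conc * Avogadro * 1e-3
        v_p = vbar * mw / Avogadro
        assert g.forward_scattering_absolute(conc, mw, vbar, drho) == pytest.approx(
            n_p * v_p**2 * drho**2, rel=1e-10
        )
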