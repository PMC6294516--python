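import numpy as np
import pytest

import gqmelt as g
from gqmelt import synthetic as syn
from gqmelt.melting import (
    FitError,
    R_KCAL,
    reconstruct_species_spectra_from_factors,
)
from gqmelt.spectra_io import MeltingMatrix, ValidationError


class TestSequentialPopulations:
    def test_midpoint_is_half(self):
        p = g.SequentialModelParams(dH=(-80.0,), Tm=(70.0,))
        np.testing.assert_allclose(g.sequential_populations(p, 70.0), [0.5, 0.5])

    def test_native_limit_cold(self):
        p = g.SequentialModelParams(dH=(-27.3, -41.0, -63.2), Tm=(38.5, 60.3, 68.9))
        f = g.sequential_populations(p, -200.0)
        assert f[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_state_oracle_at_80C(self):
        # independent direct evaluation of the partition sum
        K = np.exp((50.0 / R_KCAL) * (1.0 / (70.0 + 273.15) - 1.0 / (80.0 + 273.15)))
        expected = K / (1.0 + K)
        p = g.SequentialModelParams(dH=(50.0,), Tm=(70.0,))
        f = g.sequential_populations(p, 80.0)
        assert f[1] == pytest.approx(expected, rel=1e-12)
        assert f[1] == pytest.approx(0.889, abs=1e-3)

    def test_two_state_closed_form_equivalence(self):
        p = g.SequentialModelParams(dH=(60.0,), Tm=(55.0,))
        T = np.linspace(20.0, 95.0, 40)
        f = g.sequential_populations(p, T)
        K = np.exp((60.0 / R_KCAL) * (1.0 / (55.0 + 273.15) - 1.0 / (T + 273.15)))
        np.testing.assert_allclose(f[:, 1], K / (1.0 + K), rtol=1e-12)

    def test_extreme_temperatures_no_overflow(self):
        p = g.SequentialModelParams(dH=(-300.0, -300.0), Tm=(40.0, 60.0))
        f = g.sequential_populations(p, np.array([-250.0, 500.0]))
        assert np.all(np.isfinite(f))
        np.testing.assert_allclose(f.sum(axis=1), 1.0, rtol=1e-12)


class TestAutocorrelation:
    def test_constant_vector(self):
        assert g.autocorrelation(np.ones(10)) == pytest.approx(0.9)

    def test_alternating_vector(self):
        assert g.autocorrelation((-1.0) ** np.arange(10)) == pytest.approx(-0.9)

    def test_smooth_sigmoid_passes_cutoff(self):
        T = np.linspace(30.0, 82.0, 27)
        v = 1.0 / (1.0 + np.exp(-(T - 56.0) / 4.0))
        assert g.autocorrelation(v) > 0.8

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            g.autocorrelation(np.zeros(8))


class TestSVDDecompose:
    def test_rank_one_outer_product(self):
        m = MeltingMatrix(
            values=np.outer(np.arange(1.0, 7.0), np.arange(1.0, 5.0)),
            axis=np.arange(6.0),
            temperatures=np.arange(30.0, 38.0, 2.0),
            probe="cd",
        )
        svd = g.svd_decompose(m)
        assert np.sum(svd.singular_values > 1e-10) == 1

    def test_reconstruction_exact_full_rank(self):
        rng = np.random.default_rng(11)
        m = MeltingMatrix(
            values=rng.normal(size=(6, 5)),
            axis=np.arange(6.0),
            temperatures=np.arange(30.0, 40.0, 2.0),
            probe="cd",
        )
        svd = g.svd_decompose(m)
        err = np.linalg.norm(svd.reconstruct() - m.values) / np.linalg.norm(m.values)
        assert err < 1e-10

    def test_noiseless_four_species_rank(self, noiseless_cd_matrix):
        svd = g.svd_decompose(noiseless_cd_matrix)
        s = svd.singular_values
        assert np.sum(s > 1e-8 * s[0]) == 4

    def test_singular_vectors_unit_norm(self, noisy_cd_matrix):
        svd = g.svd_decompose(noisy_cd_matrix)
        np.testing.assert_allclose(np.linalg.norm(svd.basis, axis=0), 1.0, rtol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(svd.profiles, axis=0), 1.0, rtol=1e-12)


class TestSelectSignificantSpecies:
    def test_variance_fraction_rank_one(self):
        # singular values (3, 1) with only the first profile smooth:
        # rank 1 explains 9/10 of the squared-singular-value variance
        svd = g.SVDResult(
            basis=np.eye(2),
            singular_values=np.array([3.0, 1.0]),
            profiles=np.eye(2),
            autocorr_U=np.array([0.9, -0.5]),
            autocorr_V=np.array([0.9, -0.5]),
            temperatures=np.array([30.0, 32.0]),
            axis=np.arange(2.0),
            probe="cd",
        )
        rank, var = g.select_significant_species(svd, cutoff=0.8)
        assert rank == 1
        assert var == pytest.approx(90.0)

    def test_selection_stops_at_first_failure(self):
        # a later passing component must not be counted once one fails
        svd = g.SVDResult(
            basis=np.eye(3),
            singular_values=np.array([3.0, 2.0, 1.0]),
            profiles=np.eye(3),
            autocorr_U=np.array([0.9, 0.1, 0.9]),
            autocorr_V=np.array([0.9, 0.1, 0.9]),
            temperatures=np.array([30.0, 32.0, 34.0]),
            axis=np.arange(3.0),
            probe="cd",
        )
        rank, _ = g.select_significant_species(svd, cutoff=0.8)
        assert rank == 1

    def test_pure_noise_selects_zero_with_warning(self):
        rng = np.random.default_rng(2)
        m = MeltingMatrix(
            values=rng.normal(size=(40, 20)),
            axis=np.arange(40.0),
            temperatures=np.arange(30.0, 70.0, 2.0),
            probe="cd",
        )
        svd = g.svd_decompose(m)
        with pytest.warns(UserWarning, match="cutoff"):
            rank, var = g.select_significant_species(svd, 0.95)
        assert rank == 0

    def test_four_species_cd_matrix_rank_four(self, noisy_cd_matrix):
        svd = g.svd_decompose(noisy_cd_matrix)
        rank, var = g.select_significant_species(svd, 0.8)
        assert rank == 4
        assert var > 98.0

    def test_variance_monotone_in_rank(self, noisy_cd_matrix):
        svd = g.svd_decompose(noisy_cd_matrix)
        s2 = svd.singular_values**2
        cum = 100.0 * np.cumsum(s2) / np.sum(s2)
        assert np.all(np.diff(cum) >= 0)
        assert cum[-1] == pytest.approx(100.0)


class TestGlobalFitSequential:
    def test_noiseless_two_state_recovery(self):
        truth = g.SequentialModelParams(dH=(-45.0,), Tm=(55.0,))
        species = [
            syn.make_species_spectra("cd", syn.cd_axis(), "hybrid"),
            syn.make_species_spectra("cd", syn.cd_axis(), "unfolded"),
        ]
        spec = syn.SyntheticSpec(
            model=truth, species_spectra=species,
            temperatures=syn.cd_temperatures(), noise_sd=0.0, seed=0,
        )
        svd = g.svd_decompose(g.generate_melting_matrix(spec))
        fit = g.global_fit_sequential(svd, rank=2, steps=1)
        assert fit.params.Tm[0] == pytest.approx(55.0, rel=1e-6)
        assert abs(fit.params.dH[0]) == pytest.approx(45.0, rel=1e-6)

    def test_noiseless_four_state_recovery(self, noiseless_cd_matrix):
        svd = g.svd_decompose(noiseless_cd_matrix)
        fit = g.global_fit_sequential(svd, rank=4, steps=3)
        np.testing.assert_allclose(fit.params.Tm, (38.5, 60.3, 68.9), atol=1e-4)
        np.testing.assert_allclose(
            np.abs(fit.params.dH), (27.3, 41.0, 63.2), rtol=1e-4
        )

    def test_rank_steps_mismatch_rejected(self, noisy_cd_matrix):
        svd = g.svd_decompose(noisy_cd_matrix)
        with pytest.raises(ValidationError, match="steps"):
            g.global_fit_sequential(svd, rank=4, steps=1)

    def test_populations_sum_to_one(self, noisy_cd_matrix):
        svd = g.svd_decompose(noisy_cd_matrix)
        fit = g.global_fit_sequential(svd, rank=4, steps=3)
        np.testing.assert_allclose(fit.populations.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(fit.populations >= 0)

    def test_tm_ordered_ascending(self, noisy_cd_matrix):
        svd = g.svd_decompose(noisy_cd_matrix)
        fit = g.global_fit_sequential(svd, rank=4, steps=3)
        assert list(fit.params.Tm) == sorted(fit.params.Tm)

    def test_standard_errors_reported(self, noisy_cd_matrix):
        svd = g.svd_decompose(noisy_cd_matrix)
        fit = g.global_fit_sequential(svd, rank=4, steps=3)
        assert all(np.isfinite(fit.params.dH_err))
        assert all(np.isfinite(fit.params.Tm_err))
        assert all(e > 0 for e in fit.params.Tm_err)


class TestReconstructSpeciesSpectra:
    def test_noiseless_round_trip(self, cd_species, noiseless_cd_matrix):
        svd = g.svd_decompose(noiseless_cd_matrix)
        fit = g.global_fit_sequential(svd, rank=4, steps=3)
        E_true = np.column_stack([s.amplitude for s in cd_species])
        spectra = g.reconstruct_species_spectra(svd, fit)
        np.testing.assert_allclose(spectra, E_true, atol=1e-8)
        resid = spectra @ fit.populations.T - noiseless_cd_matrix.values
        assert np.max(np.abs(resid)) < 1e-8

    def test_noisy_recovery_correlation(self, cd_species, noisy_cd_matrix):
        svd = g.svd_decompose(noisy_cd_matrix)
        fit = g.global_fit_sequential(svd, rank=4, steps=3)
        for k, sp in enumerate(cd_species):
            r = np.corrcoef(fit.species_spectra[:, k], sp.amplitude)[0, 1]
            if sp.label == "U":
                # the unfolded spectrum peaks at ~18% of the native one,
                # so at 2% (of native peak) noise its own S/N caps the
                # attainable correlation below that of the strong species
                assert r > 0.98
            else:
                assert r > 0.99

    def test_one_species_degenerate_returns_mean_spectrum(self):
        e = np.sin(np.linspace(0.0, 3.0, 50)) + 2.0
        m = MeltingMatrix(
            values=np.outer(e, np.ones(8)),
            axis=np.arange(50.0),
            temperatures=np.arange(30.0, 46.0, 2.0),
            probe="cd",
        )
        svd = g.svd_decompose(m)
        F = np.ones((8, 1))
        C, *_ = np.linalg.lstsq(F, svd.profiles[:, :1], rcond=None)
        spectra = reconstruct_species_spectra_from_factors(svd, 1, C)
        np.testing.assert_allclose(spectra[:, 0], e, rtol=1e-10)


class TestMeltingDerivativeScreen:
    def sigmoid_matrix(self, centers, heights=None):
        T = syn.cd_temperatures()
        heights = heights or [1.0] * len(centers)
        prof = sum(
            h / (1.0 + np.exp(-(T - c) / 2.5)) for c, h in zip(centers, heights)
        )
        return MeltingMatrix(
            values=np.vstack([prof, prof]),
            axis=np.array([260.0, 290.0]),
            temperatures=T,
            probe="cd",
        )

    def test_single_sigmoid_inflection(self):
        m = self.sigmoid_matrix([65.0])
        out = g.melting_derivative_screen(m, [290.0])
        wl, temps = out[0]
        assert wl == 290.0
        assert len(temps) == 1
        assert temps[0] == pytest.approx(65.0, abs=2.0)

    def test_two_sigmoids_two_inflections(self):
        m = self.sigmoid_matrix([40.0, 70.0])
        _, temps = g.melting_derivative_screen(m, [290.0])[0]
        assert len(temps) == 2
        assert temps[0] == pytest.approx(40.0, abs=3.0)
        assert temps[1] == pytest.approx(70.0, abs=3.0)

    def test_flat_profile_empty(self):
        T = syn.cd_temperatures()
        m = MeltingMatrix(
            values=np.ones((2, T.size)),
            axis=np.array([260.0, 290.0]),
            temperatures=T,
            probe="cd",
        )
        _, temps = g.melting_derivative_screen(m, [260.0])[0]
        assert temps == []

    def test_too_few_temperatures_rejected(self):
        m = MeltingMatrix(
            values=np.ones((2, 4)),
            axis=np.array([260.0, 290.0]),
            temperatures=np.array([30.0, 40.0, 50.0, 60.0]),
            probe="cd",
        )
        with pytest.raises(ValidationError):
            g.melting_derivative_screen(m, [260.0])
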