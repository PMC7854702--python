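import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytosaxs import bead_models as bm
from phytosaxs import saxs_core as sc
from phytosaxs import synthetic_data as sd


def _write(tmp_path, text, name="p.dat"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadProfile:
    def test_three_column_parse(self, tmp_path):
        path = _write(tmp_path, "0.004 100 1\n0.008 80 1\n0.012 60 1\n")
        p = sc.read_profile(path)
        assert np.allclose(p.s, [0.004, 0.008, 0.012])
        assert np.allclose(p.intensity, [100, 80, 60])

    def test_rows_sorted_by_s(self, tmp_path):
        a = sc.read_profile(_write(tmp_path, "0.004 100 1\n0.008 80 1\n0.012 60 1\n"))
        b = sc.read_profile(_write(tmp_path, "0.012 60 1\n0.004 100 1\n0.008 80 1\n", "q.dat"))
        assert np.array_equal(a.s, b.s) and np.array_equal(a.intensity, b.intensity)

    def test_headers_and_footers_skipped(self, tmp_path):
        path = _write(tmp_path, "# header\nSample X\n0.004 100 1\n0.008 80 1\nEOF\n")
        assert len(sc.read_profile(path)) == 2

    def test_two_column_default_sigma_is_sqrt_intensity(self, tmp_path):
        p = sc.read_profile(_write(tmp_path, "0.004 100\n0.008 81\n"))
        assert np.allclose(p.sigma, [10.0, 9.0])

    def test_q_convention_halves_first_column(self, tmp_path):
        p = sc.read_profile(_write(tmp_path, "0.0628318530718 100 1\n0.12 80 1\n"),
                            q_convention="q")
        assert p.s[0] == pytest.approx(0.01)

    @pytest.mark.parametrize("text", ["", "0.004 100 1\n", "-0.004 1 1\n0.008 1 1\n"])
    def test_invalid_files_rejected(self, tmp_path, text):
        with pytest.raises(ValueError):
            sc.read_profile(_write(tmp_path, text))


class TestGuinier:
    def test_exact_gaussian_data_recovered_to_machine_precision(self, gaussian_profile):
        fit = sc.guinier_fit(gaussian_profile, 0.0, 1.0)
        assert fit.i0 == pytest.approx(50.0, rel=1e-9)
        assert fit.rg == pytest.approx(50.0, rel=1e-9)

    @pytest.mark.parametrize("window", [(0.0, 1e-4), (1e-6, 5e-5), (4e-6, 2e-5)])
    def test_recovery_window_independent(self, gaussian_profile, window):
        fit = sc.guinier_fit(gaussian_profile, *window)
        assert fit.rg == pytest.approx(50.0, rel=1e-9)

    def test_constant_profile_gives_zero_rg(self):
        s = np.linspace(1e-3, 0.01, 30)
        p = sc.ScatteringProfile(s=s, intensity=np.full_like(s, 7.0),
                                 sigma=np.ones_like(s))
        fit = sc.guinier_fit(p, 0.0, 1.0)
        assert fit.rg == pytest.approx(0.0, abs=1e-9)
        assert fit.i0 == pytest.approx(7.0)

    def test_sphere_debye_rg_matches_closed_form(self, sphere_model):
        rg_true = np.sqrt(3.0 / 5.0) * 30.0
        cap = 1.3 / (2.0 * np.pi * rg_true)
        s = np.linspace(1e-4, cap, 50)
        prof = bm.debye_intensity(sphere_model, s, mode="histogram")
        fit = sc.guinier_fit(prof, 0.0, cap ** 2)
        assert fit.rg == pytest.approx(rg_true, rel=0.02)

    def test_too_few_points_rejected(self, gaussian_profile):
        with pytest.raises(ValueError, match="usable"):
            sc.guinier_fit(gaussian_profile, 0.0, 1e-9)

    def test_positive_slope_rejected(self):
        s = np.linspace(1e-3, 0.01, 30)
        p = sc.ScatteringProfile(s=s, intensity=np.exp(1e4 * s ** 2),
                                 sigma=np.ones_like(s))
        with pytest.raises(ValueError, match="no Guinier region"):
            sc.guinier_fit(p, 0.0, 1.0)


def _planted_fits(conc, mw, a2, rg0, b_if, k=1.0):
    return [
        sc.GuinierFit(
            i0=k * c / (1.0 / mw + 2.0 * a2 * c),
            rg=float(np.sqrt(rg0 ** 2 - b_if * c)),
            i0_err=0.0, rg_err=0.0, s2_range=(0, 1), n_points=10,
            r_squared=1.0, concentration=c,
        )
        for c in conc
    ]


class TestDilutionSeries:
    def test_two_point_identity_with_zero_slopes(self):
        fits = _planted_fits([1.0, 3.0], mw=250.0, a2=0.0, rg0=57.0, b_if=0.0)
        res = sc.fit_dilution_series(fits)
        assert res.mw_apparent == pytest.approx(250.0)
        assert res.rg0 == pytest.approx(57.0)

    def test_five_point_planted_parameters_recovered(self):
        fits = _planted_fits(sd.PAPER_CONCENTRATIONS, mw=250.0, a2=1e-4,
                             rg0=57.0, b_if=5.0)
        res = sc.fit_dilution_series(fits)
        assert res.mw_apparent == pytest.approx(250.0, rel=1e-8)
        assert res.a2 == pytest.approx(1e-4, rel=1e-8)
        assert res.rg0 == pytest.approx(57.0, rel=1e-8)
        assert res.b_if == pytest.approx(5.0, rel=1e-8)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_equal_sign_coefficients_stay_equal_sign(self, sign):
        fits = _planted_fits([0.5, 1.5, 2.0, 3.0, 4.0], mw=250.0,
                             a2=sign * 2e-4, rg0=57.0, b_if=sign * 4.0)
        res = sc.fit_dilution_series(fits)
        assert np.sign(res.a2) == np.sign(res.b_if) == sign

    def test_single_concentration_rejected(self):
        fits = _planted_fits([2.0, 2.0], mw=250.0, a2=0.0, rg0=57.0, b_if=0.0)
        with pytest.raises(ValueError, match="distinct"):
            sc.fit_dilution_series(fits)

    def test_negative_rg2_intercept_rejected(self):
        fits = _planted_fits([1.0, 2.0], mw=250.0, a2=0.0, rg0=3.0, b_if=4.0)
        # rg0^2 = 9, slope -4: extrapolated intercept is positive here, so
        # construct explicitly decreasing-to-negative values instead
        fits[0].rg, fits[1].rg = 1.0, 2.0  # rising rg -> negative intercept
        with pytest.raises(ValueError, match="extrapolation invalid"):
            sc.fit_dilution_series(fits)


class TestPopulations:
    def test_pure_component_identities(self):
        pr, pfr, _ = sd.make_spectra(fraction_pfr=0.5)
        w = sc.estimate_populations(pr, pr, pfr)
        assert w.w_prpr == pytest.approx(1.0, abs=1e-10)
        w = sc.estimate_populations(pfr, pr, pfr)
        assert w.w_pfrpfr == pytest.approx(1.0, abs=1e-10)

    def test_planted_mixture_recovered_exactly(self):
        pr, pfr, steady = sd.make_spectra(fraction_pfr=0.61)
        w = sc.estimate_populations(steady, pr, pfr)
        assert w.w_prpr == pytest.approx(0.39, abs=1e-10)
        assert w.w_pfrpfr == pytest.approx(0.61, abs=1e-10)

    @given(f=st.floats(0.0, 1.0), seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_weights_always_normalized_and_bounded(self, f, seed):
        pr, pfr, steady = sd.make_spectra(fraction_pfr=f, noise=0.05, seed=seed)
        w = sc.estimate_populations(steady, pr, pfr)
        assert 0.0 <= w.w_prpr <= 1.0 and 0.0 <= w.w_pfrpfr <= 1.0
        assert w.w_prpr + w.w_pfrpfr == pytest.approx(1.0, abs=1e-12)

    def test_dependent_references_rejected(self):
        pr, _, _ = sd.make_spectra()
        with pytest.raises(ValueError, match="ill-posed"):
            sc.estimate_populations(pr, pr, pr)


class TestDecompose:
    @pytest.fixture()
    def components(self):
        s = np.linspace(1e-3, 0.05, 120)
        i_pr = bm.debye_intensity(bm.generate_shape("sphere", {"radius": 30.0}, 500, 1), s)
        i_pfr = bm.debye_intensity(bm.generate_shape("sphere", {"radius": 35.0}, 500, 2), s)
        return i_pr, i_pfr

    def test_identity_weights_return_steady(self, components):
        i_pr, i_pfr = components
        out = sc.decompose_steady(i_pfr, i_pr, sc.MixtureWeights(0.0, 1.0))
        assert np.array_equal(out.intensity, i_pfr.intensity)

    def test_mix_then_decompose_is_identity(self, components):
        i_pr, i_pfr = components
        steady = sd.make_steady_mixture(i_pr, i_pfr, w_prpr=0.39)
        out = sc.decompose_steady(steady, i_pr, sc.MixtureWeights(0.39, 0.61))
        rel = np.abs(out.intensity - i_pfr.intensity) / np.abs(i_pfr.intensity).max()
        assert rel.max() < 1e-10

    def test_error_propagation_formula(self):
        s = np.array([0.01, 0.02])
        steady = sc.ScatteringProfile(s=s, intensity=[10, 10], sigma=[2.0, 2.0])
        pr = sc.ScatteringProfile(s=s, intensity=[5, 5], sigma=[1.0, 1.0])
        out = sc.decompose_steady(steady, pr, sc.MixtureWeights(0.5, 0.5))
        assert out.sigma[0] == pytest.approx(np.sqrt(4.0 + 0.25) / 0.5)

    def test_negative_intensities_kept(self):
        s = np.array([0.01, 0.02])
        steady = sc.ScatteringProfile(s=s, intensity=[1.0, 1.0], sigma=[1, 1])
        pr = sc.ScatteringProfile(s=s, intensity=[10.0, 10.0], sigma=[1, 1])
        out = sc.decompose_steady(steady, pr, sc.MixtureWeights(0.5, 0.5))
        assert np.all(out.intensity < 0)

    def test_zero_pfr_weight_rejected(self, components):
        i_pr, i_pfr = components
        with pytest.raises(ZeroDivisionError):
            sc.decompose_steady(i_pfr, i_pr, sc.MixtureWeights(1.0, 0.0))


class TestPfrSpectrum:
    def test_identity_weights(self):
        pr, pfr, steady = sd.make_spectra(fraction_pfr=0.3)
        out = sc.compute_pfr_spectrum(steady, pr, sc.MixtureWeights(0.0, 1.0))
        assert np.allclose(out.absorbance, steady.absorbance)

    def test_round_trip_recovers_planted_pfr(self):
        pr, pfr, steady = sd.make_spectra(fraction_pfr=0.61)
        out = sc.compute_pfr_spectrum(steady, pr, sc.MixtureWeights(0.39, 0.61))
        assert np.allclose(out.absorbance, pfr.absorbance, atol=1e-12)

    def test_degenerate_weights_rejected(self):
        pr, _, steady = sd.make_spectra()
        with pytest.raises(ZeroDivisionError):
            sc.compute_pfr_spectrum(steady, pr, sc.MixtureWeights(1.0, 0.0))


@given(w=st.floats(0.05, 0.95), seed=st.integers(0, 1000))
@settings(max_examples=20, deadline=None)
def test_decompose_inverts_mixing_for_any_weights(w, seed):
    """decompose(mix(Pr, Pfr, w), Pr, w) == Pfr for random positive profiles."""
    rng = np.random.default_rng(seed)
    s = np.linspace(1e-3, 0.05, 50)
    i_pr = sc.ScatteringProfile(s=s, intensity=rng.uniform(1, 100, 50),
                                sigma=np.ones(50))
    i_pfr = sc.ScatteringProfile(s=s, intensity=rng.uniform(1, 100, 50),
                                 sigma=np.ones(50))
    steady = sd.make_steady_mixture(i_pr, i_pfr, w_prpr=1.0 - w)
    out = sc.decompose_steady(steady, i_pr, sc.MixtureWeights(1.0 - w, w))
    assert np.max(np.abs(out.intensity - i_pfr.intensity)
                  / np.abs(i_pfr.intensity)) < 1e-10
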