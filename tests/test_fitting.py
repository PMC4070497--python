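"""Spectral decomposition: recovery oracles, goodness of fit, QC flagging."""

import numpy as np
import pytest

from afspect import (
    ComponentLibrary,
    FitOptions,
    SpectralComponent,
    Spectrum,
    WavelengthGrid,
    compose,
    contributions,
    fit_spectrum,
    gmg_profile,
    make_mixture,
    normalize_peak,
    qc_hemoglobin,
)
from afspect.exceptions import NotNormalizedError
from afspect.fitting import recover_shape_parameter
from afspect.simulate import apply_hb_notch

from conftest import CONTROL_WEIGHTS


class TestFitSpectrum:
    def test_requires_normalized_input(self, control_mixture, library):
        spec, _ = control_mixture
        raw = Spectrum(spec.sample_id, "", spec.grid, spec.intensities * 2.0)
        with pytest.raises(NotNormalizedError):
            fit_spectrum(raw, library)

    def test_single_component_amplitude_recovery(self, library, in_vivo_grid):
        comp = library.get("flavins").with_params(amplitude=100.0)
        spec = normalize_peak(compose(ComponentLibrary([comp]), in_vivo_grid))
        res = fit_spectrum(spec, ComponentLibrary([library.get("flavins")]))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        fitted = res.fitted_library.get("flavins")
        assert fitted.amplitude == pytest.approx(100.0, rel=1e-6)
        assert res.contributions["flavins"] == pytest.approx(100.0)

    def test_freed_center_recovers_from_offset_start(self):
        # noiseless free NAD(P)H spectrum, center freed, started 15 nm high
        center = recover_shape_parameter(
            "nadph_free", "center_nm", initial=463.0 + 15.0, bounds=(430.0, 510.0))
        assert center == pytest.approx(463.0, abs=1.0)

    def test_oracle_equivalence_amplitudes(self, fixed_shape_library, in_vivo_grid):
        """Noiseless composed spectra: amplitudes back within 1e-3 relative."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            amps = rng.uniform(5.0, 100.0, size=len(fixed_shape_library))
            lib = ComponentLibrary([
                c.with_params(amplitude=a)
                for c, a in zip(fixed_shape_library, amps)
            ])
            spec = compose(lib, in_vivo_grid)
            scale = 100.0 / np.max(spec.intensities)
            res = fit_spectrum(normalize_peak(spec), fixed_shape_library,
                               FitOptions(n_starts=1))
            got = np.array([res.fitted_library.get(c.name).amplitude
                            for c in fixed_shape_library])
            np.testing.assert_allclose(got, amps * scale, rtol=1e-3)
            assert res.r2 > 0.9999

    def test_oracle_equivalence_free_shapes(self, library, in_vivo_grid):
        """Free protein/lipopigment shapes recovered within 1 nm, noiseless."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            truth_lib = ComponentLibrary([
                c.with_params(
                    amplitude=float(rng.uniform(10.0, 80.0)),
                    **({"center_nm": float(rng.uniform(*c.bounds["center_nm"])),
                        "fwhm_nm": float(rng.uniform(*c.bounds["fwhm_nm"]))}
                       if c.center_free else {}),
                )
                for c in library
            ])
            spec = normalize_peak(compose(truth_lib, in_vivo_grid))
            res = fit_spectrum(spec, library, FitOptions(n_starts=5, seed=3))
            assert res.r2 > 0.9999
            for c in truth_lib:
                if c.center_free:
                    fitted = res.fitted_library.get(c.name)
                    assert fitted.center_nm == pytest.approx(c.center_nm, abs=1.0)
                    assert fitted.fwhm_nm == pytest.approx(c.fwhm_nm, abs=1.0)

    def test_multistart_chi2_monotone_in_n_starts(self, library, in_vivo_grid):
        spec, _ = make_mixture(CONTROL_WEIGHTS, in_vivo_grid,
                               noise_sd_additive=1.0, seed=11)
        spec = normalize_peak(spec)
        chi2s = [fit_spectrum(spec, library, FitOptions(n_starts=n, seed=5)).chi2
                 for n in (1, 3, 5)]
        assert chi2s[0] >= chi2s[1] >= chi2s[2]

    def test_chi2_per_dof_tracks_noise_variance(self, fixed_shape_library,
                                                in_vivo_grid):
        sigma = 1.0
        rng = np.random.default_rng(13)
        ratios = []
        for _ in range(50):
            spec, _ = make_mixture(CONTROL_WEIGHTS, in_vivo_grid,
                                   seed=int(rng.integers(2**31)))
            noisy = np.clip(spec.intensities
                            + rng.normal(0, sigma, spec.intensities.size), 0, None)
            noisy = noisy * (100.0 / noisy.max())
            s = Spectrum(spec.sample_id, "", in_vivo_grid, noisy)
            res = fit_spectrum(s, fixed_shape_library, FitOptions(n_starts=1))
            dof = len(in_vivo_grid) - len(fixed_shape_library)
            ratios.append(res.chi2 / dof / sigma**2)
        assert 0.5 < np.mean(ratios) < 2.0

    def test_noisy_share_recovery_at_linear_propagation_floor(
            self, fixed_shape_library, in_vivo_grid):
        """Share errors under noise track the exact-LS noise floor.

        The seven bands overlap heavily, so additive noise propagates into
        large amplitude swings for the collinear coenzyme bands; no fitter
        can beat the exact least-squares solution of the same linear model.
        The constrained fit must stay within 1.5x of that floor (it is
        usually below it, thanks to nonnegativity), and the
        well-conditioned components must come back within 2 points.
        """
        from afspect.spectral import gmg_profile

        wl = in_vivo_grid.wavelengths()
        basis = np.column_stack([
            gmg_profile(c.with_params(amplitude=1.0), in_vivo_grid)
            for c in fixed_shape_library
        ])
        areas = np.trapezoid(basis, wl, axis=0)
        names = fixed_shape_library.names()
        clean, truth = make_mixture(CONTROL_WEIGHTS, in_vivo_grid, seed=0)
        truth_vec = np.array([truth[n] for n in names])
        rng = np.random.default_rng(31)
        fit_err, oracle_err = [], []
        for _ in range(50):
            noisy = clean.intensities + rng.normal(0.0, 1.0, wl.size)
            noisy = np.clip(noisy, 0.0, None)
            spec = Spectrum("n", "", in_vivo_grid, noisy * (100.0 / noisy.max()))
            res = fit_spectrum(spec, fixed_shape_library, FitOptions(n_starts=1))
            got = np.array([res.contributions[n] for n in names])
            fit_err.append(np.abs(got - truth_vec))
            # oracle: exact unconstrained least squares on the same basis
            amps, *_ = np.linalg.lstsq(basis, spec.intensities, rcond=None)
            w = amps * areas
            oracle_err.append(np.abs(100.0 * w / w.sum() - truth_vec))
        fit_err = np.mean(fit_err, axis=0)
        oracle_err = np.mean(oracle_err, axis=0)
        assert fit_err.mean() <= 1.5 * oracle_err.mean() + 0.5
        for name in ("flavins", "proteins", "lipopigments"):
            assert fit_err[names.index(name)] < 2.0

    def test_residuals_are_data_minus_model(self, control_mixture, library):
        spec, _ = control_mixture
        spec = normalize_peak(spec)
        res = fit_spectrum(spec, library, FitOptions(n_starts=1))
        model = compose(res.fitted_library, spec.grid).intensities
        np.testing.assert_allclose(res.residuals, spec.intensities - model,
                                   atol=1e-9)
        assert res.r2 <= 1.0
        assert res.chi2 >= 0.0


class TestContributions:
    def test_sum_to_100(self, control_mixture, library):
        spec, _ = control_mixture
        res = fit_spectrum(normalize_peak(spec), library, FitOptions(n_starts=1))
        assert sum(res.contributions.values()) == pytest.approx(100.0, abs=1e-6)

    def test_equal_identical_components_split_evenly(self, in_vivo_grid):
        a = SpectralComponent("a", 500.0, 90.0, amplitude=4.0)
        b = SpectralComponent("b", 500.0, 90.0, amplitude=4.0)
        lib = ComponentLibrary([a, b])

        class _Stub:
            fitted_library = lib
            grid = in_vivo_grid

        shares = contributions(_Stub(), in_vivo_grid)
        assert shares["a"] == pytest.approx(50.0)
        assert shares["b"] == pytest.approx(50.0)

    def test_known_area_shares_recovered(self, in_vivo_grid, library):
        weights = {"nadph_free": 60.0, "flavins": 30.0, "lipopigments": 10.0}
        sub = ComponentLibrary([library.get(n) for n in weights])
        spec, truth = make_mixture(weights, in_vivo_grid, seed=0, library=sub)
        res = fit_spectrum(normalize_peak(spec), sub, FitOptions(n_starts=3, seed=1))
        for name, share in truth.items():
            assert res.contributions[name] == pytest.approx(share, abs=0.5)

    def test_zero_amplitude_component_contributes_zero(self, in_vivo_grid):
        lib = ComponentLibrary([
            SpectralComponent("on", 500.0, 90.0, amplitude=5.0),
            SpectralComponent("off", 600.0, 80.0, amplitude=0.0),
        ])

        class _Stub:
            fitted_library = lib
            grid = in_vivo_grid

        shares = contributions(_Stub(), in_vivo_grid)
        assert shares["off"] == 0.0
        assert shares["on"] == pytest.approx(100.0)

    def test_invariant_to_prenormalization_scaling(self, in_vivo_grid, library):
        spec, _ = make_mixture(CONTROL_WEIGHTS, in_vivo_grid, seed=3)
        scaled = Spectrum("s2", "", in_vivo_grid, spec.intensities * 0.37)
        r1 = fit_spectrum(normalize_peak(spec), library, FitOptions(n_starts=1))
        r2 = fit_spectrum(normalize_peak(scaled), library, FitOptions(n_starts=1))
        for name in r1.contributions:
            assert r1.contributions[name] == pytest.approx(
                r2.contributions[name], abs=1e-6)


class TestQcHemoglobin:
    def test_clean_composed_spectrum_not_flagged(self, control_mixture):
        spec, _ = control_mixture
        assert "hb_reabsorption" not in qc_hemoglobin(spec).qc_flags

    def test_deep_notch_flagged(self, control_mixture):
        spec, _ = control_mixture
        notched = apply_hb_notch(spec, depth=0.20)
        assert "hb_reabsorption" in qc_hemoglobin(notched).qc_flags

    def test_shallow_notch_below_threshold_not_flagged(self, control_mixture):
        spec, _ = control_mixture
        notched = apply_hb_notch(spec, depth=0.02)
        assert "hb_reabsorption" not in qc_hemoglobin(notched).qc_flags

    def test_grid_without_window_marked_not_applicable(self):
        grid = WavelengthGrid(400.0, 500.0, 1.0)
        spec = Spectrum("s", "", grid, np.ones(len(grid)))
        flagged = qc_hemoglobin(spec)
        assert "qc_not_applicable" in flagged.qc_flags
        assert "hb_reabsorption" not in flagged.qc_flags

    def test_detection_robust_to_noise(self, in_vivo_grid):
        flags = []
        false_flags = []
        for seed in range(25):
            notched, _ = make_mixture(CONTROL_WEIGHTS, in_vivo_grid,
                                      noise_sd_additive=1.0, notch_depth=0.20,
                                      seed=seed)
            clean, _ = make_mixture(CONTROL_WEIGHTS, in_vivo_grid,
                                    noise_sd_additive=1.0, seed=1000 + seed)
            flags.append("hb_reabsorption" in qc_hemoglobin(notched).qc_flags)
            false_flags.append("hb_reabsorption" in qc_hemoglobin(clean).qc_flags)
        assert all(flags)
        assert not any(false_flags)
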