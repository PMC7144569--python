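"""Spectral decomposition: recovery, determinism, diagnostics, oracle."""

import numpy as np
import pytest

from serumaf.fitting import FitResult, fit_spectrum, goodness_report, pool_reference
from serumaf.library import get_components
from serumaf.lineshape import gmg_value, solve_band
from serumaf.spectra import ANALYSIS_WINDOW, normalize

from conftest import build_spectrum


def window_area(comp, amplitude, x):
    band = solve_band(comp.shape, amplitude)
    return float(np.trapezoid(gmg_value(band, x), x))


@pytest.fixture(scope="module")
def noiseless_fit(library_366):
    """Fit of a spectrum built exactly from the library bands."""
    truth_amps = {"retinol": 40.0, "arachidonic_acid": 25.0,
                  "linoleic_acid": 28.0, "oleic_acid": 15.0,
                  "proteins": 3.0, "undefined_440": 9.0}
    amps = [truth_amps[c.name] for c in library_366]
    spectrum = normalize(build_spectrum(library_366, amps))
    fit = fit_spectrum(spectrum, library_366, seed=1)
    return spectrum, fit, truth_amps


class TestRecovery:
    def test_noiseless_self_consistency_within_1pct(self, noiseless_fit, library_366):
        spectrum, fit, truth_amps = noiseless_fit
        lo, hi = fit.window
        mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
        x = spectrum.wavelengths[mask]
        scale = 100.0 / np.max(build_spectrum(
            library_366, [truth_amps[c.name] for c in library_366]).intensities)
        for comp in library_366:
            expected = window_area(comp, truth_amps[comp.name] * scale, x)
            assert fit.component_areas[comp.name] == pytest.approx(
                expected, rel=0.01), comp.name

    def test_single_band_truth_leaves_others_near_zero(self, library_366):
        retinol = [c for c in library_366 if c.name == "retinol"]
        spectrum = normalize(build_spectrum(retinol, [50.0]))
        fit = fit_spectrum(spectrum, library_366, seed=2)
        total = sum(a for a in fit.component_areas.values() if a > 0)
        for name, area in fit.component_areas.items():
            if name != "retinol":
                assert abs(area) < 0.02 * total, name

    def test_noisy_fit_r_squared_above_threshold(self, library_366):
        rng = np.random.default_rng(11)
        amps = [40.0, 25.0, 28.0, 15.0, 3.0, 9.0]
        noisy = build_spectrum(library_366, amps, noise_sd=0.5, rng=rng)
        fit = fit_spectrum(normalize(noisy), library_366, seed=3)
        assert fit.converged
        assert fit.r_squared >= 0.95


class TestFitContract:
    def test_determinism_bit_identical(self, library_366):
        rng = np.random.default_rng(5)
        spec = normalize(build_spectrum(
            library_366, [40, 25, 28, 15, 3, 9], noise_sd=0.3, rng=rng))
        a = fit_spectrum(spec, library_366, seed=7)
        b = fit_spectrum(spec, library_366, seed=7)
        assert a.params == b.params
        assert a.sse == b.sse
        assert np.array_equal(a.residuals, b.residuals)

    def test_parameters_respect_bounds(self, library_366):
        rng = np.random.default_rng(9)
        spec = normalize(build_spectrum(
            library_366, [40, 25, 28, 15, 3, 9], noise_sd=0.5, rng=rng))
        fit = fit_spectrum(spec, library_366, seed=1)
        for comp in library_366:
            p = fit.params[comp.name]
            lo, hi = comp.bounds.peak_lambda
            assert lo <= p.peak_lambda <= hi
            lo, hi = comp.bounds.fwhm
            assert lo <= p.fwhm <= hi
            lo, hi = comp.bounds.asymmetry_rho
            assert lo <= p.rho <= hi
            lo, hi = comp.bounds.amplitude
            assert lo <= p.amplitude <= hi

    def test_component_areas_sum_to_model_area(self, noiseless_fit):
        spectrum, fit, _ = noiseless_fit
        lo, hi = fit.window
        mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
        x = spectrum.wavelengths[mask]
        model_area = float(np.trapezoid(fit.model(x), x))
        assert sum(fit.component_areas.values()) == pytest.approx(
            model_area, rel=1e-6)

    def test_noise_never_improves_fit_on_average(self, library_366):
        amps = [40.0, 25.0, 28.0, 15.0, 3.0, 9.0]
        clean = normalize(build_spectrum(library_366, amps))
        r2_clean = fit_spectrum(clean, library_366, seed=1, n_restarts=1).r_squared
        diffs = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            noisy = normalize(build_spectrum(
                library_366, amps, noise_sd=0.5, rng=rng))
            r2_noisy = fit_spectrum(noisy, library_366, seed=1,
                                    n_restarts=1).r_squared
            diffs.append(r2_clean - r2_noisy)
        assert np.mean(diffs) > 0

    def test_under_determined_window_rejected(self, library_310):
        spec = normalize(build_spectrum(library_310[:4], [40, 25, 5, 8],
                                        excitation=310))
        with pytest.raises(ValueError, match="under-determined"):
            fit_spectrum(spec, library_310, window=(390.0, 410.0))

    def test_comparative_requires_matching_reference(self, library_366):
        spec = normalize(build_spectrum(library_366, [40, 25, 28, 15, 3, 9]))
        with pytest.raises(ValueError):
            fit_spectrum(spec, library_366, stage="comparative")
        ref = fit_spectrum(spec, library_366, seed=1, n_restarts=1)
        ref.excitation = 310
        with pytest.raises(ValueError, match="excitation"):
            fit_spectrum(spec, library_366, stage="comparative", reference_fit=ref)


class TestGridSearchOracle:
    def test_three_band_fit_matches_grid_search(self, library_366):
        """Amplitudes from the nonlinear fit agree with an independent
        coarse-grid + local-polish search on a noiseless 3-band problem."""
        comps = [c for c in library_366
                 if c.name in ("retinol", "arachidonic_acid", "undefined_440")]
        truth = [45.0, 20.0, 8.0]
        spectrum = normalize(build_spectrum(comps, truth))
        lo, hi = ANALYSIS_WINDOW
        mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
        x, y = spectrum.wavelengths[mask], spectrum.intensities[mask]

        def profiles(shifts):
            cols = []
            for comp, dp in zip(comps, shifts):
                shape = comp.shape
                band = solve_band(
                    type(shape)(shape.peak_lambda + dp, shape.fwhm,
                                shape.asymmetry_rho), 1.0)
                cols.append(gmg_value(band, x))
            return np.array(cols).T

        def amplitudes_for(shifts):
            F = profiles(shifts)
            a, *_ = np.linalg.lstsq(F, y, rcond=None)
            resid = y - F @ a
            return a, float(resid @ resid)

        # coarse grid over peak shifts, amplitudes solved linearly
        best_sse, best_shift = np.inf, None
        grid = np.linspace(-4.0, 4.0, 9)
        for s0 in grid:
            for s1 in grid:
                for s2 in grid:
                    _, sse = amplitudes_for((s0, s1, s2))
                    if sse < best_sse:
                        best_sse, best_shift = sse, (s0, s1, s2)
        from scipy.optimize import minimize
        polish = minimize(lambda s: amplitudes_for(s)[1], best_shift,
                          method="Nelder-Mead",
                          options={"xatol": 1e-6, "fatol": 1e-12})
        oracle_amps, _ = amplitudes_for(polish.x)

        fit = fit_spectrum(spectrum, comps, seed=4)
        for comp, a_oracle in zip(comps, oracle_amps):
            assert fit.params[comp.name].amplitude == pytest.approx(
                a_oracle, rel=0.005), comp.name


class TestGoodnessReport:
    def _result(self, residuals, r2):
        return FitResult(
            sample_id="s", group="other", excitation=366, stage="reference",
            params={}, residuals=np.asarray(residuals, dtype=float),
            sse=float(np.sum(np.square(residuals))), r_squared=r2,
            component_areas={}, converged=True, n_iterations=1,
            window=ANALYSIS_WINDOW, seed=0,
        )

    def test_perfect_fit_passes(self):
        rep = goodness_report(self._result(np.zeros(50), 1.0))
        assert rep["r_squared"] == 1.0
        assert rep["passed"]

    def test_mean_model_fails(self):
        y = np.sin(np.linspace(0, 6, 50))
        rep = goodness_report(self._result(y - y.mean(), 0.0))
        assert not rep["passed"]

    def test_noisy_synthetic_fit_passes(self, library_366):
        rng = np.random.default_rng(21)
        spec = normalize(build_spectrum(
            library_366, [40, 25, 28, 15, 3, 9], noise_sd=0.5, rng=rng))
        fit = fit_spectrum(spec, library_366, seed=1, n_restarts=1)
        assert goodness_report(fit)["passed"]


def test_pool_reference_takes_medians(library_366):
    fits = []
    for seed in (1, 2, 3):
        rng = np.random.default_rng(seed)
        spec = normalize(build_spectrum(
            library_366, [40, 25, 28, 15, 3, 9], noise_sd=0.4, rng=rng))
        fits.append(fit_spectrum(spec, library_366, seed=seed, n_restarts=1))
    pooled = pool_reference(fits)
    for name in fits[0].params:
        peaks = sorted(f.params[name].peak_lambda for f in fits)
        assert pooled.params[name].peak_lambda == peaks[1]  # median of 3
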