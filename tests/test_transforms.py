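"""Derivative, smoothing, ratio transforms and their algebraic properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import duospec as ds
from duospec.spectrum import SpectrumError
from duospec.transforms import DerivativeParams, RatioParams


GRID = ds.default_grid()


def gaussian(center=250.0, sigma=7.0, height=1.0, grid=GRID):
    return ds.Spectrum(
        grid, height * np.exp(-((grid - center) ** 2) / (2 * sigma**2))
    )


class TestFirstDerivative:
    def test_constant_has_zero_derivative(self):
        s = ds.Spectrum(GRID, np.full(GRID.size, 0.37))
        d = ds.first_derivative(s, DerivativeParams())
        np.testing.assert_allclose(d.absorbances, 0.0, atol=1e-14)

    def test_linear_ramp_gives_scaled_constant(self):
        m = 0.023
        s = ds.Spectrum(GRID, m * (GRID - 200.0))
        d = ds.first_derivative(s, DerivativeParams(4.0, 10.0))
        np.testing.assert_allclose(d.absorbances, 10.0 * m, rtol=1e-10)

    def test_matches_analytic_gap_difference(self):
        s = gaussian()
        d = ds.first_derivative(s, DerivativeParams(4.0, 10.0))

        def analytic(w):
            g = lambda x: np.exp(-((x - 250.0) ** 2) / (2 * 49.0))
            return 10.0 * (g(w + 2.0) - g(w - 2.0)) / 4.0

        np.testing.assert_allclose(
            d.absorbances, analytic(d.wavelengths), atol=1e-10
        )

    def test_zero_crossing_at_band_center(self):
        s = gaussian(center=250.0)
        d = ds.first_derivative(s, DerivativeParams())
        sign_flip = np.nonzero(np.diff(np.sign(d.absorbances)))[0]
        roots = d.wavelengths[sign_flip]
        assert np.min(np.abs(roots - 250.0)) <= 0.05 + 1e-9

    def test_interior_trimming(self):
        s = gaussian()
        d = ds.first_derivative(s, DerivativeParams(4.0, 10.0))
        assert d.wl_min == pytest.approx(202.0)
        assert d.wl_max == pytest.approx(298.0)

    def test_window_wider_than_grid_rejected(self):
        s = ds.Spectrum(np.arange(200.0, 201.0, 0.1), np.zeros(10))
        with pytest.raises(SpectrumError):
            ds.first_derivative(s, DerivativeParams(4.0, 10.0))

    def test_misaligned_window_rejected(self):
        s = gaussian()
        with pytest.raises(ValueError, match="multiple"):
            ds.first_derivative(s, DerivativeParams(0.3, 10.0))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_exact_linearity(self, a, b, seed):
        """D(a*S1 + b*S2) = a*D(S1) + b*D(S2) to 1e-12."""
        rng = np.random.default_rng(seed)
        grid = 200.0 + 0.1 * np.arange(201)
        y1 = rng.normal(0, 1, grid.size)
        y2 = rng.normal(0, 1, grid.size)
        params = DerivativeParams(2.0, 10.0)
        combo = ds.first_derivative(
            ds.Spectrum(grid, a * y1 + b * y2), params
        )
        parts = a * ds.first_derivative(
            ds.Spectrum(grid, y1), params
        ).absorbances + b * ds.first_derivative(
            ds.Spectrum(grid, y2), params
        ).absorbances
        np.testing.assert_allclose(combo.absorbances, parts, atol=1e-12)

    def test_second_order_convergence_to_analytic_derivative(self):
        """Halving the differencing window shrinks the max error ~4x."""
        grid = 200.0 + 0.05 * np.arange(2001)
        s = gaussian(grid=grid)
        analytic = (
            -(s.wavelengths - 250.0)
            / 49.0
            * np.exp(-((s.wavelengths - 250.0) ** 2) / (2 * 49.0))
        )
        errs = {}
        for dl in (2.0, 1.0):
            d = ds.first_derivative(s, DerivativeParams(dl, 1.0))
            idx = np.searchsorted(grid, d.wavelengths[0])
            ref = analytic[idx : idx + d.n]
            errs[dl] = np.max(np.abs(d.absorbances - ref))
        ratio = errs[2.0] / errs[1.0]
        assert 3.4 < ratio < 4.6


class TestSmooth:
    def test_constant_unchanged(self):
        s = ds.Spectrum(GRID, np.full(GRID.size, 1.7))
        out = ds.smooth(s, 4.0)
        np.testing.assert_allclose(out.absorbances, 1.7, rtol=1e-12)

    def test_linear_ramp_unchanged_on_interior(self):
        s = ds.Spectrum(GRID, 0.01 * (GRID - 200.0))
        out = ds.smooth(s, 4.0)
        np.testing.assert_allclose(
            out.absorbances[20:-20], s.absorbances[20:-20], rtol=1e-10
        )

    def test_white_noise_sd_reduced_by_sqrt_window(self, rng):
        s = ds.Spectrum(GRID, rng.normal(0, 1, GRID.size))
        out = ds.smooth(s, 4.0)  # 41 points at 0.1 nm
        ratio = np.std(out.absorbances[50:-50]) / np.std(s.absorbances[50:-50])
        assert ratio == pytest.approx(1 / np.sqrt(41), rel=0.25)

    def test_window_must_cover_step(self):
        s = gaussian()
        with pytest.raises(SpectrumError):
            ds.smooth(s, 0.01)


class TestRatioSpectrum:
    def setup_method(self):
        self.vgn, self.rge = ds.default_models()

    def divisor(self, model, conc=5.0):
        d = ds.simulate_mixture(ds.MixtureSpec([(model, conc)]))
        return d

    def test_self_division_gives_unity(self):
        d = self.divisor(self.rge)
        out = ds.ratio_spectrum(
            d, RatioParams(divisor=d, smooth_window=None)
        )
        np.testing.assert_allclose(
            out.absorbances[out.valid], 1.0, rtol=1e-12
        )

    def test_pure_divisor_analyte_gives_constant_delta(self):
        """A pure spectrum of the divisor analyte at k*C' divides to k."""
        d = self.divisor(self.rge, 5.0)
        mix = ds.simulate_mixture(ds.MixtureSpec([(self.rge, 35.0)]))
        out = ds.ratio_spectrum(mix, RatioParams(divisor=d, smooth_window=None))
        np.testing.assert_allclose(
            out.absorbances[out.valid], 7.0, rtol=1e-10
        )

    def test_mixture_ratio_equals_delta_plus_pure_term(self):
        """mix / divisor = C_V/C_V' + A_co(l)/A_div(l), pointwise."""
        d = self.divisor(self.vgn, 5.0)
        mix = ds.simulate_mixture(
            ds.MixtureSpec([(self.vgn, 30.0), (self.rge, 40.0)])
        )
        out = ds.ratio_spectrum(mix, RatioParams(divisor=d, smooth_window=None))
        pure_rge = ds.simulate_mixture(ds.MixtureSpec([(self.rge, 40.0)]))
        expected = 30.0 / 5.0 + pure_rge.absorbances / d.absorbances
        ok = out.valid
        np.testing.assert_allclose(
            out.absorbances[ok], expected[ok], atol=1e-10
        )

    def test_division_guard_masks_low_divisor(self):
        d = self.divisor(self.vgn, 5.0)  # silent above ~236 nm
        mix = ds.simulate_mixture(ds.MixtureSpec([(self.rge, 40.0)]))
        out = ds.ratio_spectrum(mix, RatioParams(divisor=d, smooth_window=None))
        assert not out.valid[-1]  # long-wavelength tail masked
        assert out.valid[np.searchsorted(GRID, 220.0)]
        assert np.all(np.isnan(out.absorbances[~out.valid]))

    def test_fully_masked_divisor_rejected(self):
        flat = ds.Spectrum(GRID, np.full(GRID.size, 1e-6), concentration=5.0)
        mix = ds.simulate_mixture(ds.MixtureSpec([(self.rge, 40.0)]))
        with pytest.raises(SpectrumError, match="guard"):
            ds.ratio_spectrum(mix, RatioParams(divisor=flat))

    def test_grid_mismatch_rejected(self):
        d = self.divisor(self.vgn, 5.0)
        mix = ds.simulate_mixture(ds.MixtureSpec([(self.rge, 40.0)])).resample(0.2)
        with pytest.raises(SpectrumError, match="grid"):
            ds.ratio_spectrum(mix, RatioParams(divisor=d))

    @pytest.mark.parametrize("co_conc", [0.0, 10.0, 45.0])
    def test_amplitude_difference_invariant_to_divisor_analyte(self, co_conc):
        """The additive constant cancels between any two wavelengths, so the
        difference responds only to the non-divisor analyte."""
        d = self.divisor(self.vgn, 5.0)
        mix = ds.simulate_mixture(
            ds.MixtureSpec([(self.vgn, co_conc), (self.rge, 40.0)])
        )
        out = ds.ratio_spectrum(mix, RatioParams(divisor=d, smooth_window=None))
        delta_p = out.amplitude_at(210.0) - out.amplitude_at(228.0)
        ref_mix = ds.simulate_mixture(ds.MixtureSpec([(self.rge, 40.0)]))
        ref = ds.ratio_spectrum(ref_mix, RatioParams(divisor=d, smooth_window=None))
        ref_delta = ref.amplitude_at(210.0) - ref.amplitude_at(228.0)
        assert delta_p == pytest.approx(ref_delta, abs=1e-10)

    @pytest.mark.parametrize("co_conc", [0.0, 10.0, 45.0])
    def test_ratio_derivative_invariant_to_divisor_analyte(self, co_conc):
        """Differentiation kills the additive constant at every wavelength."""
        d = self.divisor(self.vgn, 5.0)
        mix = ds.simulate_mixture(
            ds.MixtureSpec([(self.vgn, co_conc), (self.rge, 40.0)])
        )
        out = ds.first_derivative(
            ds.ratio_spectrum(mix, RatioParams(divisor=d, smooth_window=None)),
            DerivativeParams(),
        )
        ref_mix = ds.simulate_mixture(ds.MixtureSpec([(self.rge, 40.0)]))
        ref = ds.first_derivative(
            ds.ratio_spectrum(ref_mix, RatioParams(divisor=d, smooth_window=None)),
            DerivativeParams(),
        )
        ok = out.valid & ref.valid
        np.testing.assert_allclose(
            out.absorbances[ok], ref.absorbances[ok], atol=1e-10
        )


class TestFindExtrema:
    def test_single_gaussian_one_maximum(self):
        s = gaussian(center=251.23)
        ext = ds.find_extrema(s)
        maxima = [e for e in ext if e[2] == "maximum"]
        assert len(maxima) == 1
        assert maxima[0][0] == pytest.approx(251.23, abs=0.1 + 1e-9)

    def test_monotone_ramp_has_none(self):
        s = ds.Spectrum(GRID, 0.01 * (GRID - 200.0))
        assert ds.find_extrema(s) == []

    def test_gaussian_derivative_extrema_at_center_pm_sigma(self):
        sigma = 7.0
        s = gaussian(center=250.0, sigma=sigma)
        d = ds.first_derivative(s, DerivativeParams(2.0, 1.0))
        ext = ds.find_extrema(d)
        kinds = {e[2]: e[0] for e in ext}
        assert kinds["maximum"] == pytest.approx(250.0 - sigma, abs=0.3)
        assert kinds["minimum"] == pytest.approx(250.0 + sigma, abs=0.3)

    def test_plateau_resolved_to_midpoint(self):
        y = np.zeros(21)
        y[8:13] = 1.0  # flat-topped peak centred at index 10
        s = ds.Spectrum(200.0 + 0.1 * np.arange(21), y)
        ext = ds.find_extrema(s)
        maxima = [e for e in ext if e[2] == "maximum"]
        assert len(maxima) == 1
        assert maxima[0][0] == pytest.approx(201.0, abs=1e-9)


class TestFindZeroCrossings:
    def test_monotone_family_has_no_crossings(self):
        spectra = [
            ds.Spectrum(GRID, c * (GRID - 200.0)) for c in (0.5, 1.0, 2.0)
        ]
        series = ds.CalibrationSeries(spectra, [0.5, 1.0, 2.0])
        assert ds.find_zero_crossings(series, DerivativeParams()) == []

    def test_scaled_family_shares_base_crossings(self):
        vgn, _ = ds.default_models()
        series = ds.simulate_calibration_series(vgn, [2.0, 20.0, 60.0])
        crossings = ds.find_zero_crossings(series, DerivativeParams())
        single = ds.simulate_calibration_series(vgn, [1.0, 3.0, 9.0])
        again = ds.find_zero_crossings(single, DerivativeParams())
        assert len(crossings) == len(again)
        np.testing.assert_allclose(crossings, again, atol=1e-6)

    def test_crossings_match_analytic_gap_roots(self):
        """Compare against brentq roots of the analytic gap difference of the
        band-model absorptivity curve (an independent continuous oracle)."""
        _, rge = ds.default_models()
        series = ds.simulate_calibration_series(rge, [5.0, 45.0, 90.0])
        found = ds.find_zero_crossings(series, DerivativeParams(4.0, 10.0))
        assert found  # the dominant-band maximum root must be present

        def gap(w):
            return (
                rge.epsilon(np.array([w + 2.0]))[0]
                - rge.epsilon(np.array([w - 2.0]))[0]
            )

        for root in found:
            analytic = brentq(gap, root - 0.5, root + 0.5)
            assert abs(root - analytic) < 0.1
        assert any(abs(r - 226.0) < 0.1 for r in found)
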