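"""Method specs, amplitude measurement, calibration models, selection."""

import numpy as np
import pytest

import duospec as ds
from duospec.methods import (
    MethodCalibration,
    MethodCalibrationResults,
    MethodSpec,
    SelectionError,
    measure,
    select_wavelengths,
)
from duospec.spectrum import SpectrumError
from duospec.transforms import DerivativeParams, RatioParams


@pytest.fixture(scope="module")
def models():
    return ds.default_models()


def mixture(vgn, rge, cv, cr, noise=0.0, seed=0):
    return ds.simulate_mixture(
        ds.MixtureSpec([(vgn, cv), (rge, cr)], noise_sd=noise, seed=seed)
    )


class TestMethodSpec:
    def test_fds_requires_derivative_only(self):
        with pytest.raises(ValueError):
            MethodSpec("FDS", "VGN", (213.7,))  # no derivative params
        spec = MethodSpec(
            "FDS", "VGN", (213.7,), derivative=DerivativeParams()
        )
        assert spec.working_wavelengths == (213.7,)

    def test_rad_requires_two_distinct_wavelengths(self, models):
        vgn, _ = models
        divisor = ds.simulate_mixture(ds.MixtureSpec([(vgn, 5.0)]))
        rp = RatioParams(divisor=divisor)
        with pytest.raises(ValueError, match="distinct"):
            MethodSpec("RAD", "RGE", (230.3, 230.3), ratio=rp)
        with pytest.raises(ValueError):
            MethodSpec("RAD", "RGE", (230.3,), ratio=rp)

    def test_rfd_requires_both_parameter_sets(self, models):
        vgn, _ = models
        divisor = ds.simulate_mixture(ds.MixtureSpec([(vgn, 5.0)]))
        with pytest.raises(ValueError):
            MethodSpec("RFD", "RGE", (237.2,), ratio=RatioParams(divisor=divisor))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            MethodSpec("PLS", "VGN", (210.0,))


class TestMeasure:
    def test_fds_null_at_co_analyte_crossing(self, models, method_specs):
        """A pure co-analyte spectrum reads ~zero at its own zero-crossing."""
        vgn, rge = models
        spec = method_specs[("VGN", "FDS")]  # reads at an RGE crossing
        pure_rge = ds.simulate_mixture(ds.MixtureSpec([(rge, 60.0)]))
        reading = measure(spec, pure_rge)
        deriv = ds.first_derivative(pure_rge, spec.derivative)
        tol = 1e-3 * np.nanmax(np.abs(deriv.absorbances))
        assert abs(reading.value) < tol

    def test_rad_delta_cancellation(self, models, method_specs):
        """RAD reading of a mixture equals the reading of the pure analyte:
        the divisor-analyte term is the same constant at both wavelengths."""
        vgn, rge = models
        spec = method_specs[("RGE", "RAD")]
        mix_reading = measure(spec, mixture(vgn, rge, 35.0, 40.0)).value
        pure_reading = measure(spec, mixture(vgn, rge, 0.0, 40.0)).value
        assert mix_reading == pytest.approx(pure_reading, abs=1e-10)

    def test_rejects_non_absorption_input(self, models, method_specs):
        vgn, rge = models
        d = ds.first_derivative(
            mixture(vgn, rge, 10.0, 10.0), DerivativeParams()
        )
        with pytest.raises(SpectrumError):
            measure(method_specs[("VGN", "FDS")], d)


class TestCalibrationModel:
    def test_noiseless_series_r2_is_one(self, calibrations):
        for cal in calibrations.values():
            assert cal.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_offset_shifts_intercept_only(self):
        x = np.array([5.0, 15.0, 30.0, 45.0])
        y = 2.0 * x
        base = ds.fit_ols(x, y)
        shifted = ds.fit_ols(x, y + 0.25)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-12)
        assert shifted.intercept == pytest.approx(
            base.intercept + 0.25, abs=1e-12
        )

    def test_quantify_inverts_midpoint(self, calibrations):
        cal = calibrations[("VGN", "FDS")]
        lo, hi = cal.concentration_range
        mid = 0.5 * (lo + hi)
        amplitude = cal.line.predict(mid)
        assert cal.line.invert(float(amplitude)) == pytest.approx(mid, rel=1e-12)

    def test_noiseless_end_to_end_quantification(self, models, calibrations):
        vgn, rge = models
        mix = mixture(vgn, rge, 23.0, 47.0)
        for (analyte, _method), cal in calibrations.items():
            nominal = 23.0 if analyte == "VGN" else 47.0
            q = cal.quantify(mix)
            assert abs(q.concentration - nominal) / nominal < 1e-6

    def test_blank_quantifies_to_zero_with_flag(self, models, calibrations):
        vgn, rge = models
        blank = mixture(vgn, rge, 0.0, 0.0)
        for cal in calibrations.values():
            q = cal.quantify(blank)
            assert abs(q.concentration) < 1e-8
            assert q.below_range

    def test_too_few_distinct_concentrations_rejected(self, models, method_specs):
        vgn, _ = models
        series = ds.simulate_calibration_series(vgn, [5.0, 10.0])
        with pytest.raises(Exception):
            MethodCalibration(series, method_specs[("VGN", "FDS")])

    def test_json_round_trip_quantifies_identically(
        self, models, calibrations, tmp_path
    ):
        vgn, rge = models
        mix = mixture(vgn, rge, 12.0, 33.0)
        for key in [("VGN", "FDS"), ("RGE", "RAD"), ("VGN", "RFD")]:
            cal = calibrations[key]
            path = tmp_path / f"{key[0]}_{key[1]}.json"
            cal.to_json(path)
            back = MethodCalibrationResults.from_json(path)
            assert back.quantify(mix).concentration == pytest.approx(
                cal.quantify(mix).concentration, rel=1e-12
            )

    def test_summary_contains_key_statistics(self, calibrations):
        text = calibrations[("RGE", "FDS")].summary()
        assert "slope" in text and "r^2" in text and "LOD" in text


class TestSelectWavelengths:
    def test_fds_finds_constructed_root(self):
        """Analyte B has exactly one band, hence one derivative root, inside
        analyte A's absorbing region; FDS selection must return it."""
        a = ds.BandModel([ds.Band(220.0, 12.0, 20000.0)], 300.0, label="A")
        b = ds.BandModel([ds.Band(240.0, 6.0, 25000.0)], 400.0, label="B")
        series_a = ds.simulate_calibration_series(a, [5.0, 20.0, 40.0])
        series_b = ds.simulate_calibration_series(b, [5.0, 20.0, 40.0])
        spec_a, _spec_b = select_wavelengths("FDS", series_a, series_b)
        assert spec_a.working_wavelengths[0] == pytest.approx(240.0, abs=0.1)

    def test_fds_fails_for_identical_band_shapes(self):
        """Perfectly collinear spectra leave no crossing where the other
        analyte absorbs; selection must raise, not guess."""
        shape = [ds.Band(230.0, 10.0, 20000.0)]
        a = ds.BandModel(shape, 300.0, label="A")
        b = ds.BandModel(shape, 400.0, label="B")
        series_a = ds.simulate_calibration_series(a, [5.0, 20.0, 40.0])
        series_b = ds.simulate_calibration_series(b, [5.0, 20.0, 40.0])
        # the shared band centre is a crossing for both, but there the own
        # analyte's derivative is also null -> quantification impossible
        with pytest.raises(SelectionError):
            select_wavelengths("FDS", series_a, series_b)

    def test_default_system_selection_is_deterministic(self, system):
        one = select_wavelengths("RAD", system.series_a, system.series_b)
        two = select_wavelengths("RAD", system.series_a, system.series_b)
        assert one[0].working_wavelengths == two[0].working_wavelengths
        assert one[1].working_wavelengths == two[1].working_wavelengths

    def test_rad_pair_is_ordered_and_distinct(self, method_specs):
        for analyte in ("VGN", "RGE"):
            pair = method_specs[(analyte, "RAD")].working_wavelengths
            assert len(pair) == 2 and pair[0] < pair[1]


class TestSpecificityInvariants:
    def test_fds_cross_talk_below_0p1_percent(self, models, calibrations):
        """Sweeping the co-analyte across its full range moves the quantified
        value by <0.1% relative (zero-crossing nulling)."""
        vgn, rge = models
        cal_v = calibrations[("VGN", "FDS")]
        results = [
            cal_v.quantify(mixture(vgn, rge, 30.0, cr)).concentration
            for cr in (0.0, 5.0, 45.0, 90.0)
        ]
        assert (max(results) - min(results)) / 30.0 < 1e-3
        cal_r = calibrations[("RGE", "FDS")]
        results = [
            cal_r.quantify(mixture(vgn, rge, cv, 45.0)).concentration
            for cv in (0.0, 2.0, 30.0, 60.0)
        ]
        assert (max(results) - min(results)) / 45.0 < 1e-3

    @pytest.mark.parametrize("method", ["RAD", "RFD"])
    def test_ratio_methods_exactly_invariant_to_divisor_analyte(
        self, models, calibrations, method
    ):
        vgn, rge = models
        cal = calibrations[("RGE", method)]
        base = cal.quantify(mixture(vgn, rge, 0.0, 40.0)).concentration
        for cv in (10.0, 35.0, 60.0):
            q = cal.quantify(mixture(vgn, rge, cv, 40.0)).concentration
            assert q == pytest.approx(base, abs=1e-10)

    def test_method_concordance_on_noiseless_mixture(self, models, calibrations):
        vgn, rge = models
        mix = mixture(vgn, rge, 18.0, 52.0)
        for analyte, nominal in (("VGN", 18.0), ("RGE", 52.0)):
            values = [
                calibrations[(analyte, m)].quantify(mix).concentration
                for m in ("FDS", "RAD", "RFD")
            ]
            assert (max(values) - min(values)) / nominal < 1e-6
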