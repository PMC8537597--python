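"""The three quantification methods as one calibrate/quantify abstraction.

* **FDS** (zero-crossing first-derivative spectrophotometry): read the
  first-derivative amplitude of the raw absorption spectrum at a wavelength
  where the co-analyte's derivative is null at every concentration.
* **RAD** (ratio amplitude difference): divide the spectrum by a fixed
  single-analyte divisor spectrum, smooth, and read the signed amplitude
  difference between two wavelengths; the divisor analyte contributes the
  same additive constant at both, so the difference responds only to the
  other analyte.
* **RFD** (ratio first derivative): differentiate the ratio spectrum; the
  additive constant vanishes under differentiation and a single extremum
  amplitude is read.

The modelling surface follows the fit/results idiom: a
:class:`MethodCalibration` is built from a calibration series plus a
:class:`MethodSpec`; its :meth:`~MethodCalibration.fit` returns a
:class:`MethodCalibrationResults` carrying the line, its uncertainties and
``quantify()`` / ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .calibration import CalibrationError, LineFit, fit_ols
from .spectrum import (
    CalibrationSeries,
    MaskedRegionError,
    Spectrum,
    SpectrumError,
    read_series,
)
from .transforms import (
    DEFAULT_MIN_DIVISOR_ABS,
    DerivativeParams,
    RatioParams,
    find_extrema,
    find_zero_crossings,
    first_derivative,
    ratio_spectrum,
)

METHODS = ("FDS", "RAD", "RFD")

#: relative tolerance within which two candidate sensitivities count as a
#: tie during wavelength selection (ties break toward shorter wavelengths)
SELECTION_TIE_RTOL = 0.01


class SelectionError(ValueError):
    """No usable working wavelength could be selected."""


@dataclass
class MethodSpec:
    """A fully specified quantification method for one analyte.

    ``working_wavelengths`` holds one wavelength (FDS, RFD) or an ordered
    pair (RAD).  FDS needs derivative parameters only; RAD ratio parameters
    only; RFD both.
    """

    method: str
    analyte: str
    working_wavelengths: tuple[float, ...]
    derivative: DerivativeParams | None = None
    ratio: RatioParams | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        self.working_wavelengths = tuple(
            float(w) for w in self.working_wavelengths
        )
        n = len(self.working_wavelengths)
        if self.method == "FDS":
            if self.derivative is None or self.ratio is not None or n != 1:
                raise ValueError(
                    "FDS needs derivative params, no ratio params and one "
                    "working wavelength"
                )
        elif self.method == "RAD":
            if self.ratio is None or self.derivative is not None or n != 2:
                raise ValueError(
                    "RAD needs ratio params, no derivative params and two "
                    "working wavelengths"
                )
            if self.working_wavelengths[0] == self.working_wavelengths[1]:
                raise ValueError("RAD wavelengths must be distinct")
        else:  # RFD
            if self.ratio is None or self.derivative is None or n != 1:
                raise ValueError(
                    "RFD needs both ratio and derivative params and one "
                    "working wavelength"
                )

    def transform(self, spectrum: Spectrum) -> Spectrum:
        """Apply this method's signal transform to an absorption spectrum."""
        if self.method == "FDS":
            return first_derivative(spectrum, self.derivative)
        ratio = ratio_spectrum(spectrum, self.ratio)
        if self.method == "RAD":
            return ratio
        return first_derivative(ratio, self.derivative)


@dataclass(frozen=True)
class AmplitudeReading:
    """A signed amplitude (or amplitude difference) measured by one method."""

    value: float
    wavelengths: tuple[float, ...]
    method: MethodSpec


def measure(spec: MethodSpec, spectrum: Spectrum) -> AmplitudeReading:
    """Measure the method's signed amplitude reading on one spectrum.

    The spectrum must be an absorption spectrum on a grid covering the
    working wavelengths; the reading is taken from the transformed spectrum
    (amplitude difference ``P(l1) - P(l2)`` for RAD).
    """
    if spectrum.kind != "absorption":
        raise SpectrumError(
            f"measure() expects an absorption spectrum, got {spectrum.kind!r}"
        )
    t = spec.transform(spectrum)
    wls = spec.working_wavelengths
    if spec.method == "RAD":
        value = t.amplitude_at(wls[0]) - t.amplitude_at(wls[1])
    else:
        value = t.amplitude_at(wls[0])
    if not np.isfinite(value):
        raise MaskedRegionError(
            f"non-finite reading at {wls} nm for method {spec.method}"
        )
    return AmplitudeReading(value=float(value), wavelengths=wls, method=spec)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantResult:
    """A quantified concentration plus range diagnostics.

    The inverse prediction is never clamped: values can be slightly negative
    near zero; ``below_range`` / ``above_range`` flag readings outside the
    calibration span.
    """

    concentration: float
    reading: float
    below_range: bool
    above_range: bool

    def __float__(self) -> float:
        return self.concentration


class MethodCalibration:
    """Calibration model: a method spec applied to a calibration series.

    Parameters
    ----------
    series : CalibrationSeries
        Single-analyte spectra at known concentrations (>= 3 distinct).
    method_spec : MethodSpec
        The quantification method and its working wavelength(s).
    """

    def __init__(self, series: CalibrationSeries, method_spec: MethodSpec):
        if np.unique(series.concentrations).size < 3:
            raise CalibrationError(
                "calibration needs at least 3 distinct concentrations"
            )
        self.series = series
        self.method_spec = method_spec

    @classmethod
    def from_manifest(
        cls, manifest_path: str | Path, method_spec: MethodSpec
    ) -> "MethodCalibration":
        series = read_series(manifest_path, analyte=method_spec.analyte)
        return cls(series, method_spec)

    def readings(self) -> np.ndarray:
        return np.array(
            [measure(self.method_spec, s).value for s in self.series.spectra]
        )

    def fit(self) -> "MethodCalibrationResults":
        """OLS of amplitude readings on concentration."""
        y = self.readings()
        line = fit_ols(self.series.concentrations, y)
        return MethodCalibrationResults(
            method_spec=self.method_spec,
            line=line,
            concentration_range=self.series.concentration_range,
            concentrations=np.array(self.series.concentrations),
            amplitudes=y,
        )


@dataclass
class MethodCalibrationResults:
    """Fitted calibration line for one (analyte, method) pair."""

    method_spec: MethodSpec
    line: LineFit
    concentration_range: tuple[float, float]
    concentrations: np.ndarray | None = None
    amplitudes: np.ndarray | None = None

    # convenience accessors mirroring the line fit
    @property
    def slope(self) -> float:
        return self.line.slope

    @property
    def intercept(self) -> float:
        return self.line.intercept

    @property
    def rsquared(self) -> float:
        return self.line.r_squared

    @property
    def sd_slope(self) -> float:
        return self.line.sd_slope

    @property
    def sd_intercept(self) -> float:
        return self.line.sd_intercept

    @property
    def sd_residual(self) -> float:
        return self.line.sd_residual

    @property
    def nobs(self) -> int:
        return self.line.n_points

    def quantify(self, spectrum: Spectrum) -> QuantResult:
        """Invert the calibration line for one absorption spectrum."""
        reading = measure(self.method_spec, spectrum).value
        conc = self.line.invert(reading)
        lo, hi = self.concentration_range
        return QuantResult(
            concentration=float(conc),
            reading=float(reading),
            below_range=conc < lo,
            above_range=conc > hi,
        )

    def lod_loq(self) -> tuple[float, float]:
        """Detection/quantification limits from the intercept SD and slope."""
        from .validation import lod_loq

        return lod_loq(self.line.sd_intercept, self.line.slope)

    def summary(self) -> str:
        wls = "/".join(f"{w:.1f}" for w in self.method_spec.working_wavelengths)
        lod, loq = self.lod_loq()
        lo, hi = self.concentration_range
        rows = [
            f"Method calibration: {self.method_spec.method} "
            f"({self.method_spec.analyte})",
            "-" * 52,
            f"{'working wavelength(s) (nm)':34s}{wls:>18s}",
            f"{'linearity range (ug/mL)':34s}{f'{lo:g}-{hi:g}':>18s}",
            f"{'n':34s}{self.nobs:>18d}",
            f"{'slope (AU per ug/mL)':34s}{self.slope:>18.6g}",
            f"{'intercept (AU)':34s}{self.intercept:>18.6g}",
            f"{'r^2':34s}{self.rsquared:>18.6f}",
            f"{'SD slope':34s}{self.sd_slope:>18.3g}",
            f"{'SD intercept':34s}{self.sd_intercept:>18.3g}",
            f"{'SD residual':34s}{self.sd_residual:>18.3g}",
            f"{'LOD (ug/mL)':34s}{lod:>18.3f}",
            f"{'LOQ (ug/mL)':34s}{loq:>18.3f}",
        ]
        return "\n".join(rows)

    # -- serialization (model JSON for the CLI) ---------------------------

    def to_dict(self) -> dict:
        spec = self.method_spec
        d: dict = {
            "method": spec.method,
            "analyte": spec.analyte,
            "working_wavelengths": list(spec.working_wavelengths),
            "concentration_range": list(self.concentration_range),
            "line": {
                "slope": self.line.slope,
                "intercept": self.line.intercept,
                "r_squared": self.line.r_squared,
                "sd_slope": self.line.sd_slope,
                "sd_intercept": self.line.sd_intercept,
                "sd_residual": self.line.sd_residual,
                "n_points": self.line.n_points,
            },
        }
        if spec.derivative is not None:
            d["derivative"] = {
                "delta_lambda": spec.derivative.delta_lambda,
                "scaling_factor": spec.derivative.scaling_factor,
            }
        if spec.ratio is not None:
            div = spec.ratio.divisor
            d["ratio"] = {
                "min_divisor_abs": spec.ratio.min_divisor_abs,
                "smooth_window": spec.ratio.smooth_window,
                "divisor": {
                    "label": div.label,
                    "concentration": div.concentration,
                    "wavelengths": div.wavelengths.tolist(),
                    "absorbances": div.absorbances.tolist(),
                },
            }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "MethodCalibrationResults":
        derivative = None
        if "derivative" in d:
            derivative = DerivativeParams(
                delta_lambda=d["derivative"]["delta_lambda"],
                scaling_factor=d["derivative"]["scaling_factor"],
            )
        ratio = None
        if "ratio" in d:
            rd = d["ratio"]["divisor"]
            divisor = Spectrum(
                wavelengths=np.array(rd["wavelengths"]),
                absorbances=np.array(rd["absorbances"]),
                label=rd.get("label", ""),
                concentration=rd["concentration"],
            )
            ratio = RatioParams(
                divisor=divisor,
                min_divisor_abs=d["ratio"]["min_divisor_abs"],
                smooth_window=d["ratio"]["smooth_window"],
            )
        spec = MethodSpec(
            method=d["method"],
            analyte=d["analyte"],
            working_wavelengths=tuple(d["working_wavelengths"]),
            derivative=derivative,
            ratio=ratio,
        )
        ld = d["line"]
        line = LineFit(
            slope=ld["slope"],
            intercept=ld["intercept"],
            r_squared=ld["r_squared"],
            sd_slope=ld["sd_slope"],
            sd_intercept=ld["sd_intercept"],
            sd_residual=ld["sd_residual"],
            n_points=ld["n_points"],
        )
        return cls(
            method_spec=spec,
            line=line,
            concentration_range=tuple(d["concentration_range"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MethodCalibrationResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Working-wavelength selection
# ---------------------------------------------------------------------------


def _scaled_divisor(
    series: CalibrationSeries, concentration: float
) -> Spectrum:
    """A divisor spectrum at ``concentration`` scaled from a series member.

    Valid for noiseless series (Beer-Lambert homogeneity); the member whose
    concentration is closest to the target is scaled linearly.
    """
    idx = int(np.argmin(np.abs(series.concentrations - concentration)))
    base = series.spectra[idx]
    factor = concentration / float(series.concentrations[idx])
    return replace(
        base.scaled(factor),
        concentration=float(concentration),
        label=f"{series.analyte or 'divisor'} {concentration:g} ug/mL",
    )


def _unit_response(series: CalibrationSeries, transform) -> Spectrum:
    """Per-unit-concentration transformed spectrum of a series' top member."""
    top = series.top
    t = transform(top)
    return replace(t, absorbances=t.absorbances / top.concentration)


def _pick_shortest(cands: list[tuple[float, ...]], scores: np.ndarray):
    """Best-scoring candidate; near-ties resolve to shorter wavelengths."""
    best = float(np.max(scores))
    tied = [
        c
        for c, s in zip(cands, scores)
        if s >= best * (1.0 - SELECTION_TIE_RTOL)
    ]
    return min(tied)


def select_wavelengths(
    method: str,
    series_a: CalibrationSeries,
    series_b: CalibrationSeries,
    derivative: DerivativeParams | None = None,
    divisor_concentration: float = 5.0,
    min_divisor_abs: float = DEFAULT_MIN_DIVISOR_ABS,
    smooth_window: float | None = 4.0,
    amp_tolerance: float | None = None,
) -> tuple[MethodSpec, MethodSpec]:
    """Recommend working wavelengths for both analytes of a binary system.

    ``series_a`` and ``series_b`` are single-analyte calibration series on a
    common grid (noiseless synthetic or averaged laboratory scans).  Returns
    one :class:`MethodSpec` per analyte, in the order (A, B).

    Selection rules (deterministic; near-ties break toward shorter
    wavelengths):

    * FDS: for each analyte, the co-analyte's zero-crossing with the
      largest own first-derivative amplitude per unit concentration.
    * RAD: the pair of unmasked wavelengths maximizing the per-unit ratio
      amplitude difference - in practice the ratio spectrum's peak and its
      null/valley plateau, entered at the shortest wavelength within 1% of
      the extreme response.
    * RFD: the interior extremum of the ratio first derivative with the
      largest per-unit amplitude (global extremes serve as fallback when no
      interior extremum exists).
    """
    if method not in METHODS:
        raise SelectionError(f"unknown method {method!r}")
    derivative = derivative or DerivativeParams()

    def fds_spec(own: CalibrationSeries, co: CalibrationSeries) -> MethodSpec:
        roots = find_zero_crossings(co, derivative, amp_tolerance)
        if not roots:
            raise SelectionError(
                f"no qualifying zero-crossing of {co.analyte or 'co-analyte'} "
                "for FDS selection"
            )
        unit = _unit_response(own, lambda s: first_derivative(s, derivative))
        usable: list[tuple[float, ...]] = []
        scores: list[float] = []
        for r in roots:
            try:
                amp = abs(unit.amplitude_at(r))
            except SpectrumError:
                continue
            usable.append((r,))
            scores.append(amp)
        if not usable:
            raise SelectionError("all zero-crossing candidates unusable")
        floor = 1e-3 * float(np.nanmax(np.abs(unit.absorbances)))
        if max(scores) <= floor:
            raise SelectionError(
                f"no co-analyte zero-crossing carries usable "
                f"{own.analyte or 'analyte'} sensitivity (perfectly "
                "collinear spectra?)"
            )
        (wl,) = _pick_shortest(usable, np.asarray(scores))
        return MethodSpec(
            method="FDS",
            analyte=own.analyte,
            working_wavelengths=(wl,),
            derivative=derivative,
        )

    def ratio_params_for(co: CalibrationSeries) -> RatioParams:
        return RatioParams(
            divisor=_scaled_divisor(co, divisor_concentration),
            min_divisor_abs=min_divisor_abs,
            smooth_window=smooth_window,
        )

    def rad_spec(own: CalibrationSeries, co: CalibrationSeries) -> MethodSpec:
        rp = ratio_params_for(co)
        unit = _unit_response(own, lambda s: ratio_spectrum(s, rp))
        u = unit.absorbances
        ok = unit.valid & np.isfinite(u)
        if ok.sum() < 2:
            raise SelectionError("all candidate wavelengths masked")
        w = unit.wavelengths
        umax = float(np.max(u[ok]))
        umin = float(np.min(u[ok]))
        if umax == umin:
            raise SelectionError(
                "ratio spectrum is constant; no usable wavelength pair"
            )
        rng = umax - umin
        hi_mask = ok & (u >= umax - SELECTION_TIE_RTOL * rng)
        lo_mask = ok & (u <= umin + SELECTION_TIE_RTOL * rng)
        wl_hi = float(w[np.argmax(hi_mask)])
        wl_lo = float(w[np.argmax(lo_mask)])
        pair = tuple(sorted((wl_hi, wl_lo)))
        return MethodSpec(
            method="RAD",
            analyte=own.analyte,
            working_wavelengths=pair,
            ratio=rp,
        )

    def rfd_spec(own: CalibrationSeries, co: CalibrationSeries) -> MethodSpec:
        rp = ratio_params_for(co)
        unit = _unit_response(
            own,
            lambda s: first_derivative(ratio_spectrum(s, rp), derivative),
        )
        cands = [
            (wl,) for wl, _val, _kind in find_extrema(unit)
        ]
        if not cands:
            ok = unit.valid & np.isfinite(unit.absorbances)
            if not ok.any():
                raise SelectionError("all candidate wavelengths masked")
            w = unit.wavelengths[ok]
            y = unit.absorbances[ok]
            cands = [
                (float(w[int(np.argmax(y))]),),
                (float(w[int(np.argmin(y))]),),
            ]
        scores = np.array(
            [abs(unit.amplitude_at(c[0])) for c in cands]
        )
        (wl,) = _pick_shortest(cands, scores)
        return MethodSpec(
            method="RFD",
            analyte=own.analyte,
            working_wavelengths=(wl,),
            derivative=derivative,
            ratio=rp,
        )

    builders = {"FDS": fds_spec, "RAD": rad_spec, "RFD": rfd_spec}
    build = builders[method]
    return build(series_a, series_b), build(series_b, series_a)
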