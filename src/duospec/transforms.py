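"""Derivative, smoothing and ratio-spectrum transforms.

All three quantification methods are built from three exactly linear
operators on sampled spectra:

* a gap-segment first derivative
  ``D(l) = scale * [A(l + dl/2) - A(l - dl/2)] / dl``
  evaluated on the interior of the grid (endpoints where the window exits
  the grid are dropped, never zero-padded);
* a centred moving-average smoother whose window shrinks symmetrically at
  the grid ends;
* pointwise division by a fixed single-analyte divisor spectrum, guarded
  against near-zero divisor amplitudes.

The gap derivative is the default derivative operator: it is what common
instrument software implements for a user-chosen "delta lambda", it is
exactly linear (so Beer-Lambert additivity survives the transform), and its
error against the analytic derivative of a smooth band is O(dl^2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectrum import GRID_ATOL, CalibrationSeries, Spectrum, SpectrumError

#: default division guard: ratio points where |divisor| falls below this
#: absorbance (AU) are masked rather than amplified without bound.
DEFAULT_MIN_DIVISOR_ABS = 1e-3

_DERIV_KIND = {
    "absorption": "first_derivative",
    "ratio": "ratio_first_derivative",
}


@dataclass(frozen=True)
class DerivativeParams:
    """Gap-derivative settings: differencing window (nm) and display scale.

    ``delta_lambda`` must be an even multiple of the grid step so that the
    half-window offsets land on grid points.  The scaling factor is a pure
    display multiplier (the instrument convention); it cancels in every
    calibration statistic.
    """

    delta_lambda: float = 4.0
    scaling_factor: float = 10.0
    order: int = 1

    def __post_init__(self) -> None:
        if self.delta_lambda <= 0:
            raise ValueError("delta_lambda must be > 0")
        if self.scaling_factor <= 0:
            raise ValueError("scaling_factor must be > 0")
        if self.order != 1:
            raise ValueError("only first-order derivatives are supported")

    def half_offset_points(self, step: float) -> int:
        k = self.delta_lambda / (2.0 * step)
        k_int = int(round(k))
        if k_int < 1 or abs(k - k_int) > 1e-6:
            raise ValueError(
                f"delta_lambda {self.delta_lambda} nm must be an even "
                f"multiple of the grid step {step} nm"
            )
        return k_int


@dataclass
class RatioParams:
    """Ratio-spectrum settings: divisor spectrum, guard threshold, smoothing.

    The divisor must carry its concentration (the C' of the ratio-spectra
    algebra).  ``smooth_window`` (nm) smooths *after* division, matching the
    laboratory procedure of smoothing stored ratio spectra; ``None`` skips
    smoothing.
    """

    divisor: Spectrum
    min_divisor_abs: float = DEFAULT_MIN_DIVISOR_ABS
    smooth_window: float | None = 4.0

    def __post_init__(self) -> None:
        if self.divisor.concentration is None or self.divisor.concentration <= 0:
            raise ValueError("divisor spectrum must carry a concentration > 0")
        if self.min_divisor_abs <= 0:
            raise ValueError("min_divisor_abs must be > 0")


def first_derivative(spectrum: Spectrum, params: DerivativeParams) -> Spectrum:
    """Gap-segment central-difference first derivative of a spectrum.

    The output grid is the interior where the full +-dl/2 window fits; its
    kind becomes ``first_derivative`` (or ``ratio_first_derivative`` when
    differentiating a ratio spectrum).  The operator is exactly linear in
    the input amplitudes.
    """
    step = spectrum.step
    span = spectrum.wl_max - spectrum.wl_min
    if span <= 2.0 * params.delta_lambda:
        raise SpectrumError(
            f"grid span {span:.3g} nm too narrow for "
            f"delta_lambda {params.delta_lambda} nm"
        )
    k = params.half_offset_points(step)
    a = spectrum.absorbances
    v = spectrum.valid
    d = (
        params.scaling_factor
        * (a[2 * k :] - a[: -2 * k])
        / params.delta_lambda
    )
    valid = v[2 * k :] & v[: -2 * k] & np.isfinite(d)
    d = np.where(valid, d, np.nan)
    return Spectrum(
        wavelengths=spectrum.wavelengths[k:-k],
        absorbances=d,
        label=spectrum.label,
        concentration=spectrum.concentration,
        pathlength=spectrum.pathlength,
        kind=_DERIV_KIND.get(spectrum.kind, "first_derivative"),
        valid=valid,
    )


def smooth(spectrum: Spectrum, window: float) -> Spectrum:
    """Centred moving average over the odd point count spanning ``window`` nm.

    At the grid ends the window shrinks symmetrically, so the output keeps
    the full grid.  Exactly linear; a symmetric window leaves linear ramps
    unchanged on the full-window interior.
    """
    step = spectrum.step
    if window < step:
        raise SpectrumError("smoothing window must be at least the grid step")
    if window > spectrum.wl_max - spectrum.wl_min:
        raise SpectrumError("smoothing window exceeds the grid span")
    hw = int(round(window / (2.0 * step)))
    n = spectrum.n
    a = np.where(spectrum.valid, spectrum.absorbances, np.nan)
    out = np.empty(n)
    for i in range(n):
        r = min(hw, i, n - 1 - i)
        out[i] = np.mean(a[i - r : i + r + 1])  # nan poisons -> masked
    valid = np.isfinite(out)
    out = np.where(valid, out, np.nan)
    return replace(spectrum, absorbances=out, valid=valid)


def ratio_spectrum(mixture: Spectrum, params: RatioParams) -> Spectrum:
    """Pointwise quotient of a mixture spectrum by the divisor spectrum.

    Wavelengths where ``|divisor| < min_divisor_abs`` are masked (flagged in
    the ``valid`` mask and set to NaN) rather than divided; optional
    smoothing is applied after division.  The result kind is ``ratio``.
    """
    if not mixture.same_grid(params.divisor):
        raise SpectrumError("mixture and divisor are on different grids")
    d = params.divisor.absorbances
    ok = (
        mixture.valid
        & params.divisor.valid
        & (np.abs(d) >= params.min_divisor_abs)
    )
    if not ok.any():
        raise SpectrumError("divisor entirely below the guard threshold")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = mixture.absorbances / d
    q = np.where(ok, q, np.nan)
    out = Spectrum(
        wavelengths=mixture.wavelengths,
        absorbances=q,
        label=mixture.label,
        concentration=mixture.concentration,
        pathlength=mixture.pathlength,
        kind="ratio",
        valid=ok,
    )
    if params.smooth_window is not None:
        out = smooth(out, params.smooth_window)
    return out


# ---------------------------------------------------------------------------
# Feature finding
# ---------------------------------------------------------------------------


def _segment_bounds(valid: np.ndarray):
    """Yield (start, stop) index bounds of contiguous valid runs."""
    n = valid.size
    i = 0
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def _sign_change_roots(
    w: np.ndarray, y: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Roots of a sampled curve located by linear interpolation.

    A root is reported wherever the curve changes sign between adjacent
    valid points; exact zeros flanked by opposite signs count once.
    """
    roots: list[float] = []
    for lo, hi in _segment_bounds(valid):
        ys = y[lo:hi]
        ws = w[lo:hi]
        for i in range(len(ys) - 1):
            a, b = ys[i], ys[i + 1]
            if a == 0.0:
                if i > 0 and ys[i - 1] * b < 0:
                    roots.append(float(ws[i]))
                continue
            if a * b < 0:
                roots.append(float(ws[i] - a * (ws[i + 1] - ws[i]) / (b - a)))
    return np.array(sorted(roots))


def find_extrema(spectrum: Spectrum) -> list[tuple[float, float, str]]:
    """Interior local extrema of a sampled spectrum.

    Detected by sign change of the first difference; plateau ties resolve to
    the plateau midpoint.  Returns ``(wavelength, value, "maximum"|"minimum")``
    tuples in wavelength order; may be empty (e.g. a monotone ramp).
    """
    w = spectrum.wavelengths
    y = spectrum.absorbances
    out: list[tuple[float, float, str]] = []
    for lo, hi in _segment_bounds(spectrum.valid):
        if hi - lo < 3:
            continue
        ys = y[lo:hi]
        ws = w[lo:hi]
        d = np.diff(ys)
        s = np.sign(d)
        nz = np.nonzero(s)[0]
        for a, b in zip(nz[:-1], nz[1:]):
            if s[a] == s[b]:
                continue
            wl = 0.5 * (ws[a + 1] + ws[b])  # midpoint of any flat plateau
            val = float(ys[a + 1])
            out.append(
                (float(wl), val, "maximum" if s[a] > 0 else "minimum")
            )
    return sorted(out)


def find_zero_crossings(
    series: CalibrationSeries,
    params: DerivativeParams,
    amp_tolerance: float | None = None,
) -> list[float]:
    """Zero-crossing wavelengths shared by a whole calibration series.

    For every concentration the first-derivative amplitude must cross sign
    between adjacent grid points (root located by linear interpolation), the
    per-member roots must agree within one grid step, and the derivative
    amplitude at the consensus root must stay below ``amp_tolerance`` for
    every member (default: 1e-3 times the series' maximum derivative
    amplitude).  These wavelengths are where the series analyte is
    spectrally silent, hence usable to quantify the *other* analyte.
    """
    if len(series) == 0:
        raise SpectrumError("empty series")
    derivs = [first_derivative(s, params) for s in series.spectra]
    step = derivs[0].step
    if amp_tolerance is None:
        peak = max(float(np.nanmax(np.abs(d.absorbances))) for d in derivs)
        amp_tolerance = 1e-3 * peak
    ref = derivs[int(np.argmax(series.concentrations))]
    ref_roots = _sign_change_roots(ref.wavelengths, ref.absorbances, ref.valid)
    member_roots = [
        _sign_change_roots(d.wavelengths, d.absorbances, d.valid)
        for d in derivs
    ]
    crossings: list[float] = []
    for r in ref_roots:
        matched: list[float] = []
        for roots in member_roots:
            if roots.size == 0:
                matched = []
                break
            j = int(np.argmin(np.abs(roots - r)))
            if abs(roots[j] - r) > step + GRID_ATOL:
                matched = []
                break
            matched.append(float(roots[j]))
        if not matched:
            continue
        consensus = float(np.mean(matched))
        try:
            amps = [abs(d.amplitude_at(consensus)) for d in derivs]
        except SpectrumError:
            continue
        if max(amps) <= amp_tolerance:
            crossings.append(consensus)
    return crossings
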