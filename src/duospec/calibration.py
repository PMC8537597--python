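"""Least-squares calibration lines and Beer-Lambert unit conversions.

Simple unweighted linear regression of signed amplitude readings on
concentration, with the standard OLS uncertainty statistics (residual
variance on n-2 degrees of freedom); r^2 is the squared Pearson correlation,
identical to the regression R^2 in the simple-regression case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class CalibrationError(ValueError):
    """Degenerate calibration input (too few points, constant x, ...)."""


@dataclass(frozen=True)
class LineFit:
    """A fitted calibration line and its uncertainty statistics.

    ``slope`` is in AU per ug/mL, ``intercept`` in AU; ``sd_slope`` /
    ``sd_intercept`` are the OLS standard errors and ``sd_residual`` the
    root mean squared residual on n-2 degrees of freedom.
    """

    slope: float
    intercept: float
    r_squared: float
    sd_slope: float
    sd_intercept: float
    sd_residual: float
    n_points: int

    def predict(self, concentration):
        return self.slope * np.asarray(concentration) + self.intercept

    def invert(self, amplitude: float) -> float:
        """Concentration whose predicted amplitude equals ``amplitude``."""
        if abs(self.slope) < 1e-12:
            raise CalibrationError("slope too small to invert calibration")
        return (amplitude - self.intercept) / self.slope


def fit_ols(x, y) -> LineFit:
    """Ordinary least squares of amplitude ``y`` on concentration ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise CalibrationError("x and y differ in length")
    if x.size < 3:
        raise CalibrationError("at least 3 calibration points required")
    if np.all(x == x[0]):
        raise CalibrationError("concentrations are constant")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = x.size - 2
    sd_residual = float(np.sqrt(np.sum(resid**2) / dof))
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        sd_slope=float(res.stderr),
        sd_intercept=float(res.intercept_stderr),
        sd_residual=sd_residual,
        n_points=int(x.size),
    )


def molar_absorptivity(
    absorbance: float,
    concentration: float,
    molar_mass: float,
    pathlength: float = 1.0,
) -> float:
    """Molar absorptivity (L mol^-1 cm^-1) from a Beer-Lambert reading.

    ``epsilon = A / (molarity * pathlength)`` with
    ``molarity = concentration[ug/mL] * 1e-3 / molar_mass``.
    """
    if min(absorbance, concentration, molar_mass, pathlength) <= 0:
        raise CalibrationError(
            "absorbance, concentration, molar mass and pathlength "
            "must all be > 0"
        )
    molarity = concentration * 1e-3 / molar_mass
    return absorbance / (molarity * pathlength)
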