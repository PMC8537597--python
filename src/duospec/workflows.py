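"""End-to-end workflows: simulate -> select -> calibrate -> validate.

These drivers wire the synthetic generator, the wavelength selector, the
calibration models and the validation studies into the standard study
design used throughout the package:

* seven-point single-analyte calibration series (2-60 ug/mL for the
  VGN-like analyte, 5-90 ug/mL for the RGE-like analyte);
* working wavelengths discovered from noiseless series by
  :func:`~duospec.methods.select_wavelengths`;
* accuracy/precision levels at low/mid/high points of each span;
* the five-mixture specificity grid and the 2:1 formulation-style
  standard-addition design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .methods import (
    MethodCalibration,
    MethodCalibrationResults,
    MethodSpec,
    METHODS,
    select_wavelengths,
)
from .spectrum import CalibrationSeries
from .synthetic import (
    BandModel,
    DEFAULT_NOISE_SD,
    default_grid,
    default_models,
    simulate_calibration_series,
)
from .transforms import DerivativeParams
from .validation import (
    DEFAULT_SPECIFICITY_MIXTURES,
    ValidationReport,
    accuracy_study,
    lod_loq,
    precision_simulation,
    specificity_study,
    standard_addition_study,
)

#: seven-point calibration concentrations per analyte (ug/mL)
DEFAULT_CALIBRATION_CONCENTRATIONS = {
    "VGN": (2.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    "RGE": (5.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0),
}

#: low/mid/high accuracy & precision levels per analyte (ug/mL)
DEFAULT_STUDY_LEVELS = {
    "VGN": (15.0, 30.0, 50.0),
    "RGE": (25.0, 55.0, 85.0),
}

#: formulation-style base solution (2:1 RGE:VGN, diluted into range)
DEFAULT_STANDARD_ADDITION_BASE = {"VGN": 20.0, "RGE": 40.0}

#: spike grid for standard addition (per-analyte added amounts, ug/mL)
DEFAULT_STANDARD_ADDITION_SPIKES = (
    {"VGN": 5.0, "RGE": 10.0},
    {"VGN": 10.0, "RGE": 20.0},
    {"VGN": 15.0, "RGE": 30.0},
)

DEFAULT_STUDY_SEEDS = {
    "accuracy": 7,
    "precision": 11,
    "specificity": 13,
    "standard_addition": 17,
}


@dataclass
class SyntheticSystem:
    """A ready-to-use binary system: models, noiseless series, grid."""

    model_a: BandModel
    model_b: BandModel
    series_a: CalibrationSeries
    series_b: CalibrationSeries
    grid: np.ndarray

    @property
    def models(self) -> tuple[BandModel, BandModel]:
        return self.model_a, self.model_b


def build_system(
    concentrations: dict | None = None, grid: np.ndarray | None = None
) -> SyntheticSystem:
    """Default models plus noiseless calibration series on one grid."""
    model_a, model_b = default_models()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    concs = concentrations or DEFAULT_CALIBRATION_CONCENTRATIONS
    series_a = simulate_calibration_series(
        model_a, concs[model_a.label], noise_sd=0.0, grid=grid
    )
    series_b = simulate_calibration_series(
        model_b, concs[model_b.label], noise_sd=0.0, grid=grid
    )
    return SyntheticSystem(model_a, model_b, series_a, series_b, grid)


def select_all(
    system: SyntheticSystem,
    derivative: DerivativeParams | None = None,
    divisor_concentration: float = 5.0,
    smooth_window: float | None = 4.0,
) -> dict[tuple[str, str], MethodSpec]:
    """Working wavelengths for all six (analyte, method) combinations."""
    specs: dict[tuple[str, str], MethodSpec] = {}
    for method in METHODS:
        spec_a, spec_b = select_wavelengths(
            method,
            system.series_a,
            system.series_b,
            derivative=derivative,
            divisor_concentration=divisor_concentration,
            smooth_window=smooth_window,
        )
        specs[(spec_a.analyte, method)] = spec_a
        specs[(spec_b.analyte, method)] = spec_b
    return specs


def calibrate_all(
    system: SyntheticSystem,
    specs: dict[tuple[str, str], MethodSpec],
    calibration_noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[tuple[str, str], MethodCalibrationResults]:
    """Fit all six calibration models.

    With ``calibration_noise_sd`` zero (the default) the noiseless system
    series are reused; otherwise fresh noisy series are simulated.
    """
    results: dict[tuple[str, str], MethodCalibrationResults] = {}
    series_map = {
        system.model_a.label: (system.model_a, system.series_a),
        system.model_b.label: (system.model_b, system.series_b),
    }
    for (analyte, method), spec in specs.items():
        model, series = series_map[analyte]
        if calibration_noise_sd > 0:
            series = simulate_calibration_series(
                model,
                series.concentrations,
                noise_sd=calibration_noise_sd,
                seed=seed,
                grid=system.grid,
            )
        results[(analyte, method)] = MethodCalibration(series, spec).fit()
    return results


def run_validation(
    noise_sd: float = DEFAULT_NOISE_SD,
    seeds: dict | None = None,
    levels: dict | None = None,
    calibration_noise_sd: float = 0.0,
    n_replicates: int = 3,
    n_days: int = 3,
) -> ValidationReport:
    """Run the full synthetic validation suite and return the report."""
    seeds = {**DEFAULT_STUDY_SEEDS, **(seeds or {})}
    levels = levels or DEFAULT_STUDY_LEVELS
    system = build_system()
    specs = select_all(system)
    calibrations = calibrate_all(
        system, specs, calibration_noise_sd=calibration_noise_sd
    )
    linearity = {}
    for key, cal in calibrations.items():
        lod, loq = lod_loq(cal.sd_intercept, cal.slope)
        linearity[key] = {
            "slope": cal.slope,
            "intercept": cal.intercept,
            "r_squared": cal.rsquared,
            "sd_slope": cal.sd_slope,
            "sd_intercept": cal.sd_intercept,
            "lod": lod,
            "loq": loq,
            "working_wavelengths": list(
                cal.method_spec.working_wavelengths
            ),
        }
    accuracy_rows = accuracy_study(
        calibrations,
        system.models,
        levels,
        noise_sd=noise_sd,
        seed=seeds["accuracy"],
        n_replicates=n_replicates,
        grid=system.grid,
    )
    precision_rows = precision_simulation(
        calibrations,
        system.models,
        levels,
        noise_sd=noise_sd,
        seed=seeds["precision"],
        n_replicates=n_replicates,
        n_days=n_days,
        grid=system.grid,
    )
    specificity = specificity_study(
        calibrations,
        system.models,
        mixtures=DEFAULT_SPECIFICITY_MIXTURES,
        noise_sd=noise_sd,
        seed=seeds["specificity"],
        grid=system.grid,
    )
    standard_addition = standard_addition_study(
        calibrations,
        system.models,
        base=DEFAULT_STANDARD_ADDITION_BASE,
        additions=DEFAULT_STANDARD_ADDITION_SPIKES,
        noise_sd=noise_sd,
        seed=seeds["standard_addition"],
        grid=system.grid,
    )
    return ValidationReport(
        linearity=linearity,
        accuracy_rows=accuracy_rows,
        precision_rows=precision_rows,
        specificity=specificity,
        standard_addition=standard_addition,
        noise_sd=noise_sd,
        seeds=seeds,
    )
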