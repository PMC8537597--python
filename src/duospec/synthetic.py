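"""Synthetic analyte band models and Beer-Lambert mixture simulation.

The two shipped default models emulate the vildagliptin (VGN) /
remogliflozin etabonate (RGE) system: VGN absorbs essentially only below
~230 nm (dominant band near 209 nm), RGE across the whole 200-300 nm scan
(dominant band near 226 nm with short- and long-wavelength structure).
Band shapes are Gaussian in wavelength, which keeps every downstream
transform analytically checkable; mixtures are additive under Beer-Lambert
with optional homoscedastic Gaussian absorbance noise.

The defaults reproduce the *qualitative* structure of the real system
(complete spectral overlap over 200-230 nm, usable zero-crossings and
ratio-spectrum peaks/valleys, molar absorptivities of the right magnitude),
not the true spectra point-for-point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectrum import CalibrationSeries, Spectrum, SpectrumError

#: default scan grid: 200-300 nm at 0.1 nm (1001 points), matching a
#: double-beam instrument scanning with a 0.1 nm slit.
DEFAULT_GRID_START = 200.0
DEFAULT_GRID_STOP = 300.0
DEFAULT_GRID_STEP = 0.1

#: default absorbance noise (AU) for validation-style simulations
DEFAULT_NOISE_SD = 0.002


def default_grid(
    start: float = DEFAULT_GRID_START,
    stop: float = DEFAULT_GRID_STOP,
    step: float = DEFAULT_GRID_STEP,
) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    ``epsilon_peak`` is the peak molar absorptivity (L mol^-1 cm^-1),
    ``center`` and ``width_sigma`` are in nm.
    """

    center: float
    width_sigma: float
    epsilon_peak: float

    def __post_init__(self) -> None:
        if self.width_sigma <= 0:
            raise ValueError("band width must be > 0")
        if self.epsilon_peak <= 0:
            raise ValueError("band peak absorptivity must be > 0")


@dataclass
class BandModel:
    """A synthetic analyte: a sum of Gaussian bands plus a molar mass."""

    bands: list[Band]
    molar_mass: float
    label: str = ""

    def __post_init__(self) -> None:
        self.bands = [b if isinstance(b, Band) else Band(*b) for b in self.bands]
        if not self.bands:
            raise ValueError("a band model needs at least one band")
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be > 0")

    def epsilon(self, wavelengths: np.ndarray) -> np.ndarray:
        """Molar absorptivity curve: sum of Gaussian bands (non-negative)."""
        w = np.asarray(wavelengths, dtype=float)
        eps = np.zeros_like(w)
        for b in self.bands:
            eps += b.epsilon_peak * np.exp(
                -((w - b.center) ** 2) / (2.0 * b.width_sigma**2)
            )
        return eps

    def absorbance(
        self,
        wavelengths: np.ndarray,
        concentration: float,
        pathlength: float = 1.0,
    ) -> np.ndarray:
        """Noiseless Beer-Lambert absorbance at ``concentration`` ug/mL."""
        molarity = concentration * 1e-3 / self.molar_mass  # g/L -> mol/L
        return self.epsilon(wavelengths) * molarity * pathlength

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "molar_mass": self.molar_mass,
            "bands": [
                [b.center, b.width_sigma, b.epsilon_peak] for b in self.bands
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandModel":
        return cls(
            bands=[Band(*b) for b in d["bands"]],
            molar_mass=float(d["molar_mass"]),
            label=d.get("label", ""),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BandModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def epsilon_curve(model: BandModel, wavelengths: np.ndarray) -> np.ndarray:
    """Per-wavelength molar absorptivity of ``model`` (function form)."""
    return model.epsilon(wavelengths)


def default_models() -> tuple[BandModel, BandModel]:
    """The shipped VGN-like and RGE-like analyte models.

    VGN-like: dominant band at 209 nm (peak epsilon 18100, cf. the reported
    18100.24 L mol^-1 cm^-1 at 209.2 nm) plus a weak 222 nm shoulder.  The
    shoulder keeps the analyte absorbing appreciably out to 230 nm (the
    overlap region) while total absorbance still falls below 1% of the peak
    beyond 235 nm; a single Gaussian cannot do both.

    RGE-like: dominant band at 226 nm (peak epsilon 32133, cf. 32133.33 at
    225.9 nm), a narrow short-wavelength band at 201 nm, and a long-
    wavelength band at 275 nm.  The 275 nm band gives the first derivative
    non-zero amplitude near 287.7 nm where the VGN-like derivative is null;
    the 201 nm band gives both analytes' ratio spectra interior peaks and
    valleys, as the real spectra have.

    Molar masses are external chemistry constants (vildagliptin 303.4,
    remogliflozin etabonate 522.6 g/mol); they are plain inputs here and
    never enter method logic.
    """
    vgn = BandModel(
        bands=[Band(209.0, 7.5, 18100.0), Band(222.0, 4.0, 7240.0)],
        molar_mass=303.4,
        label="VGN",
    )
    rge = BandModel(
        bands=[
            Band(226.0, 11.0, 32133.0),
            Band(201.0, 2.2, 15000.0),
            Band(275.0, 9.0, 8500.0),
        ],
        molar_mass=522.6,
        label="RGE",
    )
    return vgn, rge


@dataclass
class MixtureSpec:
    """Recipe for one simulated mixture spectrum.

    ``components`` pairs each :class:`BandModel` with its concentration in
    ug/mL; ``noise_sd`` is the i.i.d. Gaussian absorbance noise in AU and
    ``seed`` makes the draw reproducible.
    """

    components: list[tuple[BandModel, float]]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for _, conc in self.components:
            if conc < 0:
                raise ValueError("component concentrations must be >= 0")


def simulate_mixture(
    spec: MixtureSpec,
    grid: np.ndarray | None = None,
    pathlength: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Simulate an additive Beer-Lambert mixture spectrum.

    ``A(lambda) = sum_i eps_i(lambda) * (c_i * 1e-3 / M_i) * pathlength``
    plus Gaussian noise of SD ``spec.noise_sd``.  When ``rng`` is given it
    supplies the noise stream (for sequential replicate draws); otherwise a
    fresh generator is seeded from ``spec.seed``.
    """
    w = default_grid() if grid is None else np.asarray(grid, dtype=float)
    total = np.zeros_like(w)
    for model, conc in spec.components:
        total += model.absorbance(w, conc, pathlength)
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        total = total + rng.normal(0.0, spec.noise_sd, size=w.size)
    labels = [m.label or "analyte" for m, _ in spec.components]
    conc = (
        float(spec.components[0][1]) if len(spec.components) == 1 else None
    )
    return Spectrum(
        wavelengths=w,
        absorbances=total,
        label="+".join(labels),
        concentration=conc,
        pathlength=pathlength,
        kind="absorption",
    )


def simulate_calibration_series(
    model: BandModel,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
    pathlength: float = 1.0,
) -> CalibrationSeries:
    """Simulate a single-analyte calibration series on a common grid.

    Each member gets an independent noise draw from one generator seeded
    with ``seed`` (so the whole series is reproducible bit-for-bit).
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size == 0:
        raise SpectrumError("empty concentration list")
    rng = np.random.default_rng(seed)
    w = default_grid() if grid is None else np.asarray(grid, dtype=float)
    spectra = []
    for c in concentrations:
        spec = MixtureSpec(
            components=[(model, float(c))], noise_sd=noise_sd, seed=seed
        )
        spectra.append(
            simulate_mixture(spec, grid=w, pathlength=pathlength, rng=rng)
        )
    return CalibrationSeries(
        spectra=spectra,
        concentrations=concentrations,
        analyte=model.label,
    )
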