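"""Spectrum container, wavelength-grid arithmetic and plain-text I/O.

A :class:`Spectrum` is a sampled absorbance curve on a strictly increasing,
uniform wavelength grid (nm), optionally tagged with an analyte label, a
concentration (ug/mL) and a cuvette pathlength (cm).  Wavelengths are always
physical nm values, never integer indices; every wavelength lookup linearly
interpolates between the two bracketing grid points, so working wavelengths
such as 213.7 nm need not be grid points.

Derivative and ratio spectra are also carried by :class:`Spectrum` (the
``kind`` field records what transform produced the values); their amplitudes
are signed and are never clamped.  Points excluded by the ratio division
guard are tracked through the boolean ``valid`` mask.

The canonical on-disk format is a two-column CSV with header
``wavelength_nm,absorbance`` and optional ``#`` comment lines carrying
metadata.  A read-only JCAMP-DX import is available through
:func:`read_spectrum` with ``dialect="jcamp"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: absolute tolerance (nm) within which the grid step must be uniform
GRID_ATOL = 1e-9

SPECTRUM_KINDS = (
    "absorption",
    "first_derivative",
    "ratio",
    "ratio_first_derivative",
)


class SpectrumError(ValueError):
    """Invalid spectrum data or an operation outside its domain."""


class MaskedRegionError(SpectrumError):
    """A wavelength lookup fell in a region excluded by the division guard."""


@dataclass
class Spectrum:
    """A sampled spectral curve on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Strictly increasing, uniformly spaced wavelengths in nm (>= 3 points).
    absorbances : array of float
        Signed amplitudes in AU (or AU-derived units for transformed spectra),
        one per wavelength.
    label : str
        Free-text analyte / provenance label.
    concentration : float or None
        Analyte concentration in ug/mL, if the spectrum is of a known solution.
    pathlength : float
        Cuvette pathlength in cm (default 1).
    kind : str
        One of ``absorption``, ``first_derivative``, ``ratio``,
        ``ratio_first_derivative``.
    valid : bool array or None
        Per-point validity mask; ``False`` marks points excluded by the ratio
        division guard (or whose transform stencil touched such points).
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    label: str = ""
    concentration: float | None = None
    pathlength: float = 1.0
    kind: str = "absorption"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavelengths.ndim != 1 or self.absorbances.ndim != 1:
            raise SpectrumError("wavelengths and absorbances must be 1-D")
        if self.wavelengths.size != self.absorbances.size:
            raise SpectrumError(
                "wavelengths and absorbances differ in length "
                f"({self.wavelengths.size} vs {self.absorbances.size})"
            )
        if self.wavelengths.size < 3:
            raise SpectrumError("a spectrum needs at least 3 points")
        steps = np.diff(self.wavelengths)
        if np.any(steps <= 0):
            raise SpectrumError("non-increasing grid")
        if np.any(np.abs(steps - steps[0]) > GRID_ATOL):
            raise SpectrumError(
                "non-uniform wavelength grid (step varies by more than "
                f"{GRID_ATOL} nm); resample explicitly instead"
            )
        if self.pathlength <= 0:
            raise SpectrumError("pathlength must be > 0")
        if self.concentration is not None and self.concentration < 0:
            raise SpectrumError("concentration must be >= 0")
        if self.kind not in SPECTRUM_KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if self.valid is None:
            self.valid = np.ones(self.wavelengths.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.wavelengths.shape:
                raise SpectrumError("valid mask length mismatch")

    # -- grid geometry -----------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.wavelengths.size)

    @property
    def step(self) -> float:
        """Uniform grid step in nm."""
        return float(
            (self.wavelengths[-1] - self.wavelengths[0]) / (self.n - 1)
        )

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths[-1])

    def same_grid(self, other: "Spectrum", atol: float = GRID_ATOL) -> bool:
        return self.n == other.n and bool(
            np.allclose(self.wavelengths, other.wavelengths, rtol=0, atol=atol)
        )

    # -- lookups -----------------------------------------------------------

    def amplitude_at(self, wavelength: float) -> float:
        """Signed amplitude at ``wavelength`` by linear interpolation.

        Exact grid hits return the stored value; valleys stay negative.
        Raises :class:`SpectrumError` outside the grid range and
        :class:`MaskedRegionError` when a bracketing point is masked.
        """
        w = float(wavelength)
        if w < self.wl_min - GRID_ATOL or w > self.wl_max + GRID_ATOL:
            raise SpectrumError(
                f"wavelength {w} nm outside grid "
                f"[{self.wl_min}, {self.wl_max}] nm"
            )
        pos = (w - self.wl_min) / self.step
        i = int(np.floor(pos))
        i = min(max(i, 0), self.n - 1)
        frac = pos - i
        if abs(frac) <= 1e-9 or i == self.n - 1:
            if not self.valid[i]:
                raise MaskedRegionError(
                    f"wavelength {w} nm lies in a masked region"
                )
            return float(self.absorbances[i])
        if not (self.valid[i] and self.valid[i + 1]):
            raise MaskedRegionError(f"wavelength {w} nm lies in a masked region")
        a, b = self.absorbances[i], self.absorbances[i + 1]
        return float(a + frac * (b - a))

    def resample(self, step: float) -> "Spectrum":
        """Linear interpolation onto a new uniform grid with the same span."""
        if step <= 0:
            raise SpectrumError("resampling step must be > 0")
        span = self.wl_max - self.wl_min
        if step > span:
            raise SpectrumError("resampling step exceeds the grid span")
        n_new = int(np.floor(span / step + 1e-9)) + 1
        new_w = self.wl_min + step * np.arange(n_new)
        new_a = np.interp(new_w, self.wavelengths, self.absorbances)
        # a resampled point is valid only if both bracketing originals are
        valid_f = np.interp(new_w, self.wavelengths, self.valid.astype(float))
        new_valid = valid_f > 1.0 - 1e-9
        return replace(
            self, wavelengths=new_w, absorbances=new_a, valid=new_valid
        )

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, absorbances=self.absorbances * factor)

    def plot(self, ax=None, **kwargs):
        """Plot the spectrum (requires matplotlib); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = np.where(self.valid, self.absorbances, np.nan)
        ax.plot(self.wavelengths, y, label=self.label or None, **kwargs)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("amplitude (AU)")
        return ax


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_HEADER = "wavelength_nm,absorbance"


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV at full double precision.

    Metadata (label, kind, concentration, pathlength) goes into leading
    ``#`` comment lines so that a read round-trip reproduces the object.
    """
    path = Path(path)
    lines = []
    if spectrum.label:
        lines.append(f"# label: {spectrum.label}")
    lines.append(f"# kind: {spectrum.kind}")
    if spectrum.concentration is not None:
        lines.append(f"# concentration_ug_per_ml: {spectrum.concentration!r}")
    lines.append(f"# pathlength_cm: {spectrum.pathlength!r}")
    lines.append(_HEADER)
    for w, a, v in zip(
        spectrum.wavelengths, spectrum.absorbances, spectrum.valid
    ):
        row = f"{float(w)!r},{float(a)!r}"
        if not v:
            row += ",masked"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path, dialect: str = "csv") -> Spectrum:
    """Read a spectrum from ``path``.

    ``dialect="csv"`` expects the two-column format written by
    :func:`write_spectrum` (metadata comments optional); non-uniform grids
    are rejected, never silently resampled.  ``dialect="jcamp"`` accepts a
    plain-text JCAMP-DX file with AFFN-encoded data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "jcamp":
        from .jcampdx import read_jcamp

        return read_jcamp(path)
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")

    meta: dict[str, str] = {}
    wls: list[float] = []
    amps: list[float] = []
    valid: list[bool] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        if line.lower().replace(" ", "") == _HEADER:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 2:
            raise SpectrumError(f"{path}:{lineno}: expected two columns")
        try:
            wls.append(float(parts[0]))
            amps.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumError(f"{path}:{lineno}: non-numeric row") from exc
        valid.append(not (len(parts) > 2 and parts[2] == "masked"))

    conc = meta.get("concentration_ug_per_ml")
    return Spectrum(
        wavelengths=np.array(wls),
        absorbances=np.array(amps),
        label=meta.get("label", ""),
        concentration=float(conc) if conc is not None else None,
        pathlength=float(meta.get("pathlength_cm", 1.0)),
        kind=meta.get("kind", "absorption"),
        valid=np.array(valid, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Calibration series
# ---------------------------------------------------------------------------


@dataclass
class CalibrationSeries:
    """An ordered collection of spectra of one analyte at known concentrations.

    All spectra must share an identical wavelength grid; concentrations are
    strictly positive and not all equal.
    """

    spectra: list[Spectrum]
    concentrations: np.ndarray
    analyte: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.spectra) == 0:
            raise SpectrumError("empty calibration series")
        if self.concentrations.size != len(self.spectra):
            raise SpectrumError("one concentration per spectrum required")
        ref = self.spectra[0]
        for s in self.spectra[1:]:
            if not ref.same_grid(s):
                raise SpectrumError(
                    "calibration series spectra must share one grid"
                )
        if np.any(self.concentrations <= 0):
            raise SpectrumError("series concentrations must be > 0")
        if np.all(self.concentrations == self.concentrations[0]):
            raise SpectrumError("series concentrations must not all be equal")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(zip(self.concentrations, self.spectra))

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    @property
    def top(self) -> Spectrum:
        """The member with the highest concentration."""
        return self.spectra[int(np.argmax(self.concentrations))]

    @property
    def concentration_range(self) -> tuple[float, float]:
        return (
            float(self.concentrations.min()),
            float(self.concentrations.max()),
        )


def write_series(
    series: CalibrationSeries, directory: str | Path, prefix: str = ""
) -> Path:
    """Write each member spectrum plus a ``manifest.csv`` into ``directory``.

    Returns the manifest path.  Manifest columns are
    ``file,concentration_ug_per_ml``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prefix = prefix or (series.analyte or "series")
    rows = ["file,concentration_ug_per_ml"]
    for i, (conc, spec) in enumerate(series):
        name = f"{prefix}_{i:02d}.csv"
        write_spectrum(spec, directory / name)
        rows.append(f"{name},{float(conc)!r}")
    manifest = directory / f"{prefix}_manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest


def read_series(manifest: str | Path, analyte: str = "") -> CalibrationSeries:
    """Load a calibration series from a manifest CSV.

    Spectrum paths in the manifest are resolved relative to its directory.
    """
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(manifest)
    spectra: list[Spectrum] = []
    concs: list[float] = []
    for lineno, raw in enumerate(manifest.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("file,"):
            continue
        name, _, conc = line.partition(",")
        try:
            c = float(conc)
        except ValueError as exc:
            raise SpectrumError(
                f"{manifest}:{lineno}: bad concentration {conc!r}"
            ) from exc
        spectra.append(read_spectrum(manifest.parent / name.strip()))
        concs.append(c)
    return CalibrationSeries(
        spectra=spectra, concentrations=np.array(concs), analyte=analyte
    )
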