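"""ICH-style method-validation statistics.

Linearity, detection/quantification limits, accuracy (recovery / relative
error), intraday & interday precision, specificity on laboratory-style
mixtures, and standard-addition spike recovery — the arithmetic behind a
conventional validation report for a spectrophotometric assay.

Dispersion conventions are explicit everywhere: published tables in this
field sometimes label a population standard deviation "%RSD", so
:func:`summarize` takes the convention as a parameter and the report
renderer labels each statistic by its actual formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .methods import MethodCalibrationResults
from .synthetic import BandModel, MixtureSpec, simulate_mixture


class ValidationError(ValueError):
    """Invalid input to a validation statistic."""


DISPERSIONS = ("sample_sd", "population_sd", "rsd_sample", "rsd_population")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (print convention for rendered tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def lod_loq(sd_intercept: float, slope: float) -> tuple[float, float]:
    """Detection and quantification limits from calibration statistics.

    ``LOD = 3.3 * sigma / |S|`` and ``LOQ = 10 * sigma / |S|`` with sigma
    the SD of the calibration intercept and S the slope, so LOQ/LOD is
    10/3.3 identically.
    """
    if slope == 0:
        raise ValidationError("zero slope: LOD/LOQ undefined")
    if sd_intercept < 0:
        raise ValidationError("sd_intercept must be >= 0")
    s = abs(slope)
    return 3.3 * sd_intercept / s, 10.0 * sd_intercept / s


def recovery(measured: float, nominal: float) -> tuple[float, float]:
    """Percent recovery and percent relative error of one determination."""
    if nominal <= 0:
        raise ValidationError("nominal concentration must be > 0")
    rec = 100.0 * measured / nominal
    return rec, rec - 100.0


def summarize(
    values: Sequence[float], dispersion: str = "sample_sd"
) -> tuple[float, float]:
    """Arithmetic mean and a dispersion statistic of a set of percentages.

    ``sample_sd`` uses the n-1 denominator, ``population_sd`` uses n;
    the ``rsd_*`` variants report 100 * SD / mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("at least 2 values required")
    if dispersion not in DISPERSIONS:
        raise ValidationError(f"unknown dispersion convention {dispersion!r}")
    mean = float(np.mean(v))
    ddof = 1 if dispersion in ("sample_sd", "rsd_sample") else 0
    sd = float(np.std(v, ddof=ddof))
    if dispersion.startswith("rsd"):
        return mean, 100.0 * sd / mean
    return mean, sd


def standard_addition(
    base_measured: float, spiked_measured: float, added: float
) -> float:
    """Percent recovery of a spiked addition on top of an assayed sample."""
    if added <= 0:
        raise ValidationError("added amount must be > 0")
    return 100.0 * (spiked_measured - base_measured) / added


def precision_study(
    replicate_results: Mapping[float, np.ndarray],
) -> list[tuple[float, float, float]]:
    """Intraday and interday %RSD per concentration level.

    ``replicate_results`` maps each level (ug/mL) to a 2-D array of measured
    concentrations shaped ``(n_days, n_replicates)``.  Intraday %RSD comes
    from the day-1 replicates; interday %RSD from the day means across days
    (sample SD, n-1).  Returns ``(level, intraday, interday)`` rows.
    """
    rows: list[tuple[float, float, float]] = []
    for level in sorted(replicate_results):
        arr = np.asarray(replicate_results[level], dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError(
                "precision needs >= 2 replicates per day and >= 2 days"
            )
        _, intraday = summarize(arr[0], "rsd_sample")
        day_means = arr.mean(axis=1)
        _, interday = summarize(day_means, "rsd_sample")
        rows.append((float(level), intraday, interday))
    return rows


# ---------------------------------------------------------------------------
# Simulation-backed studies
# ---------------------------------------------------------------------------

#: laboratory-mixture compositions (RGE, VGN) used by default for the
#: specificity study — five ratios spanning both linearity ranges.
DEFAULT_SPECIFICITY_MIXTURES = (
    (10.0, 50.0),
    (40.0, 50.0),
    (40.0, 5.0),
    (70.0, 5.0),
    (70.0, 25.0),
)


def _simulate_reading(
    models: tuple[BandModel, BandModel],
    conc_a: float,
    conc_b: float,
    noise_sd: float,
    rng: np.random.Generator,
    grid,
):
    model_a, model_b = models
    spec = MixtureSpec(
        components=[(model_a, conc_a), (model_b, conc_b)], noise_sd=noise_sd
    )
    return simulate_mixture(spec, grid=grid, rng=rng)


def accuracy_study(
    calibrations: Mapping[tuple[str, str], MethodCalibrationResults],
    models: tuple[BandModel, BandModel],
    levels: Mapping[str, Sequence[float]],
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
    grid=None,
) -> list[dict]:
    """Recovery study at low/medium/high levels, replicated.

    Each level index pairs the two analytes' levels into one binary
    mixture, scanned ``n_replicates`` times with independent noise.  Every
    (analyte, method) determination is the mean of its replicate scans,
    which is how accuracy is conventionally tabulated.  Returns one row per
    (analyte, method, level) with the mean recovery, %RSD over replicates
    and mean relative error.
    """
    model_a, model_b = models
    label_a, label_b = model_a.label, model_b.label
    rng = np.random.default_rng(seed)
    n_levels = len(levels[label_a])
    rows: list[dict] = []
    replicate_sets: dict[tuple[str, str, float], list[float]] = {}
    for i in range(n_levels):
        ca = float(levels[label_a][i])
        cb = float(levels[label_b][i])
        for _ in range(n_replicates):
            spectrum = _simulate_reading(models, ca, cb, noise_sd, rng, grid)
            for (analyte, method), cal in calibrations.items():
                nominal = ca if analyte == label_a else cb
                measured = cal.quantify(spectrum).concentration
                key = (analyte, method, nominal)
                replicate_sets.setdefault(key, []).append(measured)
    for (analyte, method, nominal), reps in sorted(replicate_sets.items()):
        recs = [recovery(m, nominal)[0] for m in reps]
        mean_rec, rsd = summarize(recs, "rsd_sample")
        rows.append(
            {
                "analyte": analyte,
                "method": method,
                "nominal": nominal,
                "measured_mean": float(np.mean(reps)),
                "recovery_mean": mean_rec,
                "recovery_rsd": rsd,
                "relative_error": mean_rec - 100.0,
                "replicates": list(map(float, reps)),
            }
        )
    return rows


def precision_simulation(
    calibrations: Mapping[tuple[str, str], MethodCalibrationResults],
    models: tuple[BandModel, BandModel],
    levels: Mapping[str, Sequence[float]],
    noise_sd: float,
    seed: int,
    n_replicates: int = 3,
    n_days: int = 3,
    grid=None,
) -> list[dict]:
    """Intraday/interday precision from a simulated replication design."""
    model_a, model_b = models
    label_a, label_b = model_a.label, model_b.label
    rng = np.random.default_rng(seed)
    n_levels = len(levels[label_a])
    measured: dict[tuple[str, str, float], np.ndarray] = {}
    for i in range(n_levels):
        ca = float(levels[label_a][i])
        cb = float(levels[label_b][i])
        per_key: dict[tuple[str, str], np.ndarray] = {
            key: np.zeros((n_days, n_replicates)) for key in calibrations
        }
        for day in range(n_days):
            for rep in range(n_replicates):
                spectrum = _simulate_reading(
                    models, ca, cb, noise_sd, rng, grid
                )
                for key, cal in calibrations.items():
                    per_key[key][day, rep] = cal.quantify(
                        spectrum
                    ).concentration
        for (analyte, method), arr in per_key.items():
            nominal = ca if analyte == label_a else cb
            measured[(analyte, method, nominal)] = arr
    rows: list[dict] = []
    for (analyte, method, nominal), arr in sorted(measured.items()):
        (_, intraday, interday) = precision_study({nominal: arr})[0]
        rows.append(
            {
                "analyte": analyte,
                "method": method,
                "nominal": nominal,
                "intraday_rsd": intraday,
                "interday_rsd": interday,
            }
        )
    return rows


def specificity_study(
    calibrations: Mapping[tuple[str, str], MethodCalibrationResults],
    models: tuple[BandModel, BandModel],
    mixtures: Sequence[tuple[float, float]] = DEFAULT_SPECIFICITY_MIXTURES,
    noise_sd: float = 0.0,
    seed: int = 0,
    grid=None,
) -> dict:
    """Assay laboratory-style mixtures at varying analyte ratios.

    ``mixtures`` lists (RGE-like, VGN-like) concentrations, i.e. in the
    order (second model, first model) of ``models`` — matching how such
    tables are conventionally printed.  Returns per-mixture recovery rows
    plus across-mixture mean and SD (population) per (analyte, method).
    """
    model_a, model_b = models  # (VGN-like, RGE-like)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    per_column: dict[tuple[str, str], list[float]] = {
        key: [] for key in calibrations
    }
    for conc_b, conc_a in mixtures:
        spectrum = _simulate_reading(
            models, float(conc_a), float(conc_b), noise_sd, rng, grid
        )
        row: dict = {"composition": (float(conc_b), float(conc_a))}
        for (analyte, method), cal in calibrations.items():
            nominal = conc_a if analyte == model_a.label else conc_b
            result = cal.quantify(spectrum)
            rec, _ = recovery(result.concentration, float(nominal))
            row[(analyte, method)] = rec
            per_column[(analyte, method)].append(rec)
        rows.append(row)
    summaries = {
        key: summarize(vals, "population_sd")
        for key, vals in per_column.items()
    }
    return {"rows": rows, "summaries": summaries}


def standard_addition_study(
    calibrations: Mapping[tuple[str, str], MethodCalibrationResults],
    models: tuple[BandModel, BandModel],
    base: Mapping[str, float],
    additions: Sequence[Mapping[str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_scans: int = 3,
    grid=None,
) -> dict:
    """Spike-recovery (standard addition) on an assayed base solution.

    The base and every spiked solution are scanned ``n_scans`` times and the
    replicate-mean concentrations used, as in routine formulation assays.
    Returns per-spike recovery rows plus mean and dispersion summaries per
    (analyte, method); the dispersion is reported under both the population
    SD and the sample %RSD conventions.
    """
    model_a, model_b = models
    rng = np.random.default_rng(seed)

    def mean_quant(conc_a: float, conc_b: float) -> dict:
        sums: dict[tuple[str, str], float] = {k: 0.0 for k in calibrations}
        for _ in range(n_scans):
            spectrum = _simulate_reading(
                models, conc_a, conc_b, noise_sd, rng, grid
            )
            for key, cal in calibrations.items():
                sums[key] += cal.quantify(spectrum).concentration
        return {k: v / n_scans for k, v in sums.items()}

    base_a = float(base[model_a.label])
    base_b = float(base[model_b.label])
    base_measured = mean_quant(base_a, base_b)
    rows: list[dict] = []
    per_column: dict[tuple[str, str], list[float]] = {
        key: [] for key in calibrations
    }
    for addition in additions:
        add_a = float(addition[model_a.label])
        add_b = float(addition[model_b.label])
        spiked = mean_quant(base_a + add_a, base_b + add_b)
        row: dict = {"added": {model_a.label: add_a, model_b.label: add_b}}
        for (analyte, method), measured in spiked.items():
            added = add_a if analyte == model_a.label else add_b
            rec = standard_addition(
                base_measured[(analyte, method)], measured, added
            )
            row[(analyte, method)] = rec
            per_column[(analyte, method)].append(rec)
        rows.append(row)
    summaries = {}
    for key, vals in per_column.items():
        mean, pop_sd = summarize(vals, "population_sd")
        _, rsd = summarize(vals, "rsd_sample")
        summaries[key] = {"mean": mean, "population_sd": pop_sd, "rsd": rsd}
    return {"rows": rows, "base_measured": base_measured, "summaries": summaries}


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """All validation outputs for one binary system, renderable as tables."""

    linearity: dict
    accuracy_rows: list[dict]
    precision_rows: list[dict]
    specificity: dict
    standard_addition: dict
    noise_sd: float
    seeds: dict

    #: acceptance envelopes mirroring routine assay criteria
    RECOVERY_WINDOW = (98.0, 102.0)
    RSD_LIMIT = 2.0
    R2_FLOOR = 0.999

    def envelope_checks(self) -> list[tuple[str, bool, float]]:
        """(criterion, passed, worst value) triples for every envelope."""
        checks: list[tuple[str, bool, float]] = []
        lo, hi = self.RECOVERY_WINDOW
        r2s = [c["r_squared"] for c in self.linearity.values()]
        worst_r2 = min(r2s)
        checks.append(("linearity r^2 >= 0.999", worst_r2 >= self.R2_FLOOR, worst_r2))
        recs = [r["recovery_mean"] for r in self.accuracy_rows]
        worst = max(recs, key=lambda v: abs(v - 100.0))
        checks.append(("accuracy recovery in [98, 102]%", lo <= min(recs) and max(recs) <= hi, worst))
        rsds = [r[k] for r in self.precision_rows for k in ("intraday_rsd", "interday_rsd")]
        worst_rsd = max(rsds)
        checks.append(("precision %RSD < 2", worst_rsd < self.RSD_LIMIT, worst_rsd))
        spec_means = [m for m, _sd in self.specificity["summaries"].values()]
        worst_spec = max(spec_means, key=lambda v: abs(v - 100.0))
        checks.append(
            (
                "specificity across-mean recovery in [98, 102]%",
                lo <= min(spec_means) and max(spec_means) <= hi,
                worst_spec,
            )
        )
        sa_means = [s["mean"] for s in self.standard_addition["summaries"].values()]
        worst_sa = max(sa_means, key=lambda v: abs(v - 100.0))
        checks.append(
            (
                "standard-addition mean recovery in [98, 102]%",
                lo <= min(sa_means) and max(sa_means) <= hi,
                worst_sa,
            )
        )
        return checks

    def render(self) -> str:
        """Human-readable tables in the shape of a printed validation report."""
        lines: list[str] = []
        lines.append("Linearity and limits")
        lines.append("-" * 72)
        header = f"{'analyte/method':18s}{'slope':>10s}{'intercept':>11s}{'r^2':>9s}{'LOD':>8s}{'LOQ':>8s}"
        lines.append(header)
        for (analyte, method), c in sorted(self.linearity.items()):
            lines.append(
                f"{analyte + '/' + method:18s}"
                f"{c['slope']:>10.4g}{c['intercept']:>11.4g}"
                f"{c['r_squared']:>9.4f}"
                f"{round_half_away(c['lod'], 3):>8.3f}"
                f"{round_half_away(c['loq'], 3):>8.3f}"
            )
        lines.append("")
        lines.append("Accuracy (replicate-mean recovery per level)")
        lines.append("-" * 72)
        lines.append(
            f"{'analyte/method':18s}{'nominal':>9s}{'recovery%':>11s}{'rel.err%':>10s}{'%RSD':>8s}"
        )
        for r in self.accuracy_rows:
            lines.append(
                f"{r['analyte'] + '/' + r['method']:18s}"
                f"{r['nominal']:>9.1f}"
                f"{round_half_away(r['recovery_mean']):>11.2f}"
                f"{round_half_away(r['relative_error']):>10.2f}"
                f"{round_half_away(r['recovery_rsd']):>8.2f}"
            )
        lines.append("")
        lines.append("Precision (%RSD)")
        lines.append("-" * 72)
        lines.append(
            f"{'analyte/method':18s}{'nominal':>9s}{'intraday':>10s}{'interday':>10s}"
        )
        for r in self.precision_rows:
            lines.append(
                f"{r['analyte'] + '/' + r['method']:18s}"
                f"{r['nominal']:>9.1f}"
                f"{round_half_away(r['intraday_rsd'], 3):>10.3f}"
                f"{round_half_away(r['interday_rsd'], 3):>10.3f}"
            )
        lines.append("")
        lines.append("Specificity (laboratory mixtures, % recovery)")
        lines.append("-" * 72)
        columns = sorted(self.specificity["summaries"])
        col_hdr = "".join(f"{a + '/' + m:>14s}" for a, m in columns)
        lines.append(f"{'mixture (B, A)':18s}" + col_hdr)
        for row in self.specificity["rows"]:
            comp = row["composition"]
            cells = "".join(
                f"{round_half_away(row[c]):>14.2f}" for c in columns
            )
            lines.append(f"{f'{comp[0]:g}, {comp[1]:g}':18s}" + cells)
        mean_cells = "".join(
            f"{round_half_away(self.specificity['summaries'][c][0]):>14.2f}"
            for c in columns
        )
        sd_cells = "".join(
            f"{round_half_away(self.specificity['summaries'][c][1], 3):>14.3f}"
            for c in columns
        )
        lines.append(f"{'across mean':18s}" + mean_cells)
        lines.append(f"{'SD (population)':18s}" + sd_cells)
        lines.append("")
        lines.append("Standard addition (% recovery of added amount)")
        lines.append("-" * 72)
        sa_cols = sorted(self.standard_addition["summaries"])
        lines.append(f"{'added':18s}" + "".join(f"{a + '/' + m:>14s}" for a, m in sa_cols))
        for row in self.standard_addition["rows"]:
            added = row["added"]
            label = ", ".join(f"{k} +{v:g}" for k, v in added.items())
            cells = "".join(
                f"{round_half_away(row[c]):>14.2f}" for c in sa_cols
            )
            lines.append(f"{label:18s}" + cells)
        summaries = self.standard_addition["summaries"]
        lines.append(
            f"{'across mean':18s}"
            + "".join(f"{round_half_away(summaries[c]['mean']):>14.2f}" for c in sa_cols)
        )
        lines.append(
            f"{'SD (population)':18s}"
            + "".join(
                f"{round_half_away(summaries[c]['population_sd'], 3):>14.3f}"
                for c in sa_cols
            )
        )
        lines.append(
            f"{'%RSD (sample)':18s}"
            + "".join(
                f"{round_half_away(summaries[c]['rsd'], 3):>14.3f}"
                for c in sa_cols
            )
        )
        lines.append("")
        lines.append("Envelopes")
        lines.append("-" * 72)
        for name, passed, worst in self.envelope_checks():
            status = "PASS" if passed else "FAIL"
            lines.append(f"{status}  {name}  (worst: {worst:.4g})")
        return "\n".join(lines)

    def all_pass(self) -> bool:
        return all(passed for _n, passed, _w in self.envelope_checks())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "noise_sd": self.noise_sd,
            "seeds": self.seeds,
            "linearity": {
                f"{a}/{m}": v for (a, m), v in self.linearity.items()
            },
            "accuracy": self.accuracy_rows,
            "precision": self.precision_rows,
            "specificity": {
                "rows": [
                    {
                        "composition": list(r["composition"]),
                        "recoveries": {
                            f"{k[0]}/{k[1]}": v
                            for k, v in r.items()
                            if isinstance(k, tuple)
                        },
                    }
                    for r in self.specificity["rows"]
                ],
                "summaries": {
                    f"{a}/{m}": list(v)
                    for (a, m), v in self.specificity["summaries"].items()
                },
            },
            "standard_addition": {
                "rows": [
                    {
                        "added": r["added"],
                        "recoveries": {
                            f"{k[0]}/{k[1]}": v
                            for k, v in r.items()
                            if isinstance(k, tuple)
                        },
                    }
                    for r in self.standard_addition["rows"]
                ],
                "summaries": {
                    f"{a}/{m}": v
                    for (a, m), v in self.standard_addition["summaries"].items()
                },
            },
            "envelopes": [
                {"criterion": n, "passed": p, "worst": w}
                for n, p, w in self.envelope_checks()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
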