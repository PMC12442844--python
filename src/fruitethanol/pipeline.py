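"""End-to-end pipeline: raw tables -> concentrations -> exposure -> dosage.

``run_pipeline`` composes the stages exactly as the CLI subcommands do:
per-method pooled calibration fits, per-sample inverse prediction,
species summaries with the n >= 3 inclusion filter, feeding-time-weighted
exposure, and the site dosage table.  Validation metrics (per-series
calibration MAE and, when two or more methods share standard levels, the
combined error budget) ride along in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as fio
from .assays import cr2_to_concentration, gc_to_concentration, mos_to_concentration
from .calibration import CalibrationFit, CalibrationSeries, fit_calibration
from .dosage import DrinkStandard, SiteSexParams, site_dosage_table
from .errors import InsufficientDataError, InvalidArgumentError
from .exposure import summarize_species, weighted_concentration
from .validation import error_budget

log = logging.getLogger("fruitethanol")


@dataclass
class StudyConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    site: str
    fruit_fraction: float
    body_mass: dict[str, float]  # by sex, kg
    bulk_food: dict[str, float]  # by sex, g/day
    samples_path: str
    standards_path: str
    feeding_path: str
    grams_per_drink: float = 10.0
    reference_mass: float = 70.0
    min_samples_per_species: int = 3
    repeat_error_pct: float = 0.0  # repeatability component for the error budget
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fruit_fraction <= 1:
            raise InvalidArgumentError("fruit_fraction must be in (0, 1]")
        for p in (self.samples_path, self.standards_path, self.feeding_path):
            if not Path(p).exists():
                raise InvalidArgumentError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        for key in ("samples_path", "standards_path", "feeding_path"):
            raw[key] = str((base / raw[key]).resolve())
        return cls(**raw)

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def drink_standard(self) -> DrinkStandard:
        return DrinkStandard(self.grams_per_drink, self.reference_mass)

    def site_params(self) -> list[SiteSexParams]:
        return [
            SiteSexParams(self.site, sex, self.body_mass[sex], self.bulk_food[sex], self.fruit_fraction)
            for sex in sorted(self.body_mass)
        ]


def fit_method_calibrations(
    series_list: list[CalibrationSeries],
) -> dict[str, CalibrationFit]:
    """One pooled fit per method, pooling every series of that method."""
    by_method: dict[str, list] = {}
    for s in series_list:
        by_method.setdefault(s.method, []).extend(s.standards)
    fits = {}
    for method, standards in by_method.items():
        pooled = CalibrationSeries(
            method=method, standards=tuple(standards), label="pooled", role="pooled"
        )
        fits[method] = fit_calibration(pooled)
        log.info("calibration %s: n=%d mae=%.4f", method, len(pooled), fits[method].mae)
    return fits


def convert_samples(
    records: list[fio.SampleRecord], fits: dict[str, CalibrationFit]
) -> list[tuple[str, str, float]]:
    """Per-sample (sample_id, species, concentration % w/w)."""
    out = []
    for rec in records:
        if rec.method not in fits:
            raise InsufficientDataError(
                f"no calibration fit for method {rec.method} (sample {rec.sample_id})"
            )
        fit = fits[rec.method]
        reading = rec.to_reading()
        if rec.method == "MOS":
            conc = mos_to_concentration(reading, fit)
        elif rec.method == "CR2":
            conc = cr2_to_concentration(reading, fit)
        else:
            conc = gc_to_concentration(reading, fit, rec.dilution_factor)
        out.append((rec.sample_id, rec.species, conc))
    return out


def _per_series_errors(series_list, fits):
    """Per method, per nominal level, max |known - predicted| (% w/w)."""
    from .calibration import predict_concentration

    errors: dict[str, dict[float, float]] = {}
    for s in series_list:
        fit = fits[s.method]
        d = errors.setdefault(s.method, {})
        for known, resp in s.standards:
            err = abs(known - predict_concentration(fit, resp, 1.0))
            d[known] = max(d.get(known, 0.0), err)
    return errors


def run_pipeline(config: StudyConfig) -> dict:
    """Run every stage and return a JSON-able report dict."""
    records = fio.read_samples(config.samples_path)
    series_list = fio.read_standards(config.standards_path)
    feeding, _locations = fio.read_feeding(
        config.feeding_path, site=config.site, fruit_fraction_of_diet=config.fruit_fraction
    )
    log.info("inputs: %d samples, %d standard series, %d feeding entries",
             len(records), len(series_list), len(feeding.entries))

    fits = fit_method_calibrations(series_list)
    concentrations = convert_samples(records, fits)

    summaries = summarize_species(
        [(sp, c) for _, sp, c in concentrations], min_n=config.min_samples_per_species
    )
    if not summaries:
        raise InsufficientDataError(
            "no species passed the minimum-sample filter; nothing to summarize"
        )
    exposure = weighted_concentration(summaries, feeding)
    dosage = site_dosage_table(config.site_params(), exposure, config.drink_standard())

    validation: dict = {
        "calibration": {
            m: {"slope": f.slope, "intercept": f.intercept, "adj_r2": f.adj_r2,
                "mae_pct": f.mae, "n_standards": f.n_standards, "transform": f.transform}
            for m, f in fits.items()
        }
    }
    per_method_errors = _per_series_errors(series_list, fits)
    level_sets = {m: frozenset(d) for m, d in per_method_errors.items()}
    if len(per_method_errors) >= 2 and len(set(level_sets.values())) == 1:
        budget = error_budget(per_method_errors, config.repeat_error_pct)
        validation["error_budget"] = {
            "per_bin_error_pct": {str(k): v for k, v in budget.per_bin_error.items()},
            "mean_calibration_error_pct": budget.mean_calibration_error,
            "repeat_sampling_error_pct": budget.repeat_sampling_error,
            "total_max_error_pct": budget.total_max_error,
        }

    return {
        "config": config.to_dict(),
        "n_samples": len(records),
        "per_sample_pct": [
            {"sample_id": sid, "species": sp, "concentration_pct": c}
            for sid, sp, c in concentrations
        ],
        "species_summaries": [
            {"species": s.species_name, "n": s.n, "mean_pct": s.mean_pct, "sd_pct": s.sd_pct}
            for s in summaries
        ],
        "weighted_exposure": {
            "weighted_mean_pct": exposure.weighted_mean_pct,
            "weighted_sd_pct": exposure.weighted_sd_pct,
            "coverage_pct": exposure.coverage_pct,
            "contributions": exposure.contributions,
        },
        "dosage_table": [r.display_row() for r in dosage],
        "dosage_full_precision": [
            {"site": r.site, "sex": r.sex, "fruit_g": r.fruit_g_per_day,
             "ethanol_g": r.ethanol_g_per_day, "ethanol_g_sd": r.ethanol_g_sd,
             "dose_g_per_kg_day": r.dose_g_per_kg_day, "dose_sd": r.dose_sd,
             "standard_drinks": r.standard_drinks, "drinks_sd": r.drinks_sd}
            for r in dosage
        ],
        "validation": validation,
    }


def format_report(report: dict) -> str:
    """Human-readable report mirroring the dosage-table layout."""
    lines = [
        f"Site: {report['config']['site']}   samples: {report['n_samples']}",
        "",
        "Species summaries (n >= %d):" % report["config"]["min_samples_per_species"],
    ]
    for s in report["species_summaries"]:
        lines.append(
            f"  {s['species']:<24} n={s['n']:<4} mean={s['mean_pct']:.3f}% sd={s['sd_pct']:.3f}%"
        )
    exp = report["weighted_exposure"]
    lines += [
        "",
        (
            f"Feeding-time weighted ethanol: {exp['weighted_mean_pct']:.2f}% "
            f"(+/- {exp['weighted_sd_pct']:.2f} SD), coverage {exp['coverage_pct']:.1f}% of feeding time"
        ),
        "",
        "Site\tSex\tBody mass (kg)\tFruit (g)\tEthanol % w/w (SD)\tEthanol g (SD)\tDosage g/kg/day (SD)\tStd drinks (SD)",
    ]
    for row in report["dosage_table"]:
        lines.append(
            "\t".join(
                [
                    row["site"], row["sex"], row["body_mass_kg"], row["fruit_g"],
                    row["ethanol_pct"], row["ethanol_g"], row["dose_g_per_kg_day"],
                    row["standard_drinks"],
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "report.txt").write_text(format_report(report))
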