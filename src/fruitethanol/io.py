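"""CSV readers and writers for the pipeline's input tables.

All tables are UTF-8 CSV with header rows.  Concentrations are stored as
% w/w numerals (``0.32`` means 0.32 % w/w, never a fraction).

Schemas
-------
samples.csv
    sample_id, species, method, response, dilution_factor,
    dry_mass_fraction (blank except Cr2), collection_date (optional).
    ``response`` is the raw instrument reading: volts for MOS, integrated
    peak area in mV*min for GC, absorbance for Cr2.
standards.csv
    series_id, method, known_pct, response, role (pre|post|pooled).
feeding.csv
    species, annual_feeding_pct, location (ground|canopy).
GC trace files
    time_s, signal_mv (two columns, seconds since injection / millivolts).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import Cr2Reading, GcTrace, MosReading, PeakIntegration
from .calibration import CalibrationSeries
from .errors import IntegrityError, ParseError, SchemaError
from .exposure import FeedingTimeTable

SAMPLE_COLUMNS = ["sample_id", "species", "method", "response", "dilution_factor"]
STANDARD_COLUMNS = ["series_id", "method", "known_pct", "response"]
FEEDING_COLUMNS = ["species", "annual_feeding_pct"]


@dataclass(frozen=True)
class SampleRecord:
    """One row of the samples table: a raw reading plus its metadata."""

    sample_id: str
    species: str
    method: str
    response: float
    dilution_factor: float = 1.0
    dry_mass_fraction: float = 0.0

    def to_reading(self):
        """Materialise the method-specific reading object."""
        if self.method == "MOS":
            return MosReading(self.sample_id, self.response, self.dilution_factor)
        if self.method == "CR2":
            return Cr2Reading(
                self.sample_id,
                self.response,
                self.dilution_factor,
                self.dry_mass_fraction,
            )
        if self.method == "GC":
            # the stored response is the already-integrated peak area
            return PeakIntegration(
                start_time=0.0, end_time=1.0, baseline=0.0, area=self.response
            )
        raise SchemaError(f"unknown method {self.method!r} for {self.sample_id}")


def _read_table(path: str | Path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    errors = []
    for col in numeric:
        if col not in df.columns:
            continue
        parsed = []
        for i, raw in enumerate(df[col]):
            if raw == "":
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(raw))  # exact round-trip parsing
            except ValueError:
                parsed.append(np.nan)
                errors.append(f"{path.name}:{i + 2}: non-numeric {col}={raw!r}")
        df[col] = parsed
    if errors:
        raise ParseError("; ".join(errors))
    return df


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Load the samples table into validated records.

    Duplicate sample ids within one file are rejected (each fruit is
    assayed once per row; replicates get distinct ids).
    """
    df = _read_table(
        path,
        SAMPLE_COLUMNS,
        ["response", "dilution_factor", "dry_mass_fraction"],
    )
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dupes:
        raise IntegrityError(f"duplicate sample_id values: {dupes}")
    records = []
    for _, row in df.iterrows():
        dm = row.get("dry_mass_fraction", np.nan)
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                species=str(row["species"]),
                method=str(row["method"]).upper(),
                response=float(row["response"]),
                dilution_factor=float(row["dilution_factor"]),
                dry_mass_fraction=0.0 if pd.isna(dm) else float(dm),
            )
        )
    return records


def read_standards(path: str | Path) -> list[CalibrationSeries]:
    """Load the standards table as one CalibrationSeries per (series, role)."""
    df = _read_table(path, STANDARD_COLUMNS, ["known_pct", "response"])
    if "role" not in df.columns:
        df["role"] = "pooled"
    series: "OrderedDict[tuple, list]" = OrderedDict()
    meta = {}
    for _, row in df.iterrows():
        key = (str(row["series_id"]), str(row["role"]) or "pooled")
        series.setdefault(key, []).append((float(row["known_pct"]), float(row["response"])))
        meta[key] = str(row["method"]).upper()
    return [
        CalibrationSeries(
            method=meta[key],
            standards=tuple(stds),
            label=key[0],
            role=key[1],
        )
        for key, stds in series.items()
    ]


def read_feeding(
    path: str | Path, site: str = "", fruit_fraction_of_diet: float = 1.0
) -> tuple[FeedingTimeTable, dict[str, str]]:
    """Load feeding percentages; returns the table and a location map."""
    df = _read_table(path, FEEDING_COLUMNS, ["annual_feeding_pct"])
    entries = tuple(
        (str(r["species"]), float(r["annual_feeding_pct"])) for _, r in df.iterrows()
    )
    locations = (
        {str(r["species"]): str(r["location"]) for _, r in df.iterrows()}
        if "location" in df.columns
        else {}
    )
    table = FeedingTimeTable(
        entries=entries, site=site, fruit_fraction_of_diet=fruit_fraction_of_diet
    )
    return table, locations


def read_gc_trace(path: str | Path, sample_id: str | None = None) -> GcTrace:
    """Load a two-column time/signal chromatogram."""
    df = _read_table(path, ["time_s", "signal_mv"], ["time_s", "signal_mv"])
    return GcTrace(
        sample_id=sample_id or Path(path).stem,
        times=df["time_s"].to_numpy(float),
        signal=df["signal_mv"].to_numpy(float),
    )


# -- writers (used by the simulate subcommand and round-trip tests) --


def write_samples(path: str | Path, records: list[SampleRecord]) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "species": r.species,
                "method": r.method,
                "response": repr(r.response),
                "dilution_factor": repr(r.dilution_factor),
                "dry_mass_fraction": repr(r.dry_mass_fraction),
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_standards(path: str | Path, series_list: list[CalibrationSeries]) -> None:
    rows = []
    for s in series_list:
        for known, resp in s.standards:
            rows.append(
                {
                    "series_id": s.label or "series",
                    "method": s.method,
                    "known_pct": repr(known),
                    "response": repr(resp),
                    "role": s.role,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_feeding(
    path: str | Path, table: FeedingTimeTable, locations: dict[str, str] | None = None
) -> None:
    locations = locations or {}
    pd.DataFrame(
        [
            {
                "species": name,
                "annual_feeding_pct": repr(pct),
                "location": locations.get(name, "canopy"),
            }
            for name, pct in table.entries
        ]
    ).to_csv(path, index=False)


def write_gc_trace(path: str | Path, trace: GcTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "signal_mv": trace.signal}).to_csv(
        path, index=False
    )
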