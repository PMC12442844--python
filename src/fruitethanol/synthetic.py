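"""Synthetic fruit-ethanol study generator with known ground truth.

Emulates the measurement processes of a two-site frugivory study so every
pipeline stage can be tested end to end without field data:

* species-level ethanol distributions — zero-truncated normals (field
  species means fall around 0.26-0.41 % w/w with SDs of roughly 0.2-0.3,
  and individual fruits can sit at or near zero);
* serial-dilution calibration standard series (e.g. 0.8/0.4/0.2/0.1 %);
* a log-linear MOS sensor voltage response;
* gas-chromatograph traces with a Gaussian ethanol peak whose onset falls
  50-54 s after injection and whose above-baseline area is proportional to
  headspace concentration;
* a linear dichromate absorbance response on slurry supernatant, with
  per-fruit dry-mass fractions.

All randomness flows from explicit integer seeds; identical seeds give
bit-identical outputs.  Noiseless models (``noise_sd = 0``) are exactly
deterministic and exactly invertible by the calibration chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .assays import Cr2Reading, GcTrace, MosReading, gc_integrate_peak
from .calibration import CalibrationSeries
from .errors import InvalidArgumentError

# population ranges used by gen_species_table (uniform draws)
SPECIES_MEAN_RANGE = (0.05, 0.55)  # % w/w; population mean 0.30
SPECIES_SD_RANGE = (0.15, 0.30)  # % w/w
FEEDING_PCT_RANGE = (0.5, 18.0)  # % of annual feeding time

#: smallest concentration the log-linear MOS forward model distinguishes
MOS_DETECTION_FLOOR = 1e-4  # % w/w


@dataclass(frozen=True)
class SpeciesProfile:
    species_name: str
    mean_ethanol: float  # % w/w
    sd_ethanol: float  # % w/w
    feeding_pct: float  # % of annual feeding time
    consumption_location: str = "canopy"  # "ground" or "canopy"

    def __post_init__(self) -> None:
        if self.mean_ethanol < 0 or self.sd_ethanol < 0:
            raise InvalidArgumentError("mean and SD must be nonnegative")
        if not 0 <= self.feeding_pct <= 100:
            raise InvalidArgumentError("feeding_pct must be in [0, 100]")
        if self.consumption_location not in ("ground", "canopy"):
            raise InvalidArgumentError("consumption_location must be ground|canopy")


@dataclass(frozen=True)
class GroundTruthSample:
    sample_id: str
    species_name: str
    true_ethanol: float  # % w/w
    dilution_factor: float = 1.0
    dry_mass_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.true_ethanol < 0:
            raise InvalidArgumentError("true_ethanol must be nonnegative")
        if self.dilution_factor < 1:
            raise InvalidArgumentError("dilution_factor must be >= 1")
        if not 0 <= self.dry_mass_fraction < 1:
            raise InvalidArgumentError("dry_mass_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SensorModel:
    """Forward response model for one assay instrument.

    ``response_params`` keys by method:

    * MOS — ``alpha`` (V), ``beta`` (V per ln %): voltage = alpha +
      beta * ln(max(conc, floor)); ``floor`` optional detection floor.
    * GC — ``gain`` (mV*s per % w/w), ``baseline`` (mV), ``onset_latency``
      (s), ``peak_width`` (s, FWHM), ``dt`` (s), ``duration`` (s).
    * CR2 — ``slope`` (AU per %), ``intercept`` (AU): absorbance =
      slope * conc + intercept.

    ``noise_sd`` is in response units (V, mV on the trace, AU).  For the
    GC, a noisy model also jitters the peak onset uniformly within the
    50-54 s expectation window; a noiseless model uses the fixed
    ``onset_latency`` so repeated simulations are bit-identical.
    """

    method: str
    response_params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("MOS", "GC", "CR2"):
            raise InvalidArgumentError(f"unknown method {self.method!r}")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be nonnegative")
        if self.method == "GC":
            onset = self.response_params.get("onset_latency", 52.0)
            if not 50.0 <= onset <= 54.0:
                raise InvalidArgumentError("GC onset_latency must lie in [50, 54] s")

    # -- default instruments, tuned to the repeatability scales of the
    # field methods (MOS repeat MAE ~0.004 % near 0.10 %; Cr2 ~0.02 %) --

    @classmethod
    def mos(cls, noise_sd: float = 0.025, seed: int = 0) -> "SensorModel":
        return cls(
            "MOS",
            {"alpha": 2.5, "beta": 0.5, "floor": MOS_DETECTION_FLOOR},
            noise_sd,
            seed,
        )

    @classmethod
    def gc(cls, noise_sd: float = 0.5, seed: int = 0) -> "SensorModel":
        return cls(
            "GC",
            {
                "gain": 700.0,
                "baseline": 2.0,
                "onset_latency": 52.0,
                "peak_width": 10.0,
                "dt": 0.1,
                "duration": 120.0,
            },
            noise_sd,
            seed,
        )

    @classmethod
    def cr2(cls, noise_sd: float = 0.018, seed: int = 0) -> "SensorModel":
        return cls("CR2", {"slope": 1.25, "intercept": 0.05}, noise_sd, seed)

    def noiseless(self) -> "SensorModel":
        return replace(self, noise_sd=0.0)


def _substream(seed: int, *tags: int) -> np.random.Generator:
    """Deterministic per-generator substream of one global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


def gen_species_table(n_species: int, seed: int) -> list[SpeciesProfile]:
    """Draw a site's species table: means, SDs, feeding times, locations.

    Means are uniform on ``SPECIES_MEAN_RANGE``, SDs on
    ``SPECIES_SD_RANGE`` and annual feeding percentages on
    ``FEEDING_PCT_RANGE``; consumption location is a fair coin.
    """
    if n_species < 1:
        raise InvalidArgumentError("n_species must be >= 1")
    rng = _substream(seed, 1)
    profiles = []
    for i in range(n_species):
        profiles.append(
            SpeciesProfile(
                species_name=f"Species_{i + 1:03d}",
                mean_ethanol=float(rng.uniform(*SPECIES_MEAN_RANGE)),
                sd_ethanol=float(rng.uniform(*SPECIES_SD_RANGE)),
                feeding_pct=float(rng.uniform(*FEEDING_PCT_RANGE)),
                consumption_location="ground" if rng.random() < 0.5 else "canopy",
            )
        )
    return profiles


def gen_fruit_samples(
    profile: SpeciesProfile,
    n: int,
    seed: int,
    dilution_factor: float = 2.0,
    dry_mass_range: tuple[float, float] = (0.05, 0.25),
) -> list[GroundTruthSample]:
    """Draw fruits from the species' zero-truncated normal ethanol law.

    Truncation is by resampling (redrawing negatives), not clamping, so
    the density stays a proper truncated normal.  ``sd_ethanol = 0`` gives
    every fruit exactly the species mean.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = _substream(seed, 2)
    if profile.sd_ethanol == 0:
        values = np.full(n, profile.mean_ethanol)
    else:
        values = rng.normal(profile.mean_ethanol, profile.sd_ethanol, size=n)
        bad = values < 0
        while bad.any():
            values[bad] = rng.normal(
                profile.mean_ethanol, profile.sd_ethanol, size=int(bad.sum())
            )
            bad = values < 0
    dm = rng.uniform(*dry_mass_range, size=n)
    return [
        GroundTruthSample(
            sample_id=f"{profile.species_name}_{i + 1:03d}",
            species_name=profile.species_name,
            true_ethanol=float(values[i]),
            dilution_factor=dilution_factor,
            dry_mass_fraction=float(dm[i]),
        )
        for i in range(n)
    ]


def truncated_normal_mean(mean: float, sd: float) -> float:
    """Mean of the normal(mean, sd) truncated to [0, inf)."""
    if sd == 0:
        return mean
    a = (0.0 - mean) / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd))


def _forward_response(model: SensorModel, concentration: float) -> float:
    """Noiseless scalar response of MOS/CR2 instruments at a concentration."""
    p = model.response_params
    if model.method == "MOS":
        floor = p.get("floor", MOS_DETECTION_FLOOR)
        return p["alpha"] + p["beta"] * math.log(max(concentration, floor))
    if model.method == "CR2":
        return p["slope"] * concentration + p["intercept"]
    raise InvalidArgumentError(f"no scalar forward response for {model.method}")


def _gc_trace_arrays(
    model: SensorModel, concentration: float, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray]:
    p = model.response_params
    sigma = p["peak_width"] / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # FWHM -> sd
    onset = p["onset_latency"]
    if model.noise_sd > 0 and rng is not None:
        onset = float(rng.uniform(50.0, 54.0))
    center = onset + 3.0 * sigma
    times = np.arange(0.0, p["duration"] + p["dt"] / 2, p["dt"])
    amplitude = p["gain"] * concentration / (sigma * math.sqrt(2.0 * math.pi))
    signal = p["baseline"] + amplitude * np.exp(
        -((times - center) ** 2) / (2.0 * sigma**2)
    )
    if model.noise_sd > 0 and rng is not None:
        signal = signal + rng.normal(0.0, model.noise_sd, size=times.size)
    return times, signal


def simulate_reading(
    sample: GroundTruthSample,
    model: SensorModel,
    rng: np.random.Generator | None = None,
):
    """Simulate one raw instrument reading for a ground-truth fruit.

    MOS sees the headspace of slurry diluted by the sample's dilution
    factor; the GC likewise (typically undiluted); the Cr2 assay sees the
    supernatant, at true / dilution / (1 - dry mass).  Pass a shared
    ``rng`` to draw independent replicate readings; with ``rng=None`` a
    fresh generator seeded from ``model.seed`` is used, so repeated calls
    are identical.
    """
    if rng is None:
        rng = _substream(model.seed, 3)
    if model.method == "MOS":
        conc = sample.true_ethanol / sample.dilution_factor
        v = _forward_response(model, conc)
        if model.noise_sd > 0:
            v += float(rng.normal(0.0, model.noise_sd))
        return MosReading(
            sample_id=sample.sample_id,
            voltage=v,
            dilution_factor=sample.dilution_factor,
        )
    if model.method == "CR2":
        conc = sample.true_ethanol / (
            sample.dilution_factor * (1.0 - sample.dry_mass_fraction)
        )
        a = _forward_response(model, conc)
        if model.noise_sd > 0:
            a += float(rng.normal(0.0, model.noise_sd))
        return Cr2Reading(
            sample_id=sample.sample_id,
            absorbance=a,
            dilution_factor=sample.dilution_factor,
            dry_mass_fraction=sample.dry_mass_fraction,
        )
    # GC
    conc = sample.true_ethanol / sample.dilution_factor
    times, signal = _gc_trace_arrays(model, conc, rng)
    return GcTrace(sample_id=sample.sample_id, times=times, signal=signal)


def gen_calibration_series(
    levels: list[float],
    model: SensorModel,
    label: str = "synthetic",
    role: str = "pooled",
    rng: np.random.Generator | None = None,
    gc_integration: dict | None = None,
) -> CalibrationSeries:
    """Simulate a standard series: one raw response per known level.

    For the GC, each standard is simulated as a full trace and integrated
    with :func:`gc_integrate_peak` (keyword overrides via
    ``gc_integration``), so standards travel the same measurement path as
    samples.
    """
    if not levels:
        raise InvalidArgumentError("need at least one standard level")
    if model.method == "MOS" and any(lvl <= 0 for lvl in levels):
        raise InvalidArgumentError("MOS standards must be > 0 (log response)")
    if any(lvl < 0 for lvl in levels):
        raise InvalidArgumentError("standard levels must be nonnegative")
    if rng is None:
        rng = _substream(model.seed, 4)
    standards = []
    for lvl in levels:
        if model.method == "GC":
            times, signal = _gc_trace_arrays(model, lvl, rng)
            trace = GcTrace(sample_id=f"std_{lvl}", times=times, signal=signal)
            resp = gc_integrate_peak(trace, **(gc_integration or {})).area
        else:
            resp = _forward_response(model, lvl)
            if model.noise_sd > 0:
                resp += float(rng.normal(0.0, model.noise_sd))
        standards.append((float(lvl), float(resp)))
    return CalibrationSeries(
        method=model.method, standards=tuple(standards), label=label, role=role
    )


def simulate_site(
    n_species: int,
    n_per_species: int,
    seed: int,
    model: SensorModel | None = None,
    levels: tuple[float, ...] = (0.8, 0.4, 0.2, 0.1),
):
    """Simulate a whole field site ready for the pipeline.

    Draws a species table, fruits per species, one noisy reading per fruit
    with the given instrument model (default: the Cr2 colorimetric assay)
    and a pre/post pair of calibration standard series.  Returns a dict
    with the generated profiles, ground-truth samples, sample records
    (raw responses), calibration series, feeding-time table, location map
    and the true feeding-time-weighted mean concentration (computed from
    the zero-truncated species means, the actual data-generating means).
    """
    from .exposure import FeedingTimeTable
    from .io import SampleRecord

    if model is None:
        model = SensorModel.cr2(seed=seed)
    profiles = gen_species_table(n_species, seed)
    rng = _substream(seed, 5)
    samples: list[GroundTruthSample] = []
    records: list[SampleRecord] = []
    for k, prof in enumerate(profiles):
        fruits = gen_fruit_samples(prof, n_per_species, seed + 1000 + k)
        for s in fruits:
            reading = simulate_reading(s, model, rng=rng)
            if model.method == "MOS":
                resp = reading.voltage
            elif model.method == "CR2":
                resp = reading.absorbance
            else:
                resp = gc_integrate_peak(reading).area
            records.append(
                SampleRecord(
                    sample_id=s.sample_id,
                    species=s.species_name,
                    method=model.method,
                    response=float(resp),
                    dilution_factor=s.dilution_factor,
                    dry_mass_fraction=s.dry_mass_fraction,
                )
            )
        samples.extend(fruits)
    pre = gen_calibration_series(list(levels), model, label="pre", role="pre", rng=rng)
    post = gen_calibration_series(list(levels), model, label="post", role="post", rng=rng)
    feeding = FeedingTimeTable(
        entries=tuple((p.species_name, p.feeding_pct) for p in profiles),
        site="synthetic",
    )
    locations = {p.species_name: p.consumption_location for p in profiles}
    f = np.array([p.feeding_pct for p in profiles])
    true_means = np.array(
        [truncated_normal_mean(p.mean_ethanol, p.sd_ethanol) for p in profiles]
    )
    true_weighted = float((f / f.sum()) @ true_means)
    return {
        "profiles": profiles,
        "samples": samples,
        "records": records,
        "series": [pre, post],
        "feeding": feeding,
        "locations": locations,
        "true_weighted_mean_pct": true_weighted,
        "true_species_means": dict(zip((p.species_name for p in profiles), true_means)),
    }
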