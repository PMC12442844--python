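"""Species-level summaries and feeding-time-weighted ethanol exposure.

The dietary exposure statistic is a weighted average of species-level mean
ethanol concentrations, with weights proportional to the annual percentage
of feeding time a chimpanzee community devotes to each fruit species,
renormalised over the sampled species.  Species with fewer than three
assayed ripe fruits are excluded.  Congeneric species may be pooled (e.g.
figs reported as *Ficus* spp.), concatenating their samples and summing
their feeding percentages.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError, MissingWeightError

MIN_SAMPLES_PER_SPECIES = 3


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species ethanol mean/SD over its ripe-fruit samples."""

    species_name: str
    n: int
    mean_pct: float
    sd_pct: float
    methods: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FeedingTimeTable:
    """Annual % feeding time per species at one site.

    ``fruit_fraction_of_diet`` is the share of total feeding time spent on
    fruit (0.71 at Ngogo, 0.76 at Tai); it feeds the dosage stage, not the
    weighting, which uses the per-species percentages directly.
    """

    entries: tuple[tuple[str, float], ...]
    site: str = ""
    fruit_fraction_of_diet: float = 1.0

    def __post_init__(self) -> None:
        ent = tuple((_norm(s), float(p)) for s, p in self.entries)
        object.__setattr__(self, "entries", ent)
        if any(p <= 0 for _, p in ent):
            raise InvalidArgumentError("annual feeding percentages must be positive")
        if not 0 < self.fruit_fraction_of_diet <= 1:
            raise InvalidArgumentError("fruit_fraction_of_diet must be in (0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)


@dataclass(frozen=True)
class WeightedExposure:
    weighted_mean_pct: float
    weighted_sd_pct: float
    coverage_pct: float  # summed feeding % of the sampled species
    contributions: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False  # all species means zero: contributions undefined


def _norm(name: str) -> str:
    return " ".join(name.split())


def summarize_species(
    samples: list[tuple[str, float]],
    min_n: int = MIN_SAMPLES_PER_SPECIES,
    methods: dict[str, set[str]] | None = None,
) -> list[SpeciesSummary]:
    """Group samples by species; keep species with at least ``min_n`` fruits.

    Mean is the arithmetic mean, SD the sample standard deviation (n - 1
    denominator).  Species names are grouped after whitespace
    normalisation.  An empty input yields an empty list.
    """
    groups: OrderedDict[str, list[float]] = OrderedDict()
    for name, conc in samples:
        if conc < 0:
            raise InvalidArgumentError(f"negative concentration for {name!r}")
        groups.setdefault(_norm(name), []).append(float(conc))
    out = []
    for name, vals in groups.items():
        if len(vals) < min_n:
            continue
        arr = np.array(vals)
        out.append(
            SpeciesSummary(
                species_name=name,
                n=arr.size,
                mean_pct=float(arr.mean()),
                sd_pct=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                methods=frozenset(methods.get(name, set())) if methods else frozenset(),
            )
        )
    return out


def pool_species(samples_or_table, group_map: dict[str, str]):
    """Pool species under shared names (e.g. two figs as "Ficus spp.").

    Accepts either a list of ``(species, concentration)`` samples — whose
    grouped species are simply relabelled, concatenating their samples —
    or a :class:`FeedingTimeTable`, whose grouped feeding percentages are
    summed.  Species absent from ``group_map`` pass through unchanged;
    names in the map that do not occur in the input are an error.
    """
    gmap = {_norm(k): _norm(v) for k, v in group_map.items()}
    if isinstance(samples_or_table, FeedingTimeTable):
        known = {s for s, _ in samples_or_table.entries}
        _check_known(gmap, known)
        pooled: OrderedDict[str, float] = OrderedDict()
        for name, pct in samples_or_table.entries:
            target = gmap.get(name, name)
            pooled[target] = pooled.get(target, 0.0) + pct
        return replace(samples_or_table, entries=tuple(pooled.items()))
    samples = list(samples_or_table)
    _check_known(gmap, {_norm(s) for s, _ in samples})
    return [(gmap.get(_norm(s), _norm(s)), c) for s, c in samples]


def _check_known(gmap: dict[str, str], known: set[str]) -> None:
    unknown = set(gmap) - known
    if unknown:
        raise InvalidArgumentError(f"group_map names unknown species: {sorted(unknown)}")


def weighted_concentration(
    summaries: list[SpeciesSummary], feeding: FeedingTimeTable
) -> WeightedExposure:
    """Feeding-time-weighted mean ethanol concentration across species.

    Each sampled species' feeding percentage is divided by the summed
    percentage over sampled species (w_i = f_i / sum f_j) and multiplied by
    that species' mean concentration; the products sum to the weighted
    mean.  ``contributions`` maps each species to its fraction of that
    mean.  The weighted SD is the feeding-weighted SD of the species means,
    sqrt(sum w_i (mean_i - weighted_mean)^2).
    """
    if not summaries:
        raise InsufficientDataError("no species summaries to weight")
    fmap = feeding.as_dict()
    missing = [s.species_name for s in summaries if s.species_name not in fmap]
    if missing:
        raise MissingWeightError(f"no feeding-time entry for species: {missing}")
    f = np.array([fmap[s.species_name] for s in summaries])
    means = np.array([s.mean_pct for s in summaries])
    coverage = float(f.sum())
    w = f / f.sum()
    wmean = float(w @ means)
    wsd = float(math.sqrt(w @ (means - wmean) ** 2))
    if wmean > 0:
        contributions = {
            s.species_name: float(wi * mi / wmean)
            for s, wi, mi in zip(summaries, w, means)
        }
        degenerate = False
    else:
        contributions = {s.species_name: 0.0 for s in summaries}
        degenerate = True
    return WeightedExposure(
        weighted_mean_pct=wmean,
        weighted_sd_pct=wsd,
        coverage_pct=coverage,
        contributions=contributions,
        degenerate=degenerate,
    )


def location_contrast(
    summaries: list[SpeciesSummary], locations
) -> tuple[float, float, float, float, float]:
    """Welch t test of species-mean ethanol, ground- vs canopy-fed species.

    The unit of analysis is the species (one mean per species).
    ``locations`` is either a mapping species -> "ground"/"canopy" or a
    list of species profiles carrying ``consumption_location``.  Returns
    (ground_mean, canopy_mean, t, Welch df, two-sided p).  Two identical
    constant groups are the exact null: t = 0, p = 1.
    """
    if not isinstance(locations, dict):
        locations = {p.species_name: p.consumption_location for p in locations}
    loc = {_norm(k): v for k, v in locations.items()}
    ground, canopy = [], []
    for s in summaries:
        where = loc.get(s.species_name)
        if where == "ground":
            ground.append(s.mean_pct)
        elif where == "canopy":
            canopy.append(s.mean_pct)
        else:
            raise InvalidArgumentError(
                f"species {s.species_name!r} lacks a ground/canopy label"
            )
    if len(ground) < 2 or len(canopy) < 2:
        raise InsufficientDataError("need >= 2 species per consumption location")
    g, c = np.array(ground), np.array(canopy)
    if g.std(ddof=1) == 0 and c.std(ddof=1) == 0 and g.mean() == c.mean():
        return float(g.mean()), float(c.mean()), 0.0, float(g.size + c.size - 2), 1.0
    res = stats.ttest_ind(g, c, equal_var=False)
    return (
        float(g.mean()),
        float(c.mean()),
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
    )
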