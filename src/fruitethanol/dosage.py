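"""Daily ethanol intake, body-mass-specific dosage and standard drinks.

The chain mirrors the exposure-to-dosage table of the study: daily fruit
mass = bulk food intake x fruit fraction of diet; ethanol grams = fruit
mass x weighted concentration (% w/w) / 100; dosage = grams / body mass;
standard drinks = dosage / (grams-per-drink / reference human mass), i.e.
0.14 g/kg per 10-g drink at 70 kg.  The weighted concentration's SD is the
sole propagated uncertainty — every step is linear in concentration, so
the SD simply scales along.  All intermediates are kept at full precision;
rounding is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidArgumentError
from .exposure import WeightedExposure


@dataclass(frozen=True)
class SiteSexParams:
    """Literature-derived intake and body-mass constants for one site/sex."""

    site: str
    sex: str  # "F" or "M"
    body_mass: float  # kg
    bulk_food: float  # g/day, all dietary categories
    fruit_fraction: float  # fraction of diet that is fruit

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise InvalidArgumentError("sex must be 'F' or 'M'")
        if min(self.body_mass, self.bulk_food, self.fruit_fraction) <= 0:
            raise InvalidArgumentError("body_mass, bulk_food, fruit_fraction must be > 0")
        if self.fruit_fraction > 1:
            raise InvalidArgumentError("fruit_fraction must be <= 1")


@dataclass(frozen=True)
class DrinkStandard:
    """International standard-drink convention: 10 g ethanol, 70-kg human."""

    grams_per_drink: float = 10.0
    reference_mass: float = 70.0

    def __post_init__(self) -> None:
        if self.grams_per_drink <= 0 or self.reference_mass <= 0:
            raise InvalidArgumentError("drink standard values must be positive")

    @property
    def dose_per_drink(self) -> float:
        """g/kg/day represented by one drink (0.14 by default)."""
        return self.grams_per_drink / self.reference_mass


@dataclass(frozen=True)
class DosageResult:
    site: str
    sex: str
    body_mass: float
    fruit_g_per_day: float
    concentration_pct: float
    concentration_sd: float
    ethanol_g_per_day: float
    ethanol_g_sd: float
    dose_g_per_kg_day: float
    dose_sd: float
    standard_drinks: float
    drinks_sd: float

    def display_row(self) -> dict[str, str]:
        """Printed-precision row: grams to 1 dp, dose to 2 dp, drinks to 1 dp."""
        return {
            "site": self.site,
            "sex": self.sex,
            "body_mass_kg": f"{self.body_mass:.1f}",
            "fruit_g": f"{self.fruit_g_per_day:.0f}",
            "ethanol_pct": f"{self.concentration_pct:.2f} ({self.concentration_sd:.2f})",
            "ethanol_g": f"{self.ethanol_g_per_day:.1f} ({self.ethanol_g_sd:.1f})",
            "dose_g_per_kg_day": f"{self.dose_g_per_kg_day:.2f} ({self.dose_sd:.2f})",
            "standard_drinks": f"{self.standard_drinks:.1f} ({self.drinks_sd:.1f})",
        }


def daily_fruit_mass(params: SiteSexParams) -> float:
    """Grams of fruit eaten per day: bulk food x fruit fraction of diet."""
    return params.bulk_food * params.fruit_fraction


def ethanol_grams(
    fruit_g: float, concentration_pct: float, concentration_sd: float = 0.0
) -> tuple[float, float]:
    """Daily grams of pure ethanol, with the concentration SD scaled along."""
    if min(fruit_g, concentration_pct, concentration_sd) < 0:
        raise InvalidArgumentError("inputs must be nonnegative")
    scale = fruit_g / 100.0
    return concentration_pct * scale, concentration_sd * scale


def dose_per_kg(
    ethanol_g: float, body_mass: float, ethanol_sd: float = 0.0
) -> tuple[float, float]:
    """Body-mass-specific dosage in g/kg/day (value and SD)."""
    if body_mass <= 0:
        raise InvalidArgumentError("body_mass must be positive")
    return ethanol_g / body_mass, ethanol_sd / body_mass


def standard_drinks(
    dose: float, standard: DrinkStandard = DrinkStandard(), dose_sd: float = 0.0
) -> tuple[float, float]:
    """Daily standard-drink equivalents: dose / (g per drink / reference kg)."""
    per_drink = standard.dose_per_drink
    return dose / per_drink, dose_sd / per_drink


def site_dosage_table(
    params: list[SiteSexParams],
    exposure_by_site: WeightedExposure | dict[str, WeightedExposure],
    standard: DrinkStandard = DrinkStandard(),
) -> list[DosageResult]:
    """Compose the full dosage chain for each site/sex row.

    ``exposure_by_site`` may be a single :class:`WeightedExposure` applied
    to every row or a mapping from site name to exposure.  Full precision
    is carried throughout; use :meth:`DosageResult.display_row` to round.
    """
    if not params:
        raise InvalidArgumentError("no site/sex parameter rows")
    out = []
    for p in params:
        exp = (
            exposure_by_site[p.site]
            if isinstance(exposure_by_site, dict)
            else exposure_by_site
        )
        fruit_g = daily_fruit_mass(p)
        g, g_sd = ethanol_grams(fruit_g, exp.weighted_mean_pct, exp.weighted_sd_pct)
        dose, d_sd = dose_per_kg(g, p.body_mass, g_sd)
        drinks, dr_sd = standard_drinks(dose, standard, d_sd)
        out.append(
            DosageResult(
                site=p.site,
                sex=p.sex,
                body_mass=p.body_mass,
                fruit_g_per_day=fruit_g,
                concentration_pct=exp.weighted_mean_pct,
                concentration_sd=exp.weighted_sd_pct,
                ethanol_g_per_day=g,
                ethanol_g_sd=g_sd,
                dose_g_per_kg_day=dose,
                dose_sd=d_sd,
                standard_drinks=drinks,
                drinks_sd=dr_sd,
            )
        )
    return out
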