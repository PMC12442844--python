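"""Published study constants used as pipeline inputs.

Literature-derived intake and body-mass parameters for the two long-term
chimpanzee study sites (Ngogo, Uganda; Tai, Cote d'Ivoire), the
international standard-drink convention, and the site-level weighted
ethanol concentrations and cross-validation error components reported for
those sites.  These are configuration constants, not computed here.
"""

from __future__ import annotations

from .dosage import DrinkStandard, SiteSexParams
from .exposure import WeightedExposure

#: fraction of total feeding time spent on fruit
NGOGO_FRUIT_FRACTION = 0.71
TAI_FRUIT_FRACTION = 0.76

#: bulk food intake (g/day, all dietary categories) and adult body mass (kg)
SITE_SEX_PARAMS: list[SiteSexParams] = [
    SiteSexParams("Ngogo", "F", body_mass=35.9, bulk_food=6020.0, fruit_fraction=NGOGO_FRUIT_FRACTION),
    SiteSexParams("Ngogo", "M", body_mass=42.0, bulk_food=6333.0, fruit_fraction=NGOGO_FRUIT_FRACTION),
    SiteSexParams("Tai", "F", body_mass=41.6, bulk_food=6020.0, fruit_fraction=TAI_FRUIT_FRACTION),
    SiteSexParams("Tai", "M", body_mass=46.3, bulk_food=6333.0, fruit_fraction=TAI_FRUIT_FRACTION),
]

#: 10 g of pure ethanol per drink, referenced to a 70-kg human
INTERNATIONAL_DRINK = DrinkStandard(grams_per_drink=10.0, reference_mass=70.0)

#: site-level feeding-time-weighted ethanol concentration (% w/w, +/- SD)
SITE_WEIGHTED_EXPOSURE: dict[str, WeightedExposure] = {
    "Ngogo": WeightedExposure(
        weighted_mean_pct=0.32, weighted_sd_pct=0.20, coverage_pct=79.0
    ),
    "Tai": WeightedExposure(
        weighted_mean_pct=0.31, weighted_sd_pct=0.21, coverage_pct=32.0
    ),
}

#: per-standard-level combined (two-method) maximum calibration errors from
#: the Cr2/MOS cross-validation, % w/w, keyed by nominal standard level
CROSS_VALIDATION_BIN_ERRORS: dict[float, float] = {
    0.1: 0.07,
    0.2: 0.13,
    0.4: 0.06,
    0.8: 0.09,
}

#: repeat-sampling error component of the cross-validation budget (% w/w)
CROSS_VALIDATION_REPEAT_ERROR = 0.05

#: serial-dilution standard levels (% w/w) by assay campaign
MOS_TAI_LEVELS = [0.8, 0.4, 0.2, 0.1]
GC_LEVELS = [2.4, 1.2, 0.6, 0.3, 0.15]
CR2_LEVELS = [0.8, 0.4, 0.2, 0.1]
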