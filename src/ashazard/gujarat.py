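"""Published Gujarat reference figures used as worked-example inputs.

Values transcribed from the published state-wide groundwater arsenic
assessment for Gujarat (India) that this package's method follows: the 2015
Central Ground Water Board survey counts, the exposure table and the
modelled health-effects table.  They serve as fixed *inputs* for arithmetic
cross-checks (shares, totals) — the underlying well dataset and covariate
rasters are not publicly deposited, so the full tables cannot be recomputed
from raw data here.
"""

from __future__ import annotations

import pandas as pd

#: 2015 survey: samples reported, excluded as not analysed ("nd"), excluded
#: for missing location, and the usable remainder.
RAW_SAMPLES = 599
NOT_ANALYSED = 183
MISSING_LOCATION = 18
USABLE_SAMPLES = 398

#: Usable records whose concentration strictly exceeds each threshold (µg/L).
EXCEEDANCE_COUNTS: dict[float, int] = {
    10.0: 24, 5.0: 57, 4.0: 78, 3.0: 124, 2.0: 185, 1.0: 301,
}

#: Projected total state population used in the exposure assessment.
TOTAL_POPULATION = 70_445_000

#: Calibrated sensitivity = specificity cutoffs of the five mapped models.
PUBLISHED_CUTOFFS: dict[float, float] = {
    10.0: 0.69, 5.0: 0.66, 4.0: 0.61, 3.0: 0.57, 2.0: 0.50,
}

#: Exposure assessment: population living in each modelled concentration
#: band, and the subset drawing untreated groundwater (persons).
BAND_ORDER = (">10", "5-10", "4-5", "3-4", "2-3", "<2")
POPULATION_BY_BAND: dict[str, int] = {
    ">10": 122_000,
    "5-10": 206_000,
    "4-5": 1_773_000,
    "3-4": 5_011_000,
    "2-3": 32_981_000,
    "<2": 30_351_000,
}
EXPOSED_BY_BAND: dict[str, int] = {
    ">10": 49_000,
    "5-10": 82_000,
    "4-5": 708_000,
    "3-4": 2_000_000,
    "2-3": 13_162_000,
    "<2": 12_113_000,
}
PUBLISHED_POPULATION_TOTAL = 70_444_000
PUBLISHED_EXPOSED_TOTAL = 28_114_000

#: Modelled health effects by (stratum, sex): prevalent skin-cancer cases
#: (persons) and internal-cancer incidence (fatalities per year).
HEALTH_STRATA = (("rural", "male"), ("rural", "female"),
                 ("urban", "male"), ("urban", "female"))
SKIN_PREVALENCE_CASES = {("rural", "male"): 380, ("rural", "female"): 80,
                         ("urban", "male"): 180, ("urban", "female"): 30}
LUNG_INCIDENCE = {("rural", "male"): 8, ("rural", "female"): 0,
                  ("urban", "male"): 4, ("urban", "female"): 0}
BLADDER_INCIDENCE = {s: 0 for s in HEALTH_STRATA}
LIVER_INCIDENCE = {s: 0 for s in HEALTH_STRATA}
PUBLISHED_SKIN_TOTAL = 670
PUBLISHED_INTERNAL_TOTAL = 12


def exposure_table() -> pd.DataFrame:
    """The published exposure table as a band-indexed frame (no totals)."""
    return pd.DataFrame(
        {
            "population": POPULATION_BY_BAND,
            "exposed": EXPOSED_BY_BAND,
        }
    ).loc[list(BAND_ORDER)]


def health_table() -> pd.DataFrame:
    """The published health-effects table, rows = cancer, cols = strata."""
    return pd.DataFrame(
        {
            "skin": SKIN_PREVALENCE_CASES,
            "lung": LUNG_INCIDENCE,
            "bladder": BLADDER_INCIDENCE,
            "liver": LIVER_INCIDENCE,
        }
    ).T
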