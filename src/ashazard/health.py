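"""Population exposure accounting and dose-response cancer risk.

The band map is overlaid on a population-density raster to count the
population living in each concentration band.  Cells are classed rural or
urban by a density threshold (default 400 persons/km²) and the population
drawing untreated groundwater is estimated with usage fractions — by
default 48% of rural and 29% of urban households.

Health effects use the multistage dose-response forms for arsenic-induced
cancers, with nonnegative parameters q1, q2 (linear and quadratic potency),
k (stage exponent) and m (onset age) and a Heaviside onset at age m:

* lifetime skin-cancer prevalence ratio
  ``p(c, t) = 1 − exp(−(q1·c + q2·c²)·(t − m)^k · H(t − m))``
* internal-cancer (lung, bladder, liver) incidence rate per year
  ``h(c, t) = k·(q1·c + q2·c²)·(t − m)^(k−1) · H(t − m)``

where c is the arsenic concentration (µg/L) and t the age (years).  The
two are linked by h = d/dt[−ln(1 − p)].  Aggregation sums over bands,
rural/urban strata, sexes and age bins of the exposed population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GeometryError, GridGeometry
from .hazard import BandMap
from .synthetic import AgeStructure

F_RURAL = 0.48
F_URBAN = 0.29
RURAL_DENSITY_MAX = 400.0  # persons/km²; denser cells count as urban

#: Representative concentration per band (µg/L): band midpoints, with the
#: open-ended top band pegged at 15 µg/L.  Editable per run; results scale
#: through the dose-response curves.
def default_band_concentrations(thresholds=(2.0, 3.0, 4.0, 5.0, 10.0)) -> dict[str, float]:
    t = sorted(thresholds)
    from .hazard import band_labels

    labels = band_labels(t)
    concs = {labels[0]: t[0] / 2.0}
    for lab, lo, hi in zip(labels[1:-1], t[:-1], t[1:]):
        concs[lab] = (lo + hi) / 2.0
    concs[labels[-1]] = 15.0
    return concs


@dataclass(frozen=True)
class DoseResponseParams:
    """Multistage parameters for one cancer type and sex."""

    q1: float  # per µg/L per year^k
    q2: float  # per (µg/L)² per year^k
    k: float
    m: float  # onset age, years

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "k", "m"):
            if getattr(self, name) < 0:
                raise ValueError(f"dose-response parameter {name} must be nonnegative")


#: Package-default multistage potencies, one entry per cancer type and sex.
#: These are generic order-of-magnitude values in the NRC/Brown multistage
#: form chosen so that a low-hazard region (most exposure below 5 µg/L)
#: yields a small burden relative to the exposed population: a few hundred
#: prevalent skin-cancer cases and of order ten internal-cancer fatalities
#: per year per ~30 M exposed.  They are a starting point for
#: configuration, not authoritative epidemiology — any real assessment
#: must substitute potencies fitted to the relevant cohort.
DEFAULT_DR_PARAMS: dict[str, dict[str, dict[str, float]]] = {
    "skin": {
        "male": {"q1": 1.5e-8, "q2": 1.0e-9, "k": 2.0, "m": 0.0},
        "female": {"q1": 0.6e-8, "q2": 0.4e-9, "k": 2.0, "m": 0.0},
    },
    "lung": {
        "male": {"q1": 2.0e-10, "q2": 0.0, "k": 3.0, "m": 10.0},
        "female": {"q1": 1.0e-10, "q2": 0.0, "k": 3.0, "m": 10.0},
    },
    "bladder": {
        "male": {"q1": 4.0e-11, "q2": 0.0, "k": 3.0, "m": 10.0},
        "female": {"q1": 2.0e-11, "q2": 0.0, "k": 3.0, "m": 10.0},
    },
    "liver": {
        "male": {"q1": 4.0e-11, "q2": 0.0, "k": 3.0, "m": 10.0},
        "female": {"q1": 2.0e-11, "q2": 0.0, "k": 3.0, "m": 10.0},
    },
}


def band_population(
    band_map: BandMap,
    density: np.ndarray,
    geometry: GridGeometry,
    density_threshold: float | None = RURAL_DENSITY_MAX,
) -> pd.DataFrame:
    """Zonal population per band, optionally split rural/urban.

    Returns a frame indexed by band label with a ``population`` column and,
    when ``density_threshold`` is given, ``rural`` and ``urban`` columns
    (rural = density ≤ threshold).
    """
    if geometry != band_map.geometry:
        raise GeometryError("population grid is not co-registered with the band map")
    persons = np.asarray(density, dtype=float) * geometry.cell_area
    if np.any(persons < 0):
        raise ValueError("population density must be non-negative")
    bands = band_map.bands
    valid = bands >= 0
    nb = len(band_map.labels)
    out = {"population": np.bincount(bands[valid], weights=persons[valid], minlength=nb)}
    if density_threshold is not None:
        rural = valid & (np.asarray(density) <= density_threshold)
        urban = valid & ~rural
        out["rural"] = np.bincount(bands[rural], weights=persons[rural], minlength=nb)
        out["urban"] = np.bincount(bands[urban], weights=persons[urban], minlength=nb)
    return pd.DataFrame(out, index=list(band_map.labels))


def exposed_population(
    band_pops: pd.DataFrame,
    f_rural: float = F_RURAL,
    f_urban: float = F_URBAN,
) -> pd.DataFrame:
    """Exposure table: per band, population and exposed population.

    ``band_pops`` needs ``rural`` and ``urban`` columns (persons).  Exposed
    = rural × f_rural + urban × f_urban.  A ``Total`` row of column sums is
    appended.
    """
    for f, name in ((f_rural, "f_rural"), (f_urban, "f_urban")):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if np.any(band_pops[["rural", "urban"]].to_numpy() < 0):
        raise ValueError("populations must be non-negative")
    tab = band_pops.copy()
    if "population" not in tab:
        tab["population"] = tab["rural"] + tab["urban"]
    tab["exposed_rural"] = tab["rural"] * f_rural
    tab["exposed_urban"] = tab["urban"] * f_urban
    tab["exposed"] = tab["exposed_rural"] + tab["exposed_urban"]
    tab.loc["Total"] = tab.sum(axis=0)
    return tab


def _dose_term(c, params: DoseResponseParams):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    return params.q1 * c + params.q2 * c**2


def skin_prevalence(c, t, params: DoseResponseParams):
    """Lifetime prevalence ratio p(c, t); zero before onset age or at c=0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    g = _dose_term(c, params)
    dt = t - params.m
    onset = dt >= 0
    p = np.where(onset, 1.0 - np.exp(-g * np.where(onset, dt, 0.0) ** params.k), 0.0)
    if p.ndim == 0:
        return float(p)
    return p


def internal_incidence(c, t, params: DoseResponseParams):
    """Age-specific incidence rate h(c, t) per year; zero before onset.

    At t = m with k < 1 the rate diverges, which is rejected; k ≥ 1 uses
    the continuous limit (0 for k > 1, the flat hazard for k = 1).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    g = _dose_term(c, params)
    dt = t - params.m
    at_onset = dt == 0
    if params.k < 1.0 and np.any(at_onset & (np.asarray(g) > 0)):
        raise ValueError("incidence diverges at t = m for k < 1")
    safe_dt = np.where(dt > 0, dt, 1.0)
    h = np.where(
        dt > 0,
        params.k * g * safe_dt ** (params.k - 1.0),
        np.where(at_onset & (params.k == 1.0), params.k * g, 0.0),
    )
    if h.ndim == 0:
        return float(h)
    return h


def aggregate_health(
    exposure: pd.DataFrame,
    band_concentrations: dict[str, float],
    ages: AgeStructure,
    params: dict[str, dict[str, DoseResponseParams]],
    skin_cancers: tuple[str, ...] = ("skin",),
    decimals: int | None = 0,
) -> pd.DataFrame:
    """Expected cancer burden of the exposed population.

    ``params`` maps cancer type → sex → :class:`DoseResponseParams`.  For
    skin cancers the entries are prevalent cases (persons); for the others,
    incident fatalities per year.  Rows are cancer types; columns are
    (stratum, sex) pairs plus a ``Total``.  Ages are evaluated at bin
    midpoints of the sex/age pyramid; every output is linear in the
    exposed population.
    """
    body = exposure.drop(index="Total", errors="ignore")
    strata = {"rural": "exposed_rural", "urban": "exposed_urban"}
    cols: dict[tuple[str, str], dict[str, float]] = {}
    for cancer, by_sex in params.items():
        is_prev = cancer in skin_cancers
        for stratum, col in strata.items():
            for sex in ("male", "female"):
                if sex not in by_sex:
                    raise KeyError(f"missing dose-response params for {cancer}/{sex}")
                pr = by_sex[sex]
                total = 0.0
                for band, exposed in body[col].items():
                    c = band_concentrations.get(str(band))
                    if c is None:
                        raise KeyError(f"no representative concentration for band {band!r}")
                    for lo, hi, prop in ages.bins[sex]:
                        t_mid = 0.5 * (lo + hi)
                        persons = exposed * ages.sex_fraction(sex) * prop
                        rate = (
                            skin_prevalence(c, t_mid, pr)
                            if is_prev
                            else internal_incidence(c, t_mid, pr)
                        )
                        total += persons * rate
                cols.setdefault((stratum, sex), {})[cancer] = total
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stratum", "sex"])
    out[("Total", "")] = out.sum(axis=1)
    if decimals is not None:
        out = out.round(decimals)
    return out
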