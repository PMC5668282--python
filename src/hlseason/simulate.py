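"""Synthetic cancer-registry generator with known seasonal ground truth.

The generator emulates a SEER-like Hodgkin-lymphoma case listing with the
statistical structure the seasonality analyses assume, so every pipeline
stage can be exercised — and its estimators validated against known truth
— without access to real registry data:

* the month of diagnosis follows a sinusoid of configurable amplitude and
  peak month, modulated by calendar month lengths, with an optional
  latitude gradient in the amplitude;
* covariate marginals (sex, histology, age group, stage, year bin,
  latitude quartile) default to proportions typical of a large US
  Hodgkin-lymphoma registry cohort;
* survival is exponential with a log-linear covariate hazard including a
  seasonal term of the same sinusoid form the mortality analysis fits
  (``x1 = cos(2 pi (M - m_mort)/12)``) and a latitude × season
  interaction, optionally floored to whole months to induce the heavy
  event-time ties of real month-resolution follow-up;
* censoring combines an administrative follow-up horizon with random
  (exponential) loss to follow-up.

Counties are a packaged fictional table spanning 30–48 °N whose distinct-
county quartile cutpoints are 34.19 / 38.05 / 41.68 °N, so the latitude
stratification logic is exercised with realistic geography-free structure.
Everything is driven by one :class:`numpy.random.Generator` seed and is
fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .incidence import MEAN_MONTH_LENGTH, MONTH_LENGTHS
from .registry import CaseRecord, write_cases
from .survival import WINTER_MONTHS

__all__ = [
    "SimConfig",
    "simulate_registry",
    "table1_marginals",
    "default_counties",
    "write_fixture",
]

#: Age range sampled uniformly within each age-group label.
_AGE_RANGES = {
    "0-19": (0, 19),
    "20-29": (20, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-69": (60, 69),
    ">=70": (70, 84),
}
_YEAR_RANGES = {
    "<1990": (1973, 1989),
    "1990-1999": (1990, 1999),
    "2000-2009": (2000, 2009),
    ">=2010": (2010, 2012),
}


def table1_marginals() -> dict[str, dict[str, float]]:
    """Default covariate marginals for a large US Hodgkin-lymphoma cohort.

    Proportions (renormalized to sum to one) typical of adult + pediatric
    HL in a population-based registry: male predominance, nodular
    sclerosis as the dominant subtype, the bimodal age distribution
    leaning young, and stage II as the most common presentation.
    """
    raw = {
        "sex": {"male": 54.8, "female": 45.2},
        "histology": {
            "lymphocyte-rich": 3.3,
            "mixed-cellularity": 14.9,
            "lymphocyte-depleted": 1.7,
            "nodular-sclerosis": 59.5,
            "NLPHL": 3.9,
            "NOS": 16.7,
        },
        "age_group": {
            "0-19": 12.9,
            "20-29": 23.8,
            "30-39": 19.0,
            "40-49": 13.6,
            "50-59": 10.1,
            "60-69": 8.8,
            ">=70": 11.8,
        },
        "stage": {"I": 21.3, "II": 39.4, "III": 20.6, "IV": 18.7},
        "year_bin": {
            "<1990": 11.1,
            "1990-1999": 21.8,
            "2000-2009": 51.4,
            ">=2010": 15.7,
        },
        "latitude_quartile": {"q1": 19.2, "q2": 30.8, "q3": 24.5, "q4": 25.5},
    }
    return {
        dim: {k: v / sum(weights.values()) for k, v in weights.items()}
        for dim, weights in raw.items()
    }


def default_counties() -> list[tuple[str, float]]:
    """Fictional county table: 40 counties, 10 per latitude quartile.

    Latitudes are evenly spaced within the bands [30, 34.19), [34.19,
    38.05), [38.05, 41.68) and [41.68, 48), so the distinct-county
    quartile cutpoints are exactly 34.19, 38.05 and 41.68 °N.
    """
    bands = [(30.0, 34.19), (34.19, 38.05), (38.05, 41.68), (41.68, 48.0)]
    counties: list[tuple[str, float]] = []
    i = 0
    for lo, hi in bands:
        step = (hi - lo) / 10.0
        for j in range(10):
            counties.append((f"C{i:02d}", round(lo + j * step, 4)))
            i += 1
    return counties


# default per-covariate log-hazards: realistic HL prognostic gradients
# (age dominates; advanced stage and aggressive histologies add risk;
# later diagnosis years carry lower mortality)
_DEFAULT_LOG_HAZARDS: dict[str, float] = {
    "age_per_year": 0.04,  # per year above age 40
    "sex[male]": 0.20,
    "stage[II]": 0.20,
    "stage[III]": 0.60,
    "stage[IV]": 1.00,
    "histology[lymphocyte-rich]": -0.20,
    "histology[mixed-cellularity]": 0.20,
    "histology[lymphocyte-depleted]": 0.60,
    "histology[NLPHL]": -0.40,
    "histology[NOS]": 0.10,
    "year_per_year": -0.02,  # per year after 2000
}


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic registry.

    Defaults reflect the seasonal structure a US-wide HL registry
    exhibits: incidence amplitude 0.077 peaking in March with a northward
    amplitude gradient, and a seasonal mortality term peaking in November
    with a positive latitude interaction.
    """

    n_cases: int = 41405
    seed: int = 0
    # incidence seasonality
    incidence_amplitude: float = 0.077  # a in [0, 1)
    incidence_peak_month: int = 3  # m0
    amplitude_latitude_slope: float = 0.06  # extra amplitude per 10 deg north
    reference_latitude: float = 38.05  # where amplitude equals a
    counties: list[tuple[str, float]] = field(default_factory=default_counties)
    marginals: dict[str, dict[str, float]] = field(default_factory=table1_marginals)
    # mortality
    baseline_monthly_hazard: float = 0.002  # lambda at reference covariates
    covariate_log_hazards: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOG_HAZARDS)
    )
    seasonal_log_hr: float = math.log(1.06)  # gamma on x1(month, m_mort)
    mortality_peak_month: int = 11  # m_mort
    latitude_interaction_log_hr: float = math.log(1.10)  # delta per 10 deg
    seasonal_form: str = "sinusoid"  # or "winter" (dichotomous injection)
    # follow-up
    follow_up_months: float = 120.0  # administrative horizon
    censoring_rate: float = 0.002  # monthly random loss to follow-up
    floor_months: bool = True  # induce event-time ties
    # optional missingness, to exercise the exclusion cascade
    p_flagged: float = 0.0  # death-certificate/autopsy-only
    p_missing_month: float = 0.0
    p_missing_age: float = 0.0
    p_missing_stage: float = 0.0
    registry_id: str = "SYN"

    def validate(self) -> None:
        if not 0 <= self.incidence_amplitude < 1:
            raise ValueError("incidence_amplitude must lie in [0, 1)")
        if not 1 <= self.incidence_peak_month <= 12:
            raise ValueError("incidence_peak_month must be in 1..12")
        if not 1 <= self.mortality_peak_month <= 12:
            raise ValueError("mortality_peak_month must be in 1..12")
        if self.baseline_monthly_hazard <= 0:
            raise ValueError("baseline_monthly_hazard must be positive")
        if self.seasonal_form not in ("sinusoid", "winter"):
            raise ValueError("seasonal_form must be 'sinusoid' or 'winter'")
        lats = [lat for _c, lat in self.counties]
        max_a = self.incidence_amplitude + max(
            0.0,
            self.amplitude_latitude_slope
            * (max(lats) - self.reference_latitude)
            / 10.0,
        )
        if max_a >= 1:
            raise ValueError("effective incidence amplitude reaches 1 at the north")
        for dim, weights in self.marginals.items():
            total = sum(weights.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"marginal {dim!r} sums to {total}, not 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["counties"] = [list(c) for c in d["counties"]]
        return d


def _draw_categorical(
    rng: np.random.Generator, weights: dict[str, float], n: int
) -> np.ndarray:
    labels = list(weights)
    p = np.array([weights[k] for k in labels], dtype=float)
    idx = rng.choice(len(labels), size=n, p=p / p.sum())
    return np.array(labels, dtype=object)[idx]


def simulate_registry(config: SimConfig) -> list[CaseRecord]:
    """Draw a fully synthetic case listing under the configured truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    # --- county and latitude -------------------------------------------
    counties = sorted(config.counties, key=lambda c: c[1])
    county_lats = np.array([lat for _c, lat in counties])
    n_c = len(counties)
    # county weights: quartile marginal split evenly within the quartile
    q_w = config.marginals["latitude_quartile"]
    q_labels = list(q_w)
    per_quartile = n_c // 4
    county_p = np.empty(n_c)
    for qi in range(4):
        county_p[qi * per_quartile : (qi + 1) * per_quartile] = (
            q_w[q_labels[qi]] / per_quartile
        )
    county_idx = rng.choice(n_c, size=n, p=county_p / county_p.sum())
    lat = county_lats[county_idx]

    # --- month of diagnosis --------------------------------------------
    months = np.arange(1, 13)
    base_shape = np.cos(
        2 * np.pi * (months - config.incidence_peak_month) / 12.0
    )
    length_w = MONTH_LENGTHS / MEAN_MONTH_LENGTH
    month_dx = np.empty(n, dtype=int)
    for ci in range(n_c):
        mask = county_idx == ci
        m = int(mask.sum())
        if m == 0:
            continue
        a_eff = config.incidence_amplitude + config.amplitude_latitude_slope * (
            county_lats[ci] - config.reference_latitude
        ) / 10.0
        a_eff = min(max(a_eff, 0.0), 0.999)
        p = (1.0 + a_eff * base_shape) * length_w
        month_dx[mask] = rng.choice(months, size=m, p=p / p.sum())

    # --- covariates -----------------------------------------------------
    sex = _draw_categorical(rng, config.marginals["sex"], n)
    histology = _draw_categorical(rng, config.marginals["histology"], n)
    stage = _draw_categorical(rng, config.marginals["stage"], n)
    age_group = _draw_categorical(rng, config.marginals["age_group"], n)
    year_bin = _draw_categorical(rng, config.marginals["year_bin"], n)
    age = np.empty(n, dtype=int)
    for label, (lo, hi) in _AGE_RANGES.items():
        mask = age_group == label
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    year = np.empty(n, dtype=int)
    for label, (lo, hi) in _YEAR_RANGES.items():
        mask = year_bin == label
        year[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    # --- hazard and follow-up ------------------------------------------
    lh = config.covariate_log_hazards
    lp = lh.get("age_per_year", 0.0) * (age - 40.0)
    lp = lp + lh.get("year_per_year", 0.0) * (year - 2000.0)
    for name, arr in (("sex", sex), ("histology", histology), ("stage", stage)):
        for level in np.unique(arr):
            coef = lh.get(f"{name}[{level}]", 0.0)
            if coef:
                lp = lp + coef * (arr == level)
    if config.seasonal_form == "sinusoid":
        season_term = np.cos(
            2 * np.pi * (month_dx - config.mortality_peak_month) / 12.0
        )
    else:  # dichotomous winter injection
        season_term = np.isin(month_dx, list(WINTER_MONTHS)).astype(float)
    lp = lp + config.seasonal_log_hr * season_term
    lp = lp + config.latitude_interaction_log_hr * season_term * (
        lat - config.reference_latitude
    ) / 10.0

    rate = config.baseline_monthly_hazard * np.exp(lp)
    t_death = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.follow_up_months)
    time = np.minimum(t_death, t_cens)
    event = t_death <= t_cens
    if config.floor_months:
        time = np.floor(time)

    # --- optional missingness / flags ----------------------------------
    flagged = rng.random(n) < config.p_flagged
    flag_kind = rng.random(n) < 0.5  # split flagged between the two kinds
    miss_month = rng.random(n) < config.p_missing_month
    miss_age = rng.random(n) < config.p_missing_age
    miss_stage = rng.random(n) < config.p_missing_stage

    cases: list[CaseRecord] = []
    for i in range(n):
        flags = "none"
        if flagged[i]:
            flags = "death-certificate-only" if flag_kind[i] else "autopsy-only"
        cases.append(
            CaseRecord(
                case_id=f"S{i:06d}",
                month_dx=None if miss_month[i] else int(month_dx[i]),
                year_dx=int(year[i]),
                age_years=None if miss_age[i] else int(age[i]),
                sex=str(sex[i]),
                histology=str(histology[i]),
                stage=None if miss_stage[i] else str(stage[i]),
                county_latitude=float(lat[i]),
                survival_months=float(time[i]),
                event="death" if event[i] else "censored",
                flags=flags,
                registry_id=config.registry_id,
            )
        )
    return cases


def write_fixture(
    cases: Sequence[CaseRecord],
    path: str | Path,
    config: SimConfig | None = None,
) -> None:
    """Write cases as a canonical case-listing CSV plus a manifest JSON.

    The manifest records the generating configuration (including the
    seed) next to the fixture, so a fixture is always re-derivable.
    Output is byte-identical across runs with the same configuration.
    """
    path = Path(path)
    write_cases(cases, path)
    if config is not None:
        manifest = {"n_cases_written": len(cases), "config": config.to_dict()}
        path.with_suffix(".manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
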