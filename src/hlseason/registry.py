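"""Cancer-registry case listings: data model, CSV I/O, exclusions, strata.

A case listing is one row per diagnosed case carrying the timing of
diagnosis (calendar month and year), demographic and disease covariates,
the latitude of the county of diagnosis, and follow-up (survival time in
months plus vital status).  This module provides the :class:`CaseRecord`
container, loading/writing of the canonical CSV schema, a sequential
exclusion cascade with per-rule accounting, and the stratifications used
throughout the seasonality analyses: age groups, county-latitude quartiles,
the north/south county split, the meteorological winter/summer half-years
(September–February vs March–August) and year-of-diagnosis bins.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "SEXES",
    "HISTOLOGIES",
    "STAGES",
    "FLAGS",
    "CANONICAL_COLUMNS",
    "CaseRecord",
    "ExclusionReport",
    "ExclusionStep",
    "StratumScheme",
    "load_cases",
    "write_cases",
    "apply_exclusions",
    "latitude_quartile_cutpoints",
    "assign_strata",
]

SEXES = ("male", "female")
HISTOLOGIES = (
    "lymphocyte-rich",
    "mixed-cellularity",
    "lymphocyte-depleted",
    "nodular-sclerosis",
    "NLPHL",
    "NOS",
)
STAGES = ("I", "II", "III", "IV")
FLAGS = ("death-certificate-only", "autopsy-only", "none")

#: Canonical case-listing CSV columns, in writing order.
CANONICAL_COLUMNS = (
    "case_id",
    "month_dx",
    "year_dx",
    "age_years",
    "sex",
    "histology",
    "stage",
    "county_latitude",
    "survival_months",
    "event",
    "flags",
    "registry_id",
)

#: Sentinels accepted as "missing" in CSV cells.
_MISSING = {"", "NA", "na", "NaN", "nan", "None"}


class RegistryConfigError(ValueError):
    """Configuration problem: unknown rule, missing column, bad mapping."""


class RegistryDataError(ValueError):
    """A data value violates the case-listing contract."""


@dataclass
class CaseRecord:
    """One registry case.

    ``month_dx``, ``age_years`` and ``stage`` may be ``None`` (unknown);
    the exclusion cascade removes such cases before analysis.  Stratum
    labels are filled in by :func:`assign_strata`.
    """

    case_id: str
    month_dx: int | None
    year_dx: int
    age_years: int | None
    sex: str
    histology: str
    stage: str | None
    county_latitude: float
    survival_months: float
    event: str  # "death" | "censored"
    flags: str = "none"
    registry_id: str = ""
    # stratum labels (set by assign_strata)
    age_group: str | None = None
    latitude_quartile: int | None = None
    north_south: str | None = None
    season: str | None = None
    year_bin: str | None = None

    def __post_init__(self) -> None:
        if self.month_dx is not None and not 1 <= int(self.month_dx) <= 12:
            raise RegistryDataError(
                f"month_dx must be in 1..12, got {self.month_dx!r}"
            )
        if self.survival_months < 0:
            raise RegistryDataError(
                f"survival_months must be >= 0, got {self.survival_months!r}"
            )
        if not 0.0 < self.county_latitude < 90.0:
            raise RegistryDataError(
                f"county_latitude must be in (0, 90), got {self.county_latitude!r}"
            )
        if self.sex not in SEXES:
            raise RegistryDataError(f"unknown sex {self.sex!r}")
        if self.histology not in HISTOLOGIES:
            raise RegistryDataError(f"unknown histology {self.histology!r}")
        if self.stage is not None and self.stage not in STAGES:
            raise RegistryDataError(f"unknown stage {self.stage!r}")
        if self.event not in ("death", "censored"):
            raise RegistryDataError(f"event must be death|censored, got {self.event!r}")
        if self.flags not in FLAGS:
            raise RegistryDataError(f"unknown flags value {self.flags!r}")


@dataclass(frozen=True)
class ExclusionStep:
    rule_name: str
    n_removed: int
    n_remaining: int


@dataclass
class ExclusionReport:
    """Ordered accounting of a sequential exclusion cascade."""

    initial_count: int
    steps: list[ExclusionStep] = field(default_factory=list)

    @property
    def final_count(self) -> int:
        return self.steps[-1].n_remaining if self.steps else self.initial_count

    def validate(self) -> None:
        """Check step-to-step consistency of the accounting."""
        prev = self.initial_count
        for step in self.steps:
            if step.n_removed < 0:
                raise RegistryDataError(f"negative removal in step {step.rule_name}")
            if step.n_remaining != prev - step.n_removed:
                raise RegistryDataError(
                    f"inconsistent accounting at step {step.rule_name}: "
                    f"{prev} - {step.n_removed} != {step.n_remaining}"
                )
            prev = step.n_remaining
        removed = sum(s.n_removed for s in self.steps)
        if removed + self.final_count != self.initial_count:
            raise RegistryDataError("exclusion accounting does not sum up")

    @classmethod
    def from_counts(
        cls, initial_count: int, removals: Sequence[tuple[str, int]]
    ) -> "ExclusionReport":
        """Build a report from (rule, n_removed) pairs alone.

        Useful for reproducing a published selection cascade when only the
        printed removal counts, not the case-level data, are available.
        """
        report = cls(initial_count=initial_count)
        remaining = initial_count
        for rule, n_removed in removals:
            remaining -= n_removed
            report.steps.append(ExclusionStep(rule, n_removed, remaining))
        report.validate()
        return report

    def to_json_lines(self) -> str:
        lines = [
            json.dumps(
                {"rule": s.rule_name, "removed": s.n_removed, "remaining": s.n_remaining}
            )
            for s in self.steps
        ]
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class StratumScheme:
    """Stratification scheme for a cohort.

    Defaults follow the analysis conventions: age groups 0–19, 20–29, …,
    ≥70; winter = September–February, summer = March–August; year bins
    <1990, 1990–1999, 2000–2009, ≥2010.  Latitude quartile cutpoints are
    half-open, lower-inclusive (a case at exactly a cutpoint belongs to the
    higher quartile), and the north/south split reuses the middle cutpoint,
    with "north" lower-inclusive at the cutpoint.
    """

    age_group_edges: tuple[int, ...] = (20, 30, 40, 50, 60, 70)
    latitude_quartile_cutpoints: tuple[float, float, float] = (34.19, 38.05, 41.68)
    north_south_cutpoint: float | None = None  # defaults to middle quartile cutpoint
    winter_months: frozenset[int] = frozenset({9, 10, 11, 12, 1, 2})
    year_bin_edges: tuple[int, ...] = (1990, 2000, 2010)

    def __post_init__(self) -> None:
        cp = self.latitude_quartile_cutpoints
        if not (cp[0] < cp[1] < cp[2]):
            raise RegistryConfigError("quartile cutpoints must be strictly increasing")
        if self.north_south_cutpoint is None:
            self.north_south_cutpoint = cp[1]

    # -- single-dimension label helpers -------------------------------
    def age_group(self, age_years: int) -> str:
        edges = self.age_group_edges
        if age_years < edges[0]:
            return f"0-{edges[0] - 1}"
        for lo, hi in zip(edges, edges[1:]):
            if lo <= age_years < hi:
                return f"{lo}-{hi - 1}"
        return f">={edges[-1]}"

    def latitude_quartile(self, latitude: float) -> int:
        q = 1
        for cp in self.latitude_quartile_cutpoints:
            if latitude >= cp:
                q += 1
        return q

    def north_south(self, latitude: float) -> str:
        assert self.north_south_cutpoint is not None
        return "north" if latitude >= self.north_south_cutpoint else "south"

    def season(self, month: int) -> str:
        return "winter" if month in self.winter_months else "summer"

    def year_bin(self, year: int) -> str:
        edges = self.year_bin_edges
        if year < edges[0]:
            return f"<{edges[0]}"
        for lo, hi in zip(edges, edges[1:]):
            if lo <= year < hi:
                return f"{lo}-{hi - 1}"
        return f">={edges[-1]}"


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_value(col: str, raw: str):
    raw = raw.strip()
    if raw in _MISSING:
        return None
    if col in ("month_dx", "year_dx", "age_years"):
        return int(float(raw))
    if col in ("county_latitude", "survival_months"):
        return float(raw)
    return raw


def load_cases(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[CaseRecord], list[tuple[int, str]]]:
    """Load a case-listing CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Optional mapping ``canonical_name -> file column name`` for
        non-canonical dialects.  Unmapped canonical names are looked up
        verbatim.

    Returns
    -------
    cases, problems
        ``cases`` holds one :class:`CaseRecord` per parseable row.
        ``problems`` lists ``(row_number, message)`` for rows whose
        required fields could not be parsed — they are reported, never
        silently dropped.  Rows with a *missing* month, age or stage parse
        fine (those are legitimate registry states handled by the
        exclusion cascade).

    Raises
    ------
    RegistryConfigError
        If a required column is absent after mapping.
    RegistryDataError
        If the file has no data rows.
    """
    column_map = dict(column_map or {})
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        resolved = {c: column_map.get(c, c) for c in CANONICAL_COLUMNS}
        missing = [src for src in resolved.values() if src not in header]
        if missing:
            raise RegistryConfigError(
                f"missing required column(s) in {path.name}: {', '.join(missing)}"
            )
        cases: list[CaseRecord] = []
        problems: list[tuple[int, str]] = []
        n_rows = 0
        for i, row in enumerate(reader, start=2):  # header is line 1
            n_rows += 1
            try:
                values = {
                    c: _parse_value(c, row[src] if row[src] is not None else "")
                    for c, src in resolved.items()
                }
                for required in (
                    "case_id",
                    "year_dx",
                    "sex",
                    "histology",
                    "county_latitude",
                    "survival_months",
                    "event",
                ):
                    if values[required] is None:
                        raise RegistryDataError(f"missing required field {required}")
                if values["flags"] is None:
                    values["flags"] = "none"
                if values["registry_id"] is None:
                    values["registry_id"] = ""
                cases.append(CaseRecord(**values))
            except (ValueError, KeyError) as exc:
                problems.append((i, str(exc)))
    if n_rows == 0:
        raise RegistryDataError(f"{path.name} contains no data rows")
    return cases, problems


def write_cases(
    cases: Iterable[CaseRecord],
    path: str | Path,
    include_strata: bool = False,
) -> None:
    """Write cases to the canonical CSV schema (missing values as '')."""
    columns = list(CANONICAL_COLUMNS)
    if include_strata:
        columns += ["age_group", "latitude_quartile", "north_south", "season", "year_bin"]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for case in cases:
            row = []
            for col in columns:
                value = getattr(case, col)
                row.append("" if value is None else value)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Exclusion cascade

RuleFn = Callable[[CaseRecord], bool]  # True -> remove the case


def _rule_factory(rule: str | tuple[str, Sequence[str]]) -> tuple[str, RuleFn]:
    """Resolve a rule spec to (name, predicate).

    Known rules: ``dco-autopsy-only``, ``unknown-month``, ``missing-age``,
    ``missing-stage``, and ``("excluded-registry", [ids...])``.
    """
    if isinstance(rule, tuple):
        name, payload = rule
        if name != "excluded-registry":
            raise RegistryConfigError(f"unknown parameterized rule {name!r}")
        ids = frozenset(payload)
        return (
            f"excluded-registry({','.join(sorted(ids))})",
            lambda c: c.registry_id in ids,
        )
    simple: dict[str, RuleFn] = {
        "dco-autopsy-only": lambda c: c.flags != "none",
        "unknown-month": lambda c: c.month_dx is None,
        "missing-age": lambda c: c.age_years is None,
        "missing-stage": lambda c: c.stage is None,
    }
    if rule not in simple:
        raise RegistryConfigError(f"unknown exclusion rule {rule!r}")
    return rule, simple[rule]


def apply_exclusions(
    cases: Sequence[CaseRecord],
    rules: Sequence[str | tuple[str, Sequence[str]]],
) -> tuple[list[CaseRecord], ExclusionReport]:
    """Apply exclusion rules sequentially, recording per-rule removals.

    Each rule removes the cases its predicate matches among those still
    remaining; the report records (rule, n_removed, n_remaining) in order.
    """
    cohort = list(cases)
    report = ExclusionReport(initial_count=len(cohort))
    for rule in rules:
        name, predicate = _rule_factory(rule)
        kept = [c for c in cohort if not predicate(c)]
        report.steps.append(ExclusionStep(name, len(cohort) - len(kept), len(kept)))
        cohort = kept
    report.validate()
    return cohort, report


# ---------------------------------------------------------------------------
# Stratification


def latitude_quartile_cutpoints(
    county_latitudes: Iterable[tuple[str, float]],
) -> tuple[float, float, float]:
    """Quartile cutpoints over *distinct counties* sorted by latitude.

    Counties (not cases) are sorted by latitude and split into four groups
    of as-equal-as-possible size; the cutpoints are the latitudes of the
    first county of groups 2, 3 and 4 (intervals are half-open,
    lower-inclusive, so a county exactly at a cutpoint falls in the higher
    quartile).  The result is independent of input ordering.
    """
    lats = sorted({lat for _cid, lat in county_latitudes})
    n = len(lats)
    if n < 4:
        raise RegistryDataError(f"need >=4 distinct counties, got {n}")
    boundaries = [round(i * n / 4) for i in (1, 2, 3)]
    return tuple(lats[b] for b in boundaries)  # type: ignore[return-value]


def assign_strata(
    cases: Iterable[CaseRecord], scheme: StratumScheme
) -> list[CaseRecord]:
    """Label every case with all stratum dimensions (in place; returns list).

    Latitudes outside the quartile ranges fall in the extreme quartiles by
    the boundary convention — never an error.  Season requires a known
    month of diagnosis; run the exclusion cascade first.
    """
    labeled = list(cases)
    for case in labeled:
        if case.age_years is not None:
            case.age_group = scheme.age_group(case.age_years)
        case.latitude_quartile = scheme.latitude_quartile(case.county_latitude)
        case.north_south = scheme.north_south(case.county_latitude)
        if case.month_dx is not None:
            case.season = scheme.season(case.month_dx)
        case.year_bin = scheme.year_bin(case.year_dx)
    return labeled
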