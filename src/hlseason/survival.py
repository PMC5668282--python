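"""Seasonal mortality analysis: Cox proportional hazards and the peak-month scan.

The survival questions are asked with a Cox proportional-hazards model
maximizing the partial likelihood, with the Efron correction for tied
event times (follow-up is recorded in whole months, so ties are heavy).
Three seasonal formulations are supported:

* a dichotomous winter indicator (diagnosis September–February = 1,
  March–August = 0) added to the covariate set;
* a multiplicative interaction between the season term and county
  latitude in 10-degree steps, to test whether the seasonal mortality
  penalty grows towards the north;
* a sinusoid seasonal-risk covariate
  ``x1 = cos(2 pi (M - M_max) / 12)``, where ``M`` is the calendar month
  of diagnosis and ``M_max`` the hypothesized peak-risk month; fitting
  one model per candidate ``M_max`` in 1..12 and taking the coefficient-
  maximizing month locates the peak of seasonal mortality risk without
  committing to a particular half-year split.  Because
  ``x1(M, m + 6) = -x1(M, m)``, the scan is antisymmetric: coefficients
  for peak months six apart are exact negatives and share their p-value.

The Newton–Raphson solver starts at beta = 0, uses step-halving on any
partial-log-likelihood decrease, and reports standard errors from the
inverse observed information.  Covariates are centered internally for
numerical stability (this leaves coefficients and standard errors of a
Cox model unchanged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .registry import HISTOLOGIES, STAGES, CaseRecord

__all__ = [
    "SurvivalDesign",
    "CoxFit",
    "SeasonScan",
    "ConvergenceError",
    "make_survival",
    "encode_covariates",
    "decode_factor",
    "fit_cox",
    "season_hr",
    "seasonal_risk_term",
    "scan_peak_month",
    "latitude_interaction",
    "WINTER_MONTHS",
]

#: Meteorological winter half-year (autumn + winter): September–February.
WINTER_MONTHS = frozenset({9, 10, 11, 12, 1, 2})

#: Default factor codings: column -> (reference level, all levels).
DEFAULT_FACTORS: dict[str, tuple[str, tuple[str, ...]]] = {
    "sex": ("female", ("female", "male")),
    "histology": ("nodular-sclerosis", HISTOLOGIES),
    "stage": ("I", STAGES),
}
#: Default continuous covariates (case attributes).
DEFAULT_CONTINUOUS: tuple[str, ...] = ("age_years", "year_dx")


class DegenerateDesignError(ValueError):
    """The design cannot identify the model (no events, constant column...)."""


class ConvergenceError(RuntimeError):
    """Newton–Raphson failed to converge (possible separation)."""


@dataclass
class SurvivalDesign:
    """Survival outcome plus a named covariate matrix."""

    time: np.ndarray  # (n,) months
    event: np.ndarray  # (n,) 0/1
    X: np.ndarray  # (n, p)
    columns: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.time < 0):
            raise ValueError("survival times must be non-negative")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")

    @property
    def n(self) -> int:
        return self.time.size

    def with_column(self, name: str, values: np.ndarray) -> "SurvivalDesign":
        """Return a copy with one extra covariate column appended."""
        values = np.asarray(values, dtype=float).reshape(-1)
        if values.size != self.n:
            raise ValueError("column length mismatch")
        return SurvivalDesign(
            time=self.time,
            event=self.event,
            X=np.column_stack([self.X, values]),
            columns=self.columns + [name],
            reference_levels=dict(self.reference_levels),
        )

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]


@dataclass
class CoxFit:
    """Partial-likelihood fit summary."""

    columns: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    tie_method: str
    n: int
    n_events: int
    covariance: np.ndarray
    conf_level: float = 0.95

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> np.ndarray:
        z = stats.norm.ppf(0.5 + self.conf_level / 2.0)
        return np.exp(
            np.column_stack([self.beta - z * self.se, self.beta + z * self.se])
        )

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, np.abs(self.beta) / self.se, np.inf)
        return 2.0 * stats.norm.sf(z)

    def term(self, name: str) -> dict[str, float]:
        """Summary for one covariate: beta, se, hr, ci, p."""
        i = self.columns.index(name)
        lo, hi = self.ci[i]
        return {
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "hr": float(self.hazard_ratio[i]),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
            "p": float(self.p_values[i]),
        }

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": self.columns,
                "coef": self.beta,
                "se": self.se,
                "hr": self.hazard_ratio,
                "ci_lower": self.ci[:, 0],
                "ci_upper": self.ci[:, 1],
                "p": self.p_values,
            }
        )


@dataclass
class SeasonScan:
    """One Cox fit per candidate peak-risk month of the sinusoid term."""

    peak_months: np.ndarray  # 1..12
    fits: list[CoxFit]
    term: str = "seasonal_risk"

    @property
    def beta1(self) -> np.ndarray:
        return np.array([f.term(self.term)["beta"] for f in self.fits])

    @property
    def best_m_max(self) -> int:
        return int(self.peak_months[int(np.argmax(self.beta1))])

    def grid_frame(self):
        """12-row grid: peak month, HR, CI, p."""
        import pandas as pd

        rows = [f.term(self.term) for f in self.fits]
        return pd.DataFrame(
            {
                "peak_month": self.peak_months,
                "hr": [r["hr"] for r in rows],
                "ci_lower": [r["ci_lower"] for r in rows],
                "ci_upper": [r["ci_upper"] for r in rows],
                "p": [r["p"] for r in rows],
            }
        )


# ---------------------------------------------------------------------------
# Design construction


def make_survival(
    cases: Sequence[CaseRecord], horizon_months: float
) -> tuple[np.ndarray, np.ndarray]:
    """Administratively censor follow-up at a horizon (36 or 60 months).

    ``time = min(survival, horizon)``; a death counts as an event only if
    it occurred at or before the horizon.
    """
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    surv = np.array([c.survival_months for c in cases], dtype=float)
    if np.any(surv < 0):
        raise ValueError("negative survival time")
    died = np.array([c.event == "death" for c in cases])
    time = np.minimum(surv, horizon_months)
    event = (died & (surv <= horizon_months)).astype(np.int8)
    return time, event


def encode_covariates(
    cases: Sequence[CaseRecord],
    horizon_months: float = 36,
    factors: Mapping[str, tuple[str, tuple[str, ...]]] | None = None,
    continuous: Sequence[str] | None = None,
) -> SurvivalDesign:
    """Build the default covariate design for the mortality models.

    Factors get k-1 treatment-coded dummy columns named
    ``<factor>[<level>]`` (reference level omitted), in the declared level
    order; continuous case attributes pass through unchanged.  Column
    order is deterministic: factors in mapping order, then continuous
    terms.  An unseen factor level raises and names the level.
    """
    factors = dict(DEFAULT_FACTORS if factors is None else factors)
    continuous = tuple(DEFAULT_CONTINUOUS if continuous is None else continuous)
    n = len(cases)
    columns: list[str] = []
    data: list[np.ndarray] = []
    refs: dict[str, str] = {}
    for name, (ref, levels) in factors.items():
        refs[name] = ref
        values = [getattr(c, name) for c in cases]
        known = set(levels)
        for v in values:
            if v not in known:
                raise ValueError(f"unseen level {v!r} for factor {name!r}")
        for level in levels:
            if level == ref:
                continue
            columns.append(f"{name}[{level}]")
            data.append(np.array([v == level for v in values], dtype=float))
    for name in continuous:
        columns.append(name)
        col = np.array([getattr(c, name) for c in cases], dtype=float)
        data.append(col)
    time, event = make_survival(cases, horizon_months)
    X = np.column_stack(data) if data else np.empty((n, 0))
    return SurvivalDesign(time, event, X, columns, refs)


def decode_factor(design: SurvivalDesign, factor: str) -> list[str]:
    """Invert treatment coding: per-case level labels for one factor."""
    dummy_cols = [c for c in design.columns if c.startswith(f"{factor}[")]
    if not dummy_cols:
        raise KeyError(f"no dummy columns for factor {factor!r}")
    ref = design.reference_levels[factor]
    labels = [ref] * design.n
    for col in dummy_cols:
        level = col[len(factor) + 1 : -1]
        for i in np.nonzero(design.column(col) == 1.0)[0]:
            labels[i] = level
    return labels


# ---------------------------------------------------------------------------
# Partial-likelihood core


def _loglik_grad_info(
    beta: np.ndarray,
    X: np.ndarray,
    groups: list[tuple[np.ndarray, np.ndarray]],
    tie_method: str,
    want_derivs: bool = True,
) -> tuple[float, np.ndarray | None, np.ndarray | None]:
    """Partial log-likelihood (and derivatives) over event-time groups.

    ``groups`` lists, per distinct event time in decreasing order, the
    indices newly entering the risk set at that time and the indices of
    the deaths at that time; running sums accumulate the risk set.
    """
    n, p = X.shape
    eta = X @ beta
    # guard against overflow during aggressive trial steps
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X

    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    loglik = 0.0
    grad = np.zeros(p) if want_derivs else None
    info = np.zeros((p, p)) if want_derivs else None

    for entering, deaths in groups:
        if entering.size:
            xe = X[entering]
            we = w[entering]
            s0 += float(we.sum())
            s1 += wx[entering].sum(axis=0)
            s2 += (we[:, None] * xe).T @ xe
        if deaths.size == 0:
            continue
        d = deaths.size
        loglik += float(eta[deaths].sum())
        if want_derivs:
            grad += X[deaths].sum(axis=0)
        if tie_method == "breslow" or d == 1:
            fracs = np.zeros(d)
        else:  # efron
            fracs = np.arange(d) / d
        if d == 1 or tie_method == "breslow":
            denoms = np.full(d, s0)
            z1 = np.broadcast_to(s1, (d, p))
            use_tied = False
        else:
            s0d = float(w[deaths].sum())
            s1d = wx[deaths].sum(axis=0)
            xd = X[deaths]
            s2d = (w[deaths][:, None] * xd).T @ xd
            denoms = s0 - fracs * s0d
            z1 = s1[None, :] - fracs[:, None] * s1d[None, :]
            use_tied = True
        loglik -= float(np.log(denoms).sum())
        if want_derivs:
            zbar = z1 / denoms[:, None]
            grad -= zbar.sum(axis=0)
            if use_tied:
                for l in range(d):
                    z2 = s2 - fracs[l] * s2d
                    info += z2 / denoms[l] - np.outer(zbar[l], zbar[l])
            else:
                info += d * (s2 / s0 - np.outer(s1 / s0, s1 / s0))
    return loglik, grad, info


def _event_groups(
    time: np.ndarray, event: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group case indices by distinct time, descending, for running sums."""
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    groups: list[tuple[np.ndarray, np.ndarray]] = []
    start = 0
    n = time.size
    while start < n:
        stop = start
        while stop < n and t_sorted[stop] == t_sorted[start]:
            stop += 1
        idx = order[start:stop]
        deaths = idx[event[idx] == 1]
        groups.append((idx, deaths))
        start = stop
    return groups


def fit_cox(
    design: SurvivalDesign,
    tie_method: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
    conf_level: float = 0.95,
) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton–Raphson.

    Starts at beta = 0; halves the step whenever the partial log-
    likelihood would decrease; converged means the gradient max-norm fell
    below ``tol`` scaled by the magnitude of the null log-likelihood
    (an absolute cutoff is unattainable in double precision once the
    likelihood involves tens of thousands of cases).  Standard errors
    come from the inverse observed information at the solution.
    Non-convergence raises :class:`ConvergenceError` (a symptom of
    separation or collinearity).
    """
    if tie_method not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {tie_method!r}")
    n_events = int(design.event.sum())
    if n_events == 0:
        raise DegenerateDesignError("no events in the design")
    X = design.X.astype(float)
    if X.shape[1] == 0:
        raise DegenerateDesignError("design has no covariates")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(design.columns, sd) if s == 0]
        raise DegenerateDesignError(f"constant covariate column(s): {', '.join(bad)}")
    # center for numerical stability; invariant for beta and its covariance
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise DegenerateDesignError(
            "collinear covariate columns (design is rank deficient)"
        )
    groups = _event_groups(design.time, design.event)
    p = Xc.shape[1]
    beta = np.zeros(p)
    loglik, grad, info = _loglik_grad_info(beta, Xc, groups, tie_method)
    loglik_null = loglik
    grad_tol = tol * max(1.0, abs(loglik_null))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if float(np.max(np.abs(grad))) < grad_tol:
            converged = True
            n_iter -= 1
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step-halving: accept only likelihood-improving steps
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            new_loglik, new_grad, new_info = _loglik_grad_info(
                candidate, Xc, groups, tie_method
            )
            if np.isfinite(new_loglik) and new_loglik >= loglik - 1e-12:
                break
            scale /= 2.0
        else:
            raise ConvergenceError("step-halving failed to improve the likelihood")
        beta, loglik, grad, info = candidate, new_loglik, new_grad, new_info
    if not converged and float(np.max(np.abs(grad))) < grad_tol:
        converged = True
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(gradient max-norm {float(np.max(np.abs(grad))):.3g}); "
            "possible separation"
        )
    covariance = np.linalg.inv(info)
    se = np.sqrt(np.diag(covariance))
    return CoxFit(
        columns=list(design.columns),
        beta=beta,
        se=se,
        loglik=loglik,
        loglik_null=loglik_null,
        n_iter=n_iter,
        converged=converged,
        tie_method=tie_method,
        n=design.n,
        n_events=n_events,
        covariance=covariance,
        conf_level=conf_level,
    )


# ---------------------------------------------------------------------------
# Seasonal formulations


def seasonal_risk_term(M, M_max) -> np.ndarray | float:
    """Sinusoid seasonal-risk covariate ``cos(2 pi (M - M_max) / 12)``.

    Equals +1 when the diagnosis month ``M`` is the hypothesized peak-risk
    month ``M_max``, -1 six months away, and 0 at three months' distance.
    """
    M_arr = np.asarray(M)
    Mmax_arr = np.asarray(M_max)
    for name, a in (("M", M_arr), ("M_max", Mmax_arr)):
        if np.any((a < 1) | (a > 12)) or not np.all(np.equal(np.mod(a, 1), 0)):
            raise ValueError(f"{name} must be integer month(s) in 1..12")
    value = np.cos(2.0 * np.pi * (M_arr - Mmax_arr) / 12.0)
    return float(value) if value.ndim == 0 else value


def _winter_indicator(cases: Sequence[CaseRecord]) -> np.ndarray:
    months = [c.month_dx for c in cases]
    if any(m is None for m in months):
        raise ValueError("all cases need a known month of diagnosis")
    return np.array([1.0 if m in WINTER_MONTHS else 0.0 for m in months])


def season_hr(
    cases: Sequence[CaseRecord],
    horizon_months: float = 36,
    stratum: Callable[[CaseRecord], bool] | None = None,
    tie_method: str = "efron",
) -> CoxFit:
    """Winter-vs-summer mortality model.

    Adds the dichotomous winter-diagnosis indicator (September–February)
    to the full covariate set and fits the Cox model, optionally within a
    stratum (e.g. northern counties only).  The term of interest is
    ``winter``; its hazard ratio compares mortality after a winter versus
    a summer diagnosis.
    """
    subset = [c for c in cases if stratum(c)] if stratum is not None else list(cases)
    if not subset:
        raise DegenerateDesignError("stratum filter left no cases")
    design = encode_covariates(subset, horizon_months=horizon_months)
    design = design.with_column("winter", _winter_indicator(subset))
    return fit_cox(design, tie_method=tie_method)


def scan_peak_month(
    design: SurvivalDesign,
    months: Sequence[int],
    tie_method: str = "efron",
    term: str = "seasonal_risk",
) -> SeasonScan:
    """Fit the sinusoid seasonal-risk model once per candidate peak month.

    ``design`` must not already contain a season term; ``months`` is the
    per-case month of diagnosis.  For each ``M_max`` in 1..12 the covariate
    ``x1(M, M_max)`` is appended and the Cox model refitted; the best peak
    month maximizes the seasonal coefficient.
    """
    months = np.asarray(months)
    fits = []
    peak_months = np.arange(1, 13)
    for m_max in peak_months:
        x1 = seasonal_risk_term(months, int(m_max))
        fits.append(fit_cox(design.with_column(term, x1), tie_method=tie_method))
    return SeasonScan(peak_months=peak_months, fits=fits, term=term)


def latitude_interaction(
    design: SurvivalDesign,
    season_values: Sequence[float],
    latitudes: Sequence[float],
    tie_method: str = "efron",
    include_latitude_main: bool = True,
) -> CoxFit:
    """Season × latitude interaction model.

    Appends the season term (winter indicator or sinusoid ``x1``),
    latitude in 10-degree steps, and their product; the interaction
    hazard ratio (term ``season:lat10``) is the multiplicative change in
    the seasonal effect per 10 degrees of northward latitude.  The
    latitude main effect is kept by default (hierarchical principle) but
    can be dropped.
    """
    season = np.asarray(season_values, dtype=float)
    lat10 = np.asarray(latitudes, dtype=float) / 10.0
    out = design.with_column("season", season)
    if include_latitude_main:
        out = out.with_column("lat10", lat10)
    out = out.with_column("season:lat10", season * lat10)
    return fit_cox(out, tie_method=tie_method)
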