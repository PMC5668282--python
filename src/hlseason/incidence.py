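"""Seasonal incidence analysis: monthly standardization and cosinor fitting.

The pipeline is: tally cases per calendar month of diagnosis; adjust each
month's count for the length of the month (February counted as 28.25 days
to average over leap years) by rescaling to the mean month length of
30.4375 days; standardize so the average month has incidence 1; then fit a
single-component cosinor,

    y_t = M + A cos(theta_t - phi) + e_t,
        theta_t = 2 pi (t - 1) / P,  t = 1..P  (P = 12 months),

by ordinary least squares in the linearized form
``y = mesor + beta_c cos(theta) + beta_s sin(theta)``.  The amplitude is
``A = sqrt(beta_c^2 + beta_s^2)``, the acrophase ``phi = atan2(beta_s,
beta_c)`` is the angular timing of the fitted peak, and the zero-amplitude
(seasonality) test is the joint two-degree-of-freedom F-test of
``beta_c = beta_s = 0``.  Group amplitudes are compared by a stacked
regression with group-by-trig interaction terms and a delta-method
standard error for the amplitude difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .registry import CaseRecord

__all__ = [
    "MONTH_LENGTHS",
    "MEAN_MONTH_LENGTH",
    "MonthlyIncidence",
    "CosinorFit",
    "AmplitudeComparison",
    "monthly_counts",
    "adjust_month_length",
    "normalize",
    "fit_cosinor",
    "peak_trough_percent",
    "peak_month",
    "compare_amplitudes",
    "holm_adjust",
]

#: Calendar month lengths in days, February averaged over the leap cycle.
MONTH_LENGTHS = np.array(
    [31.0, 28.25, 31.0, 30.0, 31.0, 30.0, 31.0, 31.0, 30.0, 31.0, 30.0, 31.0]
)
#: Mean month length in days (365.25 / 12).
MEAN_MONTH_LENGTH = 30.4375


class DegenerateInputError(ValueError):
    """Input carries no usable signal (all-zero counts, too few points, ...)."""


@dataclass
class MonthlyIncidence:
    """Per-month raw, month-length-adjusted and standardized incidence."""

    raw_count: np.ndarray  # (12,) ints
    month_length_days: np.ndarray  # (12,)
    adjusted_count: np.ndarray  # (12,) full precision
    normalized_incidence: np.ndarray  # (12,) mean 1

    @property
    def adjusted_rounded(self) -> np.ndarray:
        """Adjusted counts rounded to the nearest integer, for reporting."""
        return np.rint(self.adjusted_count).astype(int)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "month": np.arange(1, 13),
                "raw_count": self.raw_count.astype(int),
                "adjusted_count": self.adjusted_rounded,
                "normalized_incidence": np.round(self.normalized_incidence, 3),
            }
        )


@dataclass
class CosinorFit:
    """Least-squares single-component cosinor fit."""

    mesor: float
    amplitude: float
    acrophase: float  # radians in [0, 2 pi); angle of the fitted peak
    peak_month: int
    beta_cos: float
    beta_sin: float
    covariance: np.ndarray  # (3, 3) for (mesor, beta_cos, beta_sin)
    seasonality_p: float
    amplitude_se: float
    amplitude_ci: tuple[float, float]
    n_points: int
    period: int

    @property
    def trough_month(self) -> int:
        return (self.peak_month - 1 + self.period // 2) % self.period + 1


@dataclass
class AmplitudeComparison:
    amplitude_group_a: float
    amplitude_group_b: float
    difference: float  # b - a
    difference_se: float
    difference_ci: tuple[float, float]
    p_value: float


# ---------------------------------------------------------------------------


def monthly_counts(cases: Iterable[CaseRecord]) -> MonthlyIncidence:
    """Tally cases per month of diagnosis and standardize.

    Cases with unknown month are not countable and must be excluded
    upstream; encountering one here raises.
    """
    raw = np.zeros(12)
    for case in cases:
        if case.month_dx is None:
            raise DegenerateInputError("case with unknown month of diagnosis")
        raw[case.month_dx - 1] += 1
    return incidence_from_counts(raw)


def incidence_from_counts(
    raw_counts: Sequence[float], month_lengths: Sequence[float] | None = None
) -> MonthlyIncidence:
    """Build the full raw/adjusted/normalized table from 12 raw counts."""
    raw = np.asarray(raw_counts, dtype=float)
    lengths = MONTH_LENGTHS if month_lengths is None else np.asarray(month_lengths, float)
    adjusted = adjust_month_length(raw, lengths)
    if adjusted.sum() > 0:
        normalized = normalize(adjusted)
    else:
        normalized = np.zeros(12)
    return MonthlyIncidence(raw, lengths, adjusted, normalized)


def adjust_month_length(
    raw_counts: Sequence[float],
    month_lengths: Sequence[float] | None = None,
    target_length: float = MEAN_MONTH_LENGTH,
) -> np.ndarray:
    """Rescale counts to a common month length: raw / length * target."""
    raw = np.asarray(raw_counts, dtype=float)
    lengths = MONTH_LENGTHS if month_lengths is None else np.asarray(month_lengths, float)
    if np.any(lengths <= 0):
        raise ValueError("month lengths must be positive")
    if raw.shape != lengths.shape:
        raise ValueError("counts and month lengths must align")
    return raw / lengths * target_length


def normalize(adjusted_counts: Sequence[float]) -> np.ndarray:
    """Standardize so the average month has incidence 1."""
    adjusted = np.asarray(adjusted_counts, dtype=float)
    mean = adjusted.mean()
    if mean <= 0:
        raise DegenerateInputError("cannot normalize an all-zero series")
    return adjusted / mean


def _month_angles(t: np.ndarray, period: int) -> np.ndarray:
    return 2.0 * np.pi * (t - 1) / period


def fit_cosinor(
    y: Sequence[float],
    t: Sequence[int] | None = None,
    period: int = 12,
    conf_level: float = 0.95,
) -> CosinorFit:
    """Fit ``y = mesor + beta_c cos(theta) + beta_s sin(theta)`` by OLS.

    Parameters
    ----------
    y
        Periodic observations (e.g. the 12 standardized monthly values, or
        any longer per-month series).
    t
        Month index (1-based) of each observation; defaults to ``1..len(y)``
        taken cyclically, which is the 12-value aggregated use-case.
    period
        Number of time units per cycle (12 for monthly data).

    The seasonality p-value is the joint F-test of the two trigonometric
    coefficients against the mesor-only model; the amplitude standard
    error and CI come from the delta method on ``(beta_c, beta_s)`` with
    the OLS covariance.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if t is None:
        t = (np.arange(n) % period) + 1
    t = np.asarray(t, dtype=float)
    if np.unique(t).size < 4:
        raise DegenerateInputError(
            "cosinor needs observations at >=4 distinct time points"
        )
    theta = _month_angles(t, period)
    X = np.column_stack([np.ones(n), np.cos(theta), np.sin(theta)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta_c, beta_s = beta
    resid = y - X @ beta
    dof = n - 3
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * xtx_inv

    amplitude = math.hypot(beta_c, beta_s)
    acrophase = math.atan2(beta_s, beta_c) % (2.0 * math.pi)

    # joint F-test of (beta_c, beta_s) = (0, 0) vs the mesor-only model
    rss_full = float(resid @ resid)
    rss_null = float(((y - y.mean()) ** 2).sum())
    if dof > 0 and rss_full > 0:
        f_stat = ((rss_null - rss_full) / 2.0) / (rss_full / dof)
        seasonality_p = float(stats.f.sf(f_stat, 2, dof))
    elif rss_null > rss_full:
        seasonality_p = 0.0  # perfect fit of a genuine rhythm
    else:
        seasonality_p = 1.0

    # delta method: dA/dbeta = (beta_c, beta_s) / A
    if amplitude > 0:
        grad = np.array([beta_c, beta_s]) / amplitude
        amp_var = float(grad @ cov[1:, 1:] @ grad)
    else:
        amp_var = float(np.trace(cov[1:, 1:])) / 2.0
    amplitude_se = math.sqrt(max(amp_var, 0.0))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    ci = (max(amplitude - z * amplitude_se, 0.0), amplitude + z * amplitude_se)

    fit = CosinorFit(
        mesor=float(mesor),
        amplitude=float(amplitude),
        acrophase=float(acrophase),
        peak_month=0,
        beta_cos=float(beta_c),
        beta_sin=float(beta_s),
        covariance=cov,
        seasonality_p=seasonality_p,
        amplitude_se=amplitude_se,
        amplitude_ci=ci,
        n_points=int(n),
        period=int(period),
    )
    fit.peak_month = peak_month(fit)
    return fit


def peak_month(fit: CosinorFit) -> int:
    """Calendar month whose angle is circularly closest to the acrophase.

    An acrophase exactly halfway between two months ties to the earlier
    month.
    """
    period = fit.period
    months = np.arange(1, period + 1)
    angles = _month_angles(months.astype(float), period)
    diff = np.abs((angles - fit.acrophase + np.pi) % (2 * np.pi) - np.pi)
    # round to kill float dust so exact halfway ties go to the earlier month
    return int(months[np.argmin(np.round(diff, 12))])


def peak_trough_percent(fit: CosinorFit) -> float:
    """Fitted peak-minus-trough difference as a percentage of the mesor.

    The fitted curve ranges over ``mesor ± amplitude``, so the peak exceeds
    the trough by ``2 A``, i.e. ``100 * 2 A / mesor`` percent of the mesor.
    """
    if fit.mesor <= 0:
        raise ValueError("peak-trough percent requires a positive mesor")
    return 100.0 * 2.0 * fit.amplitude / fit.mesor


def compare_amplitudes(
    y_a: Sequence[float],
    y_b: Sequence[float],
    period: int = 12,
    conf_level: float = 0.95,
) -> AmplitudeComparison:
    """Test whether two groups' seasonal amplitudes differ.

    Stacks the two standardized series into one regression with a group
    main effect and group × cos, group × sin interactions, so each group
    gets its own trig coefficients; the amplitude difference
    ``A_b - A_a`` and its standard error follow by the delta method on the
    joint coefficient covariance, with a two-sided Wald test.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_b = np.asarray(y_b, dtype=float)
    if np.ptp(y_a) == 0 and np.ptp(y_b) == 0:
        raise DegenerateInputError("both series are constant; amplitudes undefined")
    n_a, n_b = y_a.size, y_b.size
    t_a = (np.arange(n_a) % period) + 1.0
    t_b = (np.arange(n_b) % period) + 1.0
    th_a, th_b = _month_angles(t_a, period), _month_angles(t_b, period)
    y = np.concatenate([y_a, y_b])
    g = np.concatenate([np.zeros(n_a), np.ones(n_b)])
    cos_t = np.concatenate([np.cos(th_a), np.cos(th_b)])
    sin_t = np.concatenate([np.sin(th_a), np.sin(th_b)])
    X = np.column_stack([np.ones(y.size), g, cos_t, sin_t, g * cos_t, g * sin_t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.size - X.shape[1]
    if dof <= 0:
        raise DegenerateInputError("not enough observations for the stacked model")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)

    bc_a, bs_a = beta[2], beta[3]
    bc_b, bs_b = beta[2] + beta[4], beta[3] + beta[5]
    amp_a = math.hypot(bc_a, bs_a)
    amp_b = math.hypot(bc_b, bs_b)
    if amp_a == 0 and amp_b == 0:
        raise DegenerateInputError("both series are constant; amplitudes undefined")
    diff = amp_b - amp_a

    # gradient of (A_b - A_a) wrt (bc, bs, d_c, d_s); A_a has no d terms
    ga = np.array([bc_a, bs_a]) / amp_a if amp_a > 0 else np.zeros(2)
    gb = np.array([bc_b, bs_b]) / amp_b if amp_b > 0 else np.zeros(2)
    grad = np.array([gb[0] - ga[0], gb[1] - ga[1], gb[0], gb[1]])
    cov_trig = cov[2:, 2:]
    var_diff = float(grad @ cov_trig @ grad)
    se = math.sqrt(max(var_diff, 0.0))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(diff) / se))
    else:
        p = 1.0 if diff == 0 else 0.0
    return AmplitudeComparison(
        amplitude_group_a=float(amp_a),
        amplitude_group_b=float(amp_b),
        difference=float(diff),
        difference_se=se,
        difference_ci=(diff - z * se, diff + z * se),
        p_value=p,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni–Holm step-down adjustment, capped at 1.

    Sorted ascending, p_(i) is multiplied by (m - i); a running maximum
    enforces monotonicity of the adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.maximum.accumulate(
        np.minimum((m - np.arange(m)) * p[order], 1.0)
    )
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted
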