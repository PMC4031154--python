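"""Reliability, validity and responsiveness statistics for scalar measures.

These are the standard psychometric quantities of clinimetrics:

* test-retest repeatability within a session via the coefficient of
  variation (CV) of repeated trials;
* intrarater across-session reliability via the two-way mixed,
  single-measure, consistency-form intraclass correlation ICC(3,1) with its
  Shrout-Fleiss F-based 95 % confidence interval;
* measurement error via the standard error of measurement
  SEM = SD * sqrt(1 - ICC);
* the minimal detectable change MDC95 = z * sqrt(2) * SEM (z = 1.96 by
  default) and its percentage of the baseline mean;
* responsiveness via the effect size |mean change| / SD(baseline);
* validity via Spearman/Pearson correlations classed on Munro's magnitude
  bands (little / low / moderate / high / very high).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, UndefinedStatisticError

__all__ = [
    "MDC95_DEFAULT_Z",
    "ReliabilityResult",
    "CorrelationResult",
    "AnovaResult",
    "coefficient_of_variation",
    "icc_3_1",
    "sem",
    "mdc95",
    "pct_mdc",
    "effect_size",
    "munro_class",
    "correlate",
    "anova_vision_support",
    "reliability_bundle",
]

_log = logging.getLogger(__name__)

#: two-sided 95 % normal quantile used in the MDC95 factor z*sqrt(2)
MDC95_DEFAULT_Z = 1.959964


@dataclass(frozen=True)
class ReliabilityResult:
    """ICC / SEM / MDC bundle for one measure."""

    icc: float
    icc_ci_low: float
    icc_ci_high: float
    sem: float
    mdc95: float
    pct_mdc: float
    n_subjects: int
    k_occasions: int


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    method: str
    munro_class: str
    n: int


@dataclass(frozen=True)
class AnovaResult:
    """Two-way factorial ANOVA on a measure with vision and support factors."""

    f_vision: float
    p_vision: float
    df_vision: float
    f_support: float
    p_support: float
    df_support: float
    f_interaction: float
    p_interaction: float
    df_interaction: float
    df_residual: float


def coefficient_of_variation(values) -> float:
    """Sample CV of repeated trial values, as a percentage of their mean.

    Undefined (raises) when the mean is numerically zero, which is why it is
    never computed for the mean-position coordinates X and Y.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidArgumentError("CV needs at least 2 values")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    if abs(m) <= 1e-12 * max(sd, 1.0):
        raise UndefinedStatisticError("CV undefined at mean zero")
    return 100.0 * sd / m


def icc_3_1(values, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(3,1): two-way mixed, single measure, consistency form.

    ``values`` is a complete subjects x occasions matrix.  From the two-way
    ANOVA decomposition with between-subject mean square BMS and residual
    mean square EMS,

        ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS)

    and the confidence interval follows from the F bounds for this form:
    with F = BMS/EMS, F_L = F / F_{1-a/2}(n-1, (n-1)(k-1)) and
    F_U = F * F_{1-a/2}((n-1)(k-1), n-1), the bounds are
    (F_* - 1) / (F_* + k - 1).

    Returns ``(icc, (ci_low, ci_high))``.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise InvalidArgumentError("need a subjects x occasions matrix")
    if np.isnan(m).any():
        raise InvalidArgumentError("ICC requires complete cases (no NaN)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise InvalidArgumentError("ICC needs >= 2 subjects and >= 2 occasions")
    grand = m.mean()
    ss_rows = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if ems <= 0 and bms <= 0:
        raise UndefinedStatisticError("all mean squares zero: ICC undefined")
    if ems == 0:
        return 1.0, (1.0, 1.0)
    icc = (bms - ems) / (bms + (k - 1) * ems)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = bms / ems
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + k - 1)
    hi = (f_u - 1) / (f_u + k - 1)
    return float(icc), (float(lo), float(hi))


def sem(measurements_sd: float, icc: float) -> float:
    """Standard error of measurement, SD * sqrt(1 - ICC).

    The SD is the pooled between-subject SD of all measurements that entered
    the ICC.  A (rare) negative ICC is clamped to 0 with a warning; an ICC
    above 1 is rejected.
    """
    if measurements_sd < 0:
        raise InvalidArgumentError("SD must be non-negative")
    if icc > 1.0 + 1e-12:
        raise InvalidArgumentError(f"ICC {icc} > 1")
    if icc < 0:
        _log.warning("negative ICC %.3f clamped to 0 for SEM", icc)
        icc = 0.0
    return measurements_sd * math.sqrt(1.0 - min(icc, 1.0))


def mdc95(sem_value: float, z: float = MDC95_DEFAULT_Z) -> float:
    """Minimal detectable change, z * sqrt(2) * SEM."""
    if sem_value < 0:
        raise InvalidArgumentError("SEM must be non-negative")
    return z * math.sqrt(2.0) * sem_value


def pct_mdc(mdc95_value: float, baseline_mean: float) -> float:
    """MDC95 as a percentage of the baseline assessment mean."""
    if baseline_mean == 0:
        raise UndefinedStatisticError("%MDC undefined at baseline mean zero")
    return 100.0 * mdc95_value / baseline_mean


def effect_size(first, second) -> float:
    """Responsiveness effect size: |mean(second - first)| / SD(first).

    Paired per-subject values from the first and second assessments; the
    denominator is the sample SD (n-1) of the baseline values.  The absolute
    value is reported so that improvement registers positively for measures
    that decrease as the subject improves.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InvalidArgumentError("need paired vectors of >= 2 subjects")
    sd0 = float(a.std(ddof=1))
    if sd0 == 0:
        raise UndefinedStatisticError("zero baseline SD: effect size undefined")
    return abs(float((b - a).mean())) / sd0


_MUNRO_BANDS = (
    (0.255, "little"),
    (0.495, "low"),
    (0.695, "moderate"),
    (0.895, "high"),
)


def munro_class(coefficient: float) -> str:
    """Munro's magnitude band for a correlation coefficient.

    The conventional band edges are quoted at 2 decimals (0.25/0.26,
    0.49/0.50, ...); the midpoints 0.255, 0.495, 0.695, 0.895 close the
    gaps, with the boundary value itself belonging to the higher band.
    """
    r = abs(coefficient)
    if r > 1.0 + 1e-12:
        raise InvalidArgumentError(f"|coefficient| {r} > 1")
    for upper, label in _MUNRO_BANDS:
        if r < upper:
            return label
    return "very_high"


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Correlation with two-sided p-value and Munro class."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise InvalidArgumentError("need equal-length vectors of >= 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("constant input: correlation undefined")
    if method == "spearman":
        r, p = stats.spearmanr(a, b)
    elif method == "pearson":
        r, p = stats.pearsonr(a, b)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")
    return CorrelationResult(
        coefficient=float(r),
        p_value=float(p),
        method=method,
        munro_class=munro_class(float(r)),
        n=int(a.size),
    )


def anova_vision_support(values, vision_labels, support_labels) -> AnovaResult:
    """Two-way factorial ANOVA with vision and support-base main effects.

    Uses type II sums of squares, appropriate for the unbalanced designs
    that condition dropout produces; for a balanced two-level design type II
    coincides with type I.
    """
    import statsmodels.api as sm_api
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "vision": list(vision_labels),
            "support": list(support_labels),
        }
    )
    if df["vision"].nunique() < 2 or df["support"].nunique() < 2:
        raise InvalidArgumentError("need >= 2 levels per factor")
    cells = df.groupby(["vision", "support"], observed=True).size()
    if len(cells) < df["vision"].nunique() * df["support"].nunique():
        raise InvalidArgumentError("empty vision x support cell")
    model = ols("value ~ C(vision) * C(support)", data=df).fit()
    tab = sm_api.stats.anova_lm(model, typ=2)
    vis = tab.loc["C(vision)"]
    sup = tab.loc["C(support)"]
    inter = tab.loc["C(vision):C(support)"]
    resid = tab.loc["Residual"]
    return AnovaResult(
        f_vision=float(vis["F"]),
        p_vision=float(vis["PR(>F)"]),
        df_vision=float(vis["df"]),
        f_support=float(sup["F"]),
        p_support=float(sup["PR(>F)"]),
        df_support=float(sup["df"]),
        f_interaction=float(inter["F"]),
        p_interaction=float(inter["PR(>F)"]),
        df_interaction=float(inter["df"]),
        df_residual=float(resid["df"]),
    )


def reliability_bundle(
    matrix, baseline_mean: float | None = None, mdc_z: float = MDC95_DEFAULT_Z
) -> ReliabilityResult:
    """ICC(3,1), SEM, MDC95 and %MDC for one subjects x occasions matrix.

    The SEM uses the pooled SD of every value in the matrix; the %MDC
    baseline defaults to the mean of the first occasion's values.
    """
    m = np.asarray(matrix, dtype=float)
    icc, (lo, hi) = icc_3_1(m)
    pooled_sd = float(m.std(ddof=1))
    s = sem(pooled_sd, icc)
    mdc = mdc95(s, z=mdc_z)
    base = float(m[:, 0].mean()) if baseline_mean is None else float(baseline_mean)
    pct = pct_mdc(mdc, base) if base != 0 else float("nan")
    return ReliabilityResult(
        icc=icc,
        icc_ci_low=lo,
        icc_ci_high=hi,
        sem=s,
        mdc95=mdc,
        pct_mdc=pct,
        n_subjects=m.shape[0],
        k_occasions=m.shape[1],
    )
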