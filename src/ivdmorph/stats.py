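"""Reliability and comparison statistics for disc morphometry.

Covers the analyses a reliability/validation study of this kind runs:

* intraclass correlation (ICC) with a 95% confidence interval, for the
  reliability of repeated contouring by independent measurements;
* paired t-tests, for systematic differences between two scanners measuring
  the same specimens;
* Pearson correlation (reported with r², the convention for
  cross-instrument predictiveness);
* one-way ANOVA with post-hoc pairwise comparisons across age groups.

The ICC defaults to the two-way random-effects, absolute-agreement,
single-measurement form — ICC(2,1) — which treats repeated contourings as
random raters; the consistency form ICC(3,1) is selectable.  Confidence
intervals use the standard F-distribution bounds (McGraw & Wong).

"Tukey's LSD" in common usage conflates two procedures, so both are
implemented: Tukey's HSD (adjusted p-values, the default) and Fisher's
protected LSD (unadjusted pairwise p-values, to be read only when the ANOVA
itself is significant).  Every report records which was used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


class DegenerateVarianceWarning(UserWarning):
    """A variance component needed by the statistic is zero."""


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaterTable:
    """Complete n_subjects x k_raters table of one metric."""

    values: np.ndarray
    subjects: tuple[str, ...] = ()
    raters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise StatsError(f"rater table must be 2-D, got shape {vals.shape}")
        n, k = vals.shape
        if n < 2 or k < 2:
            raise StatsError(f"need >=2 subjects and >=2 raters, got {n}x{k}")
        if not np.all(np.isfinite(vals)):
            raise StatsError("rater table has missing/non-finite cells; a complete design is required")
        subjects = tuple(self.subjects) or tuple(f"S{i+1}" for i in range(n))
        raters = tuple(self.raters) or tuple(f"R{j+1}" for j in range(k))
        if len(subjects) != n or len(raters) != k:
            raise StatsError("subject/rater id lengths do not match the table")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "subjects", subjects)
        object.__setattr__(self, "raters", raters)


@dataclass(frozen=True)
class GroupTable:
    """Metric values with group labels (e.g. age groups)."""

    groups: tuple[tuple[str, np.ndarray], ...]

    def __post_init__(self) -> None:
        groups = tuple((str(name), np.asarray(vals, float).ravel()) for name, vals in self.groups)
        if len(groups) < 2:
            raise StatsError("need >=2 groups")
        for name, vals in groups:
            if len(vals) < 2:
                raise StatsError(f"group {name!r} has {len(vals)} observation(s); need >=2")
            if not np.all(np.isfinite(vals)):
                raise StatsError(f"group {name!r} has non-finite values")
        object.__setattr__(self, "groups", groups)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str, group_col: str) -> "GroupTable":
        return cls(tuple((str(g), sub[value_col].to_numpy()) for g, sub in df.groupby(group_col)))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

class ICCResult(NamedTuple):
    estimate: float
    ci_lower: float
    ci_upper: float
    form: str
    degenerate: bool


def _mean_squares(vals: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = vals.shape
    grand = vals.mean()
    row_means = vals.mean(axis=1)
    col_means = vals.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((vals - grand) ** 2))
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(
    table: RaterTable | np.ndarray | pd.DataFrame,
    form: str = "icc2",
    alpha: float = 0.05,
) -> ICCResult:
    """Intraclass correlation with an F-based confidence interval.

    Parameters
    ----------
    table
        Complete subjects-by-raters matrix (RaterTable, array or DataFrame).
    form : {'icc2', 'icc3'}
        ``icc2`` — two-way random effects, absolute agreement, single
        measurement (default); ``icc3`` — two-way mixed, consistency.
    alpha
        1 − confidence level (default 95% CI).

    Zero between-subject variance makes the ICC undefined in practice; the
    estimate is returned as 0 with ``degenerate=True`` and a warning.
    """
    if isinstance(table, pd.DataFrame):
        table = RaterTable(table.to_numpy(float), tuple(map(str, table.index)), tuple(map(str, table.columns)))
    elif not isinstance(table, RaterTable):
        table = RaterTable(np.asarray(table, float))
    msr, msc, mse, n, k = _mean_squares(table.values)

    if msr <= 0.0:
        warnings.warn(
            "zero between-subject variance; ICC is degenerate and reported as 0",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        return ICCResult(0.0, float("nan"), float("nan"), form, True)

    if form == "icc3":
        est = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0.0:
            return ICCResult(1.0, 1.0, 1.0, form, False)
        fstat = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fstat / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = fstat * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return ICCResult(float(est), float(lo), float(hi), form, False)

    if form != "icc2":
        raise ValueError(f"unknown ICC form {form!r}; use 'icc2' or 'icc3'")

    est = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if mse == 0.0 and msc == 0.0:
        # perfect agreement: every rater reproduces every subject exactly
        return ICCResult(1.0, 1.0, 1.0, form, False)
    # McGraw & Wong F-based interval for ICC(A,1), Satterthwaite df
    fj = msc / mse if mse > 0 else np.inf
    icc_ = est
    num = (k - 1) * (n - 1) * (k * icc_ * fj + n * (1 + (k - 1) * icc_) - k * icc_) ** 2
    den = (n - 1) * k**2 * icc_**2 * fj**2 + (n * (1 + (k - 1) * icc_) - k * icc_) ** 2
    if not np.isfinite(num / den):
        v = (k - 1) * (n - 1)
    else:
        v = num / den
    f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f2u * mse) / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
    return ICCResult(float(est), float(lo), float(hi), form, False)


# ---------------------------------------------------------------------------
# Paired t, Pearson
# ---------------------------------------------------------------------------

class PairedTResult(NamedTuple):
    t: float
    p: float
    mean_difference: float


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test on matched measurements.

    Pairs that are exactly equal everywhere have zero difference variance;
    by convention that returns t = 0, p = 1 (no evidence of a difference),
    and a constant nonzero difference returns p = 0 (a certain difference).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("paired vectors must be 1-D and equal length")
    n = len(x)
    if n < 2:
        raise StatsError(f"need n >= 2 pairs, got {n}")
    d = x - y
    md = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(md, 0.0):
            return PairedTResult(0.0, 1.0, 0.0)
        return PairedTResult(float(np.sign(md)) * float("inf"), 0.0, md)
    res = sps.ttest_rel(x, y)
    return PairedTResult(float(res.statistic), float(res.pvalue), md)


class PearsonResult(NamedTuple):
    r: float
    r_squared: float
    p: float


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson product-moment correlation, reported with r²."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("vectors must be 1-D and equal length")
    if len(x) < 3:
        raise StatsError(f"need n >= 3, got {len(x)}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise StatsError("Pearson correlation is undefined for a zero-variance vector")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return PearsonResult(r, r * r, float(res.pvalue))


# ---------------------------------------------------------------------------
# ANOVA + post hoc
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    method: str
    pairwise: pd.DataFrame = field(repr=False)


def anova_posthoc(
    groups: GroupTable | Mapping[str, Sequence[float]],
    method: str = "tukey_hsd",
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way fixed-effects ANOVA with pairwise post-hoc comparisons.

    ``tukey_hsd`` returns family-wise adjusted p-values; ``fisher_lsd``
    returns unadjusted protected-LSD p-values from the pooled error mean
    square (interpret only when the omnibus ANOVA is significant).  The
    pairwise table records group pair, mean difference, p-value and a
    significance flag at ``alpha`` (protected by the omnibus test for LSD).
    """
    if not isinstance(groups, GroupTable):
        groups = GroupTable(tuple((str(k), np.asarray(v, float)) for k, v in groups.items()))
    names = [name for name, _ in groups.groups]
    samples = [vals for _, vals in groups.groups]
    f_stat, p_omni = (float(v) for v in sps.f_oneway(*samples))

    rows = []
    if method == "tukey_hsd":
        res = sps.tukey_hsd(*samples)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                p = float(res.pvalue[i, j])
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "mean_difference": float(samples[i].mean() - samples[j].mean()),
                        "p": p,
                        "significant": bool(p < alpha),
                    }
                )
    elif method == "fisher_lsd":
        ns = np.array([len(s) for s in samples])
        df_err = int(ns.sum() - len(samples))
        mse = sum(float(np.sum((s - s.mean()) ** 2)) for s in samples) / df_err
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                diff = float(samples[i].mean() - samples[j].mean())
                se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
                if se == 0.0:
                    t_stat, p = (0.0, 1.0) if diff == 0 else (np.sign(diff) * np.inf, 0.0)
                else:
                    t_stat = diff / se
                    p = 2.0 * float(sps.t.sf(abs(t_stat), df_err))
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "mean_difference": diff,
                        "p": p,
                        "significant": bool(p_omni < alpha and p < alpha),
                    }
                )
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return AnovaResult(f_stat, p_omni, method, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Cross-resolution comparison
# ---------------------------------------------------------------------------

def cross_resolution_report(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    metrics: Sequence[str] | None = None,
    id_col: str = "sample_id",
) -> pd.DataFrame:
    """Compare per-sample morphometry from two scan resolutions.

    For every shared numeric metric the report gives the paired t-test and
    Pearson r² across matched samples — the structure of a
    fine-vs-coarse-scanner agreement analysis.

    Raises
    ------
    StatsError
        If the two tables do not contain exactly matching sample ids (the
        orphans are listed).
    """
    a = metrics_a.set_index(id_col) if id_col in metrics_a.columns else metrics_a.copy()
    b = metrics_b.set_index(id_col) if id_col in metrics_b.columns else metrics_b.copy()
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise StatsError(
            f"unmatched sample ids: only in first table {only_a}, only in second {only_b}"
        )
    b = b.loc[a.index]
    if metrics is None:
        metrics = [
            c
            for c in a.columns
            if c in b.columns and np.issubdtype(a[c].dtype, np.number)
        ]
    rows = []
    for col in metrics:
        x = a[col].to_numpy(float)
        y = b[col].to_numpy(float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        t_res = paired_t(x, y)
        try:
            p_res = pearson(x, y)
            r, r2, rp = p_res
        except StatsError:
            r = r2 = rp = float("nan")
        rows.append(
            {
                "metric": col,
                "n": int(len(x)),
                "r": r,
                "r_squared": r2,
                "pearson_p": rp,
                "t": t_res.t,
                "paired_t_p": t_res.p,
                "mean_difference": t_res.mean_difference,
            }
        )
    return pd.DataFrame(rows)
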