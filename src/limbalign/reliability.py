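"""Agreement statistics for paired angle measurements.

Quantifies agreement between any two measurement sources (two human
raters, or a human rater and the automatic pipeline) per alignment
parameter: mean difference with 95% confidence interval, standard
deviation of differences, root-mean-square error, Pearson's r with a
two-sided p-value, and the single-measure absolute-agreement intraclass
correlation ICC(A,1) from the two-way ANOVA decomposition, with its
F-distribution confidence interval (McGraw & Wong).

Missing values are handled by pairwise-complete deletion per parameter,
so the reported n can differ between parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import PARAMETERS

__all__ = ["RaterTable", "ReliabilityResult", "agreement_stats", "icc_a1",
           "pearson", "reliability_report", "rmse_identity"]


class UndefinedStatisticError(ValueError):
    """The statistic has no defined value on this input (e.g. zero variance)."""


@dataclass
class RaterTable:
    """Subjects x parameters measurement table for one source (degrees)."""

    values: pd.DataFrame  # index: subject ids; columns: parameter names

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject="subject",
                  parameter="parameter", value="value") -> "RaterTable":
        wide = df.pivot(index=subject, columns=parameter, values=value)
        return cls(values=wide)

    @classmethod
    def read_csv(cls, path) -> "RaterTable":
        df = pd.read_csv(path)
        if {"subject", "parameter", "value"}.issubset(df.columns):
            return cls.from_long(df)
        return cls(values=df.set_index(df.columns[0]))

    def parameters(self) -> list[str]:
        return [c for c in self.values.columns]


@dataclass
class ReliabilityResult:
    """One parameter's agreement statistics between two sources."""

    parameter: str
    n: int
    icc: float
    icc_ci: tuple[float, float]
    mean_error: float
    mean_error_ci: tuple[float, float]
    sd: float
    rmse: float
    pearson_r: float
    pearson_p: float

    def __post_init__(self):
        if not -1.0001 <= self.icc <= 1.0001:
            raise ValueError("ICC outside [-1, 1]")


def agreement_stats(a, b, alpha: float = 0.05):
    """Mean difference with CI, SD of differences, and RMSE.

    Differences are ``a - b``; the SD uses the n-1 denominator and the CI
    is the exact t-interval ``mean +- t(1-alpha/2, n-1) * sd / sqrt(n)``.
    RMSE is ``sqrt(mean(d^2))``, satisfying
    ``rmse^2 = mean^2 + sd^2 * (n-1)/n``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    n = d.size
    if n < 2:
        raise UndefinedStatisticError(f"need >= 2 pairs, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    t = float(stats.t.ppf(1 - alpha / 2, n - 1))
    half = t * sd / np.sqrt(n)
    rmse = float(np.sqrt(np.mean(d**2)))
    return {"n": n, "mean_error": mean, "mean_error_ci": (mean - half, mean + half),
            "sd": sd, "rmse": rmse}


def rmse_identity(mean_error: float, sd: float, n: int | None = None) -> float:
    """RMSE reconstructed from a printed mean error and SD.

    With ``n`` given, uses the exact sample-SD identity
    ``sqrt(me^2 + sd^2 (n-1)/n)``; without, the population reading
    ``sqrt(me^2 + sd^2)``.
    """
    if n is None:
        return float(np.sqrt(mean_error**2 + sd**2))
    return float(np.sqrt(mean_error**2 + sd**2 * (n - 1) / n))


def _anova_mean_squares(ratings: np.ndarray):
    n, k = ratings.shape
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((ratings - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


def icc_a1(ratings, alpha: float = 0.05):
    """Single-measure absolute-agreement ICC from a two-way model.

    ``ratings`` is an (n subjects x k sources) array; k=2 for a rater
    pair.  Returns ``(icc, (ci_low, ci_high))`` where the interval uses
    the McGraw & Wong F-distribution method for ICC(A,1).
    """
    r = np.asarray(ratings, dtype=float)
    r = r[~np.isnan(r).any(axis=1)]
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise UndefinedStatisticError("ICC needs >= 2 subjects and >= 2 sources")
    n, k = r.shape
    ms_r, ms_c, ms_e = _anova_mean_squares(r)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom <= 0:
        raise UndefinedStatisticError("zero total variance: ICC undefined")
    icc = (ms_r - ms_e) / denom

    # F-based interval (McGraw & Wong 1996, ICC(A,1))
    if ms_e <= 0:
        return float(icc), (float(icc), float(icc))
    fj = ms_c / ms_e
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = ((n - 1) * k**2 * icc**2 * fj**2
          + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
    v = vn / vd if vd > 0 else 1.0
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (ms_r - f_u * ms_e)
             / (f_u * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r))
    upper = (n * (f_l * ms_r - ms_e)
             / (k * ms_c + (k * n - k - n) * ms_e + n * f_l * ms_r))
    lower = min(lower, icc)
    upper = max(upper, icc)
    return float(icc), (float(lower), float(upper))


def pearson(a, b):
    """Product-moment correlation with a two-sided t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise UndefinedStatisticError(f"Pearson r needs >= 3 pairs, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError("constant input: correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def reliability_report(source_a: RaterTable, source_b: RaterTable,
                       parameters: Sequence[str] = PARAMETERS,
                       alpha: float = 0.05) -> list[ReliabilityResult]:
    """Per-parameter agreement between two sources, pairwise-complete.

    Subjects are matched on the table index; each parameter's n counts the
    subjects with non-missing values in both sources (so n may differ
    between parameters, as in cohorts with per-parameter detection
    failures).
    """
    common = source_a.values.index.intersection(source_b.values.index)
    if len(common) < 2:
        raise UndefinedStatisticError("fewer than 2 overlapping subjects")
    rows = []
    for param in parameters:
        if param not in source_a.values.columns or param not in source_b.values.columns:
            continue
        a = source_a.values.loc[common, param].to_numpy(dtype=float)
        b = source_b.values.loc[common, param].to_numpy(dtype=float)
        keep = ~(np.isnan(a) | np.isnan(b))
        if keep.sum() < 2:
            continue
        a, b = a[keep], b[keep]
        agg = agreement_stats(a, b, alpha=alpha)
        icc, icc_ci = icc_a1(np.column_stack([a, b]), alpha=alpha)
        try:
            r, p = pearson(a, b)
        except UndefinedStatisticError:
            r, p = float("nan"), float("nan")
        rows.append(ReliabilityResult(
            parameter=param, n=agg["n"], icc=icc, icc_ci=icc_ci,
            mean_error=agg["mean_error"], mean_error_ci=agg["mean_error_ci"],
            sd=agg["sd"], rmse=agg["rmse"], pearson_r=r, pearson_p=p))
    return rows


def report_frame(rows: Sequence[ReliabilityResult]) -> pd.DataFrame:
    """Flatten reliability rows into a table shaped like published reports."""
    return pd.DataFrame([{
        "parameter": r.parameter, "n": r.n,
        "icc": r.icc, "icc_ci_low": r.icc_ci[0], "icc_ci_high": r.icc_ci[1],
        "mean_error": r.mean_error,
        "mean_error_ci_low": r.mean_error_ci[0],
        "mean_error_ci_high": r.mean_error_ci[1],
        "sd": r.sd, "rmse": r.rmse,
        "pearson_r": r.pearson_r, "pearson_p": r.pearson_p,
    } for r in rows])
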