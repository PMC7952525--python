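"""Two-group nonparametric comparisons and rater-agreement statistics.

These back the descriptive tables of a treated-vs-conservative cohort:
continuous variables are summarised as median (IQR) and compared with the
Mann-Whitney U test; binary variables as count (%) with Fisher's exact test
(or Pearson chi-square when all expected counts allow it).  Inter-observer
agreement uses the two-way random-effects, absolute-agreement,
single-measurement intraclass correlation, ICC(2,1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "median_iqr",
    "mann_whitney",
    "fisher_exact",
    "chi_square",
    "icc",
    "group_comparison_table",
    "MannWhitneyResult",
    "ICCResult",
    "GroupComparisonRow",
]


def median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """Median and quartiles by inclusive linear interpolation.

    Quartiles interpolate linearly between order statistics on the (n-1)
    scale (the "inclusive" convention), so a single value v yields (v, v, v).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise InvalidInputError("median_iqr requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" | "asymptotic" | "degenerate"
    zero_variance: bool = False


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n1*n2 <= 400 and the pooled sample is tie-free;
    otherwise the normal approximation with tie-corrected variance and
    continuity correction.  A pooled sample with a single distinct value has
    zero variance; U is then its null mean and p = 1 (flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return MannWhitneyResult(
            u=x.size * y.size / 2.0, p=1.0, method="degenerate", zero_variance=True
        )
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= 400 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method=method)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Sum of hypergeometric probabilities of tables at least as extreme
    (probability <= that of the observed table).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise InvalidInputError("fisher_exact needs a 2x2 table of non-negative integers")
        t = np.round(t).astype(int)
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi_square(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Pearson chi-square statistic and p for an r x c contingency table.

    No continuity correction (plain Pearson statistic); emits a UserWarning
    when any expected count is below 5, where the exact test is preferable.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise InvalidInputError("chi_square needs a non-negative r x c table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateInputError("chi_square: zero row or column margin")
    stat, p, _, expected = sps.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        import warnings

        warnings.warn(
            "chi-square approximation questionable: an expected count is below 5",
            UserWarning,
            stacklevel=2,
        )
    return float(stat), float(p)


@dataclass(frozen=True)
class ICCResult:
    value: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    zero_between_subject_variance: bool = False


def icc(ratings: Sequence[Sequence[float]]) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is subjects x raters with no missing cells.  From the mean
    squares of the two-way decomposition (MSR rows/subjects, MSC columns/
    raters, MSE residual):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Zero between-subject variance yields 0 with a flag.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InvalidInputError("icc needs at least 2 subjects and 2 raters")
    if np.isnan(m).any():
        raise InvalidInputError("icc does not accept missing cells")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if np.isclose(msr, 0.0) or np.isclose(denom, 0.0):
        return ICCResult(0.0, msr, msc, mse, zero_between_subject_variance=True)
    return ICCResult(float((msr - mse) / denom), msr, msc, mse)


@dataclass(frozen=True)
class GroupComparisonRow:
    variable: str
    summary_a: str
    summary_b: str
    test: str  # "mann-whitney" | "fisher" | "chi-square" | "degenerate"
    p: float


#: (column, kind) pairs driving the default two-group comparison table;
#: kinds are "continuous" (median/IQR + rank test) or "binary" (count/% +
#: exact or chi-square test).
DEFAULT_COMPARISON_VARIABLES: List[Tuple[str, str]] = [
    ("ga_weeks", "continuous"),
    ("birth_weight_g", "continuous"),
    ("apgar5", "continuous"),
    ("cord_ph", "continuous"),
    ("advanced_resuscitation", "binary"),
    ("postnatal_age_h", "continuous"),
    ("td_mm", "continuous"),
    ("vmax_vmin", "continuous"),
    ("lpa_cms", "continuous"),
    ("la_ao", "continuous"),
    ("lvo_svc_ratio", "continuous"),
    ("ea_ratio", "continuous"),
    ("dao_reverse", "binary"),
    ("pda_score", "continuous"),
]


def group_comparison_table(
    cohort: pd.DataFrame,
    variables: Optional[Sequence[Tuple[str, str]]] = None,
    group_column: str = "group",
    groups: Tuple[str, str] = ("CM", "IBT"),
) -> pd.DataFrame:
    """Two-group comparison table (one row per variable, test chosen by type).

    Continuous rows report median (q1-q3) per group and a Mann-Whitney p;
    binary rows report n (%) and Fisher's exact p (Pearson chi-square when
    every expected count is >= 5).  ``dao_reverse`` and ``lvo_svc_ratio`` are
    derived on the fly if absent but derivable.
    """
    df = cohort.copy()
    if "dao_reverse" not in df.columns and "dao_direction" in df.columns:
        df["dao_reverse"] = (df["dao_direction"] == "reverse").astype(int)
    if (
        "lvo_svc_ratio" not in df.columns
        and {"lvo_mlkgmin", "svc_mlkgmin"} <= set(df.columns)
    ):
        df["lvo_svc_ratio"] = df["lvo_mlkgmin"] / df["svc_mlkgmin"]
    variables = (
        [(v, k) for v, k in DEFAULT_COMPARISON_VARIABLES if v in df.columns]
        if variables is None
        else list(variables)
    )
    a = df[df[group_column] == groups[0]]
    b = df[df[group_column] == groups[1]]
    rows = []
    for var, kind in variables:
        if var not in df.columns:
            raise InvalidInputError(f"variable {var!r} not in cohort")
        xa = a[var].dropna().to_numpy(dtype=float)
        xb = b[var].dropna().to_numpy(dtype=float)
        if kind == "continuous":
            med_a, q1_a, q3_a = median_iqr(xa)
            med_b, q1_b, q3_b = median_iqr(xb)
            res = mann_whitney(xa, xb)
            rows.append(
                GroupComparisonRow(
                    variable=var,
                    summary_a=f"{med_a:g} ({q1_a:g}–{q3_a:g})",
                    summary_b=f"{med_b:g} ({q1_b:g}–{q3_b:g})",
                    test="degenerate" if res.zero_variance else "mann-whitney",
                    p=res.p,
                )
            )
        elif kind == "binary":
            na, nb = int(xa.sum()), int(xb.sum())
            table = np.array(
                [[na, len(xa) - na], [nb, len(xb) - nb]], dtype=int
            )
            if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
                test, p = "degenerate", 1.0  # constant in both groups
            else:
                expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
                if (expected < 5).any():
                    test, p = "fisher", fisher_exact(table)
                else:
                    test, p = "chi-square", chi_square(table)[1]
            rows.append(
                GroupComparisonRow(
                    variable=var,
                    summary_a=f"{na} ({100 * na / len(xa):.0f}%)",
                    summary_b=f"{nb} ({100 * nb / len(xb):.0f}%)",
                    test=test,
                    p=p,
                )
            )
        else:
            raise InvalidInputError(f"unknown variable kind {kind!r} for {var!r}")
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.columns = ["variable", groups[0], groups[1], "test", "p"]
    return out
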