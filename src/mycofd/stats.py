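"""Statistical comparison of measurement tables.

Long-format tables (one value per row with one or two categorical
factors) feed three procedures: a factorial ANOVA (Type II sums of
squares, suitable for the mildly unbalanced designs typical of image
batches), Tukey HSD pairwise contrasts based on the studentized range,
and an unequal-variance (Welch) two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "WelchResult",
    "anova",
    "two_way_anova",
    "tukey_hsd",
    "welch_t_test",
    "welch_df_from_summary",
    "student_t_test",
]


def _check_factor(df: pd.DataFrame, col: str) -> None:
    if col not in df.columns:
        raise ValueError(f"missing column {col!r}")
    if df[col].nunique() < 2:
        raise ValueError(f"factor {col!r} needs at least 2 levels")


def anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str | None = "factor_b",
    typ: int = 2,
) -> pd.DataFrame:
    """Factorial ANOVA table (main effects + interaction when two factors).

    Type II sums of squares by default: each main effect is tested after
    the other, without the interaction — the conventional choice for
    unbalanced designs when the interaction is not of primary interest.
    Returns a tidy frame with columns term, sum_sq, df, F, p.
    """
    _check_factor(table, factor_a)
    if factor_b is not None and factor_b in table.columns and table[factor_b].notna().any():
        _check_factor(table, factor_b)
        formula = f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))"
    else:
        formula = f"Q('{value}') ~ C(Q('{factor_a}'))"
    model = smf.ols(formula, data=table).fit()
    tab = sm.stats.anova_lm(model, typ=typ).reset_index().rename(columns={"index": "term"})
    tab["term"] = (
        tab["term"]
        .str.replace(f"C(Q('{factor_a}'))", factor_a, regex=False)
        .str.replace(f"C(Q('{factor_b}'))", str(factor_b), regex=False)
    )
    tab = tab.rename(columns={"PR(>F)": "p", "F": "F"})
    return tab[["term", "sum_sq", "df", "F", "p"]]


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
    typ: int = 2,
) -> pd.DataFrame:
    """ANOVA with both factors and their interaction (see :func:`anova`)."""
    _check_factor(table, factor_b)
    return anova(table, value=value, factor_a=factor_a, factor_b=factor_b, typ=typ)


def tukey_hsd(
    table: pd.DataFrame,
    term: str,
    value: str = "value",
    other: str | None = None,
) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts for the levels of ``term``.

    The error mean square and residual df come from the OLS fit of the
    full model (including ``other`` and the interaction when given, i.e.
    post hoc to the factorial ANOVA); unequal group sizes use the
    Tukey–Kramer standard error.  Adjusted p-values come from the
    studentized range distribution; with two groups this reduces exactly
    to the pooled-variance t test.
    """
    _check_factor(table, term)
    if other is not None:
        _check_factor(table, other)
        formula = f"Q('{value}') ~ C(Q('{term}')) * C(Q('{other}'))"
    else:
        formula = f"Q('{value}') ~ C(Q('{term}'))"
    fit = smf.ols(formula, data=table).fit()
    mse = fit.mse_resid
    df_resid = fit.df_resid
    groups = table.groupby(term, observed=True)[value]
    means = groups.mean()
    ns = groups.size()
    levels = list(means.index)
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = means[b] - means[a]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se
            p = float(_sps.studentized_range.sf(q, k, df_resid))
            rows.append(
                {"group_a": a, "group_b": b, "mean_diff": float(diff), "se": float(se),
                 "q": float(q), "p_adj": min(max(p, 0.0), 1.0)}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def welch_df_from_summary(n1: int, s1: float, n2: int, s2: float) -> float:
    """Welch–Satterthwaite degrees of freedom from summary statistics:
    ``(v1 + v2)^2 / (v1^2/(n1-1) + v2^2/(n2-1))`` with ``vi = si^2 / ni``."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1 = s1**2 / n1
    v2 = s2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups")
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def welch_t_test(values_a, values_b) -> WelchResult:
    """Two-sample t test without the equal-variance assumption.

    The fractional df follow Welch–Satterthwaite and never exceed
    ``n1 + n2 - 2`` (equality holds for equal variances and equal n).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    df = welch_df_from_summary(a.size, sd_a, b.size, sd_b)
    res = _sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=sd_a,
        sd_b=sd_b,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def student_t_test(values_a, values_b) -> WelchResult:
    """Pooled-variance (classic Student) variant, df = n1 + n2 - 2."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    res = _sps.ttest_ind(a, b, equal_var=True)
    return WelchResult(
        t=float(res.statistic),
        df=float(a.size + b.size - 2),
        p=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
    )
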