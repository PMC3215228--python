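"""Cohort-level statistics: group summaries, sex comparisons, correlations.

Conventions follow the quantitative-morphometry literature this package
targets: sample SD with the ``n - 1`` denominator; coefficient of variation
``CV% = 100 * SD / mean`` (undefined, and flagged, at zero mean); percent
sex difference referenced to women, ``100 * (mean_men - mean_women) /
mean_women``; two-tailed unpaired t-test, pooled-variance Student's t by
default with Welch as an option; Pearson product-moment correlations
computed within sex only, never pooled across sexes (pooling would inflate
every correlation through the common size difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .segio import ValidationError

__all__ = [
    "GroupSummary", "ComparisonRow", "CorrelationCell", "group_summary",
    "percent_difference", "unpaired_t_test", "t_test_from_summary",
    "pearson_correlation", "correlation_matrix", "build_comparison_table",
    "variability_comparison", "format_comparison_table",
]


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    cv_percent: float       # NaN when undefined (mean == 0)
    cv_defined: bool = True


@dataclass
class ComparisonRow:
    measure: str
    men: GroupSummary
    women: GroupSummary
    diff_percent: float
    t: float
    df: float
    p_value: float
    test: str


@dataclass
class CorrelationCell:
    var_x: str
    var_y: str
    r: float
    p: float
    n: int
    defined: bool = True

    @property
    def band(self) -> str:
        """Significance band annotation: '**' p < 0.001, 'x' p < 0.05, else ''."""
        if not self.defined:
            return "undefined"
        if self.p < 0.001:
            return "**"
        if self.p < 0.05:
            return "x"
        return ""


def group_summary(values) -> GroupSummary:
    """Mean, sample SD (n - 1) and CV% of one group (n >= 2)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValidationError("group summary needs at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0.0:
        return GroupSummary(len(v), mean, sd, math.nan, cv_defined=False)
    return GroupSummary(len(v), mean, sd, 100.0 * sd / abs(mean))


def percent_difference(mean_men: float, mean_women: float) -> float:
    """Women-referenced percent difference, sign preserved."""
    if mean_women == 0:
        raise ValidationError("percent difference undefined at zero reference mean")
    return 100.0 * (mean_men - mean_women) / mean_women


def unpaired_t_test(group1, group2, variant: str = "pooled"):
    """Two-tailed unpaired t-test; returns (t, df, p).

    ``variant='pooled'`` is the classical Student's t with
    ``df = n1 + n2 - 2``; ``'welch'`` uses the Welch-Satterthwaite df.
    """
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("t-test needs at least 2 values per group")
    _check_variant(variant)
    res = sps.ttest_ind(g1, g2, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def t_test_from_summary(m1, sd1, n1, m2, sd2, n2, variant: str = "pooled"):
    """Same test computed from group summary statistics (for published tables)."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("t-test needs at least 2 values per group")
    _check_variant(variant)
    res = sps.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2,
                                   equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        a, b = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def _check_variant(variant: str) -> None:
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")


def pearson_correlation(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationCell:
    """Product-moment r with two-tailed p from t = r * sqrt((n-2)/(1-r^2))."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("correlation needs two equal-length vectors, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationCell(var_x, var_y, math.nan, math.nan, len(x), defined=False)
    r, p = sps.pearsonr(x, y)
    return CorrelationCell(var_x, var_y, float(r), float(p), len(x))


def correlation_matrix(cohort: pd.DataFrame, variables, by_sex: bool = True,
                       sex_col: str = "sex"):
    """Upper-triangle correlation cells per sex (men/women kept separate).

    Returns ``{sex: {(v1, v2): CorrelationCell}}`` (a single ``"all"`` group
    when ``by_sex`` is false).  Constant variables yield flagged undefined
    cells.  Cells carry a significance-band annotation (p < 0.001 / p < 0.05).
    """
    variables = list(variables)
    groups = cohort.groupby(sex_col) if by_sex else [("all", cohort)]
    out: dict[str, dict[tuple[str, str], CorrelationCell]] = {}
    for sex, df in groups:
        cells = {}
        for i, v1 in enumerate(variables):
            for v2 in variables[i + 1:]:
                cells[(v1, v2)] = pearson_correlation(df[v1], df[v2], v1, v2)
        out[str(sex)] = cells
    return out


def build_comparison_table(cohort: pd.DataFrame, measures, variant: str = "pooled",
                           sex_col: str = "sex") -> list[ComparisonRow]:
    """Men-vs-women comparison rows (summary, percent difference, t-test)."""
    if cohort.empty:
        raise ValidationError("empty cohort")
    _check_variant(variant)
    men = cohort[cohort[sex_col] == "M"]
    women = cohort[cohort[sex_col] == "F"]
    if len(men) < 2 or len(women) < 2:
        raise ValidationError("need at least 2 subjects per sex")
    rows = []
    for m in measures:
        gm, gw = group_summary(men[m]), group_summary(women[m])
        t, df, p = unpaired_t_test(men[m], women[m], variant)
        rows.append(ComparisonRow(
            measure=m, men=gm, women=gw,
            diff_percent=percent_difference(gm.mean, gw.mean),
            t=t, df=df, p_value=p, test=variant))
    return rows


def _sig(value: float, figures: int) -> str:
    if value == 0 or not np.isfinite(value):
        return str(value)
    ndigits = figures - 1 - int(math.floor(math.log10(abs(value))))
    rounded = round(value, ndigits)
    if ndigits <= 0:
        return f"{rounded:.0f}"
    return f"{rounded:.{ndigits}f}"


def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_comparison_table(rows: list[ComparisonRow]) -> str:
    """Plain-text rendering: mean/SD to 3 significant figures, Diff (%) to
    one decimal, p to three decimals with a '<0.001' floor."""
    header = f"{'measure':<18}{'MenMean':>9}{'SD':>8}{'WomenMean':>11}{'SD':>8}" \
             f"{'Diff (%)':>10}{'t-test':>9}"
    lines = [header]
    for r in rows:
        lines.append(
            f"{r.measure:<18}{_sig(r.men.mean, 3):>9}{_sig(r.men.sd, 3):>8}"
            f"{_sig(r.women.mean, 3):>11}{_sig(r.women.sd, 3):>8}"
            f"{r.diff_percent:>10.1f}{format_p(r.p_value):>9}")
    return "\n".join(lines)


def comparison_to_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "measure": r.measure,
        "men_n": r.men.n, "men_mean": r.men.mean, "men_sd": r.men.sd,
        "men_cv_pct": r.men.cv_percent,
        "women_n": r.women.n, "women_mean": r.women.mean, "women_sd": r.women.sd,
        "women_cv_pct": r.women.cv_percent,
        "diff_pct": r.diff_percent, "t": r.t, "df": r.df, "p": r.p_value,
        "test": r.test,
    } for r in rows])


def variability_comparison(cohort: pd.DataFrame, tot_col: str = "TOT_A",
                           ratio_col: str = "TOTA_over_ACdAB",
                           sex_col: str = "sex") -> dict:
    """CV% of absolute vs plateau-normalized meniscus size, per sex.

    Reports whether normalizing total meniscus surface area by the
    ipsi-compartmental plateau area reduces the within-sex inter-subject
    variability (it does in size-correlated cohorts; the ordering is
    reported, not asserted).
    """
    out = {}
    for sex, df in cohort.groupby(sex_col):
        cv_tot = group_summary(df[tot_col]).cv_percent
        cv_ratio = group_summary(df[ratio_col]).cv_percent
        out[str(sex)] = {
            "cv_tot_area_pct": cv_tot,
            "cv_ratio_pct": cv_ratio,
            "normalization_reduces_cv": bool(cv_ratio < cv_tot),
        }
    return out
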