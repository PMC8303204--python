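"""Sex-specific VO2peak quartile descriptives.

Participants are grouped by the empirical quartiles of their sex-specific
VO2peak (type-7 quantile convention; values tied with a boundary fall in
the lower quarter). Numeric characteristics are compared across quarters
with Welch's heteroscedastic ANOVA, categorical ones (menopausal status)
with Pearson's chi-squared test, and relative means (mean of quarter q
over mean of quarter 1) provide the radar-plot-ready summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import COVARIATE_NAMES, PhenotypeTable, ValidationError

__all__ = [
    "QuarterSummary",
    "quartile_groups",
    "welch_anova",
    "chi_squared_quarters",
    "quarter_summary_table",
    "summaries_to_frame",
]


@dataclass
class QuarterSummary:
    variable_id: str
    n: tuple[int, int, int, int]
    mean: tuple[float, float, float, float]
    sd: tuple[float, float, float, float]
    relative_mean: tuple[float, float, float, float]
    test: str                     # "welch_anova" or "chi_squared"
    p_value: float


def quartile_groups(values) -> np.ndarray:
    """Quarter labels 1..4 from the empirical quartiles of ``values``.

    Uses the type-7 (linear interpolation) quantile convention; a value
    equal to a boundary goes to the lower quarter.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise ValidationError(["need at least 8 values for quartile groups"])
    if np.all(x == x[0]):
        raise ValidationError(["constant vector has no quartiles"])
    q1, q2, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # type-7 default
    return 1 + (x > q1).astype(int) + (x > q2).astype(int) + (x > q3).astype(int)


def welch_anova(values, groups) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns (F, df1, df2, p) with the Satterthwaite denominator degrees of
    freedom. Requires every group to have at least 2 members and nonzero
    variance overall.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValidationError(["need at least 2 groups"])
    ns, means, variances = [], [], []
    for lab in labels:
        xi = x[g == lab]
        if len(xi) < 2:
            raise ValidationError([f"group {lab!r} has fewer than 2 members"])
        ns.append(len(xi))
        means.append(xi.mean())
        variances.append(xi.var(ddof=1))
    ns = np.array(ns, float)
    means = np.array(means)
    variances = np.array(variances)
    k = len(labels)
    if np.all(variances == 0):
        # all groups internally constant
        if np.all(means == means[0]):
            return 0.0, float(k - 1), float("inf"), 1.0
        raise ValidationError(["zero within-group variance with unequal means"])
    w = ns / variances
    grand = (w * means).sum() / w.sum()
    num = ((w * (means - grand) ** 2).sum()) / (k - 1)
    h = ((1 - w / w.sum()) ** 2 / (ns - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * h
    F = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * h)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, float(df2), p


def chi_squared_quarters(categories, groups) -> tuple[float, float, float]:
    """Pearson chi-squared test of independence (no continuity correction).

    Emits a warning when an expected cell count falls below 5 but still
    returns the statistic.
    """
    table = pd.crosstab(pd.Series(categories), pd.Series(groups))
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any() or table.size == 0:
        raise ValidationError(["degenerate contingency table"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError(["need at least a 2x2 table"])
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("expected cell count below 5; chi-squared approximation is weak")
    return float(res.statistic), float(res.dof), float(res.pvalue)


#: numeric basic characteristics summarized per quarter
NUMERIC_CHARACTERISTICS = ("age", "vo2peak", *COVARIATE_NAMES)


def quarter_summary_table(pheno: PhenotypeTable, sex: str) -> list[QuarterSummary]:
    """One row per basic characteristic for one sex subgroup.

    Assumes imputable covariates were imputed beforehand, so every
    characteristic uses the full subgroup n.
    """
    sub = pheno.subset(sex).data
    if sub.empty:
        raise ValidationError([f"no samples with sex {sex}"])
    groups = quartile_groups(sub["vo2peak"].to_numpy())
    out: list[QuarterSummary] = []
    for var in NUMERIC_CHARACTERISTICS:
        x = sub[var].to_numpy(float)
        if np.isnan(x).any():
            raise ValidationError([f"{var}: missing values (impute first)"])
        ns, means, sds = [], [], []
        for q in (1, 2, 3, 4):
            xq = x[groups == q]
            ns.append(len(xq))
            means.append(float(xq.mean()))
            sds.append(float(xq.std(ddof=1)))
        if np.all(x == x[0]):
            p = 1.0
        else:
            _, _, _, p = welch_anova(x, groups)
        ref = means[0]
        rel = tuple(m / ref if ref != 0 else float("nan") for m in means)
        out.append(QuarterSummary(var, tuple(ns), tuple(means), tuple(sds),
                                  rel, "welch_anova", p))
    if sex == "F":
        meno = sub["menopausal_status"].to_numpy()
        try:
            statistic, _, p = chi_squared_quarters(meno, groups)
        except ValidationError:
            statistic, p = float("nan"), float("nan")
        share = [float((meno[groups == q] == "pre").mean()) for q in (1, 2, 3, 4)]
        ref = share[0]
        rel = tuple(s / ref if ref else float("nan") for s in share)
        out.append(QuarterSummary(
            "menopausal_pre_share",
            tuple(int((groups == q).sum()) for q in (1, 2, 3, 4)),
            tuple(share), (float("nan"),) * 4, rel, "chi_squared", p))
    return out


def summaries_to_frame(rows: list[QuarterSummary]) -> pd.DataFrame:
    records = []
    for r in rows:
        rec = {"variable": r.variable_id, "test": r.test, "p_value": r.p_value}
        for q in range(4):
            rec[f"n_q{q + 1}"] = r.n[q]
            rec[f"mean_q{q + 1}"] = r.mean[q]
            rec[f"sd_q{q + 1}"] = r.sd[q]
            rec[f"relative_mean_q{q + 1}"] = r.relative_mean[q]
        records.append(rec)
    return pd.DataFrame(records)
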