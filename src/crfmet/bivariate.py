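"""Partial Pearson correlations of VO2peak with each analyte.

Significance is decided exclusively by whether the Fisher-z 95% confidence
interval excludes zero; no p-values and no multiple-testing correction are
computed (see the methods note for a discussion of that choice). The
standard error of atanh(r) is 1/sqrt(n − 3) with no degrees-of-freedom
correction for the covariates removed — the convention validated against
the worked interval examples in the test suite.

Two adjustment profiles are exposed throughout:

* ``star`` (*): confounders only — age, plus menopausal status in women;
* ``doublestar`` (**): confounders plus the 21 phenotypical/clinical
  covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import MajorPathway, ScoreMatrix, ValidationError
from .preprocess import residualize

__all__ = [
    "CorrelationResult",
    "PathwaySummary",
    "fisher_ci",
    "partial_correlation",
    "correlate_all",
    "summarize_by_pathway",
    "pathway_shares",
    "top_table",
    "results_to_frame",
    "results_from_frame",
]

RELEVANCE_THRESHOLD = 0.25  # |r| at or above this is a "relevant" correlation


@dataclass(frozen=True)
class CorrelationResult:
    variable_id: str
    r: float
    ci_low: float
    ci_high: float
    n: int
    n_covariates: int
    significant: bool

    def __post_init__(self):
        if not (self.ci_low <= self.r <= self.ci_high):
            raise ValidationError([f"{self.variable_id}: CI does not bracket r"])


@dataclass(frozen=True)
class PathwaySummary:
    pathway: MajorPathway
    n_total: int
    n_significant_star: int
    n_significant_doublestar: int


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh(r) ± z_{1−α/2}/sqrt(n−3))."""
    if n <= 3:
        raise ValidationError(["need n > 3 for a Fisher-z interval"])
    z = stats.norm.ppf(1 - alpha / 2)
    half = z / np.sqrt(n - 3)
    center = np.arctanh(r)
    return float(np.tanh(center - half)), float(np.tanh(center + half))


def partial_correlation(x, y, covariates=None, variable_id: str = "",
                        alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation of x and y after removing the covariates from both.

    With an empty covariate set this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is not None and np.size(covariates) > 0:
        n_cov = covariates.shape[1] if np.ndim(covariates) == 2 else 1
    else:
        n_cov = 0
    if n < 5 + n_cov:
        raise ValidationError([f"{variable_id}: need n >= 5 + n_covariates"])
    rx = residualize(x, covariates)
    ry = residualize(y, covariates)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValidationError([f"{variable_id}: zero variance after residualization"])
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        lo, hi = r, r
    else:
        lo, hi = fisher_ci(r, n, alpha)
    significant = not (lo <= 0.0 <= hi)
    return CorrelationResult(variable_id, r, lo, hi, n, n_cov, significant)


def correlate_all(matrix: ScoreMatrix | pd.DataFrame, response,
                  covariates: pd.DataFrame | None = None,
                  alpha: float = 0.05) -> list[CorrelationResult]:
    """One partial correlation per column, column order preserved."""
    frame = matrix.scores if isinstance(matrix, ScoreMatrix) else matrix
    response = np.asarray(response, dtype=float)
    if covariates is not None:
        for c in covariates.columns:
            if np.allclose(covariates[c].to_numpy(float), response):
                raise ValidationError([f"covariate {c} identical to the response"])
    return [partial_correlation(frame[c].to_numpy(), response, covariates,
                                variable_id=str(c), alpha=alpha)
            for c in frame.columns]


def summarize_by_pathway(star: list[CorrelationResult],
                         doublestar: list[CorrelationResult],
                         analytes) -> list[PathwaySummary]:
    """Per-pathway totals and significant counts under both profiles,
    plus a grand-total row (pathway 'unknown' is a real category; the
    total row uses pathway=None)."""
    star_ids = {r.variable_id for r in star}
    double_ids = {r.variable_id for r in doublestar}
    if star_ids != double_ids:
        raise ValidationError(["star and doublestar results cover different analytes"])
    pathway_of = {a.analyte_id: a.major_pathway for a in analytes}
    missing = sorted(star_ids - set(pathway_of))
    if missing:
        raise ValidationError([f"annotation missing analytes: {missing}"])
    sig_star = {r.variable_id for r in star if r.significant}
    sig_double = {r.variable_id for r in doublestar if r.significant}
    rows = []
    for pw in MajorPathway:
        ids = [i for i in star_ids if pathway_of[i] == pw]
        if not ids and pw != MajorPathway.UNKNOWN:
            # keep empty rows out except the catch-all
            continue
        rows.append(PathwaySummary(pw, len(ids),
                                   len(sig_star & set(ids)),
                                   len(sig_double & set(ids))))
    rows.append(PathwaySummary(None, len(star_ids), len(sig_star), len(sig_double)))
    return rows


def pathway_shares(counts: pd.Series) -> pd.DataFrame:
    """Percentage shares of identified metabolites by major pathway.

    ``counts`` maps pathway name → number of analytes; the ``unknown``
    entry counts unidentified analytes and is excluded from the identified
    total. Returns a frame with per-pathway count and percent of the
    identified total.
    """
    counts = counts.astype(int)
    identified = counts.drop(labels=["unknown"], errors="ignore")
    total = int(identified.sum())
    if total == 0:
        raise ValidationError(["no identified metabolites"])
    out = pd.DataFrame({"count": identified})
    out["pct_of_identified"] = 100.0 * out["count"] / total
    out.attrs["n_identified"] = total
    return out


def top_table(results: list[CorrelationResult], k: int = 10) -> pd.DataFrame:
    """Top-k positive and top-k negative correlations, flagged for relevance.

    Positive side sorted by descending r, negative side by ascending r;
    ties broken by variable id. Short sides simply truncate.
    """
    if k < 1:
        raise ValidationError(["k must be >= 1"])
    pos = sorted((r for r in results if r.r > 0),
                 key=lambda c: (-c.r, c.variable_id))[:k]
    neg = sorted((r for r in results if r.r < 0),
                 key=lambda c: (c.r, c.variable_id))[:k]
    rows = []
    for side, group in (("positive", pos), ("negative", neg)):
        for rank, res in enumerate(group, start=1):
            rows.append({
                "side": side, "rank": rank, "variable": res.variable_id,
                "r": res.r, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "significant": res.significant,
                "relevant": abs(res.r) >= RELEVANCE_THRESHOLD,
            })
    return pd.DataFrame(rows, columns=["side", "rank", "variable", "r",
                                       "ci_low", "ci_high", "significant",
                                       "relevant"])


# -- serialization helpers ---------------------------------------------------

def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variable": r.variable_id, "r": r.r, "ci_low": r.ci_low,
          "ci_high": r.ci_high, "n": r.n, "n_covariates": r.n_covariates,
          "significant": r.significant} for r in results],
        columns=["variable", "r", "ci_low", "ci_high", "n", "n_covariates",
                 "significant"])


def results_from_frame(frame: pd.DataFrame) -> list[CorrelationResult]:
    return [CorrelationResult(str(row.variable), float(row.r), float(row.ci_low),
                              float(row.ci_high), int(row.n),
                              int(row.n_covariates), bool(row.significant))
            for row in frame.itertuples()]


def pathway_summary_frame(rows: list[PathwaySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"pathway": r.pathway.value if r.pathway is not None else "all",
          "n_total": r.n_total,
          "n_significant_star": r.n_significant_star,
          "n_significant_doublestar": r.n_significant_doublestar}
         for r in rows])
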