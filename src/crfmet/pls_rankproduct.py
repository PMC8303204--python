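"""Multivariate association via cross-validated PLS rank products.

The statistic: over ``n_outer_splits`` random 80/20 calibration/test
splits, a single-response PLS regression is tuned (inner random k-fold
cross-validation on RMSE, component count capped) and fitted on the
calibration samples; within each split every analyte receives a rank by
descending absolute regression coefficient (rank 1 = largest influence).
The per-analyte *rank product* is the geometric mean of its ranks across
splits — consistently influential analytes get small rank products.

Significance comes from permutations of the response: an analyte is
significant when the fraction of permutation rank products falling
strictly below its observed rank product is at most ``alpha``. The mean
test-set RMSE of the permuted models is kept alongside as a global
model-relevance check (if permuted models predict as well as the real
one, the multivariate association carries no information).

Two permutation modes are provided because the procedure's cost is
dominated by re-tuning: ``full_refit`` re-runs the entire outer procedure
per permutation, ``fast_reuse`` keeps the observed splits and tuned
component counts and only refits the final models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning

from .dataio import ScoreMatrix, ValidationError
from .bivariate import CorrelationResult, RELEVANCE_THRESHOLD

__all__ = [
    "PLSRunConfig",
    "PLSModel",
    "RankProductResult",
    "fit_pls",
    "tune_ncomp",
    "outer_rank_products",
    "permutation_significance",
    "volcano_table",
]


@dataclass(frozen=True)
class PLSRunConfig:
    n_outer_splits: int = 20
    calibration_fraction: float = 0.8
    inner_folds: int = 8
    max_components: int = 10
    n_permutations: int = 2500
    alpha: float = 0.05
    seed: int = 0
    permutation_mode: str = "fast_reuse"  # or "full_refit"

    def __post_init__(self):
        problems = []
        if self.inner_folds < 2:
            problems.append("inner_folds must be >= 2")
        if self.max_components < 1:
            problems.append("max_components must be >= 1")
        if not 0 < self.alpha < 1:
            problems.append("alpha must lie in (0, 1)")
        if not 0 < self.calibration_fraction < 1:
            problems.append("calibration_fraction must lie in (0, 1)")
        if self.permutation_mode not in ("full_refit", "fast_reuse"):
            problems.append(f"unknown permutation mode {self.permutation_mode}")
        if problems:
            raise ValidationError(problems)


@dataclass
class PLSModel:
    """Fitted single-response PLS model in affine form.

    ``coefficients`` are per unit *scaled* predictor; prediction is
    ``intercept + ((x − x_means) / x_scales) · coefficients``.
    """

    n_components: int
    x_means: np.ndarray
    x_scales: np.ndarray
    coefficients: np.ndarray
    intercept: float

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_means) / self.x_scales
        return self.intercept + Xs @ self.coefficients


def _standardize(X: np.ndarray):
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    if (scales == 0).any():
        bad = list(np.flatnonzero(scales == 0))
        raise ValidationError([f"zero-variance columns: {bad}"])
    return (X - means) / scales, means, scales


def fit_pls(X, y, n_components: int) -> PLSModel:
    """NIPALS single-response PLS on column-standardized predictors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError(["missing values not allowed in PLS"])
    if n_components < 1:
        raise ValidationError(["n_components must be >= 1"])
    Xs, means, scales = _standardize(X)
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        warnings.warn(f"n_components={n_components} truncated to rank bound {rank}")
        n_components = rank
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Xs, y - y.mean())
    coef = np.ravel(pls.coef_)
    return PLSModel(n_components, means, scales, coef, float(y.mean()))


def tune_ncomp(X_cal, y_cal, config: PLSRunConfig, rng: np.random.Generator | None = None) -> int:
    """Pick the component count minimizing inner-CV RMSE (single random
    fold assignment; ties resolved toward the smaller count)."""
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    n = len(y_cal)
    if n < config.inner_folds:
        raise ValidationError(["calibration set smaller than inner_folds"])
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fold_of = np.resize(np.arange(config.inner_folds), n)
    rng.shuffle(fold_of)
    kmax = min(config.max_components, n - 1 - int(np.ceil(n / config.inner_folds)), X_cal.shape[1])
    kmax = max(kmax, 1)
    rmses = np.empty(kmax)
    sq_err = np.zeros((kmax, n))
    for f in range(config.inner_folds):
        test = fold_of == f
        train = ~test
        Xs, means, scales = _standardize_safe(X_cal[train])
        Xt = (X_cal[test] - means) / scales
        ym = y_cal[train].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in range(1, kmax + 1):
                pls = PLSRegression(n_components=min(k, train.sum() - 1), scale=False)
                pls.fit(Xs, y_cal[train] - ym)
                pred = ym + Xt @ np.ravel(pls.coef_)
                sq_err[k - 1, test] = (y_cal[test] - pred) ** 2
    rmses = np.sqrt(sq_err.mean(axis=1))
    # smallest count within numerical tolerance of the minimum (exact ties
    # arise for noiseless signals where every extra component is inert)
    best = rmses.min()
    return int(np.flatnonzero(rmses <= best * (1 + 1e-8) + 1e-12)[0]) + 1


def _standardize_safe(X: np.ndarray):
    """Standardize, mapping zero-variance columns to all-zero columns."""
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    scales = np.where(scales == 0, 1.0, scales)
    return (X - means) / scales, means, scales


@dataclass
class RankProductResult:
    analyte_ids: list[str]
    ranks: np.ndarray                 # n_outer_splits × p (average-rank ties)
    rank_product: np.ndarray          # geometric mean of ranks, per analyte
    mean_test_rmse: float
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    ncomps: list[int] = field(default_factory=list)
    perm_frequency: np.ndarray | None = None
    significant: np.ndarray | None = None
    perm_mean_test_rmse: np.ndarray | None = None
    alpha: float = 0.05
    n_permutations: int = 0

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"analyte": self.analyte_ids,
                              "rank_product": self.rank_product})
        for s in range(self.ranks.shape[0]):
            frame[f"rank_split{s + 1}"] = self.ranks[s]
        if self.perm_frequency is not None:
            frame["perm_frequency"] = self.perm_frequency
            frame["significant"] = self.significant
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RankProductResult":
        rank_cols = [c for c in frame.columns if c.startswith("rank_split")]
        ranks = frame[rank_cols].to_numpy(float).T
        perm = frame["perm_frequency"].to_numpy(float) if "perm_frequency" in frame else None
        sig = frame["significant"].to_numpy(bool) if "significant" in frame else None
        return cls(list(frame["analyte"].astype(str)), ranks,
                   frame["rank_product"].to_numpy(float),
                   mean_test_rmse=float("nan"),
                   perm_frequency=perm, significant=sig)


def _split_indices(n: int, config: PLSRunConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Reproducible outer splits: one child seed per split so any split can
    be regenerated in isolation."""
    n_cal = int(round(config.calibration_fraction * n))
    n_cal = min(max(n_cal, config.inner_folds), n - 1)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_outer_splits)
    splits = []
    for ss in seeds:
        perm = np.random.default_rng(ss).permutation(n)
        splits.append((np.sort(perm[:n_cal]), np.sort(perm[n_cal:])))
    return splits


def _rank_coefficients(coef: np.ndarray) -> np.ndarray:
    # rank 1 = largest |coefficient|; average ranks on ties
    return stats.rankdata(-np.abs(coef), method="average")


def outer_rank_products(X, y, config: PLSRunConfig,
                        splits=None, ncomps=None) -> RankProductResult:
    """Observed rank products over the outer calibration/test splits.

    Scaling and tuning happen inside each split using calibration data
    only. Passing precomputed ``splits``/``ncomps`` re-uses an existing
    layout (the fast permutation mode relies on this).
    """
    if isinstance(X, ScoreMatrix):
        X = X.scores
    ids = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else [
        f"v{i}" for i in range(np.shape(X)[1])]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValidationError(["need at least 2 analytes"])
    if splits is None:
        splits = _split_indices(n, config)
    tune_rngs = [np.random.default_rng((config.seed + 7919 * (s + 1)) % (2**31))
                 for s in range(len(splits))]
    all_ranks = np.empty((len(splits), p))
    rmses = np.empty(len(splits))
    used_ncomps = []
    for s, (cal, test) in enumerate(splits):
        if ncomps is None:
            k = tune_ncomp(X[cal], y[cal], config, tune_rngs[s])
        else:
            k = ncomps[s]
        model = fit_pls(X[cal], y[cal], k)
        all_ranks[s] = _rank_coefficients(model.coefficients)
        pred = model.predict(X[test])
        rmses[s] = np.sqrt(np.mean((y[test] - pred) ** 2))
        used_ncomps.append(model.n_components)
    rank_product = np.exp(np.log(all_ranks).mean(axis=0))
    return RankProductResult(ids, all_ranks, rank_product,
                             float(rmses.mean()), splits=list(splits),
                             ncomps=used_ncomps, alpha=config.alpha)


def permutation_significance(X, y, observed: RankProductResult,
                             config: PLSRunConfig) -> RankProductResult:
    """Permutation test of the rank products.

    Per permutation the response is shuffled and rank products are
    recomputed; ``perm_frequency`` is the fraction of permutations whose
    rank product falls strictly below the observed one (ties count as not
    below). ``fast_reuse`` keeps the observed splits and tuned component
    counts; ``full_refit`` re-runs tuning inside every permutation.
    """
    if config.n_permutations < 1:
        raise ValidationError(["n_permutations must be >= 1"])
    if isinstance(X, ScoreMatrix):
        X = X.scores
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng((config.seed + 104729) % (2**31))
    below = np.zeros(len(observed.analyte_ids))
    perm_rmse = np.empty(config.n_permutations)

    if config.permutation_mode == "fast_reuse":
        # precompute per-split standardized calibration/test predictor blocks
        cache = []
        for (cal, test), k in zip(observed.splits, observed.ncomps):
            Xs, means, scales = _standardize(X[cal])
            Xt = (X[test] - means) / scales
            cache.append((cal, test, Xs, Xt, k))
        for j in range(config.n_permutations):
            y_perm = rng.permutation(y)
            ranks = np.empty((len(cache), X.shape[1]))
            rmses = np.empty(len(cache))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for s, (cal, test, Xs, Xt, k) in enumerate(cache):
                    ym = y_perm[cal].mean()
                    pls = PLSRegression(n_components=k, scale=False)
                    pls.fit(Xs, y_perm[cal] - ym)
                    coef = np.ravel(pls.coef_)
                    ranks[s] = _rank_coefficients(coef)
                    pred = ym + Xt @ coef
                    rmses[s] = np.sqrt(np.mean((y_perm[test] - pred) ** 2))
            rp = np.exp(np.log(ranks).mean(axis=0))
            below += rp < observed.rank_product
            perm_rmse[j] = rmses.mean()
    else:  # full_refit
        for j in range(config.n_permutations):
            y_perm = rng.permutation(y)
            res = outer_rank_products(pd.DataFrame(X, columns=observed.analyte_ids),
                                      y_perm, config, splits=observed.splits)
            below += res.rank_product < observed.rank_product
            perm_rmse[j] = res.mean_test_rmse

    freq = below / config.n_permutations
    return replace(observed,
                   perm_frequency=freq,
                   significant=freq <= config.alpha,
                   perm_mean_test_rmse=perm_rmse,
                   alpha=config.alpha,
                   n_permutations=config.n_permutations)


def volcano_table(bivariate: list[CorrelationResult],
                  multivariate: RankProductResult,
                  analytes=None) -> pd.DataFrame:
    """Combine both association views into a plot-ready table.

    x = partial correlation r; y = −log10 of the permutation frequency,
    floored at 1/(n_permutations + 1) so an empirical zero stays finite.
    The relevance class follows the interpretation rule: an analyte is
    relevant when |r| ≥ 0.25 or its multivariate contribution is
    significant.
    """
    if multivariate.perm_frequency is None:
        raise ValidationError(["run permutation_significance first"])
    r_of = {c.variable_id: c.r for c in bivariate}
    if set(r_of) != set(multivariate.analyte_ids):
        raise ValidationError(["bivariate and multivariate analyte sets differ"])
    pathway_of = {}
    if analytes is not None:
        pathway_of = {a.analyte_id: a.major_pathway.value for a in analytes}
    floor = 1.0 / (multivariate.n_permutations + 1)
    rows = []
    for i, aid in enumerate(multivariate.analyte_ids):
        freq = multivariate.perm_frequency[i]
        sig = bool(multivariate.significant[i])
        r = r_of[aid]
        biv_rel = abs(r) >= RELEVANCE_THRESHOLD
        cls = ("both" if biv_rel and sig else
               "bivariate" if biv_rel else
               "multivariate" if sig else "none")
        rows.append({
            "analyte": aid, "r": r,
            "neg_log10_perm_frequency": float(-np.log10(max(freq, floor))),
            "perm_frequency": float(freq),
            "significant_multivariate": sig,
            "pathway": pathway_of.get(aid, ""),
            "relevance_class": cls,
        })
    return pd.DataFrame(rows)
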