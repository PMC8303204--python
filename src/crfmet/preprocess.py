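"""Matrix integration filters, rank-normal scores, residualization, imputation.

The fixed preprocessing order of the pipeline is:

1. resolve cross-platform duplicate analytes (keep the most quantitative),
2. drop analytes detected in fewer than 20% of either sex subgroup,
3. per sex: Van der Waerden (rank-based inverse normal) transform,
4. residualize on the confounders (age, plus menopausal status in women).

Below-LOD intensities take part in the ranking as a tied block at the
bottom; missing values propagate as missing and never enter a rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .dataio import (
    COVARIATE_NAMES,
    IMPUTABLE_COVARIATES,
    PLATFORM_ORDER,
    MetaboliteMatrix,
    PhenotypeTable,
    ScoreMatrix,
    ValidationError,
)

__all__ = [
    "PreprocessReport",
    "resolve_platform_duplicates",
    "filter_detection_frequency",
    "vdw_transform",
    "vdw_scores_frame",
    "residualize",
    "impute_random_forest",
    "preprocess_matrix",
]


@dataclass
class PreprocessReport:
    """Bookkeeping of sample/analyte exclusions and imputed cells.

    Output counts are derived, never stored, so the conservation law
    ``n_out = n_in − removals`` holds by construction on both axes.
    """

    n_samples_in: int = 0
    n_analytes_in: int = 0
    removed_samples: list[str] = field(default_factory=list)
    removed_duplicates: list[str] = field(default_factory=list)
    removed_low_frequency: list[str] = field(default_factory=list)
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - len(self.removed_samples)

    @property
    def n_analytes_out(self) -> int:
        return self.n_analytes_in - len(self.removed_duplicates) - len(self.removed_low_frequency)

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        """Chain two stages: input counts come from the first stage."""
        overlap = set(self.removed_duplicates) & set(other.removed_low_frequency)
        if overlap:
            raise ValidationError([f"analyte removed twice: {sorted(overlap)}"])
        return PreprocessReport(
            n_samples_in=self.n_samples_in,
            n_analytes_in=self.n_analytes_in,
            removed_samples=self.removed_samples + other.removed_samples,
            removed_duplicates=self.removed_duplicates + other.removed_duplicates,
            removed_low_frequency=self.removed_low_frequency + other.removed_low_frequency,
            imputed_cells=self.imputed_cells + other.imputed_cells,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("removed_sample", s) for s in self.removed_samples]
            + [("removed_duplicate", a) for a in self.removed_duplicates]
            + [("removed_low_frequency", a) for a in self.removed_low_frequency]
            + [("imputed_cell", f"{s}:{c}") for s, c in self.imputed_cells]
        )
        frame = pd.DataFrame(rows, columns=["event", "target"])
        frame.attrs["n_samples_in"] = self.n_samples_in
        frame.attrs["n_analytes_in"] = self.n_analytes_in
        return frame


def resolve_platform_duplicates(matrix: MetaboliteMatrix) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Keep, within each duplicate group, only the most quantitative copy.

    Survivor = smallest ``quantitative_rank``; ties broken by platform
    enum order, then analyte id (deterministic and documented).
    """
    report = PreprocessReport(n_samples_in=matrix.n_samples,
                              n_analytes_in=matrix.n_analytes)
    groups: dict[str, list] = {}
    for ann in matrix.analytes:
        if ann.duplicate_group:
            groups.setdefault(ann.duplicate_group, []).append(ann)
    removed: list[str] = []
    for members in groups.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda a: (
            a.quantitative_rank, PLATFORM_ORDER[a.platform.value], a.analyte_id))
        removed.extend(a.analyte_id for a in members[1:])
    report.removed_duplicates = sorted(removed)
    keep = [a.analyte_id for a in matrix.analytes if a.analyte_id not in set(removed)]
    return matrix.subset_analytes(keep), report


def filter_detection_frequency(matrix: MetaboliteMatrix, sex_labels: pd.Series,
                               min_freq: float = 0.20) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Drop analytes detected in < ``min_freq`` of either sex subgroup.

    An analyte survives iff its detection frequency is >= the threshold in
    *both* subgroups (values exactly at the threshold are kept).
    """
    report = PreprocessReport(n_samples_in=matrix.n_samples,
                              n_analytes_in=matrix.n_analytes)
    sex_labels = sex_labels.reindex(matrix.sample_ids)
    detected = matrix.detected()
    keep_mask = pd.Series(True, index=matrix.analyte_ids)
    for sex, idx in sex_labels.groupby(sex_labels).groups.items():
        if len(idx) == 0:
            raise ValidationError([f"empty {sex} subgroup"])
        freq = detected.loc[idx].mean(axis=0)
        keep_mask &= freq >= min_freq
    if sex_labels.nunique() == 0:
        raise ValidationError(["no samples"])
    report.removed_low_frequency = sorted(keep_mask.index[~keep_mask])
    return matrix.subset_analytes(list(keep_mask.index[keep_mask])), report


def vdw_transform(values, below_lod=None, strict: bool = False) -> np.ndarray:
    """Van der Waerden scores: Φ⁻¹(rank / (n + 1)) with average-rank ties.

    ``below_lod`` marks entries with no numeric value that are known to be
    below the detection limit; they enter the ranking as a tied block below
    every observed value. NaN entries (missing) propagate as NaN and do not
    contribute to ``n``. Requires at least 3 usable entries.

    A fully tied vector is degenerate: with ``strict`` it raises, otherwise
    every score is 0.
    """
    x = np.asarray(values, dtype=float).copy()
    lod = np.zeros(x.shape, dtype=bool) if below_lod is None else np.asarray(below_lod, dtype=bool)
    x[lod] = -np.inf  # tied bottom block
    usable = ~np.isnan(x)
    n = int(usable.sum())
    if n < 3:
        raise ValidationError(["need at least 3 non-missing values for VdW scores"])
    ranks = stats.rankdata(x[usable], method="average")
    if np.all(ranks == ranks[0]):
        if strict:
            raise ValidationError(["degenerate analyte: all values tied"])
        scores_obs = np.zeros(n)
    else:
        scores_obs = stats.norm.ppf(ranks / (n + 1))
    out = np.full(x.shape, np.nan)
    out[usable] = scores_obs
    return out


def vdw_scores_frame(values: pd.DataFrame, below_lod: pd.DataFrame | None = None,
                     strict: bool = False) -> pd.DataFrame:
    """Column-wise VdW transform of a samples × variables frame."""
    out = {}
    for col in values.columns:
        lod_col = None if below_lod is None else below_lod[col].to_numpy()
        out[col] = vdw_transform(values[col].to_numpy(), lod_col, strict=strict)
    return pd.DataFrame(out, index=values.index)


def residualize(y, covariates=None, names=None) -> np.ndarray:
    """OLS residuals of ``y`` on an intercept plus the covariate columns.

    Residuals are mean-zero (≤1e-10) and orthogonal to every covariate.
    A rank-deficient design raises an error naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        return y - y.mean()
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        covariates = covariates.to_numpy(float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if np.isnan(y).any() or np.isnan(C).any():
        raise ValidationError(["missing values not allowed in residualization"])
    X = np.column_stack([np.ones(len(y)), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, names)
        raise ValidationError([f"rank-deficient covariate set: {collinear}"])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    labels = names if names is not None else [f"col{i}" for i in range(X.shape[1] - 1)]
    bad = []
    base_rank = 1  # intercept
    kept = [np.ones(X.shape[0])]
    for j in range(1, X.shape[1]):
        cand = np.column_stack(kept + [X[:, j]])
        if np.linalg.matrix_rank(cand) == base_rank:
            bad.append(labels[j - 1])
        else:
            kept.append(X[:, j])
            base_rank += 1
    return bad


def residualize_frame(frame: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Residualize every column of ``frame`` on the same covariate set."""
    out = {c: residualize(frame[c].to_numpy(), covariates) for c in frame.columns}
    return pd.DataFrame(out, index=frame.index)


def confounder_columns(pheno: PhenotypeTable, sex: str) -> pd.DataFrame:
    """Confounder design for one sex: VdW age, plus a 0/1 post-menopause
    indicator in women."""
    sub = pheno.data[pheno.data["sex"] == sex]
    cols = {"age": vdw_transform(sub["age"].to_numpy())}
    if sex == "F":
        cols["menopause_post"] = (sub["menopausal_status"] == "post").astype(float).to_numpy()
    return pd.DataFrame(cols, index=sub.index)


def impute_random_forest(pheno: PhenotypeTable, targets=IMPUTABLE_COVARIATES,
                         seed: int = 0, n_trees: int = 500) -> tuple[PhenotypeTable, PreprocessReport]:
    """Random-forest imputation of the imputable covariates (AEE, PWV).

    For each target a forest is trained on complete cases, using age plus
    the remaining covariates (sex coded 0/1) as features, single pass.
    Deterministic given ``seed``; forest predictions are averages of
    observed values so imputed cells stay within the observed range.
    """
    data = pheno.data.copy()
    report = PreprocessReport(n_samples_in=len(data),
                              n_analytes_in=0)
    feature_base = [c for c in COVARIATE_NAMES if c not in targets]
    for k, target in enumerate(targets):
        col = data[target]
        missing = col.isna()
        if not missing.any():
            continue
        complete = ~missing
        if complete.sum() < 20:
            raise ValidationError([f"fewer than 20 complete cases for {target}"])
        if complete.sum() == 0:
            raise ValidationError([f"target {target} entirely missing"])
        other = [t for t in targets if t != target]
        features = pd.DataFrame({
            "age": data["age"],
            "sex_male": (data["sex"] == "M").astype(float),
            **{c: data[c] for c in feature_base},
        })
        # other imputable targets can themselves be missing: mean-fill them
        for t in other:
            features[t] = data[t].fillna(data[t].mean())
        forest = RandomForestRegressor(n_estimators=n_trees,
                                       random_state=(seed + k) % (2**31))
        forest.fit(features[complete], col[complete])
        data.loc[missing, target] = forest.predict(features[missing])
        report.imputed_cells.extend((str(s), target) for s in data.index[missing])
    return PhenotypeTable(data), report


def preprocess_matrix(matrix: MetaboliteMatrix, pheno: PhenotypeTable,
                      min_freq: float = 0.20) -> tuple[MetaboliteMatrix, PreprocessReport]:
    """Duplicate resolution followed by the detection-frequency filter.

    The order is part of the method's contract (the frequency filter must
    see the de-duplicated matrix) and is asserted by the test suite.
    """
    deduped, rep1 = resolve_platform_duplicates(matrix)
    filtered, rep2 = filter_detection_frequency(deduped, pheno.sex_labels(), min_freq)
    return filtered, rep1.merge(rep2)


def sex_stratified_scores(matrix: MetaboliteMatrix, pheno: PhenotypeTable,
                          sex: str, adjust: bool = True) -> tuple[ScoreMatrix, np.ndarray]:
    """VdW-transform one sex subgroup and (optionally) residualize on the
    confounders; returns (analyte ScoreMatrix, adjusted VO2peak scores)."""
    sub_ids = [s for s in matrix.sample_ids if pheno.data.loc[s, "sex"] == sex]
    sub = matrix.subset_samples(sub_ids)
    scores = vdw_scores_frame(sub.values, sub.below_lod)
    if scores.isna().any().any():
        # missing metabolite cells are not imputed: mean-fill at score scale
        scores = scores.fillna(0.0)
    y = vdw_transform(pheno.data.loc[sub_ids, "vo2peak"].to_numpy())
    adjustment: list[str] = []
    if adjust:
        conf = confounder_columns(pheno, sex).loc[sub_ids]
        scores = residualize_frame(scores, conf)
        y = residualize(y, conf)
        adjustment = list(conf.columns)
    return ScoreMatrix(scores, adjustment), y
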