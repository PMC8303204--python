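"""Cross-validated stepwise selection of VO2peak explanation models.

Three model-building approaches share one machinery:

* approach 1 — only the 21 phenotypical/clinical variables compete;
* approach 2 — the 21 phenotypical/clinical variables are fixed in the
  model, only metabolites compete;
* approach 3 — phenotypical/clinical variables and metabolites compete
  on equal footing.

Variable entry is greedy in-sample R² maximization (no p-to-enter, no
backward steps). Stability comes from repeated 80/20 splits: on each
repeat, forward selection runs on the calibration samples and the test
RMSE is tracked step by step; selection stops the first time test RMSE
increases, and the degrading variable is excluded. The fraction of
repeats in which a variable survives is its selection frequency, and all
variables at frequency ≥ 0.05 enter a final least-squares model on all
samples, summarized by R² and adjusted R².

All inputs (response included) are expected to be confounder-adjusted
Van der Waerden scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ScoreMatrix, ValidationError

__all__ = [
    "StepwisePath",
    "SelectionFrequencies",
    "FinalModel",
    "stepwise_forward",
    "cv_stepwise_frequencies",
    "build_final_model",
    "run_approach",
    "adjusted_r2",
]


@dataclass
class StepwisePath:
    steps: list[tuple[str, float]]            # (variable, cumulative R²)
    fixed_set: list[str] = field(default_factory=list)

    def variables(self) -> list[str]:
        return [v for v, _ in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"step": i + 1, "variable": v, "cumulative_r2": r2}
             for i, (v, r2) in enumerate(self.steps)])


@dataclass
class SelectionFrequencies:
    frequency: pd.Series                       # variable → fraction of repeats
    n_repeats: int

    def to_frame(self) -> pd.DataFrame:
        out = self.frequency.rename("frequency").rename_axis("variable").reset_index()
        out["n_repeats"] = self.n_repeats
        return out


@dataclass
class FinalModel:
    approach: int
    variables: list[str]                       # ordered by selection frequency
    coefficients: np.ndarray
    intercept: float
    r2: float
    adjusted_r2: float
    sex: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{"term": "intercept", "coefficient": self.intercept}]
        rows += [{"term": v, "coefficient": c}
                 for v, c in zip(self.variables, self.coefficients)]
        frame = pd.DataFrame(rows)
        frame["approach"] = self.approach
        frame["r2"] = self.r2
        frame["adjusted_r2"] = self.adjusted_r2
        frame["sex"] = self.sex
        return frame


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if n - p - 1 <= 0:
        raise ValidationError(["not enough samples for adjusted R²"])
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _design(data: pd.DataFrame, variables: list[str]) -> np.ndarray:
    return np.column_stack([np.ones(len(data))] +
                           [data[v].to_numpy(float) for v in variables])


def _fit_r2(y: np.ndarray, X: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValidationError(["constant response"])
    return beta, 1.0 - float((resid ** 2).sum()) / tss


def stepwise_forward(y, fixed: list[str], candidates: list[str],
                     data: ScoreMatrix | pd.DataFrame,
                     max_steps: int | None = None) -> StepwisePath:
    """Greedy forward selection maximizing in-sample R².

    Starts from the fixed set (entered but not recorded as steps); each
    step adds the candidate with the largest R² gain, ties broken by
    variable id. Rank-deficient additions are skipped.
    """
    frame = data.scores if isinstance(data, ScoreMatrix) else data
    y = np.asarray(y, dtype=float)
    if set(fixed) & set(candidates):
        raise ValidationError(["fixed and candidate sets overlap"])
    selected = list(fixed)
    steps: list[tuple[str, float]] = []
    remaining = sorted(candidates)
    limit = len(remaining) if max_steps is None else max_steps
    current_rank = np.linalg.matrix_rank(_design(frame, selected))
    while remaining and len(steps) < limit:
        best = None
        for cand in remaining:  # sorted → deterministic tie-break by id
            X = _design(frame, selected + [cand])
            if np.linalg.matrix_rank(X) <= current_rank:
                continue  # collinear with the current model; skip
            _, r2 = _fit_r2(y, X)
            if best is None or r2 > best[1] + 1e-12:
                best = (cand, r2)
        if best is None:
            break
        selected.append(best[0])
        remaining.remove(best[0])
        current_rank += 1
        steps.append(best)
    return StepwisePath(steps, fixed_set=list(fixed))


def cv_stepwise_frequencies(y, fixed: list[str], candidates: list[str],
                            data: ScoreMatrix | pd.DataFrame,
                            n_repeats: int = 1000,
                            calibration_fraction: float = 0.8,
                            seed: int = 0,
                            max_steps: int | None = None) -> SelectionFrequencies:
    """Selection frequencies over repeated cross-validated stepwise runs.

    Each repeat: random calibration/test split, forward selection on the
    calibration set, stop at the first step whose test RMSE exceeds the
    previous step's (that variable is not kept). Evaluation starts after
    the fixed block is fitted, so fixed variables never face the stopping
    rule.
    """
    frame = data.scores if isinstance(data, ScoreMatrix) else data
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_cal = int(round(calibration_fraction * n))
    if n - n_cal < 5:
        raise ValidationError(["test set smaller than 5 samples"])
    counts = pd.Series(0.0, index=sorted(candidates))
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        cal, test = perm[:n_cal], perm[n_cal:]
        cal_frame = frame.iloc[cal]
        path = stepwise_forward(y[cal], fixed, candidates, cal_frame,
                                max_steps=max_steps)
        kept = _stop_at_degradation(y, frame, fixed, path, cal, test)
        counts[kept] += 1.0
    return SelectionFrequencies(counts / n_repeats, n_repeats)


def _stop_at_degradation(y, frame, fixed, path: StepwisePath, cal, test) -> list[str]:
    """Walk the calibration path, keep variables until test RMSE first rises."""
    y_cal, y_test = y[cal], y[test]
    selected = list(fixed)
    X_cal = _design(frame.iloc[cal], selected)
    X_test = _design(frame.iloc[test], selected)
    beta, *_ = np.linalg.lstsq(X_cal, y_cal, rcond=None)
    best_rmse = float(np.sqrt(np.mean((y_test - X_test @ beta) ** 2)))
    kept: list[str] = []
    for var, _ in path.steps:
        cand = selected + [var]
        Xc = _design(frame.iloc[cal], cand)
        Xt = _design(frame.iloc[test], cand)
        beta, *_ = np.linalg.lstsq(Xc, y_cal, rcond=None)
        rmse = float(np.sqrt(np.mean((y_test - Xt @ beta) ** 2)))
        if rmse > best_rmse:
            break  # first degradation: this variable is not included
        best_rmse = rmse
        selected = cand
        kept.append(var)
    return kept


def build_final_model(frequencies: SelectionFrequencies, y,
                      data: ScoreMatrix | pd.DataFrame,
                      threshold: float = 0.05,
                      fixed: list[str] | None = None,
                      approach: int = 0, sex: str = "") -> FinalModel:
    """Joint least-squares fit of all variables at frequency ≥ threshold.

    Variables are ordered by descending frequency (ties by id); fixed
    variables (approach 2) precede them. An empty selection yields the
    intercept-only model with R² = 0.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(["threshold must lie in (0, 1]"])
    frame = data.scores if isinstance(data, ScoreMatrix) else data
    y = np.asarray(y, dtype=float)
    freq = frequencies.frequency
    chosen = freq[freq >= threshold]
    ordered = sorted(chosen.index, key=lambda v: (-chosen[v], v))
    variables = list(fixed or []) + [v for v in ordered if v not in set(fixed or [])]
    n = len(y)
    if not variables:
        return FinalModel(approach, [], np.array([]), float(y.mean()), 0.0, 0.0, sex)
    X = _design(frame, variables)
    beta, r2 = _fit_r2(y, X)
    return FinalModel(approach, variables, beta[1:], float(beta[0]), r2,
                      adjusted_r2(r2, n, len(variables)), sex)


def run_approach(approach: int, pheno_vars: list[str], metabolite_vars: list[str],
                 y, data: ScoreMatrix | pd.DataFrame,
                 n_repeats: int = 1000, calibration_fraction: float = 0.8,
                 threshold: float = 0.05, seed: int = 0,
                 max_steps: int | None = None, sex: str = "") -> tuple[StepwisePath, SelectionFrequencies, FinalModel]:
    """Wire the fixed/candidate sets for one approach and run everything."""
    if set(pheno_vars) & set(metabolite_vars):
        raise ValidationError(["phenotype and metabolite variable sets overlap"])
    if approach == 1:
        fixed, candidates = [], list(pheno_vars)
    elif approach == 2:
        fixed, candidates = list(pheno_vars), list(metabolite_vars)
    elif approach == 3:
        fixed, candidates = [], list(pheno_vars) + list(metabolite_vars)
    else:
        raise ValidationError([f"unknown approach {approach!r}"])
    path = stepwise_forward(y, fixed, candidates, data, max_steps=max_steps)
    freqs = cv_stepwise_frequencies(y, fixed, candidates, data,
                                    n_repeats=n_repeats,
                                    calibration_fraction=calibration_fraction,
                                    seed=seed, max_steps=max_steps)
    final = build_final_model(freqs, y, data, threshold=threshold,
                              fixed=fixed, approach=approach, sex=sex)
    return path, freqs, final
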