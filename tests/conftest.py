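import pandas as pd
import pytest

from crfmet.dataio import COVARIATE_NAMES
from crfmet.preprocess import (
    confounder_columns,
    impute_random_forest,
    preprocess_matrix,
    residualize_frame,
    sex_stratified_scores,
    vdw_scores_frame,
)
from crfmet.synthetic_data import SyntheticConfig, generate_cohort, generate_null_dataset


@pytest.fixture(scope="session")
def default_cohort():
    """One study-scale synthetic cohort (102 F / 150 M, 120 analytes)."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def imputed_cohort(default_cohort):
    pheno, matrix, truth = default_cohort
    pheno_imp, _ = impute_random_forest(pheno, seed=0, n_trees=100)
    filtered, report = preprocess_matrix(matrix, pheno_imp)
    return pheno_imp, filtered, truth, report


@pytest.fixture(scope="session")
def null_cohort():
    """Analytes independent of fitness given confounders."""
    return generate_null_dataset(n=120, p=60, seed=3)


def adjusted_inputs(pheno, matrix, sex):
    """Confounder-adjusted VdW scores for one sex: (analytes, y, covariates)."""
    scores, y = sex_stratified_scores(matrix, pheno, sex)
    conf = confounder_columns(pheno, sex)
    cov = residualize_frame(vdw_scores_frame(pheno.subset(sex).covariates()), conf)
    return scores, y, cov[list(COVARIATE_NAMES)]


@pytest.fixture(scope="session")
def female_adjusted(imputed_cohort):
    pheno, matrix, truth, _ = imputed_cohort
    return adjusted_inputs(pheno, matrix, "F")


@pytest.fixture(scope="session")
def male_adjusted(imputed_cohort):
    pheno, matrix, truth, _ = imputed_cohort
    return adjusted_inputs(pheno, matrix, "M")
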