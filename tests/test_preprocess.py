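"""Filters, Van der Waerden scoring, residualization, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crfmet.dataio import (
    AnalyteAnnotation,
    MetaboliteMatrix,
    Platform,
    ValidationError,
)
from crfmet.preprocess import (
    PreprocessReport,
    filter_detection_frequency,
    impute_random_forest,
    preprocess_matrix,
    residualize,
    resolve_platform_duplicates,
    vdw_transform,
)


def _matrix(columns: dict, analytes):
    values = pd.DataFrame(columns)
    values.index = [f"S{i}" for i in range(len(values))]
    lod = pd.DataFrame(False, index=values.index, columns=values.columns)
    return MetaboliteMatrix(values, lod, analytes)


class TestDuplicateResolution:
    def test_less_quantitative_platform_removed(self):
        analytes = [
            AnalyteAnnotation("glu_p180", Platform.LCMS_P180,
                              quantitative_rank=1, duplicate_group="glu"),
            AnalyteAnnotation("glu_gcxgc", Platform.GCXGC_MS,
                              quantitative_rank=3, duplicate_group="glu"),
        ]
        m = _matrix({"glu_p180": [1.0, 2.0, 3.0], "glu_gcxgc": [1.1, 2.1, 3.1]},
                    analytes)
        out, report = resolve_platform_duplicates(m)
        assert out.analyte_ids == ["glu_p180"]
        assert report.removed_duplicates == ["glu_gcxgc"]
        assert report.n_analytes_out == 1

    def test_no_duplicate_groups_identity(self):
        analytes = [AnalyteAnnotation("a", Platform.NMR),
                    AnalyteAnnotation("b", Platform.NMR)]
        m = _matrix({"a": [1.0, 2.0], "b": [3.0, 4.0]}, analytes)
        out, report = resolve_platform_duplicates(m)
        assert out.analyte_ids == ["a", "b"]
        assert report.removed_duplicates == []

    def test_three_way_duplicate_keeps_minimum_rank(self):
        analytes = [
            AnalyteAnnotation(f"x{r}", Platform.NMR, quantitative_rank=r,
                              duplicate_group="g") for r in (3, 1, 2)]
        m = _matrix({f"x{r}": [1.0, 2.0] for r in (3, 1, 2)}, analytes)
        out, _ = resolve_platform_duplicates(m)
        assert out.analyte_ids == ["x1"]


class TestDetectionFilter:
    def _sexed_matrix(self, f_detect, m_detect, n_f=10, n_m=10):
        col = [1.0] * int(f_detect * n_f) + [np.nan] * (n_f - int(f_detect * n_f))
        col += [1.0] * int(m_detect * n_m) + [np.nan] * (n_m - int(m_detect * n_m))
        m = _matrix({"a": col, "b": list(np.linspace(1, 2, n_f + n_m))},
                    [AnalyteAnnotation("a", Platform.NMR),
                     AnalyteAnnotation("b", Platform.NMR)])
        sex = pd.Series(["F"] * n_f + ["M"] * n_m, index=m.sample_ids)
        return m, sex

    def test_low_in_one_subgroup_removed(self):
        m, sex = self._sexed_matrix(0.1, 0.9)
        out, report = filter_detection_frequency(m, sex)
        assert out.analyte_ids == ["b"]
        assert report.removed_low_frequency == ["a"]

    def test_exactly_at_threshold_kept(self):
        m, sex = self._sexed_matrix(0.2, 0.2)
        out, _ = filter_detection_frequency(m, sex)
        assert "a" in out.analyte_ids

    def test_fully_detected_kept_and_counts_conserved(self):
        m, sex = self._sexed_matrix(1.0, 1.0)
        out, report = filter_detection_frequency(m, sex)
        assert out.analyte_ids == ["a", "b"]
        assert report.n_analytes_in == len(report.removed_low_frequency) + out.n_analytes


class TestVdwTransform:
    def test_three_point_inverse_normal_oracle(self):
        got = vdw_transform([1.0, 2.0, 3.0])
        expected = stats.norm.ppf(np.array([1, 2, 3]) / 4.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got[1] == 0.0
        assert got[0] == pytest.approx(-0.6744897501960817, abs=1e-12)

    def test_full_tie_gives_zero_scores(self):
        np.testing.assert_array_equal(vdw_transform([5.0] * 4), np.zeros(4))
        with pytest.raises(ValidationError, match="degenerate"):
            vdw_transform([5.0] * 4, strict=True)

    def test_lod_block_shares_tied_minimum_rank(self):
        got = vdw_transform([np.nan, np.nan, 1.0, 2.0],
                            below_lod=[True, True, False, False])
        expected = stats.norm.ppf(np.array([1.5, 1.5, 3, 4]) / 5.0)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_missing_propagates_without_entering_n(self):
        got = vdw_transform([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(got[1])
        np.testing.assert_allclose(got[[0, 2, 3]],
                                   stats.norm.ppf(np.array([1, 2, 3]) / 4.0))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.1, 1e6, allow_nan=False), min_size=3, max_size=40,
                    unique=True))
    def test_monotone_and_idempotent(self, xs):
        scores = vdw_transform(xs)
        order = np.argsort(xs)
        assert np.all(np.diff(scores[order]) > 0)
        np.testing.assert_allclose(vdw_transform(scores), scores, atol=1e-12)


class TestResidualize:
    def test_orthogonal_covariate_only_demeans(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to the trend
        np.testing.assert_allclose(residualize(y, c), y - y.mean(), atol=1e-10)

    def test_affine_response_gives_zero_residuals(self):
        c = np.array([0.0, 1.0, 2.0, 5.0])
        y = 3.0 + 2.0 * c
        np.testing.assert_allclose(residualize(y, c), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        C = rng.normal(size=(4, 2))
        y = rng.normal(size=4)
        X = np.column_stack([np.ones(4), C])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y  # explicit inversion oracle
        np.testing.assert_allclose(residualize(y, C), y - X @ beta, atol=1e-10)

    def test_residual_properties(self):
        rng = np.random.default_rng(5)
        C = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        r = residualize(y, C)
        assert abs(r.mean()) < 1e-10
        for j in range(3):
            assert abs(r @ C[:, j]) < 1e-8

    def test_collinear_covariates_named(self):
        C = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValidationError, match="b"):
            residualize(np.array([1.0, 0.0, 1.0, 0.0]), C)


class TestImputation:
    def test_no_missing_is_identity(self, default_cohort):
        pheno, _, _ = default_cohort
        complete = pheno.data.dropna(subset=["aee", "pwv"])
        from crfmet.dataio import PhenotypeTable
        sub = PhenotypeTable(complete)
        out, report = impute_random_forest(sub, seed=1, n_trees=20)
        pd.testing.assert_frame_equal(out.data, sub.data)
        assert report.imputed_cells == []

    def test_deterministic_and_within_observed_range(self, default_cohort):
        pheno, _, _ = default_cohort
        out1, rep1 = impute_random_forest(pheno, seed=7, n_trees=50)
        out2, _ = impute_random_forest(pheno, seed=7, n_trees=50)
        pd.testing.assert_frame_equal(out1.data, out2.data)
        assert len(rep1.imputed_cells) == int(pheno.data[["aee", "pwv"]].isna().sum().sum())
        for col in ("aee", "pwv"):
            observed = pheno.data[col].dropna()
            assert out1.data[col].between(observed.min(), observed.max()).all()

    def test_monotone_signal_imputed_near_neighbours(self):
        # AEE as a noiseless linear function of age: prediction must fall
        # within the envelope of the training values
        from crfmet.synthetic_data import SyntheticConfig, generate_cohort
        pheno, _, _ = generate_cohort(SyntheticConfig(seed=2, missing_aee_pwv_rate=0.0))
        data = pheno.data.copy()
        data["aee"] = 10.0 * data["age"]
        missing = data.index[5]
        data.loc[missing, "aee"] = np.nan
        from crfmet.dataio import PhenotypeTable
        out, _ = impute_random_forest(PhenotypeTable(data), seed=3, n_trees=100)
        age = data.loc[missing, "age"]
        nearest = (data["age"].drop(missing) - age).abs().sort_values().index[:20]
        neighbours = data.loc[nearest, "aee"]
        assert neighbours.min() * 0.8 <= out.data.loc[missing, "aee"] <= neighbours.max() * 1.2


def test_pipeline_order_and_conservation(default_cohort):
    """Duplicates are resolved before the frequency filter, and counts add up."""
    pheno, matrix, _ = default_cohort
    filtered, report = preprocess_matrix(matrix, pheno)
    assert report.n_analytes_in == matrix.n_analytes
    assert (report.n_analytes_out ==
            matrix.n_analytes - len(report.removed_duplicates)
            - len(report.removed_low_frequency))
    assert filtered.n_analytes == report.n_analytes_out
    # every duplicate group is singular afterwards
    groups = [a.duplicate_group for a in filtered.analytes if a.duplicate_group]
    assert len(groups) == len(set(groups))
    # removal lists are disjoint
    assert not set(report.removed_duplicates) & set(report.removed_low_frequency)


def test_report_merge_rejects_double_removal():
    r1 = PreprocessReport(n_samples_in=10, n_analytes_in=5,
                          removed_duplicates=["a"])
    r2 = PreprocessReport(n_samples_in=10, n_analytes_in=4,
                          removed_low_frequency=["a"])
    with pytest.raises(ValidationError):
        r1.merge(r2)
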