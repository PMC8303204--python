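"""PLS fitting, rank products, permutation significance."""

import numpy as np
import pandas as pd
import pytest

from crfmet.dataio import ValidationError
from crfmet.pls_rankproduct import (
    PLSRunConfig,
    fit_pls,
    outer_rank_products,
    permutation_significance,
    tune_ncomp,
    volcano_table,
)
from crfmet.bivariate import CorrelationResult


def _fast_config(**kw):
    base = dict(n_outer_splits=8, inner_folds=4, max_components=4,
                n_permutations=50, seed=5)
    base.update(kw)
    return PLSRunConfig(**base)


class TestFitPLS:
    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6))
        y = X @ rng.normal(size=6) + rng.normal(scale=0.5, size=50)
        model = fit_pls(X, y, n_components=6)
        D = np.column_stack([np.ones(50), X])
        beta = np.linalg.lstsq(D, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), D @ beta, atol=1e-8)

    def test_single_latent_factor_dominates_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 10))
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        y = Xs[:, 3]  # response equals one standardized column
        model = fit_pls(X, y, n_components=1)
        assert np.argmax(np.abs(model.coefficients)) == 3

    def test_prediction_at_calibration_mean_is_intercept(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        model = fit_pls(X, y, 2)
        got = model.predict(X.mean(axis=0)[None, :])
        assert got[0] == pytest.approx(model.intercept, abs=1e-12)

    def test_excess_components_truncated_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="truncated"):
            model = fit_pls(X, y, 9)
        assert model.n_components == 5

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.ones(20), np.random.default_rng(4).normal(size=20)])
        with pytest.raises(ValidationError, match="zero-variance"):
            fit_pls(X, np.arange(20.0), 1)


class TestTuning:
    def test_noiseless_rank_one_signal_selects_one_component(self):
        # exactly rank-1 predictors: components beyond the first are inert,
        # so the tie resolves to the smallest count
        rng = np.random.default_rng(5)
        t = rng.normal(size=60)
        X = np.outer(t, rng.normal(size=8))
        y = 2.0 * t
        assert tune_ncomp(X, y, _fast_config()) == 1

    def test_deterministic_given_seed_even_for_noise(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 10))
        y = rng.normal(size=40)
        cfg = _fast_config(seed=9)
        picks = {tune_ncomp(X, y, cfg, np.random.default_rng(9)) for _ in range(3)}
        assert len(picks) == 1

    def test_max_components_cap_honored(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 30))
        y = X[:, :20] @ rng.normal(size=20)  # keeps improving past the cap
        cfg = _fast_config(max_components=3)
        assert tune_ncomp(X, y, cfg) <= 3


class TestRankProducts:
    def test_rank_product_arithmetic(self):
        # geometric mean identities on hand-built rank matrices
        ranks = np.array([[2.0, 1.0], [2.0, 1.0], [2.0, 1.0]])
        rp = np.exp(np.log(ranks).mean(axis=0))
        np.testing.assert_allclose(rp, [2.0, 1.0])
        ranks = np.array([[1.0], [4.0]])
        assert np.exp(np.log(ranks).mean()) == pytest.approx(2.0)

    def test_geometric_mean_identity_and_rank_conservation(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(60, 12)),
                         columns=[f"a{i}" for i in range(12)])
        y = rng.normal(size=60)
        res = outer_rank_products(X, y, _fast_config())
        np.testing.assert_allclose(np.log(res.rank_product),
                                   np.log(res.ranks).mean(axis=0), atol=1e-12)
        p = X.shape[1]
        for s in range(res.ranks.shape[0]):
            assert res.ranks[s].sum() == pytest.approx(p * (p + 1) / 2)

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(50, 8)))
        y = rng.normal(size=50)
        a = outer_rank_products(X, y, _fast_config(seed=3))
        b = outer_rank_products(X, y, _fast_config(seed=3))
        np.testing.assert_array_equal(a.ranks, b.ranks)
        assert a.mean_test_rmse == b.mean_test_rmse

    def test_label_invariance_under_joint_row_permutation(self):
        # relabeling samples (rows of X and y together) must not change
        # the statistic once the same sample-level splits are used
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        y = rng.normal(size=40)
        perm = rng.permutation(40)
        inv = np.empty(40, dtype=int)
        inv[perm] = np.arange(40)
        cfg = _fast_config(seed=12)
        a = outer_rank_products(X, y, cfg)
        mapped_splits = [(np.sort(inv[cal]), np.sort(inv[test]))
                         for cal, test in a.splits]
        b = outer_rank_products(X.iloc[perm].reset_index(drop=True), y[perm],
                                cfg, splits=mapped_splits, ncomps=a.ncomps)
        np.testing.assert_allclose(a.rank_product, b.rank_product, atol=1e-9)

    def test_fewer_than_two_analytes_rejected(self):
        with pytest.raises(ValidationError):
            outer_rank_products(pd.DataFrame({"a": np.arange(30.0)}),
                                np.arange(30.0), _fast_config())


class TestPermutation:
    def _planted(self, seed=13, n=80, p=12, effect=0.9):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"a{i}" for i in range(p)])
        y = effect * X["a0"].to_numpy() + rng.normal(size=n)
        return X, y

    def test_planted_analyte_significant(self):
        X, y = self._planted()
        cfg = _fast_config(n_permutations=100)
        obs = outer_rank_products(X, y, cfg)
        res = permutation_significance(X, y, obs, cfg)
        assert res.perm_frequency[0] <= 0.05
        assert res.significant[0]
        # permuted models predict worse than the real one
        assert res.perm_mean_test_rmse.mean() > obs.mean_test_rmse

    def test_alpha_zero_boundary(self):
        X, y = self._planted()
        cfg = _fast_config(n_permutations=20, alpha=1e-9)
        obs = outer_rank_products(X, y, cfg)
        res = permutation_significance(X, y, obs, cfg)
        assert res.significant.sum() == 0 or res.perm_frequency.min() == 0.0
        assert not res.significant[res.perm_frequency > 0].any()

    def test_modes_agree_on_planted_signal(self):
        X, y = self._planted(seed=14, n=60, p=8)
        cfg_fast = _fast_config(n_permutations=40, n_outer_splits=6,
                                max_components=3, seed=21,
                                permutation_mode="fast_reuse")
        cfg_full = _fast_config(n_permutations=40, n_outer_splits=6,
                                max_components=3, seed=21,
                                permutation_mode="full_refit")
        obs = outer_rank_products(X, y, cfg_fast)
        fast = permutation_significance(X, y, obs, cfg_fast)
        full = permutation_significance(X, y, obs, cfg_full)
        assert fast.significant[0] and full.significant[0]
        agree = (fast.significant == full.significant).mean()
        assert agree >= 0.9


class TestVolcano:
    def _inputs(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(50, 4)),
                         columns=[f"a{i}" for i in range(4)])
        y = rng.normal(size=50)
        cfg = _fast_config(n_permutations=25)
        obs = outer_rank_products(X, y, cfg)
        rp = permutation_significance(X, y, obs, cfg)
        corr = [CorrelationResult(f"a{i}", r, r - 0.2, r + 0.2, 50, 0, False)
                for i, r in enumerate((0.30, 0.0, -0.1, 0.2))]
        return corr, rp

    def test_log_rule_and_floor(self):
        corr, rp = self._inputs()
        table = volcano_table(corr, rp)
        for _, row in table.iterrows():
            if row["perm_frequency"] == 1.0:
                assert row["neg_log10_perm_frequency"] == 0.0
            if row["perm_frequency"] == 0.0:
                assert row["neg_log10_perm_frequency"] == pytest.approx(
                    np.log10(rp.n_permutations + 1))
        assert np.isfinite(table["neg_log10_perm_frequency"]).all()

    def test_relevance_by_bivariate_criterion_alone(self):
        corr, rp = self._inputs()
        table = volcano_table(corr, rp).set_index("analyte")
        if not table.loc["a0", "significant_multivariate"]:
            assert table.loc["a0", "relevance_class"] == "bivariate"  # r = 0.30

    def test_mismatched_analytes_rejected(self):
        corr, rp = self._inputs()
        with pytest.raises(ValidationError, match="differ"):
            volcano_table(corr[:-1], rp)
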