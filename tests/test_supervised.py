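"""Ridge solver, Spearman metric, alpha selection, evaluation, ablation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import Ridge

from protfit.ensemble import FeatureBlock, build_representation
from protfit.errors import ConfigError, DataError
from protfit.supervised import (
    EvaluationResult,
    ablate,
    default_ablation_subsets,
    evaluate,
    fit_ridge,
    select_alpha,
    spearman,
)


def ridge_oracle(X, y, alpha):
    """Independent centered normal-equations / pseudo-inverse solve.

    alpha = 0 uses pinv(Xc) directly: pinv of the squared Gram matrix is
    numerically ill-defined when X is exactly rank-deficient (the zeroed
    eigenvalue lands at the cutoff).
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if alpha == 0.0:
        w = np.linalg.pinv(Xc) @ yc
    else:
        w = np.linalg.pinv(Xc.T @ Xc + alpha * np.eye(X.shape[1])) @ Xc.T @ yc
    return w, y.mean() - X.mean(axis=0) @ w


def spearman_oracle(a, b):
    """Brute-force average ranks + Pearson correlation."""

    def avg_rank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        sorted_v = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = avg_rank(np.asarray(a, float)), avg_rank(np.asarray(b, float))
    return float(np.corrcoef(ra, rb)[0, 1])


class TestFitRidge:
    def test_exact_linear_fit_alpha_zero(self):
        x = np.linspace(0, 1, 20)[:, None]
        y = 2 * x[:, 0] + 1
        m = fit_ridge(x, y, alpha=0.0)
        assert m.weights[0] == pytest.approx(2.0, abs=1e-10)
        assert m.intercept == pytest.approx(1.0, abs=1e-10)

    def test_huge_alpha_shrinks_to_mean(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        m = fit_ridge(X, y, alpha=1e9)
        assert np.abs(m.weights).max() < 1e-6
        assert m.intercept == pytest.approx(y.mean(), abs=1e-4)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((50, 10))
        y = rng.standard_normal(50)
        m = fit_ridge(X, y, alpha=1.0)
        w, b = ridge_oracle(X, y, 1.0)
        np.testing.assert_allclose(m.weights, w, atol=1e-8)
        assert m.intercept == pytest.approx(b, abs=1e-8)

    def test_matches_sklearn_svd_solver(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        for alpha in (0.1, 1.0, 10.0):
            m = fit_ridge(X, y, alpha)
            sk = Ridge(alpha=alpha, solver="svd").fit(X, y)
            np.testing.assert_allclose(m.weights, sk.coef_, atol=1e-8)
            assert m.intercept == pytest.approx(sk.intercept_, abs=1e-8)

    def test_rank_deficient_alpha_zero_min_norm(self, rng):
        X = rng.standard_normal((10, 4))
        X = np.hstack([X, X[:, :1]])  # duplicated column
        y = rng.standard_normal(10)
        m = fit_ridge(X, y, alpha=0.0)
        w, _ = ridge_oracle(X, y, 0.0)
        np.testing.assert_allclose(m.weights, w, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError):
            fit_ridge(np.array([[np.nan], [1.0]]), np.array([0.0, 1.0]), 1.0)

    def test_negative_alpha_rejected(self, rng):
        with pytest.raises(ConfigError):
            fit_ridge(rng.standard_normal((5, 2)), rng.standard_normal(5), -1.0)


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        y = rng.standard_normal(30)
        assert spearman(y, np.exp(y)) == pytest.approx(1.0)
        assert spearman(y, 3 * y + 7) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, rng):
        y = rng.standard_normal(30)
        assert spearman(y, -y) == pytest.approx(-1.0)

    def test_ties_match_hand_ranks(self):
        # ranks of (1,2,2,3) are (1, 2.5, 2.5, 4); of (1,3,2,4) are (1,3,2,4)
        a = np.array([1.0, 2.0, 2.0, 3.0])
        b = np.array([1.0, 3.0, 2.0, 4.0])
        assert spearman(a, b) == pytest.approx(spearman_oracle(a, b), abs=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=50).astype(float)  # heavy ties
        b = rng.standard_normal(50)
        assert spearman(a, b) == pytest.approx(spearman_oracle(a, b), abs=1e-12)

    def test_constant_vector_returns_nan(self, caplog):
        with caplog.at_level("WARNING"):
            out = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(out)
        assert "undefined" in caplog.text

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_antisymmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        assert spearman(a, -b) == pytest.approx(-spearman(a, b), abs=1e-12)


class TestSelectAlpha:
    def test_noiseless_linear_selects_zero(self, rng):
        X = rng.standard_normal((60, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        alpha, table = select_alpha(X, y, [0.0, 1e6], k_folds=3, seed=0)
        assert alpha == 0.0
        assert table.loc[table["alpha"] == 0.0, "mean_rho"].iloc[0] > table.loc[
            table["alpha"] == 1e6, "mean_rho"
        ].iloc[0]

    def test_single_candidate(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        alpha, _ = select_alpha(X, y, [3.7], seed=0)
        assert alpha == 3.7

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        _, t1 = select_alpha(X, y, [0.1, 1.0, 10.0], seed=4)
        _, t2 = select_alpha(X, y, [0.1, 1.0, 10.0], seed=4)
        assert t1.equals(t2)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ConfigError):
            select_alpha(rng.standard_normal((10, 2)), rng.standard_normal(10), [])


def _noiseless_problem(rng, n=80, d=5):
    X = rng.standard_normal((n, d))
    w = rng.standard_normal(d)
    return X, X @ w


class TestEvaluate:
    def test_noiseless_recovery(self, rng):
        X, y = _noiseless_problem(rng)
        res = evaluate(X, y, seed=0)
        assert res.mean_rho >= 0.999

    def test_bitwise_deterministic(self, rng):
        X, y = _noiseless_problem(rng)
        assert evaluate(X, y, seed=3) == evaluate(X, y, seed=3)

    def test_holdout_protocol(self, rng):
        X, y = _noiseless_problem(rng)
        res = evaluate(X, y, protocol="holdout", test_fraction=0.25, seed=1)
        assert len(res.fold_rhos) == 1
        assert res.fold_sizes[0] == (60, 20)

    def test_too_small_rejected(self, rng):
        with pytest.raises(DataError):
            evaluate(rng.standard_normal((3, 2)), np.arange(3.0), k=5)

    def test_no_leakage_from_poisoned_test_rows(self, rng):
        """Corrupting held-out rows must not change training-side results.

        Under a holdout split the test rows are replaced by wild outliers;
        the selected alpha must be identical to the clean run, because test
        rows never touch scaling, alpha selection or fitting — while the
        held-out correlation does change (the canary landed in the test set).
        """
        X, y = _noiseless_problem(rng, n=60, d=3)
        clean = evaluate(X, y, protocol="holdout", test_fraction=0.25, seed=0)
        from sklearn.model_selection import train_test_split

        _, te = train_test_split(np.arange(60), test_size=0.25, random_state=0)
        Xp, yp = X.copy(), y.copy()
        Xp[te] += 1e6
        yp[te] = rng.standard_normal(te.size) * 1e3
        poisoned = evaluate(Xp, yp, protocol="holdout", test_fraction=0.25, seed=0)
        assert poisoned.fold_alphas == clean.fold_alphas
        assert poisoned.fold_rhos != clean.fold_rhos


class TestAblate:
    def test_full_subset_delta_zero(self, rng):
        blocks = [
            FeatureBlock("a", rng.standard_normal((40, 3))),
            FeatureBlock("b", rng.standard_normal((40, 4))),
        ]
        rep = build_representation(blocks)
        y = rep.matrix @ rng.standard_normal(7)
        table, _ = ablate(rep, y, subsets=[("a", "b")], k=4, seed=0)
        assert table.loc[0, "delta_vs_full"] == 0.0

    def test_informative_block_beats_noise_block(self, rng):
        a = FeatureBlock("a", rng.standard_normal((60, 4)))
        b = FeatureBlock("b", rng.standard_normal((60, 4)))
        rep = build_representation([a, b])
        y = a.vectors @ rng.standard_normal(4)  # fitness depends only on a
        table, _ = ablate(rep, y, subsets=[("a",), ("b",)], k=4, seed=0)
        rho = dict(zip(table["subset"], table["mean_rho"]))
        assert rho["a"] >= rho["b"]

    def test_six_scenario_grid_shape(self):
        subsets = default_ablation_subsets(["g1", "g2"], "local")
        assert len(subsets) == 6
        assert ("g1",) in subsets and ("g1", "g2", "local") in subsets

    def test_subsets_share_folds(self, rng):
        blocks = [
            FeatureBlock("a", rng.standard_normal((40, 3))),
            FeatureBlock("b", rng.standard_normal((40, 3))),
        ]
        rep = build_representation(blocks)
        y = rep.matrix @ rng.standard_normal(6)
        _, results = ablate(rep, y, subsets=[("a",), ("b",)], k=4, seed=9)
        sizes = {res.fold_sizes for res in results.values()}
        assert len(sizes) == 1  # identical splits everywhere
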