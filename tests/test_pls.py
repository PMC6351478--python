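"""PLS1, permutation inference and VIP: oracles, invariants, edge cases.

Oracles: the component-1 weight equals the normalized cross-covariance
vector; full-rank PLS1 reproduces ordinary least squares; fitted values
cross-checked against scikit-learn's PLSRegression.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mspls import pls
from mspls.errors import (
    ConfigurationError,
    DataError,
    DegenerateOutcomeError,
    RankError,
)


def _random_instance(seed, n=30, p=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(size=n)
    return pls.standardize(X, y)[:2]


class TestStandardize:
    def test_hand_example(self):
        Xs, ys, scaler = pls.standardize(np.array([[1.0], [2.0], [3.0]]), [0, 0, 3])
        np.testing.assert_allclose(Xs[:, 0], [-1, 0, 1])
        np.testing.assert_allclose(ys, [-1, -1, 2])
        assert scaler.y_mean == pytest.approx(1.0)

    def test_idempotent_on_standardized_input(self):
        Xs, ys = _random_instance(0)
        Xs2, ys2, _ = pls.standardize(Xs, ys + ys.mean() - ys.mean())
        np.testing.assert_allclose(Xs2, Xs, atol=1e-12)

    def test_constant_column_named(self):
        X = np.ones((5, 2))
        X[:, 0] = np.arange(5)
        with pytest.raises(DataError, match="wm_volume"):
            pls.standardize(X, np.arange(5), names=["age", "wm_volume"])

    def test_missing_values_rejected(self):
        X = np.ones((4, 2)) * np.arange(4)[:, None]
        X[1, 0] = np.nan
        with pytest.raises(DataError):
            pls.standardize(X, np.arange(4))


class TestFit:
    def test_perfect_univariate_fit_explains_everything(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        Xs, ys, _ = pls.standardize(x[:, None], x)
        model = pls.fit_pls1(Xs, ys, 1)
        assert model.ss_y[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_component1_weight_matches_cross_covariance_oracle(self, seed):
        Xs, ys = _random_instance(seed)
        model = pls.fit_pls1(Xs, ys, 1)
        w_oracle = Xs.T @ ys
        w_oracle /= np.linalg.norm(w_oracle)
        if w_oracle[np.flatnonzero(np.abs(w_oracle) > 1e-12)[0]] < 0:
            w_oracle = -w_oracle
        np.testing.assert_allclose(model.W[:, 0], w_oracle, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_rank_pls_reproduces_ols(self, seed):
        Xs, ys = _random_instance(seed)
        model = pls.fit_pls1(Xs, ys, 5)
        fitted_ols = Xs @ np.linalg.lstsq(Xs, ys, rcond=None)[0]
        np.testing.assert_allclose(model.fitted(), fitted_ols, atol=1e-6)

    def test_fitted_values_match_sklearn_cross_check(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        Xs, ys = _random_instance(42, n=40, p=6)
        model = pls.fit_pls1(Xs, ys, 3)
        ref = sklearn_pls.PLSRegression(n_components=3, scale=False).fit(Xs, ys)
        np.testing.assert_allclose(
            model.fitted(), ref.predict(Xs).ravel(), atol=1e-8
        )

    def test_score_orthogonality_and_reconstruction(self):
        Xs, ys = _random_instance(3, n=50, p=8)
        model = pls.fit_pls1(Xs, ys, 4)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        norms = np.sqrt(np.diag(G))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))
        np.testing.assert_allclose(model.T @ model.P.T + model.E, Xs, atol=1e-10)
        np.testing.assert_allclose(model.T @ model.Q + model.F, ys, atol=1e-10)

    def test_variance_fractions_are_monotone_and_bounded(self):
        Xs, ys = _random_instance(4, n=40, p=6)
        model = pls.fit_pls1(Xs, ys, 4)
        assert np.all(model.ss_y >= 0) and model.ss_y.sum() <= 1 + 1e-12
        assert np.all(model.ss_x >= 0) and model.ss_x.sum() <= 1 + 1e-12
        assert np.all(np.diff(np.cumsum(model.ss_y)) >= 0)

    def test_rank_error(self):
        Xs, ys = _random_instance(5)
        with pytest.raises(RankError):
            pls.fit_pls1(Xs, ys, 6)

    def test_truncate_equals_refit(self):
        Xs, ys = _random_instance(6)
        full = pls.fit_pls1(Xs, ys, 4)
        short = pls.fit_pls1(Xs, ys, 2)
        trunc = full.truncate(2)
        np.testing.assert_allclose(trunc.W, short.W, atol=1e-12)
        np.testing.assert_allclose(trunc.F, short.F, atol=1e-12)


class TestPermutation:
    def test_add_one_p_value_formula(self):
        Xs, ys = _random_instance(7)
        res = pls.permutation_test(Xs, ys, 1, n_perm=99, seed=0)
        count = (res.null[:, 0] >= res.observed[0]).sum()
        assert res.p_values[0] == pytest.approx((1 + count) / 100)
        assert 0 < res.p_values[0] <= 1

    def test_strong_signal_hits_p_value_floor(self):
        # observed above every null draw: p = 1/(n_perm + 1)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(53, 5))
        y = X @ np.array([2.0, 1.5, 1.0, 0.5, 0.25])
        Xs, ys, _ = pls.standardize(X, y)
        res = pls.permutation_test(Xs, ys, 1, n_perm=999, seed=1)
        assert res.p_values[0] == pytest.approx(1 / 1000)

    def test_reproducible_under_seed(self):
        Xs, ys = _random_instance(9)
        a = pls.permutation_test(Xs, ys, 2, n_perm=50, seed=3)
        b = pls.permutation_test(Xs, ys, 2, n_perm=50, seed=3)
        np.testing.assert_array_equal(a.null, b.null)

    def test_zero_permutations_rejected(self):
        Xs, ys = _random_instance(10)
        with pytest.raises(ConfigurationError):
            pls.permutation_test(Xs, ys, 1, n_perm=0)

    def test_constant_outcome_rejected(self):
        Xs, _ = _random_instance(11)
        with pytest.raises(DegenerateOutcomeError):
            pls.permutation_test(Xs, np.zeros(30), 1, n_perm=10)


class TestVIP:
    def test_single_component_closed_form_equal_weights(self):
        model = _model_with_weights(np.array([[1 / np.sqrt(2)], [1 / np.sqrt(2)]]))
        vip = pls.vip_scores(model)
        np.testing.assert_allclose(vip.vip, [1.0, 1.0])
        assert not vip.selected.any()  # strict rule: exactly 1 not selected

    def test_single_component_closed_form_concentrated_weight(self):
        model = _model_with_weights(np.array([[1.0], [0.0]]))
        vip = pls.vip_scores(model)
        np.testing.assert_allclose(vip.vip, [np.sqrt(2), 0.0])
        np.testing.assert_array_equal(vip.selected, [True, False])

    def test_single_predictor_vip_is_exactly_one(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=25)
        y = 2 * x + rng.normal(size=25)
        Xs, ys, _ = pls.standardize(x[:, None], y)
        vip = pls.vip_scores(pls.fit_pls1(Xs, ys, 1))
        assert vip.vip[0] == pytest.approx(1.0)
        assert pls.select_variables(vip) == []

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_mean_squared_vip_is_one(self, seed, r):
        Xs, ys = _random_instance(seed, n=35, p=7)
        vip = pls.vip_scores(pls.fit_pls1(Xs, ys, r))
        assert np.mean(vip.vip**2) == pytest.approx(1.0, abs=1e-8)


def _model_with_weights(W):
    p, r = W.shape
    return pls.PLSModel(
        W=W,
        T=np.zeros((3, r)),
        P=np.zeros((p, r)),
        Q=np.zeros(r),
        U=np.zeros((3, r)),
        E=np.zeros((3, p)),
        F=np.zeros(3),
        ss_y=np.ones(r),
        ss_x=np.ones(r),
        n=3,
        p=p,
        r=r,
    )


class TestSelection:
    def test_component_retention_first_lv_only(self):
        perm = pls.PermutationResult(
            observed=np.array([5.0, 1.0]),
            null=np.zeros((1, 2)),
            p_values=np.array([0.0002, 0.3]),
            n_perm=4999,
            seed=0,
        )
        sel = pls.select_components(np.array([0.5067, 0.09]), perm)
        assert sel.n_retained == 1 and sel.significant

    def test_component_retention_two_lvs(self):
        perm = pls.PermutationResult(
            observed=np.zeros(2),
            null=np.zeros((1, 2)),
            p_values=np.array([0.001, 0.01]),
            n_perm=999,
            seed=0,
        )
        sel = pls.select_components(np.array([0.6, 0.2]), perm)
        assert sel.n_retained == 2

    def test_no_significant_model(self):
        perm = pls.PermutationResult(
            observed=np.zeros(2),
            null=np.zeros((1, 2)),
            p_values=np.array([0.4, 0.6]),
            n_perm=99,
            seed=0,
        )
        sel = pls.select_components(np.array([0.3, 0.1]), perm)
        assert sel.n_retained == 0 and not sel.significant

    def test_greater_than_one_rule_is_strict(self):
        vip = pls.VIPResult(
            vip=np.array([1.0, 1.0]),
            selected=np.array([False, False]),
            predictor_names=["a", "b"],
        )
        assert pls.select_variables(vip) == []

    def test_reported_vip_profile_selection(self):
        names = ["age", "nawm_ad", "nawm_md", "lesion_fa", "lesion_rd", "pbv"]
        values = np.array([1.72, 1.979, 1.169, 1.17, 1.08, 0.62])
        vip = pls.VIPResult(vip=values, selected=values > 1, predictor_names=names)
        assert pls.select_variables(vip) == names[:5]
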