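"""GGM estimation: Spearman input, PD repair, partials, glasso, strength."""

import numpy as np
import pytest

from sympnet.network import (
    EstimatorConfig,
    NetworkError,
    estimate_network,
    full_corr_network,
    glasso_ebic,
    global_strength,
    nearest_pd,
    partial_from_corr,
    spearman_corr,
)
from sympnet.synthetic import TrueNetworkSpec, make_true_network, sample_ordinal_visit


def residual_partial_oracle(R):
    """Partial correlations via regressing out all other variables."""
    p = R.shape[0]
    rng = np.random.default_rng(0)
    # exact computation on the correlation matrix itself, no sampling:
    # r_ij.rest = corr of residuals from the population regressions
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            rest = [k for k in range(p) if k not in (i, j)]
            if rest:
                Rrr = R[np.ix_(rest, rest)]
                bi = np.linalg.solve(Rrr, R[rest, i])
                bj = np.linalg.solve(Rrr, R[rest, j])
                num = R[i, j] - R[rest, i] @ bj
                den = np.sqrt((1 - R[rest, i] @ bi) * (1 - R[rest, j] @ bj))
                W[i, j] = W[j, i] = num / den
            else:
                W[i, j] = W[j, i] = R[i, j]
    return W


def random_pd_corr(p, rng):
    A = rng.standard_normal((p, p + 3))
    S = A @ A.T + 0.5 * np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestSpearman:
    def test_identical_columns_give_unit_correlation(self, rng):
        x = rng.integers(0, 4, size=(200, 1)).astype(float)
        data = np.hstack([x, x, -x])
        cm = spearman_corr(data)
        assert cm.r[0, 1] == pytest.approx(1.0)
        assert cm.r[0, 2] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 4, size=(10_000, 2)).astype(float)
        cm = spearman_corr(data)
        assert abs(cm.r[0, 1]) < 0.05

    def test_constant_column_warns_and_is_missing(self, rng):
        data = rng.integers(0, 4, size=(100, 3)).astype(float)
        data[:, 1] = 2.0
        with pytest.warns(UserWarning, match="constant"):
            cm = spearman_corr(data)
        assert np.isnan(cm.r[0, 1]) and not np.isnan(cm.r[0, 2])

    def test_pairwise_policy_records_effective_n(self, rng):
        data = rng.integers(0, 4, size=(60, 3)).astype(float)
        data[:10, 0] = np.nan
        cm = spearman_corr(data, missing="pairwise")
        assert cm.n_pairs[0, 1] == 50 and cm.n_pairs[1, 2] == 60

    def test_too_small_sample(self):
        with pytest.raises(NetworkError, match="below the minimum"):
            spearman_corr(np.zeros((5, 3)))


class TestNearestPd:
    def test_identity_unchanged(self):
        eye = np.eye(4)
        assert nearest_pd(eye) is eye

    def test_strong_but_pd_2x2_unchanged(self):
        A = np.array([[1.0, 0.999], [0.999, 1.0]])
        assert nearest_pd(A) is A

    def test_rank_deficient_repair_matches_eigenclip_oracle(self):
        # duplicated variable -> singular correlation matrix
        A = np.array([[1.0, 1.0, 0.3], [1.0, 1.0, 0.3], [0.3, 0.3, 1.0]])
        B = nearest_pd(A, eps=1e-6)
        assert np.linalg.eigvalsh(B).min() > 0
        # oracle: direct eigenvalue clip + re-standardization
        w, V = np.linalg.eigh(A)
        C = (V * np.clip(w, 1e-6, None)) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        assert np.linalg.norm(B - C) < 1e-10


class TestPartials:
    def test_two_variable_partial_equals_marginal(self):
        net = partial_from_corr(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert net.weights[0, 1] == pytest.approx(0.5)

    def test_identity_gives_empty_network(self):
        net = partial_from_corr(np.eye(5))
        assert global_strength(net) == 0

    @pytest.mark.parametrize("p", [3, 4, 6, 9])
    def test_matches_regression_residual_oracle(self, p):
        rng = np.random.default_rng(p)
        for _ in range(25):
            R = random_pd_corr(p, rng)
            net = partial_from_corr(R)
            assert np.abs(net.weights - residual_partial_oracle(R)).max() < 1e-8

    def test_model_roundtrip_recovers_weights(self):
        W, R = make_true_network(TrueNetworkSpec(target_strength=1.8, seed=2))
        net = partial_from_corr(R)
        assert np.abs(net.weights - W).max() < 1e-10


class TestGlasso:
    def test_lambda_to_zero_matches_unregularized(self):
        _, R = make_true_network(TrueNetworkSpec(target_strength=1.5, seed=9))
        unreg = partial_from_corr(R)
        net = glasso_ebic(R, n=1000, lambdas=[1e-6])
        assert np.abs(net.weights - unreg.weights).max() < 1e-4

    def test_large_lambda_gives_empty_network(self):
        _, R = make_true_network(TrueNetworkSpec(target_strength=1.5, seed=9))
        net = glasso_ebic(R, n=1000, lambdas=[2.0])
        assert global_strength(net) == 0

    def test_specificity_on_sparse_truth(self):
        W, R = make_true_network(TrueNetworkSpec(target_strength=1.8, seed=4))
        X = sample_ordinal_visit(2000, R, (-1, 0, 1), 0.0, seed=21)
        cfg = EstimatorConfig(estimator="glasso", gamma=0.5)
        net = estimate_network(X, cfg)
        true_zero = (W == 0) & ~np.eye(9, dtype=bool)
        specificity = (net.weights[true_zero] == 0).mean()
        assert specificity >= 0.9


class TestStrength:
    def test_each_pair_counted_once(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.3
        assert global_strength(W) == pytest.approx(0.3)
        W[1, 2] = W[2, 1] = -0.2
        W[2, 3] = W[3, 2] = 0.2
        W[0, 3] = W[3, 0] = 0.2
        assert global_strength(W) == pytest.approx(0.9)

    def test_invariant_to_node_permutation_and_sign_flips(self, rng):
        W = rng.normal(size=(9, 9))
        W = np.triu(W, 1)
        W = W + W.T
        s = global_strength(W)
        perm = rng.permutation(9)
        assert global_strength(W[np.ix_(perm, perm)]) == pytest.approx(s)
        F = W.copy()
        F[0, :] *= -1
        F[:, 0] *= -1
        assert global_strength(F) == pytest.approx(s)

    def test_estimated_strength_converges_with_n(self):
        W, R = make_true_network(TrueNetworkSpec(target_strength=1.6, seed=6))
        truth = global_strength(W)
        med_err = []
        for n in (100, 300, 1000, 3000):
            errs = []
            for s in range(7):
                X = sample_ordinal_visit(n, R, (-1, 0, 1), 0.0, seed=100 * n + s)
                errs.append(abs(global_strength(estimate_network(X)) - truth))
            med_err.append(np.median(errs))
        assert all(a > b for a, b in zip(med_err, med_err[1:]))

    def test_strength_tracks_item_variance_across_severity(self):
        # same network, increasing severity shift -> lower item variance
        # (ceiling effect) -> lower estimated strength
        _, R = make_true_network(TrueNetworkSpec(target_strength=2.0, seed=8))
        strengths, variances = [], []
        for mu in (0.0, 1.2, 2.2):
            X = sample_ordinal_visit(4000, R, (-1, 0, 1), mu, seed=17)
            strengths.append(global_strength(estimate_network(X)))
            variances.append(X.var(axis=0).mean())
        assert sorted(variances, reverse=True) == variances
        assert sorted(strengths, reverse=True) == strengths


class TestFullCorrNetwork:
    def test_marginal_weights_and_zero_diagonal(self, rng):
        x = rng.integers(0, 4, size=(300, 1)).astype(float)
        data = np.hstack([x, x, rng.integers(0, 4, size=(300, 1))])
        net = full_corr_network(data)
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(net.weights) == 0)
        assert net.estimator == "full_nonparametric"

    def test_independent_columns_low_strength(self):
        rng = np.random.default_rng(12)
        data = rng.integers(0, 4, size=(20_000, 9)).astype(float)
        assert global_strength(full_corr_network(data)) < 0.5
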