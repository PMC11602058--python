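import numpy as np
import pytest
from scipy.stats import kruskal, rankdata

import semgrasp as sg
from semgrasp.relieff import ReliefFConfig


def relieff_oracle(X, y, k):
    """Plain-loop multiclass ReliefF with Kononenko prior weighting.

    Deterministic pass over every instance; Manhattan distance on
    range-normalised features; ties in distance broken by ascending index.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.where(hi - lo > 0, hi - lo, 1.0)
    Xn = (X - lo) / rng
    classes = sorted(set(y))
    members = {c: [i for i in range(n) if y[i] == c] for c in classes}
    priors = {c: len(members[c]) / n for c in classes}
    W = np.zeros(d)
    for r in range(n):
        dist = {j: float(np.sum(np.abs(Xn[r] - Xn[j]))) for j in range(n) if j != r}
        for c in classes:
            cand = sorted(
                (j for j in members[c] if j != r), key=lambda j: (dist[j], j)
            )[:k]
            diffs = np.zeros(d)
            for j in cand:
                diffs += np.abs(Xn[r] - Xn[j])
            if c == y[r]:
                W -= diffs / (n * k)
            else:
                W += priors[c] / (1.0 - priors[y[r]]) * diffs / (n * k)
    return W


def informative_vs_noise_table(seed=0, n_per_class=50, n_classes=3, noise=0.05):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), n_per_class)
    informative = y + rng.normal(0, noise, y.size)
    pure_noise = rng.normal(0, 1, y.size)
    return np.column_stack([informative, pure_noise]), y.astype(str)


class TestReliefFWeights:
    def test_informative_feature_outranks_noise_and_matches_oracle(self):
        X, y = informative_vs_noise_table(seed=0)
        W = sg.relieff_weights(X, y, ReliefFConfig(k_neighbors=10))
        assert W[0] > W[1] and W[0] > 0
        expected = relieff_oracle(X, y, k=10)
        assert np.allclose(W, expected, atol=1e-9)
        assert np.all(np.abs(W) <= 1.0)

    def test_constant_feature_scores_exactly_zero(self):
        X, y = informative_vs_noise_table(seed=1)
        X = np.column_stack([X, np.full(X.shape[0], 3.7)])
        W = sg.relieff_weights(X, y, ReliefFConfig(k_neighbors=5))
        assert W[2] == 0.0

    def test_duplicated_samples_preserve_ranking(self):
        X, y = informative_vs_noise_table(seed=2)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        W = sg.relieff_weights(X2, y2, ReliefFConfig(k_neighbors=10))
        expected = relieff_oracle(X2, y2, k=10)
        assert np.allclose(W, expected, atol=1e-9)
        assert W[0] > W[1]

    def test_affine_feature_rescaling_leaves_weights_unchanged(self):
        X, y = informative_vs_noise_table(seed=3)
        W1 = sg.relieff_weights(X, y)
        X_scaled = X.copy()
        X_scaled[:, 0] = 100.0 * X_scaled[:, 0] - 7.0
        X_scaled[:, 1] = -2.0 * X_scaled[:, 1] + 1.0
        W2 = sg.relieff_weights(X_scaled, y)
        # Range normalisation absorbs positive affine maps; a sign flip
        # mirrors distances so magnitudes still agree.
        assert W2[0] == pytest.approx(W1[0], abs=1e-12)
        assert W2[1] == pytest.approx(W1[1], abs=1e-12)

    def test_random_subsampling_is_seed_deterministic(self):
        X, y = informative_vs_noise_table(seed=4)
        cfg = ReliefFConfig(k_neighbors=5, m_samples=40, seed=11)
        assert np.array_equal(sg.relieff_weights(X, y, cfg),
                              sg.relieff_weights(X, y, cfg))

    def test_single_class_raises(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError):
            sg.relieff_weights(X, np.array(["CY"] * 20))

    def test_k_too_large_for_class_raises(self):
        X, y = informative_vs_noise_table(seed=5, n_per_class=8)
        with pytest.raises(ValueError):
            sg.relieff_weights(X, y, ReliefFConfig(k_neighbors=10))


class TestSelectTop:
    def test_orders_by_descending_weight(self):
        res = sg.select_top(np.array([0.5, 0.1, 0.9]), 2)
        assert list(res.selected_indices) == [2, 0]

    def test_full_dimension_is_identity_set(self):
        res = sg.select_top(np.array([0.3, 0.2, 0.4]), 3)
        assert sorted(res.ranked_indices.tolist()) == [0, 1, 2]
        assert sorted(res.selected_indices.tolist()) == [0, 1, 2]

    def test_ties_broken_by_ascending_index(self):
        res = sg.select_top(np.array([0.2, 0.2]), 1)
        assert list(res.selected_indices) == [0]

    def test_idempotent_and_stable(self):
        w = np.array([0.1, 0.7, 0.7, 0.3])
        a = sg.select_top(w, 3)
        b = sg.select_top(w, 3)
        assert np.array_equal(a.ranked_indices, b.ranked_indices)
        assert list(a.ranked_indices) == [1, 2, 3, 0]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            sg.select_top(np.array([0.1]), 2)


def permutation_pvalue(values, labels, n_shuffles=10_000, seed=0):
    """Oracle: permutation distribution of the Kruskal-Wallis H statistic."""
    classes = np.unique(labels)
    H_obs = kruskal(*[values[labels == c] for c in classes]).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        H = kruskal(*[values[perm == c] for c in classes]).statistic
        hits += H >= H_obs
    return (hits + 1) / (n_shuffles + 1)


class TestKruskalWallisScreen:
    def test_disjoint_class_ranges_are_highly_significant(self):
        rng = np.random.default_rng(0)
        y = np.repeat(np.array(["a", "b", "c"]), 10)
        x = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(2, 3, 10),
                            rng.uniform(4, 5, 10)])
        out = sg.kruskal_wallis_screen(x[:, None], y)
        assert out["p_value"].iloc[0] < 0.001
        assert permutation_pvalue(x, y, n_shuffles=2000) < 0.001
        assert bool(out["significant"].iloc[0])

    def test_two_groups_no_ties_matches_rank_formula(self):
        rng = np.random.default_rng(1)
        x = rng.permutation(20).astype(float)  # no ties
        y = np.array(["a"] * 10 + ["b"] * 10)
        out = sg.kruskal_wallis_screen(x[:, None], y)
        ranks = rankdata(x)
        n = x.size
        H_direct = 12 / (n * (n + 1)) * sum(
            g.size * (g.mean() - (n + 1) / 2) ** 2
            for g in (ranks[:10], ranks[10:])
        )
        assert out["H"].iloc[0] == pytest.approx(H_direct, abs=1e-10)

    def test_null_feature_rejection_rate_near_alpha(self):
        """Rejection rate over 300 null simulations within 3 s.e. of 0.05."""
        rng = np.random.default_rng(2)
        y = np.repeat(np.array(list("abcdef")), 20)
        n_sims, alpha = 300, 0.05
        rejections = 0
        for _ in range(n_sims):
            x = rng.normal(size=y.size)
            out = sg.kruskal_wallis_screen(x[:, None], y, alpha=alpha)
            rejections += int(out["significant"].iloc[0])
        rate = rejections / n_sims
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rate - alpha) < 3 * se

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            sg.kruskal_wallis_screen(np.zeros((3, 1)), np.array(["a", "a", "b"]))
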