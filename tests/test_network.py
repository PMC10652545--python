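"""Mutual information, DPI pruning, degree centrality."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from dcnet.network import (
    NetworkConfig,
    apply_dpi,
    build_mi_matrix,
    degree_centrality,
    estimate_group_network,
)
from dcnet.simulate import SyntheticScenario, simulate


def _frame(arr, p=None):
    p = p or arr.shape[1]
    return pd.DataFrame(arr, columns=[f"g{j}" for j in range(p)])


class TestMutualInformation:
    def test_identical_columns_closed_form(self):
        """Two identical continuous columns, n=9, 3 equal-frequency bins → log 3."""
        x = np.array([0.3, 1.2, -0.5, 2.2, 0.9, -1.7, 3.1, 0.1, 1.9])
        df = _frame(np.column_stack([x, x]))
        m = build_mi_matrix(df, n_bins=3, estimator="empirical")
        assert m.iloc[0, 1] == pytest.approx(np.log(3), abs=1e-12)

    def test_brute_force_oracle(self, rng):
        """Empirical MI equals a direct double-sum over the joint histogram."""
        x = rng.normal(size=(20, 2))
        df = _frame(x)
        b = 4
        m = build_mi_matrix(df, n_bins=b, estimator="empirical")
        # independent oracle: explicit joint table from explicit bin codes
        def codes(v):
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v), dtype=int)
            r[order] = np.arange(len(v))
            return (r * b) // len(v)

        ci, cj = codes(x[:, 0]), codes(x[:, 1])
        mi = 0.0
        n = len(ci)
        for a in range(b):
            for c in range(b):
                pij = np.mean((ci == a) & (cj == c))
                if pij > 0:
                    mi += pij * np.log(pij / (np.mean(ci == a) * np.mean(cj == c)))
        assert m.iloc[0, 1] == pytest.approx(mi, abs=1e-12)

    @pytest.mark.parametrize("estimator", ["empirical", "spearman"])
    def test_constant_gene_zero(self, rng, estimator):
        x = rng.normal(size=(12, 3))
        x[:, 1] = 5.0
        m = build_mi_matrix(_frame(x), estimator=estimator)
        assert (m.iloc[1, :] == 0).all() and (m.iloc[:, 1] == 0).all()

    def test_spearman_matches_rank_correlation_formula(self, rng):
        x = rng.normal(size=(50, 2))
        from scipy.stats import spearmanr

        rho = spearmanr(x[:, 0], x[:, 1]).statistic
        m = build_mi_matrix(_frame(x), estimator="spearman")
        assert m.iloc[0, 1] == pytest.approx(max(-0.5 * np.log(1 - rho**2), 0.0), rel=1e-10)

    @pytest.mark.parametrize("estimator", ["empirical", "spearman"])
    @pytest.mark.parametrize(
        "transform", [np.exp, lambda v: 3 * v + 2, lambda v: v**3]
    )
    def test_monotone_transform_invariance(self, rng, estimator, transform):
        x = rng.normal(size=(25, 4))
        m1 = build_mi_matrix(_frame(x), estimator=estimator)
        y = x.copy()
        y[:, 2] = transform(y[:, 2])
        m2 = build_mi_matrix(_frame(y), estimator=estimator)
        np.testing.assert_allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("estimator", ["empirical", "spearman"])
    def test_consistency_for_independent_genes(self, estimator):
        """Mean off-diagonal MI of independent genes shrinks from n=50 to n=500.

        The bin count is pinned (b=4): under auto √n binning the plug-in
        bias is ≈ (b−1)²/(2n) → ½, so consistency only holds at fixed b.
        """
        def mean_mi(n, seed):
            g = np.random.default_rng(seed)
            m = build_mi_matrix(_frame(g.normal(size=(n, 8))), n_bins=4, estimator=estimator)
            v = m.to_numpy()
            return v[np.triu_indices_from(v, k=1)].mean()

        assert mean_mi(500, 0) < mean_mi(50, 0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_mi_matrix(_frame(np.zeros((1, 3))))


def _dpi_oracle(W, epsilon=0.0):
    """Exhaustive triplet enumeration on the input matrix."""
    p = W.shape[0]
    out = W.copy()
    for i, j, k in itertools.product(range(p), repeat=3):
        if len({i, j, k}) < 3:
            continue
        if W[i, j] < min(W[i, k], W[k, j]) - epsilon - 1e-12:
            out[i, j] = 0.0
    np.fill_diagonal(out, 0.0)
    return out


class TestDPI:
    def test_hand_example(self):
        """MI(a,b)=0.9, MI(a,c)=0.8, MI(b,c)=0.5 → the weak (b,c) edge is pruned."""
        W = np.array([[0, 0.9, 0.8], [0.9, 0, 0.5], [0.8, 0.5, 0]])
        out = apply_dpi(pd.DataFrame(W, index=list("abc"), columns=list("abc")))
        expected = np.array([[0, 0.9, 0.8], [0.9, 0, 0.0], [0.8, 0.0, 0]])
        np.testing.assert_array_equal(out.to_numpy(), expected)

    def test_two_genes_no_triplets(self):
        W = pd.DataFrame([[0, 0.4], [0.4, 0]])
        np.testing.assert_array_equal(apply_dpi(W).to_numpy(), W.to_numpy())

    def test_large_epsilon_keeps_everything(self, rng):
        W = np.abs(rng.normal(size=(5, 5)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        df = pd.DataFrame(W)
        np.testing.assert_array_equal(
            apply_dpi(df, epsilon=W.max()).to_numpy(), df.to_numpy()
        )

    def test_asymmetric_rejected(self):
        W = pd.DataFrame([[0, 0.1, 0.2], [0.3, 0, 0.1], [0.2, 0.1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            apply_dpi(W)

    def test_grid_oracle_all_3gene_matrices(self):
        """Exhaustive agreement with the triplet oracle over {0.1..0.9}³."""
        grid = np.arange(0.1, 0.95, 0.1)
        for wab, wac, wbc in itertools.product(grid, repeat=3):
            W = np.array([[0, wab, wac], [wab, 0, wbc], [wac, wbc, 0]])
            out = apply_dpi(pd.DataFrame(W)).to_numpy()
            np.testing.assert_array_equal(out, _dpi_oracle(W))

    def test_random_matrices_match_oracle_and_shrink(self, rng):
        for _ in range(20):
            W = np.abs(rng.normal(size=(6, 6)))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            out = apply_dpi(pd.DataFrame(W)).to_numpy()
            np.testing.assert_array_equal(out, _dpi_oracle(W))
            assert (out <= W + 1e-15).all()  # never increases an entry


class TestDegree:
    def test_zero_matrix(self):
        adj = pd.DataFrame(np.zeros((4, 4)))
        assert (degree_centrality(adj) == 0).all()

    def test_uniform_weights(self):
        W = np.full((3, 3), 0.5)
        np.fill_diagonal(W, 0)
        np.testing.assert_allclose(degree_centrality(pd.DataFrame(W)), [1.0, 1.0, 1.0])

    def test_loop_oracle_and_conservation(self, rng):
        W = np.abs(rng.normal(size=(6, 6)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        theta = degree_centrality(pd.DataFrame(W))
        oracle = [sum(W[k, j] for j in range(6) if j != k) for k in range(6)]
        np.testing.assert_allclose(theta.to_numpy(), oracle, atol=1e-12)
        upper = sum(W[i, j] for i in range(6) for j in range(i + 1, 6))
        assert theta.sum() == pytest.approx(2 * upper, rel=1e-12)


class TestEstimateGroupNetwork:
    def test_shape_and_determinism(self, rng):
        expr = _frame(rng.normal(size=(10, 4)))
        adj1, th1 = estimate_group_network(expr)
        adj2, th2 = estimate_group_network(expr)
        assert th1.shape == (4,)
        pd.testing.assert_frame_equal(adj1, adj2)
        pd.testing.assert_series_equal(th1, th2)

    def test_hub_genes_more_connected_in_perturbed_group(self):
        sc = SyntheticScenario(n_per_group=(60, 60), p=20, hub_size=5, seed=5)
        expr, pheno, truth = simulate(sc)
        grp = pheno.data["condition"].to_numpy()
        _, th_a = estimate_group_network(expr[grp == 0])
        _, th_b = estimate_group_network(expr[grp == 1])
        hub = sorted(truth)
        assert (th_b[hub] - th_a[hub]).mean() > 0

    def test_pruned_degree_not_larger(self, rng):
        expr = _frame(rng.normal(size=(30, 6)))
        _, th_raw = estimate_group_network(expr, NetworkConfig(prune=False))
        _, th_pruned = estimate_group_network(expr, NetworkConfig(prune=True))
        assert (th_pruned <= th_raw + 1e-12).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st_h.integers(min_value=0, max_value=2**31 - 1))
def test_dpi_output_edges_subset_of_input(seed):
    g = np.random.default_rng(seed)
    W = np.abs(g.normal(size=(5, 5)))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    out = apply_dpi(pd.DataFrame(W)).to_numpy()
    assert ((out == 0) | (out == W)).all()
    assert (out <= W).all()
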