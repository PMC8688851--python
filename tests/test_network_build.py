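import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from traitnets.network_build import (
    TraitNetworkBuilder,
    build_network,
    correlate,
    pca_embed,
    threshold_adjacency,
    trait_distances,
)
from traitnets.synthetic_data import GeneratorSpec, exchangeable_corr, generate


class TestCorrelate:
    def test_identical_and_antithetical_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        cr = correlate(np.column_stack([x, x, -x]))
        assert cr.r[0, 1] == pytest.approx(1.0)
        assert cr.r[0, 2] == pytest.approx(-1.0)
        assert cr.p[0, 1] < 1e-10

    def test_null_calibration_monte_carlo(self):
        """Independent normals: |r| small and p not extreme, nearly always."""
        rng = np.random.default_rng(1)
        ok = 0
        repeats = 200
        for _ in range(repeats):
            cr = correlate(rng.standard_normal((1000, 2)))
            if abs(cr.r[0, 1]) < 0.1 and cr.p[0, 1] > 0.001:
                ok += 1
        assert ok >= 0.99 * repeats

    def test_pairwise_complete_matches_listwise_per_pair(self):
        """Pairwise deletion must equal pearsonr on the complete rows."""
        from scipy import stats

        rng = np.random.default_rng(2)
        x = rng.standard_normal((60, 3))
        x[rng.random((60, 3)) < 0.2] = np.nan
        cr = correlate(x)
        for i in range(3):
            for j in range(i + 1, 3):
                keep = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
                ref = stats.pearsonr(x[keep, i], x[keep, j])
                assert cr.r[i, j] == pytest.approx(ref.statistic)
                assert cr.p[i, j] == pytest.approx(ref.pvalue)
                assert cr.n_pairs[i, j] == keep.sum()

    def test_fast_and_slow_paths_agree(self):
        """The no-missing vectorised path must match the per-pair path."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((40, 4))
        fast = correlate(x)
        x_slow = np.vstack([x, np.full((1, 4), np.nan)])  # force per-pair path
        slow = correlate(x_slow)
        np.testing.assert_allclose(fast.r, slow.r, rtol=1e-12)
        np.testing.assert_allclose(fast.p, slow.p, rtol=1e-9)

    def test_constant_column_undefined_not_error(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        cr = correlate(x)
        assert np.isnan(cr.r[0, 1]) and np.isnan(cr.p[0, 1])
        adj, _ = threshold_adjacency(cr)
        assert adj[0, 1] == 0

    def test_too_few_traits(self):
        with pytest.raises(ValueError):
            correlate(np.ones((10, 1)))


class TestThreshold:
    def test_gate_and_sign(self):
        r = np.array([[1.0, 0.8, -0.6], [0.8, 1.0, 0.5], [-0.6, 0.5, 1.0]])
        p = np.array([[0.0, 0.001, 0.01], [0.001, 0.0, 0.20], [0.01, 0.20, 0.0]])
        adj, sign = threshold_adjacency(
            type("CR", (), {"r": r, "p": p})(), alpha=0.05
        )
        assert adj[0, 1] == pytest.approx(0.8) and sign[0, 1] == 1
        assert adj[0, 2] == pytest.approx(0.6) and sign[0, 2] == -1
        assert adj[1, 2] == 0 and sign[1, 2] == 0
        assert np.all(np.diag(adj) == 0)

    def test_strict_inequality(self):
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        p = np.array([[0.0, 0.05], [0.05, 0.0]])
        adj, _ = threshold_adjacency(type("CR", (), {"r": r, "p": p})(), 0.05)
        assert adj[0, 1] == 0  # p == alpha is NOT significant

    @given(alphas=st.tuples(st.floats(0.001, 0.999), st.floats(0.001, 0.999)),
           seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_alpha(self, alphas, seed):
        """edges(a1) ⊆ edges(a2) whenever a1 ≤ a2."""
        a1, a2 = sorted(alphas)
        rng = np.random.default_rng(seed)
        n = 5
        r = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (n, n))), -1, 1)
        p = (lambda m: (m + m.T) / 2)(rng.uniform(0, 1, (n, n)))
        np.fill_diagonal(r, 1.0)
        np.fill_diagonal(p, 0.0)
        cr = type("CR", (), {"r": r, "p": p})()
        lo, _ = threshold_adjacency(cr, a1)
        hi, _ = threshold_adjacency(cr, a2)
        assert np.all((lo > 0) <= (hi > 0))


class TestPCA:
    def test_duplicated_trait_distance_zero(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        emb = pca_embed(np.column_stack([x, x, y]))
        d = trait_distances(emb)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert d[0, 2] > 0.1

    def test_explained_variance_completeness(self):
        rng = np.random.default_rng(5)
        emb = pca_embed(rng.standard_normal((100, 6)))
        assert emb.n_components == 6
        assert emb.explained_variance.sum() == pytest.approx(1.0)
        assert np.all(emb.explained_variance >= 0)

    def test_isotropy_of_independent_traits(self):
        """Six independent traits → each component explains ≈ 1/6."""
        rng = np.random.default_rng(6)
        emb = pca_embed(rng.standard_normal((5000, 6)))
        np.testing.assert_allclose(emb.explained_variance, 1 / 6, atol=0.02)

    def test_scaled_scores_reproduce_correlation(self):
        """Variance-scaled coordinates satisfy scores @ scores.T = R."""
        rng = np.random.default_rng(7)
        x = generate(GeneratorSpec(["a", "b", "c", "d"],
                                   exchangeable_corr(4, 0.5),
                                   n_observations=300, lognormal=False, seed=7))
        emb = pca_embed(x)
        z = (x.values - x.values.mean(0)) / x.values.std(0, ddof=1)
        corr = z.T @ z / (len(z) - 1)
        np.testing.assert_allclose(emb.scores @ emb.scores.T, corr, atol=1e-8)

    def test_distance_invariant_under_component_sign_flip(self):
        rng = np.random.default_rng(8)
        emb = pca_embed(rng.standard_normal((200, 5)))
        d0 = trait_distances(emb)
        emb.scores[:, [1, 3]] *= -1  # consistent per-component flips
        np.testing.assert_allclose(trait_distances(emb), d0, atol=1e-9)

    def test_brute_force_distance_oracle(self):
        rng = np.random.default_rng(9)
        emb = pca_embed(rng.standard_normal((100, 6)))
        d = trait_distances(emb)
        for i in range(6):
            for j in range(6):
                ref = np.sqrt(((emb.scores[j] - emb.scores[i]) ** 2).sum())
                assert d[i, j] == pytest.approx(ref, abs=1e-12)

    def test_too_few_complete_rows(self):
        x = np.full((4, 6), 1.0) + np.random.default_rng(0).standard_normal((4, 6))
        with pytest.raises(ValueError, match="complete-case"):
            pca_embed(x)


class TestBuildNetwork:
    def test_strong_coupling_gives_complete_network(self):
        tm = generate(GeneratorSpec(
            [f"T{i}" for i in range(6)], exchangeable_corr(6, 0.7),
            n_observations=500, lognormal=False, seed=10))
        net = build_network(tm)
        assert net.n_edges == 15

    def test_null_edge_rate_near_alpha(self):
        """Independent traits at n = 30: edge count ≈ 15 α on average."""
        repeats, hits = 400, 0
        for s in range(repeats):
            tm = generate(GeneratorSpec(
                [f"T{i}" for i in range(6)], np.eye(6),
                n_observations=30, lognormal=False, seed=s))
            hits += build_network(tm, alpha=0.05).n_edges
        rate = hits / (repeats * 15)
        sd = np.sqrt(0.05 * 0.95 / (repeats * 15))
        assert abs(rate - 0.05) < 3 * sd

    def test_duplicated_trait_single_edge(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(50)
        net = build_network(np.column_stack([x, x]))
        assert net.n_edges == 1
        assert net.adjacency[0, 1] == pytest.approx(1.0)

    def test_zero_edge_network_flagged_not_error(self):
        rng = np.random.default_rng(12)
        net = build_network(rng.standard_normal((10, 3)), alpha=1e-6)
        assert net.n_edges == 0
        assert net.meta["zero_edges"]

    def test_adjacency_invariant_under_row_permutation(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((80, 4))
        net1 = build_network(x)
        net2 = build_network(x[rng.permutation(80)])
        np.testing.assert_allclose(net1.adjacency, net2.adjacency, atol=1e-12)
        np.testing.assert_allclose(net1.distances, net2.distances, atol=1e-9)

    def test_edge_implies_significant_p(self):
        tm = generate(GeneratorSpec(
            [f"T{i}" for i in range(5)], exchangeable_corr(5, 0.4),
            n_observations=100, lognormal=False, seed=14))
        net = build_network(tm, alpha=0.05)
        edges = net.adjacency > 0
        assert np.all(net.correlations.p[edges] < 0.05)

    def test_estimator_api(self):
        est = TraitNetworkBuilder(alpha=0.01)
        assert est.get_params()["alpha"] == 0.01
        est.set_params(alpha=0.2)
        rng = np.random.default_rng(15)
        est.fit(rng.standard_normal((50, 3)))
        assert est.network_.alpha == 0.2
        assert est.n_features_in_ == 3
        assert est.adjacency_.shape == (3, 3)

    def test_bonferroni_never_adds_edges(self):
        tm = generate(GeneratorSpec(
            [f"T{i}" for i in range(6)], exchangeable_corr(6, 0.3),
            n_observations=60, lognormal=False, seed=16))
        raw = build_network(tm, alpha=0.05)
        adj = build_network(tm, alpha=0.05, p_adjust="bonferroni")
        assert np.all((adj.adjacency > 0) <= (raw.adjacency > 0))

    def test_graphml_and_edge_list_round_trip(self, tmp_path):
        import networkx as nx

        tm = generate(GeneratorSpec(
            [f"T{i}" for i in range(4)], exchangeable_corr(4, 0.6),
            n_observations=200, lognormal=False, seed=17))
        net = build_network(tm)
        path = tmp_path / "net.graphml"
        net.write_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == net.n_edges
        el = net.edge_list()
        assert set(el.columns) == {"trait_i", "trait_j", "weight", "sign", "p",
                                   "distance"}
        assert len(el) == net.n_edges
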