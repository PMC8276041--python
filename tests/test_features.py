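"""Biological features, CRITIC fusion, topology and initial scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kfpm import (DomainAnnotation, ExpressionMatrix, OrthologyTable,
                  PPIGraph, SubcellTable, bio_score, build_hetero_network,
                  critic_weights, expression_score, feature_table,
                  initial_scores, orthology_score, pcc, subcellular_score,
                  topology_score)

from conftest import hetero_adjacency_sets, naive_top, random_graph


class TestOrthology:
    def test_max_normalisation(self):
        tab = OrthologyTable(counts={"a": 2.0, "b": 4.0})
        np.testing.assert_allclose(orthology_score(tab, ["a", "b"]),
                                   [0.5, 1.0])

    def test_all_equal_counts(self):
        tab = OrthologyTable(counts={"a": 3.0, "b": 3.0})
        np.testing.assert_allclose(orthology_score(tab, ["a", "b"]),
                                   [1.0, 1.0])

    def test_missing_protein_scores_zero(self):
        tab = OrthologyTable(counts={"a": 2.0})
        np.testing.assert_allclose(orthology_score(tab, ["a", "x"]),
                                   [1.0, 0.0])

    def test_all_zero_counts_warn_and_zero(self):
        tab = OrthologyTable(counts={"a": 0.0})
        assert orthology_score(tab, ["a", "b"]).sum() == 0


class TestPCC:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 4.0])
        assert pcc(x, x) == pytest.approx(1.0)

    def test_negated_vector(self):
        x = np.array([1.0, 2.0, 4.0])
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_constant_vector_defined_as_zero(self):
        assert pcc(np.ones(5), np.arange(5.0)) == 0.0

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x, y = rng.standard_normal((2, 20))
            assert pcc(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            pcc(np.ones(3), np.ones(4))


class TestExpressionScore:
    def test_isolated_protein_scores_zero(self):
        g = PPIGraph(proteins=["a", "b", "c"], edges={(0, 1)})
        expr = ExpressionMatrix(
            profiles={p: np.arange(4.0) for p in "abc"}, length=4)
        assert expression_score(expr, g)[2] == 0.0

    def test_hub_with_identical_neighbour_profiles(self):
        g = PPIGraph(proteins=list("hxyz"), edges={(0, 1), (0, 2), (0, 3)})
        expr = ExpressionMatrix(
            profiles={p: np.array([1.0, 2.0, 3.0]) for p in "hxyz"},
            length=3)
        assert expression_score(expr, g)[0] == pytest.approx(3.0)

    def test_missing_profile_contributes_zero(self):
        g = PPIGraph(proteins=["a", "b"], edges={(0, 1)})
        expr = ExpressionMatrix(profiles={"a": np.arange(3.0)}, length=3)
        np.testing.assert_allclose(expression_score(expr, g), [0.0, 0.0])

    def test_matches_per_pair_brute_force(self):
        """Sum over neighbours equals explicit per-pair PCC summation on a
        4-node graph with random profiles."""
        rng = np.random.default_rng(5)
        g = PPIGraph(proteins=list("abcd"),
                     edges={(0, 1), (0, 2), (1, 2), (2, 3)})
        expr = ExpressionMatrix(
            profiles={p: rng.standard_normal(8) for p in "abcd"}, length=8)
        got = expression_score(expr, g)
        nb = g.neighbor_sets()
        for i in range(4):
            want = sum(pcc(expr.profiles[g.proteins[i]],
                           expr.profiles[g.proteins[j]]) for j in nb[i])
            assert got[i] == pytest.approx(want)


class TestSubcellularScore:
    def test_two_compartment_hand_example(self):
        """Counts [2, 4] give mean 3 and enrichments [2/3, 4/3]; a protein
        in both compartments scores 2.0."""
        tab = SubcellTable(
            localizations={"a": {"l1", "l2"}, "b": {"l1", "l2"},
                           "c": {"l2"}, "d": {"l2"}},
            universe=["l1", "l2"])
        got = subcellular_score(tab, ["a", "b", "c", "d"])
        assert got[0] == pytest.approx(2.0)
        assert got[2] == pytest.approx(4 / 3)

    def test_unannotated_protein_scores_zero(self):
        tab = SubcellTable(localizations={"a": {"l1"}}, universe=["l1"])
        np.testing.assert_allclose(subcellular_score(tab, ["a", "b"]),
                                   [1.0, 0.0])

    def test_single_label_universe_gives_one(self):
        tab = SubcellTable(localizations={"a": {"l1"}, "b": {"l1"}},
                           universe=["l1"])
        np.testing.assert_allclose(subcellular_score(tab, ["a", "b"]),
                                   [1.0, 1.0])

    def test_counts_restricted_to_given_proteins(self):
        tab = SubcellTable(
            localizations={"a": {"l1"}, "zz": {"l1"}, "b": {"l2"}},
            universe=["l1", "l2"])
        got = subcellular_score(tab, ["a", "b"])  # zz outside the PPI set
        assert got[0] == pytest.approx(1.0)  # counts [1,1], mean 1


class TestCritic:
    def test_independent_columns_near_uniform(self):
        """Three independent standard-normal columns carry equal
        information, so weights approach 1/3 each."""
        rng = np.random.default_rng(42)
        f = rng.standard_normal((5000, 3))
        w = critic_weights(f).weights
        np.testing.assert_allclose(w, [1 / 3] * 3, atol=0.05)

    def test_constant_column_gets_zero_weight(self):
        rng = np.random.default_rng(1)
        f = np.column_stack([rng.standard_normal(50),
                             np.full(50, 2.5),
                             rng.standard_normal(50)])
        cw = critic_weights(f)
        assert cw.weights[1] == 0.0
        assert cw.weights.sum() == pytest.approx(1.0)

    def test_duplicated_pair_penalised(self):
        """Two identical columns conflict maximally with each other, so the
        independent third column gets the largest weight."""
        rng = np.random.default_rng(2)
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        cw = critic_weights(np.column_stack([a, a, b]))
        assert cw.weights[2] == cw.weights.max()
        assert cw.weights[0] == pytest.approx(cw.weights[1])

    def test_degenerate_table_uniform_fallback(self):
        cw = critic_weights(np.ones((10, 3)))
        assert cw.uniform_fallback
        np.testing.assert_allclose(cw.weights, [1 / 3] * 3)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_weights_nonnegative_and_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((int(rng.integers(2, 40)), 3))
        w = critic_weights(f).weights
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)


class TestBioScore:
    def test_single_feature_weight_selects_column(self):
        rng = np.random.default_rng(4)
        f = rng.random((20, 3))
        cw = critic_weights(f)
        cw.weights = np.array([1.0, 0.0, 0.0])
        got = bio_score(f, cw)
        # min-max scaling of column 0 only
        col = (f[:, 0] - f[:, 0].min()) / (f[:, 0].max() - f[:, 0].min())
        np.testing.assert_allclose(got, col)

    def test_uniform_weights_raw_mean(self):
        cw = critic_weights(np.random.default_rng(0).random((5, 3)))
        cw.weights = np.full(3, 1 / 3)
        got = bio_score(np.array([[0.3, 0.6, 0.9]]), cw, raw=True)
        assert got[0] == pytest.approx(0.6)

    def test_hand_evaluated_weighted_sum(self):
        """Frozen hand computation on a 5-row table whose columns already
        span [0, 1], so min-max scaling is the identity on cols 0 and 2 and
        divides col 1 by 4."""
        f = np.array([[0.0, 0.0, 1.0],
                      [0.25, 1.0, 0.0],
                      [0.5, 2.0, 0.5],
                      [0.75, 3.0, 0.25],
                      [1.0, 4.0, 0.75]])
        cw = critic_weights(f)
        cw.weights = np.array([0.5, 0.25, 0.25])
        got = bio_score(f, cw)
        want = 0.5 * f[:, 0] + 0.25 * (f[:, 1] / 4.0) + 0.25 * f[:, 2]
        np.testing.assert_allclose(got, want)

    def test_monotone_in_each_feature(self):
        """Raising one protein's feature never lowers its fused score when
        weights are held fixed."""
        rng = np.random.default_rng(9)
        f = rng.random((15, 3))
        cw = critic_weights(f)
        base = bio_score(f, cw)[0]
        for j in range(3):
            f2 = f.copy()
            f2[0, j] += 0.5
            assert bio_score(f2, cw)[0] >= base - 1e-12


class TestTopologyScore:
    def test_triangle_without_domains(self, triangle):
        ann = DomainAnnotation(domains=["d0"], membership=set())
        het = build_hetero_network(triangle, ann)
        np.testing.assert_allclose(topology_score(het), [1.0, 1.0, 1.0])

    def test_star_and_path_score_zero(self):
        star = PPIGraph(proteins=list("cxyz"),
                        edges={(0, 1), (0, 2), (0, 3)})
        ann = DomainAnnotation(domains=["d0"], membership=set())
        het = build_hetero_network(star, ann)
        np.testing.assert_allclose(topology_score(het), 0.0)

    def test_domain_membership_creates_shared_neighbours(self, triangle):
        """On a triangle where a and b also share domain d1, the domain is
        an extra shared neighbour of the (a, b) pair, raising their scores
        above the plain-triangle value."""
        ann = DomainAnnotation(domains=["d1"],
                               membership={("a", "d1"), ("b", "d1")})
        het = build_hetero_network(triangle, ann)
        got = topology_score(het)
        adj = hetero_adjacency_sets(het.wpp, het.wpd, het.wdd)
        np.testing.assert_allclose(got, naive_top(adj, het.n))
        assert got[0] > 1.0  # plain triangle scores exactly 1

    def test_matches_naive_on_random_networks(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n, m = int(rng.integers(5, 22)), int(rng.integers(1, 8))
            g = random_graph(n, 0.3, rng)
            membership = {(g.proteins[int(i)], f"d{j}")
                          for j in range(m)
                          for i in rng.choice(n, rng.integers(0, 5),
                                              replace=False)}
            ann = DomainAnnotation(domains=[f"d{j}" for j in range(m)],
                                   membership=membership)
            het = build_hetero_network(g, ann)
            adj = hetero_adjacency_sets(het.wpp, het.wpd, het.wdd)
            np.testing.assert_array_equal(topology_score(het),
                                          naive_top(adj, n))


class TestInitialScores:
    def _het(self, bundle):
        return build_hetero_network(bundle.ppi, bundle.domains)

    def test_theta_blend(self, tiny_bundle):
        het = self._het(tiny_bundle)
        bio = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        top = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        s0 = initial_scores(bio, top, 0.7, het.wpd)
        np.testing.assert_allclose(s0.protein_scores, 0.7 * bio + 0.3 * top)

    def test_theta_one_boundary_is_pure_biology(self, tiny_bundle):
        het = self._het(tiny_bundle)
        bio = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        s0 = initial_scores(bio, np.ones(5), 1.0, het.wpd)
        np.testing.assert_allclose(s0.protein_scores, bio)

    def test_domain_scores_max_normalised(self, path3):
        ann = DomainAnnotation(
            domains=["top", "none"],
            membership={("a", "top")})
        from kfpm import build_wpd
        wpd = build_wpd(path3, ann)
        bio = np.array([1.0, 0.2, 0.1])
        s0 = initial_scores(bio, np.zeros(3), 0.7, wpd)
        np.testing.assert_allclose(s0.domain_scores, [1.0, 0.0])

    def test_relabelling_invariance(self, tiny_bundle):
        """Permuting protein order permutes S0 consistently."""
        b = tiny_bundle
        het = self._het(b)
        bio_i = orthology_score(b.orthology, b.ppi.proteins)
        bio_e = expression_score(b.expression, b.ppi)
        bio_s = subcellular_score(b.subcellular, b.ppi.proteins)
        f = feature_table(bio_i, bio_e, bio_s)
        cw = critic_weights(f)
        s0 = initial_scores(bio_score(f, cw), topology_score(het), 0.7,
                            het.wpd)

        perm = np.array([3, 1, 4, 0, 2])
        inv = np.argsort(perm)
        g2 = PPIGraph(
            proteins=[b.ppi.proteins[i] for i in perm],
            edges={(min(inv[i], inv[j]), max(inv[i], inv[j]))
                   for i, j in b.ppi.edges})
        het2 = build_hetero_network(g2, b.domains)
        f2 = feature_table(orthology_score(b.orthology, g2.proteins),
                           expression_score(b.expression, g2),
                           subcellular_score(b.subcellular, g2.proteins))
        s0b = initial_scores(bio_score(f2, critic_weights(f2)),
                             topology_score(het2), 0.7, het2.wpd)
        np.testing.assert_allclose(s0b.protein_scores,
                                   s0.protein_scores[perm])
        np.testing.assert_allclose(s0b.domain_scores, s0.domain_scores)
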