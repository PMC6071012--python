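"""Posterior-odds scoring: priors, features, counts and normalization."""

import numpy as np
import pytest

from nbclda.bayes import (
    Feature,
    FeatureCounts,
    common_neighbors,
    feature_counts,
    normalize_scores,
    prior_odds,
    score_all,
    score_pair,
)
from nbclda.network import (
    DISEASE,
    EdgeSet,
    GENE,
    HeteroNetwork,
    LNCRNA,
    MIRNA,
    ScoreMatrix,
    assemble_gn2,
)

from bruteforce import brute_counts, brute_score
from conftest import edge_set, random_network


class TestPriorOdds:
    def test_toy_t1(self, toy_t1):
        prior = prior_odds(toy_t1)
        assert prior.p1 == 0.25
        assert prior.phi == pytest.approx(1 / 3, rel=1e-15)

    def test_no_known_associations_gives_zero_odds(self, toy_t1):
        net = toy_t1.with_ldn(set())
        prior = prior_odds(net)
        assert prior.p1 == 0.0 and prior.phi == 0.0

    def test_dataset_scale_arithmetic(self):
        """Registry sizes typical of curated compendia: p1 = |known| / (n*r)."""
        lncrnas = tuple(f"l{i}" for i in range(1089))
        diseases = tuple(f"d{i}" for i in range(373))
        rng = np.random.default_rng(0)
        li = rng.choice(1089, size=407)
        dj = rng.choice(373, size=407)
        ldn = {(lncrnas[i], diseases[j]) for i, j in zip(li, dj)}
        while len(ldn) < 407:  # top up collisions to exactly 407 edges
            ldn.add((lncrnas[rng.integers(1089)], diseases[rng.integers(373)]))
        net = HeteroNetwork(
            lncrnas, diseases, ("m0",), (),
            mdn=edge_set(MIRNA, DISEASE, set()),
            mln=edge_set(MIRNA, LNCRNA, set()),
            ldn=edge_set(LNCRNA, DISEASE, ldn),
        )
        assert prior_odds(net).p1 == 407 / 406197

    def test_excluded_edge_lowers_count(self, toy_t1):
        prior = prior_odds(toy_t1, excluded_edge=("l1", "d1"))
        assert prior.n_known == 0 and prior.phi == 0.0

    def test_empty_registry_rejected(self):
        net = HeteroNetwork((), (), (), (),
                            mdn=edge_set(MIRNA, DISEASE, set()),
                            mln=edge_set(MIRNA, LNCRNA, set()),
                            ldn=edge_set(LNCRNA, DISEASE, set()))
        with pytest.raises(ValueError):
            prior_odds(net)


class TestCommonNeighbors:
    def test_toy_t1_single_mirna(self, toy_t1):
        fs = common_neighbors(toy_t1, "l2", "d2")
        assert fs.features == (Feature("miRNA", ("m1",)),)

    def test_no_shared_neighbors_gives_empty_set(self):
        net = HeteroNetwork(
            ("l1",), ("d1",), ("m1", "m2"), (),
            mdn=edge_set(MIRNA, DISEASE, {("m1", "d1")}),
            mln=edge_set(MIRNA, LNCRNA, {("m2", "l1")}),
            ldn=edge_set(LNCRNA, DISEASE, set()),
        )
        assert len(common_neighbors(net, "l1", "d1")) == 0

    def test_interacting_pair_partition(self, interacting_pair_subnetwork):
        """An interacting miRNA-gene couple merges; the rest stay singletons."""
        fs = common_neighbors(interacting_pair_subnetwork, "l2", "d3")
        assert set(fs.features) == {
            Feature("pair", ("m3", "g4")),
            Feature("miRNA", ("m1",)),
            Feature("gene", ("g1",)),
        }

    def test_unknown_node_raises(self, toy_t1):
        with pytest.raises(KeyError):
            common_neighbors(toy_t1, "nope", "d1")

    def test_all_connected_combinations_become_pairs(self):
        """One miRNA interacting with two common genes yields two pair features."""
        base = HeteroNetwork(
            ("l1",), ("d1",), ("m1",), (),
            mdn=edge_set(MIRNA, DISEASE, {("m1", "d1")}),
            mln=edge_set(MIRNA, LNCRNA, {("m1", "l1")}),
            ldn=edge_set(LNCRNA, DISEASE, set()),
        )
        net = assemble_gn2(
            base,
            edge_set(GENE, DISEASE, {("g1", "d1"), ("g2", "d1")}),
            edge_set(GENE, LNCRNA, {("g1", "l1"), ("g2", "l1")}),
            edge_set(GENE, MIRNA, {("g1", "m1"), ("g2", "m1")}),
        )
        fs = common_neighbors(net, "l1", "d1")
        assert set(fs.features) == {
            Feature("pair", ("m1", "g1")),
            Feature("pair", ("m1", "g2")),
        }


class TestFeatureCounts:
    def test_toy_t1_mirna_counts(self, toy_t1):
        counts = feature_counts(toy_t1, Feature("miRNA", ("m1",)))
        assert (counts.n_plus, counts.n_minus, counts.n_l, counts.n_d) == (1, 3, 2, 2)

    def test_toy_t2_pair_counts(self, toy_t2):
        counts = feature_counts(toy_t2, Feature("pair", ("m1", "g1")))
        assert (counts.n_plus, counts.n_minus, counts.n_l, counts.n_d) == (0, 1, 1, 1)

    def test_isolated_feature_counts_zero(self, toy_t2):
        """A gene adjacent to nothing has an empty adjacency rectangle."""
        net = assemble_gn2(
            toy_t2.to_gn1(),
            edge_set(GENE, DISEASE, {("g1", "d2")}),
            edge_set(GENE, LNCRNA, set()),
            edge_set(GENE, MIRNA, set()),
        )
        counts = feature_counts(net, Feature("gene", ("g1",)))
        assert (counts.n_plus, counts.n_minus, counts.n_l) == (0, 0, 0)

    def test_conservation_enforced_at_construction(self):
        with pytest.raises(ValueError, match="conservation"):
            FeatureCounts(n_plus=2, n_minus=2, n_l=1, n_d=1)

    def test_counts_match_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            net = random_network(rng)
            for feature in [Feature("miRNA", (net.mirnas[0],)),
                            Feature("gene", (net.genes[0],)),
                            Feature("pair", (net.mirnas[0], net.genes[0]))]:
                counts = feature_counts(net, feature)
                expected = brute_counts(net, feature.kind, feature.members)
                assert (counts.n_plus, counts.n_minus,
                        counts.n_l, counts.n_d) == expected


class TestScorePair:
    def test_toy_t1_worked_value(self, toy_t1):
        assert score_pair(toy_t1, "l2", "d2") == pytest.approx(0.5, rel=1e-15)

    def test_toy_t2_worked_value(self, toy_t2):
        assert score_pair(toy_t2, "l2", "d2") == pytest.approx(0.5, rel=1e-15)

    def test_empty_neighborhood_returns_prior_odds(self, toy_t1):
        net = toy_t1.with_ldn({("l1", "d1")})
        # disconnect l2 from the miRNA layer so (l2, d1) has no evidence
        stripped = HeteroNetwork(
            net.lncrnas, net.diseases, net.mirnas, (),
            mdn=net.mdn,
            mln=edge_set(MIRNA, LNCRNA, {("m1", "l1")}),
            ldn=net.ldn,
        )
        assert score_pair(stripped, "l2", "d2") == pytest.approx(1 / 3, rel=1e-15)

    def test_single_feature_score_is_count_ratio(self, toy_t1):
        """With exactly one feature the prior odds cancel out of the score."""
        counts = feature_counts(toy_t1, Feature("miRNA", ("m1",)))
        expected = (counts.n_plus + 1) / (counts.n_minus + 1)
        assert score_pair(toy_t1, "l2", "d2") == pytest.approx(expected, rel=1e-15)

    def test_monotone_in_known_evidence(self):
        """Shifting one association from unknown to known raises the factor."""
        for n_l, n_d, n_plus in [(2, 3, 0), (3, 3, 4), (4, 2, 7)]:
            lo = FeatureCounts(n_plus, n_l * n_d - n_plus, n_l, n_d)
            hi = FeatureCounts(n_plus + 1, n_l * n_d - n_plus - 1, n_l, n_d)
            assert ((hi.n_plus + 1) / (hi.n_minus + 1)
                    > (lo.n_plus + 1) / (lo.n_minus + 1))

    def test_zero_prior_gives_zero_score(self, toy_t1):
        net = toy_t1.with_ldn(set())
        assert score_pair(net, "l2", "d2") == 0.0


class TestScoreAll:
    def test_matches_score_pair_on_random_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            net = random_network(rng)
            matrix = score_all(net).values
            for i, l in enumerate(net.lncrnas):
                for j, d in enumerate(net.diseases):
                    assert matrix[i, j] == pytest.approx(
                        score_pair(net, l, d), rel=1e-10)

    def test_zero_known_gives_zero_matrix(self, toy_t1):
        net = toy_t1.with_ldn(set())
        assert np.all(score_all(net).values == 0.0)

    def test_gn2_with_empty_gene_layers_equals_gn1(self, toy_t1):
        gn2 = assemble_gn2(toy_t1,
                           edge_set(GENE, DISEASE, set()),
                           edge_set(GENE, LNCRNA, set()),
                           edge_set(GENE, MIRNA, set()))
        np.testing.assert_allclose(score_all(gn2).values,
                                   score_all(toy_t1).values, rtol=1e-12)

    def test_excluded_edge_threads_through_all_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            net = random_network(rng)
            if not net.ldn.edges:
                continue
            held = sorted(net.ldn.edges)[0]
            matrix = score_all(net, excluded_edge=held).values
            i = net.lnc_index[held[0]]
            j = net.dis_index[held[1]]
            assert matrix[i, j] == pytest.approx(
                brute_score(net, held[0], held[1], excluded_edge=held),
                rel=1e-10)


class TestNormalizeScores:
    def test_fixed_lambda_closed_form(self):
        raw = ScoreMatrix(("l1",), ("d1",), np.array([[0.5]]))
        out = normalize_scores(raw, 1.0)
        assert out.values[0, 0] == pytest.approx(np.log(0.5), rel=1e-15)
        assert out.lam == 1.0

    def test_auto_lambda_bounds_scores_to_unit_interval(self):
        raw = ScoreMatrix(("l1", "l2"), ("d1",), np.array([[0.5], [1.5]]))
        out = normalize_scores(raw, "auto")
        assert out.lam == pytest.approx(abs(np.log(0.5)))
        assert np.all(np.abs(out.values) <= 1.0)

    def test_rank_invariance_across_lambdas(self):
        rng = np.random.default_rng(5)
        raw = ScoreMatrix(tuple(f"l{i}" for i in range(4)),
                          tuple(f"d{j}" for j in range(5)),
                          rng.random((4, 5)) + 0.01)
        orders = [np.argsort(normalize_scores(raw, lam).values, axis=None)
                  for lam in (1.0, 10.0, "auto")]
        assert all(np.array_equal(orders[0], o) for o in orders[1:])

    def test_zero_scores_rank_strictly_last(self):
        raw = ScoreMatrix(("l1", "l2"), ("d1",), np.array([[0.0], [0.2]]))
        out = normalize_scores(raw, "auto")
        assert out.values[0, 0] < out.values[1, 0]
        assert out.values[0, 0] == out.values[1, 0] - 1.0

    def test_nonpositive_lambda_rejected(self):
        raw = ScoreMatrix(("l1",), ("d1",), np.array([[0.5]]))
        with pytest.raises(ValueError):
            normalize_scores(raw, 0.0)
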