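from collections import Counter
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trialnet.cohort import TrialCohort
from trialnet.networks import (
    PAConfig,
    build_er_ensemble,
    build_preferential_attachment_network,
    build_shared_attribute_network,
)

from conftest import make_trial


def cohort_of(labels, **kw):
    return TrialCohort([
        make_trial(f"T{i}", year=1990 + i, group=g, disease=d, **kw)
        for i, (g, d) in enumerate(labels)
    ])


class TestSharedAttributeNetwork:
    def test_single_shared_label_forms_clique(self):
        cohort = cohort_of([("A", f"d{i}") for i in range(4)])
        g = build_shared_attribute_network(cohort, ["group"])
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 6

    def test_pairwise_distinct_labels_give_no_edges(self):
        cohort = cohort_of([(f"g{i}", f"d{i}") for i in range(5)])
        g = build_shared_attribute_network(cohort, ["group", "disease"])
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 5  # isolates retained

    def test_toy_chain_edge_set(self, toy_cohort):
        # (A,x),(A,y),(B,y),(B,z),(C,z): exhaustive pair enumeration gives
        # exactly the chain 0-1, 1-2, 2-3, 3-4
        g = build_shared_attribute_network(toy_cohort, ["group", "disease"])
        expected = {("T0", "T1"), ("T1", "T2"), ("T2", "T3"), ("T3", "T4")}
        assert {tuple(sorted(e)) for e in g.edges()} == expected

    def test_or_semantics_monotone_in_attribute_set(self, default_cohort):
        subsets = [("group",), ("group", "disease"),
                   ("group", "disease", "treatment")]
        edge_sets = []
        for attrs in subsets:
            g = build_shared_attribute_network(default_cohort, attrs)
            edge_sets.append({tuple(sorted(e)) for e in g.edges()})
        assert edge_sets[0] <= edge_sets[1] <= edge_sets[2]

    def test_simple_graph_invariants(self, default_cohort):
        g = build_shared_attribute_network(default_cohort, ["disease", "treatment"])
        assert nx.number_of_selfloops(g) == 0
        assert g.graph["model"] == "shared_attributes"
        assert g.graph["attrs"] == "disease,treatment"

    @settings(derandomize=True, max_examples=60)
    @given(labels=st.lists(
        st.tuples(st.sampled_from("ABC"), st.sampled_from("xyz")),
        min_size=2, max_size=12))
    def test_edges_exactly_where_a_label_is_shared(self, labels):
        cohort = cohort_of(labels)
        g = build_shared_attribute_network(cohort, ["group", "disease"])
        for (i, a), (j, b) in combinations(enumerate(labels), 2):
            shares = a[0] == b[0] or a[1] == b[1]
            assert g.has_edge(f"T{i}", f"T{j}") == shares

    def test_empty_or_unknown_attrs_rejected(self, toy_cohort):
        with pytest.raises(ValueError):
            build_shared_attribute_network(toy_cohort, [])
        with pytest.raises(ValueError, match="unknown attribute"):
            build_shared_attribute_network(toy_cohort, ["phase"])


class TestPreferentialAttachment:
    def test_forced_attachment_with_single_seed_node(self):
        cohort = cohort_of([("A", "x"), ("B", "y")])
        g = build_preferential_attachment_network(cohort, PAConfig(m0=1, m=1, seed=0))
        assert set(g.edges()) == {("T0", "T1")}

    def test_node_and_edge_counts(self, default_cohort):
        cfg = PAConfig(m0=19, m=18, seed=1)
        g = build_preferential_attachment_network(default_cohort, cfg)
        n = len(default_cohort)
        assert g.number_of_nodes() == n
        assert g.number_of_edges() == 19 * 18 // 2 + 18 * (n - 19)
        assert nx.is_connected(g)

    def test_deterministic_under_seed(self, default_cohort):
        cfg = PAConfig(seed=7)
        g1 = build_preferential_attachment_network(default_cohort, cfg)
        g2 = build_preferential_attachment_network(default_cohort, cfg)
        assert set(g1.edges()) == set(g2.edges())

    def test_uniform_scores_give_uniform_attachment(self):
        # identical hr and p for all: the 4th trial's single tie should be
        # uniform over the 3 seed trials
        cohort = cohort_of([("A", "x")] * 4, hr=1.5, p_value=0.3)
        counts = Counter()
        for s in range(6000):
            g = build_preferential_attachment_network(
                cohort, PAConfig(m0=3, m=1, seed=s))
            (tie,) = [v for v in g.neighbors("T3")]
            counts[tie] += 1
        _, p = stats.chisquare(list(counts.values()))
        assert p > 0.001

    def test_attachment_frequency_proportional_to_score(self):
        # scores 1, 2, 7 via the hr-only rule: the next tie should land on
        # the third trial with relative frequency ~0.7
        trials = [make_trial(f"T{i}", year=1990 + i, hr=h, p_value=0.5)
                  for i, h in enumerate([1.0, 2.0, 7.0, 1.0])]
        cohort = TrialCohort(trials)
        hits = 0
        n_rep = 10_000
        for s in range(n_rep):
            g = build_preferential_attachment_network(
                cohort, PAConfig(m0=3, m=1, score_rule="hr_only", seed=s))
            hits += g.has_edge("T3", "T2")
        se = np.sqrt(0.7 * 0.3 / n_rep)
        assert abs(hits / n_rep - 0.7) <= 3 * se

    def test_all_zero_scores_fall_back_to_uniform(self, caplog):
        cohort = cohort_of([("A", "x")] * 5, hr=1.0, p_value=1.0)
        with caplog.at_level("WARNING", logger="trialnet.networks"):
            g = build_preferential_attachment_network(
                cohort, PAConfig(m0=2, m=1, seed=0))
        assert g.number_of_edges() == 1 + 3
        assert any("all-zero scores" in r.message for r in caplog.records)

    def test_invalid_config(self, default_cohort):
        with pytest.raises(Exception):
            build_preferential_attachment_network(
                default_cohort, PAConfig(m0=3, m=4))
        small = cohort_of([("A", "x")] * 3)
        with pytest.raises(ValueError, match="cohort size"):
            build_preferential_attachment_network(small, PAConfig(m0=19, m=18))

    def test_mean_degree_increases_with_score(self, default_cohort):
        # across replicates, successful trials should end up better
        # connected: Spearman correlation between score and mean degree
        from trialnet.cohort import success_scores

        scores = success_scores(default_cohort)
        mean_deg = np.zeros(len(default_cohort))
        n_rep = 50
        for s in range(n_rep):
            g = build_preferential_attachment_network(
                default_cohort, PAConfig(seed=s))
            mean_deg += [g.degree(v) for v in default_cohort.trial_ids]
        rho, p = stats.spearmanr(scores, mean_deg / n_rep)
        assert rho > 0 and p < 0.01


class TestErdosRenyiEnsemble:
    def test_zero_degree_gives_empty_graphs(self):
        graphs = build_er_ensemble(20, 0.0, 3, seed=0)
        assert len(graphs) == 3
        assert all(g.number_of_edges() == 0 for g in graphs)

    def test_table_matched_ensemble_sizes(self):
        # n = 279 with average degree 36 matches the growth-model row
        graphs = build_er_ensemble(279, 36, 5, seed=0)
        assert all(g.number_of_nodes() == 279 for g in graphs)

    def test_mean_degree_within_binomial_error(self):
        graphs = build_er_ensemble(279, 71, 5, seed=2)
        mean_deg = np.mean([2 * g.number_of_edges() / 279 for g in graphs])
        assert 68 <= mean_deg <= 74

    def test_deterministic_and_distinct_members(self):
        a = build_er_ensemble(50, 5, 3, seed=9)
        b = build_er_ensemble(50, 5, 3, seed=9)
        for g, h in zip(a, b):
            assert set(g.edges()) == set(h.edges())
        assert set(a[0].edges()) != set(a[1].edges())

    def test_out_of_range_degree_rejected(self):
        with pytest.raises(ValueError, match="avg_degree"):
            build_er_ensemble(10, 12, 1, seed=0)
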