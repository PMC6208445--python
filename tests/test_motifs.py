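"""Motif census, typed randomization nulls, SIM and SIM-PPI analyses."""

import itertools

import networkx as nx
import numpy as np
import pytest

from floranet.motifs import (
    TRIAD_CLASSES,
    count_autoregulation,
    count_feedback_loops,
    find_sims,
    motif_enrichment,
    randomize_network,
    sim_ppi_enrichment,
    triad_census,
)
from floranet.network import MetaNetwork
from tests.conftest import wrap_digraph
from tests.oracles import (
    _CODE_TO_CLASS,
    _TRIAD_REPRESENTATIVES,
    _canonical_code,
    triad_census_bruteforce,
)


class TestOneAndTwoNodeMotifs:
    def test_no_self_edges_gives_empty_set(self):
        net = wrap_digraph(nx.path_graph(4, create_using=nx.DiGraph))
        assert count_autoregulation(net) == set()

    def test_autoregulation_matches_diagonal_scan(self):
        rng = np.random.default_rng(5)
        net = MetaNetwork()
        for i in range(20):
            net.add_node(f"r{i:02d}", {"regulator"})
        expected = set()
        for i in range(20):
            for j in range(20):
                if rng.random() < 0.1:
                    net.add_edge(f"r{i:02d}", f"r{j:02d}", "binds")
                    if i == j:
                        expected.add(f"r{i:02d}")
        assert count_autoregulation(net) == expected

    def test_paper_scale_autoregulator_count(self, paper_scale_bundle):
        assert len(count_autoregulation(paper_scale_bundle.network)) == 11

    def test_mir172_ap2_style_feedback(self):
        net = MetaNetwork()
        net.add_node("AP2", {"regulator"})
        net.add_node("MIR172", {"miRNA"})
        net.add_edge("AP2", "MIR172", "binds")
        net.add_edge("MIR172", "AP2", "silences")
        assert count_feedback_loops(net) == {frozenset({"AP2", "MIR172"})}

    def test_dag_has_no_feedback(self):
        g = nx.gn_graph(30, seed=1)  # growing network: acyclic
        assert count_feedback_loops(wrap_digraph(g)) == set()

    def test_feedback_matches_pair_scan(self):
        g = nx.gnp_random_graph(25, 0.15, directed=True, seed=9)
        net = wrap_digraph(g)
        expected = {
            frozenset({f"n{u:03d}", f"n{v:03d}"})
            for u, v in itertools.combinations(g.nodes(), 2)
            if g.has_edge(u, v) and g.has_edge(v, u)
        }
        assert count_feedback_loops(net) == expected


class TestTriadCensus:
    def test_empty_graph_all_zero(self):
        net = MetaNetwork()
        for i in range(5):
            net.add_node(f"n{i}", {"regulator"})
        assert all(v == 0 for v in triad_census(net).values())

    def test_three_cycle_is_030C(self):
        g = nx.DiGraph([(0, 1), (1, 2), (2, 0)])
        census = triad_census(wrap_digraph(g))
        assert census["030C"] == 1
        assert sum(census.values()) == 1

    def test_ffl_topology_is_030T(self):
        g = nx.DiGraph([(0, 1), (0, 2), (1, 2)])
        census = triad_census(wrap_digraph(g))
        assert census["030T"] == 1
        assert sum(census.values()) == 1

    def test_matches_all_triples_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(8):
            g = nx.gnp_random_graph(
                22, 0.12, directed=True, seed=int(rng.integers(1 << 30))
            )
            assert triad_census(wrap_digraph(g)) == triad_census_bruteforce(g)

    def test_self_edges_ignored(self):
        g = nx.DiGraph([(0, 1), (0, 2), (1, 2), (0, 0)])
        census = triad_census(wrap_digraph(g))
        assert census["030T"] == 1 and sum(census.values()) == 1

    def test_classifier_invariant_under_all_relabelings(self):
        """Every permutation of every class representative maps to itself."""
        for name, edges in _TRIAD_REPRESENTATIVES.items():
            for perm in itertools.permutations(range(3)):
                permuted = {(perm[u], perm[v]) for u, v in edges}
                assert _CODE_TO_CLASS[_canonical_code(permuted)] == name
                g = nx.DiGraph(permuted)
                g.add_nodes_from(range(3))
                census = triad_census(wrap_digraph(g))
                assert census[name] == 1
                assert sum(census.values()) == 1


def _typed_degree_sequences(net: MetaNetwork):
    from floranet.motifs import _edge_class

    seqs = {}
    for u, v in net.graph.edges():
        if u == v:
            continue
        c = _edge_class(net, u, v)
        out_d, in_d = seqs.setdefault(c, ({}, {}))
        out_d[u] = out_d.get(u, 0) + 1
        in_d[v] = in_d.get(v, 0) + 1
    return seqs


class TestRandomizeNetwork:
    def test_per_type_degree_sequences_preserved(self, small_bundle):
        net = small_bundle.network
        before = _typed_degree_sequences(net)
        shuffled = randomize_network(net, seed=0)
        assert _typed_degree_sequences(shuffled) == before

    def test_no_self_or_duplicate_edges_introduced(self, small_bundle):
        net = small_bundle.network
        original_loops = {
            u for u, v in net.graph.edges() if u == v
        }
        shuffled = randomize_network(net, seed=1)
        loops = {u for u, v in shuffled.graph.edges() if u == v}
        assert loops == original_loops
        assert shuffled.n_edges == net.n_edges  # DiGraph enforces uniqueness
        shuffled.validate()

    def test_same_seed_identical(self, small_bundle):
        net = small_bundle.network
        a = randomize_network(net, seed=42)
        b = randomize_network(net, seed=42)
        assert set(a.graph.edges()) == set(b.graph.edges())

    def test_two_edge_graph_without_legal_swap_unchanged(self):
        net = MetaNetwork()
        for n in ("R1", "R2"):
            net.add_node(n, {"regulator"})
        net.add_node("T1", {"tf_target"})
        # swapping (R1->T1, R2->T1) would duplicate an edge; must stay put
        net.add_edge("R1", "T1", "binds")
        net.add_edge("R2", "T1", "binds")
        shuffled = randomize_network(net, seed=0)
        assert set(shuffled.graph.edges()) == {("R1", "T1"), ("R2", "T1")}

    def test_ensemble_mean_tracks_er_expectation(self):
        """Null ensemble means stay near the analytic ER triad expectations."""
        n, p = 24, 0.12
        g = nx.gnp_random_graph(n, p, directed=True, seed=3)
        net = wrap_digraph(g)
        ens = []
        rng = np.random.default_rng(0)
        for _ in range(40):
            ens.append(
                [triad_census(randomize_network(net, seed=rng))[c]
                 for c in TRIAD_CLASSES]
            )
        ens = np.array(ens, dtype=float)

        # analytic: count labeled 3-node digraphs per class over all 64
        # edge subsets, weight by p^e (1-p)^(6-e)
        from math import comb

        pairs = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
        expect = dict.fromkeys(TRIAD_CLASSES, 0.0)
        for mask in range(64):
            edges = {pairs[b] for b in range(6) if mask >> b & 1}
            if not edges:
                continue
            und = nx.Graph(edges)
            und.add_nodes_from(range(3))
            if not nx.is_connected(und):
                continue
            cls = _CODE_TO_CLASS[_canonical_code(edges)]
            e = len(edges)
            expect[cls] += p**e * (1 - p) ** (6 - e)
        total_triples = comb(n, 3)
        for i, c in enumerate(TRIAD_CLASSES):
            mu, sd = ens[:, i].mean(), ens[:, i].std(ddof=1)
            analytic = total_triples * expect[c]
            assert abs(mu - analytic) <= 3 * max(sd, np.sqrt(analytic), 1.0)


class TestMotifEnrichment:
    def test_empirical_p_floor_holds_for_every_class(self, small_bundle):
        enrich = motif_enrichment(small_bundle.network, n_rand=30, seed=0)
        for e in enrich:
            assert e.empirical_p >= 1 / 31
            assert 0 < e.empirical_p <= 1

    def test_nrand_validated(self, small_bundle):
        with pytest.raises(ValueError):
            motif_enrichment(small_bundle.network, n_rand=5, seed=0)

    def test_degenerate_null_flags_z_nan(self, sep3_network):
        # the 5-edge circuit admits no legal swaps: null sd is 0 everywhere
        enrich = motif_enrichment(sep3_network, n_rand=20, seed=0)
        ffl = next(e for e in enrich if e.class_id == "030T")
        assert np.isnan(ffl.z)
        assert ffl.observed == 2


class TestSIMs:
    def test_regulator_with_four_targets_yields_six_pairs(self):
        net = MetaNetwork()
        net.add_node("R", {"regulator"})
        for i in range(4):
            net.add_node(f"T{i}", {"tf_target"})
            net.add_edge("R", f"T{i}", "binds")
        assert len(find_sims(net)) == 6

    def test_single_target_yields_none(self):
        net = MetaNetwork()
        net.add_node("R", {"regulator"})
        net.add_node("T0", {"tf_target"})
        net.add_edge("R", "T0", "binds")
        assert find_sims(net) == []

    def test_mirna_targets_not_counted_in_sims(self):
        net = MetaNetwork()
        net.add_node("R", {"regulator"})
        net.add_node("T0", {"tf_target"})
        net.add_node("M0", {"miRNA"})
        net.add_edge("R", "T0", "binds")
        net.add_edge("R", "M0", "binds")
        assert find_sims(net) == []

    def test_matches_bruteforce_pair_enumeration(self, small_bundle):
        net = small_bundle.network
        expected = set()
        for r in net.nodes_with_role("regulator"):
            targets = [
                t
                for t in net.successors(r, "binds")
                if t != r and net.roles(t) & {"tf_target", "regulator"}
            ]
            for a, b in itertools.combinations(sorted(targets), 2):
                expected.add((r, frozenset((a, b))))
        got = {(s.regulator, s.target_pair) for s in find_sims(net)}
        assert got == expected


class TestSimPpi:
    def test_ppi_superset_gives_100_percent(self, small_bundle):
        net = small_bundle.network
        all_pairs = {s.target_pair for s in find_sims(net)}
        res = sim_ppi_enrichment(net, all_pairs, n_iter=10, seed=0)
        assert np.allclose(res.observed_pct, 100.0)

    def test_empty_ppi_flagged(self, small_bundle):
        res = sim_ppi_enrichment(small_bundle.network, set(), n_iter=10, seed=0)
        assert res.skipped
        assert np.allclose(res.observed_pct, 0.0)

    def test_planted_enrichment_detected_single_seed(self, small_bundle):
        from floranet.simulate import generate_ppi

        b = small_bundle
        ppi = generate_ppi(b.config, b.truth, b.network)
        res = sim_ppi_enrichment(b.network, ppi, n_iter=50, seed=0)
        assert res.p_value < 0.05
        assert res.observed_pct.mean() > res.control_pct.mean()

    def test_too_few_regulators_rejected(self, sep3_network):
        with pytest.raises(ValueError):
            sim_ppi_enrichment(sep3_network, set(), n_iter=5, seed=0)
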