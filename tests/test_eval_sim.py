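import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from litgraph.eval_sim import (
    ClusterAssignment,
    MeshTaxonomy,
    Walk,
    WalkConfig,
    assign_clusters,
    cluster_entropy,
    coherence_measures,
    entropy_measures,
    envelope,
    load_mesh_ascii,
    load_mesh_xml,
    mesh_similarity,
    random_walk,
    read_gold_index_tsv,
    related_precision_recall,
    run_simulation_batch,
    select_next_node,
    structure_measures,
    auxiliary_measures,
    write_measure_report_tsv,
)

MESH_ASCII = """\
*NEWRECORD
MH = Parkinson Disease, Secondary
ENTRY = Secondary Parkinson Disease
MN = C10.228.662.600.700

*NEWRECORD
MH = Supranuclear Palsy, Progressive
ENTRY = Progressive Supranuclear Palsy|T047
MN = C10.228.662.700
MN = C23.888.592.636.447.690
MN = C11.590.472.500

*NEWRECORD
MH = No Codes Here
"""

MESH_XML = """<?xml version="1.0"?>
<DescriptorRecordSet>
 <DescriptorRecord>
  <DescriptorName><String>Parkinson Disease, Secondary</String></DescriptorName>
  <TreeNumberList><TreeNumber>C10.228.662.600.700</TreeNumber></TreeNumberList>
  <ConceptList><Concept>
   <TermList><Term><String>Secondary Parkinson Disease</String></Term></TermList>
  </Concept></ConceptList>
 </DescriptorRecord>
</DescriptorRecordSet>
"""


@pytest.fixture
def toy_taxonomy():
    return MeshTaxonomy(
        {
            "secondary parkinson disease": {"C10.228.662.600.700"},
            "supranuclear palsy, progressive, 3": {
                "C10.228.662.700",
                "C23.888.592.636.447.690",
                "C11.590.472.500",
            },
            "root only": {"C10"},
            "elsewhere": {"D12.776"},
        }
    )


class TestTaxonomyLoading:
    def test_ascii_loader(self, tmp_path):
        path = tmp_path / "mesh.txt"
        path.write_text(MESH_ASCII)
        tax = load_mesh_ascii(path)
        assert tax.codes("Parkinson Disease, Secondary") == {"C10.228.662.600.700"}
        assert tax.codes("Secondary Parkinson Disease") == {"C10.228.662.600.700"}
        assert len(tax.codes("Supranuclear Palsy, Progressive")) == 3
        assert "no codes here" not in tax

    def test_xml_loader(self, tmp_path):
        path = tmp_path / "mesh.xml"
        path.write_text(MESH_XML)
        tax = load_mesh_xml(path)
        assert tax.codes("Secondary Parkinson Disease") == {"C10.228.662.600.700"}

    def test_every_key_retrievable(self):
        rngterms = {f"term {i}": {f"C{i:02d}.{i}"} for i in range(10)}
        tax = MeshTaxonomy(rngterms)
        for term, codes in rngterms.items():
            assert tax.codes(term) == frozenset(codes)

    def test_malformed_code_rejected(self):
        with pytest.raises(ValueError):
            MeshTaxonomy({"bad": {"C10..228"}})


class TestAssignClusters:
    def test_worked_abstract_clusters(self, toy_taxonomy):
        a = assign_clusters("supranuclear palsy, progressive, 3", toy_taxonomy)
        assert a.abstract == {"C10", "C11", "C23"}

    def test_worked_specific_clusters(self, toy_taxonomy):
        a = assign_clusters("secondary parkinson disease", toy_taxonomy)
        assert a.specific == {"C10.228.662.600.700"}

    def test_subterm_fallback_longest_first(self, toy_taxonomy):
        a = assign_clusters("idiopathic secondary parkinson disease variant", toy_taxonomy)
        assert a.specific == {"C10.228.662.600.700"}

    def test_unmatched_term_empty(self, toy_taxonomy):
        a = assign_clusters("xyzzy frobnicator", toy_taxonomy)
        assert a.empty
        assert a.abstract == frozenset()

    def test_abstract_derived_from_specific(self, toy_taxonomy):
        for term in ("secondary parkinson disease", "supranuclear palsy, progressive, 3"):
            a = assign_clusters(term, toy_taxonomy)
            assert a.abstract == {c.split(".")[0] for c in a.specific}


class TestMeshSimilarity:
    def test_worked_two_thirds(self, toy_taxonomy):
        sim = mesh_similarity(
            "supranuclear palsy, progressive, 3",
            "secondary parkinson disease",
            toy_taxonomy,
        )
        assert sim == pytest.approx(2 / 3)

    def test_identical_codes_give_one(self, toy_taxonomy):
        assert mesh_similarity(
            "secondary parkinson disease", "secondary parkinson disease", toy_taxonomy
        ) == pytest.approx(1.0)

    def test_disjoint_roots_zero(self, toy_taxonomy):
        assert mesh_similarity("root only", "elsewhere", toy_taxonomy) == 0.0

    def test_unassigned_zero(self, toy_taxonomy):
        assert mesh_similarity("gibberish", "root only", toy_taxonomy) == 0.0

    def test_symmetric_and_bounded(self, toy_taxonomy):
        terms = toy_taxonomy.terms()
        for x in terms:
            for y in terms:
                s = mesh_similarity(x, y, toy_taxonomy)
                assert 0.0 <= s <= 1.0
                assert s == pytest.approx(mesh_similarity(y, x, toy_taxonomy))


class TestSelectNextNode:
    def make_star(self):
        g = nx.Graph()
        g.add_edge("hub", "a", weight=0.9)
        g.add_edge("hub", "b", weight=0.1)
        return g

    def test_high_acceptance_base_prefers_head(self):
        g = self.make_star()
        rng = np.random.default_rng(0)
        picks = [
            select_next_node("hub", set(), g, 2, 0.999999, rng) for _ in range(50)
        ]
        assert all(p == "a" for p in picks)

    def test_acceptance_process_probabilities(self):
        # exact law for two neighbours, base e: P(head) = e;
        # P(second) = (1-e)*e^2; fallback uniform over both
        e = 0.9
        p_head = e + (1 - e) * (1 - e * e) * 0.5
        p_second = (1 - e) * e * e + (1 - e) * (1 - e * e) * 0.5
        g = self.make_star()
        rng = np.random.default_rng(123)
        n = 100_000
        picks = [select_next_node("hub", set(), g, 2, e, rng) for _ in range(n)]
        freq_a = picks.count("a") / n
        freq_b = picks.count("b") / n
        assert freq_a == pytest.approx(p_head, abs=0.01)
        assert freq_b == pytest.approx(p_second, abs=0.01)
        assert p_head + p_second == pytest.approx(1.0)

    def test_h1_prefers_unvisited(self):
        g = nx.path_graph(["x", "y", "z"])
        rng = np.random.default_rng(0)
        picks = [
            select_next_node("y", {"x", "y"}, g, 1, 0.999999, rng)
            for _ in range(20)
        ]
        assert all(p == "z" for p in picks)

    def test_h3_vs_h4_ordering(self, toy_taxonomy):
        g = nx.Graph()
        g.add_edge("secondary parkinson disease", "supranuclear palsy, progressive, 3", weight=0.5)
        g.add_edge("secondary parkinson disease", "elsewhere", weight=0.5)
        rng = np.random.default_rng(0)
        h3_picks = {
            select_next_node(
                "secondary parkinson disease", set(), g, 3, 0.999999, rng, toy_taxonomy
            )
            for _ in range(10)
        }
        h4_picks = {
            select_next_node(
                "secondary parkinson disease", set(), g, 4, 0.999999, rng, toy_taxonomy
            )
            for _ in range(10)
        }
        assert h3_picks == {"supranuclear palsy, progressive, 3"}
        assert h4_picks == {"elsewhere"}

    def test_isolated_node_raises(self):
        g = nx.Graph()
        g.add_node("alone")
        with pytest.raises(ValueError):
            select_next_node("alone", set(), g, 1, 0.9, np.random.default_rng(0))


class TestWalkAndEnvelope:
    def test_walk_length_and_adjacency(self):
        g = nx.cycle_graph(6)
        rng = np.random.default_rng(1)
        walk = random_walk(g, 0, WalkConfig(heuristic=1, length=4), rng)
        assert len(walk.nodes) == 5
        for u, v in walk.steps:
            assert g.has_edge(u, v)

    def test_walk_stops_at_dead_end(self):
        g = nx.Graph()
        g.add_node("alone")
        rng = np.random.default_rng(0)
        walk = random_walk(g, "alone", WalkConfig(heuristic=1, length=5), rng)
        assert walk.nodes == ("alone",)

    def test_envelope_radius_zero_is_path(self):
        g = nx.path_graph(5)
        walk = Walk(nodes=(1, 2))
        assert envelope(g, walk, 0) == frozenset({1, 2})

    def test_star_hub_radius_one_covers_graph(self):
        g = nx.star_graph(5)
        assert envelope(g, Walk(nodes=(0,)), 1) == frozenset(g.nodes)

    def test_envelope_matches_bfs_ball_oracle(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(15, 0.2, seed=7)
        nodes = sorted(g.nodes)
        walk_nodes = tuple(rng.choice(nodes, size=3))
        for r in (0, 1, 2):
            expected = set(walk_nodes)
            for n in walk_nodes:
                expected |= {
                    m
                    for m in g.nodes
                    if nx.has_path(g, n, m)
                    and nx.shortest_path_length(g, n, m) <= r
                }
            assert envelope(g, Walk(nodes=walk_nodes), r) == frozenset(expected)


class TestCoherenceMeasures:
    def test_identical_code_walk(self, toy_taxonomy):
        walk = Walk(
            nodes=("secondary parkinson disease", "secondary parkinson disease")
        )
        a, b, c = coherence_measures(walk, toy_taxonomy)
        assert a == pytest.approx(1.0)
        assert b == pytest.approx(1.0)

    def test_zero_step_annihilates_product(self, toy_taxonomy):
        walk = Walk(nodes=("root only", "elsewhere", "root only"))
        _, b, _ = coherence_measures(walk, toy_taxonomy)
        assert b == 0.0

    def test_three_node_hand_computation(self, toy_taxonomy):
        walk = Walk(
            nodes=(
                "supranuclear palsy, progressive, 3",
                "secondary parkinson disease",
                "root only",
            )
        )
        s1 = 2 / 3
        s2 = 2 * 1 / (5 + 1)  # C10.228.662.600.700 vs C10
        a, b, c = coherence_measures(walk, toy_taxonomy)
        assert a == pytest.approx(2 * 1 / (4 + 1))  # best pair shares only C10
        assert b == pytest.approx(s1 * s2)
        assert c == pytest.approx((s1 + s2) / 3)

    def test_single_node_conventions(self, toy_taxonomy):
        a, b, c = coherence_measures(Walk(nodes=("root only",)), toy_taxonomy)
        assert a == pytest.approx(1.0)  # sim(S, S)
        assert b == 1.0
        assert c == 0.0


class TestEntropy:
    def test_single_cluster_zero_bits(self):
        assert cluster_entropy([5]) == 0.0

    def test_two_equal_clusters_one_bit(self):
        assert cluster_entropy([3, 3]) == pytest.approx(1.0)

    def test_empty_zero(self):
        assert cluster_entropy([]) == 0.0

    def test_bounded_by_log_cluster_count(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 10, size=rng.integers(1, 8)).tolist()
            assert cluster_entropy(counts) <= math.log2(len(counts)) + 1e-12

    def test_direct_formula_oracle_on_fixture(self, toy_taxonomy):
        g = nx.complete_graph(
            [
                "secondary parkinson disease",
                "supranuclear palsy, progressive, 3",
                "root only",
                "elsewhere",
            ]
        )
        walk = Walk(
            nodes=(
                "secondary parkinson disease",
                "supranuclear palsy, progressive, 3",
                "root only",
            )
        )
        env = envelope(g, walk, 1)
        d, e, f, g_, h = entropy_measures(walk, env, toy_taxonomy, g)
        # abstract clusters on the path: C10 x3, C11 x1, C23 x1
        counts = [3, 1, 1]
        expected_d = -sum(c / 5 * math.log2(c / 5) for c in counts)
        assert d == pytest.approx(expected_d)
        # specific clusters on the path: 5 distinct codes, one mention each
        assert e == pytest.approx(math.log2(5))
        # envelope = whole graph: abstract C10 x3, C11, C23, D12
        env_counts = [3, 1, 1, 1]
        expected_f = -sum(c / 6 * math.log2(c / 6) for c in env_counts)
        assert f == pytest.approx(expected_f)
        # K4 is a single biconnected component -> zero entropy
        assert h == 0.0


class TestStructureMeasures:
    def test_triangle(self):
        i, j, k, l = structure_measures(nx.complete_graph(3))
        assert (i, j, k, l) == (3.0, 1.0, 3.0, 1.0)

    def test_star(self):
        g = nx.star_graph(4)
        i, j, k, l = structure_measures(g)
        assert i == 5.0
        assert j == 4.0  # each spoke is its own biconnected component
        assert l == 0.0

    def test_empty(self):
        assert structure_measures(nx.Graph()) == (0.0, 0.0, 0.0, 0.0)


class TestAuxiliaryMeasures:
    def test_hand_counts(self, toy_taxonomy):
        g = nx.complete_graph(
            ["secondary parkinson disease", "root only", "elsewhere"]
        )
        walk = Walk(nodes=("secondary parkinson disease", "root only"))
        env = envelope(g, walk, 1)
        m, n_, o, p, q, r, s, t = auxiliary_measures(walk, env, toy_taxonomy)
        assert m == 1.0  # abstract path clusters: {C10}
        assert n_ == 2.0  # both path nodes mention C10
        assert o == 2.0  # envelope adds D12
        assert p == pytest.approx((2 + 1) / 2)
        assert q == 2.0  # specific: full code and bare C10
        assert r == 1.0
        assert s == 3.0
        assert t == 1.0


@pytest.fixture(scope="module")
def small_setup():
    from litgraph.fixtures import synthetic_community_graph

    return synthetic_community_graph(n_groups=2, group_size=6, seed=42)


class TestSimulationBatch:
    def test_grid_shape(self, small_setup):
        g, tax = small_setup
        reports = run_simulation_batch(
            g, tax, heuristics=(1, 2), lengths=(2, 5), radii=(0, 1),
            repetitions=3, seed=1,
        )
        assert len(reports) == 8
        combos = {(r.heuristic, r.length, r.radius) for r in reports}
        assert len(combos) == 8

    def test_deterministic_under_seed(self, small_setup):
        g, tax = small_setup
        kwargs = dict(
            heuristics=(1, 3), lengths=(2,), radii=(0, 1), repetitions=5, seed=9
        )
        r1 = run_simulation_batch(g, tax, **kwargs)
        r2 = run_simulation_batch(g, tax, **kwargs)
        assert r1 == r2

    def test_report_tsv(self, small_setup, tmp_path):
        g, tax = small_setup
        reports = run_simulation_batch(
            g, tax, heuristics=(1,), lengths=(2,), radii=(0,), repetitions=2, seed=0
        )
        out = tmp_path / "report.tsv"
        write_measure_report_tsv(reports, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("H\tL\tr")
        assert len(lines) == 2


class TestRelatedPrecisionRecall:
    def test_half_overlap(self):
        cand = {"p1": ["p2", "p3"]}
        gold = {"p1": ["p2", "p4"]}
        pre, rec, _ = related_precision_recall(cand, gold)
        assert pre == 0.5
        assert rec == 0.5

    def test_identical_rankings_correlate(self):
        cand = {"p1": ["a", "b", "c"]}
        gold = {"p1": ["a", "b", "c"]}
        _, _, frac = related_precision_recall(cand, gold)
        assert frac == 1.0

    def test_reversed_rankings_do_not(self):
        cand = {"p1": ["a", "b", "c"]}
        gold = {"p1": ["c", "b", "a"]}
        _, _, frac = related_precision_recall(cand, gold)
        assert frac == 0.0

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(0)
        items = [f"i{k}" for k in range(8)]
        cand = {"p": list(rng.permutation(items))}
        gold = {"p": list(rng.permutation(items))}
        _, _, frac = related_precision_recall(cand, gold)
        r_c = [cand["p"].index(i) for i in sorted(items)]
        r_g = [gold["p"].index(i) for i in sorted(items)]
        xc, xg = np.array(r_c, float), np.array(r_g, float)
        num = ((xc - xc.mean()) * (xg - xg.mean())).sum()
        den = math.sqrt(((xc - xc.mean()) ** 2).sum() * ((xg - xg.mean()) ** 2).sum())
        expected = num / den
        assert frac == (1.0 if expected >= 0.7 else 0.0)

    def test_weighted_entries_accepted(self):
        cand = {"p1": [("a", 0.9), ("b", 0.5)]}
        gold = {"p1": ["a", "b"]}
        pre, rec, frac = related_precision_recall(cand, gold)
        assert pre == 1.0 and rec == 1.0 and frac == 1.0

    def test_no_shared_keys_errors(self):
        with pytest.raises(ValueError):
            related_precision_recall({"a": []}, {"b": []})

    def test_top_k_truncation(self):
        cand = {"p1": ["a", "x", "y"]}
        gold = {"p1": ["a", "b", "c"]}
        pre, rec, _ = related_precision_recall(cand, gold, top_k=1)
        assert pre == 1.0 and rec == 1.0

    def test_gold_tsv_loader(self, tmp_path):
        path = tmp_path / "gold.tsv"
        path.write_text(
            "pmid\trelated_pmid\trank\n"
            "p1\tb\t2\n"
            "p1\ta\t1\n"
            "p2\tc\t1\n"
        )
        gold = read_gold_index_tsv(path)
        assert gold == {"p1": ["a", "b"], "p2": ["c"]}
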