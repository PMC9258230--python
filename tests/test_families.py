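"""Greedy set cover, subfamily comparison, MCL, and family assembly.

MCL results are cross-checked against an independently written naive dense
implementation (no pruning, fixed-point iteration, clusters read as
connected components of the limit matrix support) plus analytically known
partitions for clique fixtures.
"""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import archfam as af


# --- independent oracle -----------------------------------------------------

def naive_mcl(graph: nx.Graph, inflation: float = 2.0,
              iters: int = 120) -> set[frozenset]:
    """Reference MCL: dense fixed-point iteration, component readout."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = d.get("weight", 1.0)
    loop = a.max(axis=0)
    loop[loop == 0] = 1.0
    a[np.diag_indices(n)] = loop
    a = a / a.sum(axis=0)
    for _ in range(iters):
        a = np.linalg.matrix_power(a, 2)
        a = a ** inflation
        a = a / a.sum(axis=0)
    support = nx.Graph()
    support.add_nodes_from(range(n))
    support.add_edges_from(zip(*np.nonzero(a > 1e-9)))
    return {frozenset(nodes[i] for i in comp)
            for comp in nx.connected_components(support)}


def _triangles():
    g = nx.Graph()
    for tri in (["a", "b", "c"], ["d", "e", "f"]):
        for i in range(3):
            g.add_edge(tri[i], tri[(i + 1) % 3], weight=1.0)
    return g


def _bridged_cliques(bridge_weight=0.01):
    g = nx.Graph()
    for base in ("p", "q"):
        nodes = [f"{base}{i}" for i in range(5)]
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(nodes[i], nodes[j], weight=1.0)
    g.add_edge("p0", "q0", weight=bridge_weight)
    return g


class TestMCL:
    def test_disjoint_triangles(self):
        assert set(af.mcl(_triangles())) == {frozenset("abc"), frozenset("def")}

    def test_bridged_cliques_split_at_bridge(self):
        clusters = set(af.mcl(_bridged_cliques(), inflation=2.0))
        assert clusters == {frozenset(f"p{i}" for i in range(5)),
                            frozenset(f"q{i}" for i in range(5))}

    def test_isolated_node_singleton(self):
        g = nx.Graph()
        g.add_node("x")
        assert af.mcl(g) == [frozenset({"x"})]

    def test_negative_weight_rejected(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=-1.0)
        with pytest.raises(ValueError, match="negative"):
            af.mcl(g)

    @pytest.mark.parametrize("builder", [
        _triangles, _bridged_cliques,
        lambda: nx.path_graph(["a", "b", "c"]),
        lambda: nx.star_graph(4),
        lambda: nx.gnm_random_graph(9, 14, seed=1),
        lambda: nx.gnm_random_graph(10, 12, seed=7),
    ])
    def test_matches_reference_implementation(self, builder):
        g = builder()
        assert set(af.mcl(g)) == naive_mcl(g)

    def test_invariant_to_relabeling(self):
        g = _bridged_cliques()
        mapping = {v: f"z{ord(v[0])}{v[1]}" for v in g.nodes}
        relabeled = nx.relabel_nodes(g, mapping)
        base = {frozenset(mapping[v] for v in c) for c in af.mcl(g)}
        assert base == set(af.mcl(relabeled))

    def test_partitions_nodes(self):
        g = nx.gnm_random_graph(10, 20, seed=3)
        clusters = af.mcl(g)
        all_nodes = [v for c in clusters for v in c]
        assert sorted(all_nodes) == sorted(g.nodes)


class TestGreedySetCover:
    def _ssn(self, edges, nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return g

    def test_star_hub_dominates(self):
        subs = af.greedy_set_cover(self._ssn([("A", "B"), ("A", "C"), ("A", "D")]))
        assert len(subs) == 1
        assert subs[0].representative == "A"
        assert subs[0].members == frozenset("ABCD")

    def test_disjoint_edges(self):
        subs = af.greedy_set_cover(self._ssn([("A", "B"), ("C", "D")]))
        assert sorted(sorted(s.members) for s in subs) == [["A", "B"], ["C", "D"]]

    def test_path_center_first(self):
        # B's closed neighborhood covers all 3; ties would go lexicographic
        subs = af.greedy_set_cover(self._ssn([("A", "B"), ("B", "C")]))
        assert len(subs) == 1 and subs[0].representative == "B"

    def test_lexicographic_tie_break(self):
        # two disjoint edges: equal gain 2 everywhere, A chosen before C
        subs = af.greedy_set_cover(self._ssn([("C", "D"), ("A", "B")]))
        assert subs[0].representative == "A"

    def test_partition_property(self):
        g = nx.gnm_random_graph(40, 80, seed=5)
        subs = af.greedy_set_cover(g)
        members = [v for s in subs for v in s.members]
        assert sorted(members) == sorted(g.nodes)
        assert len(subs) <= g.number_of_nodes()
        for s in subs:
            assert s.representative in s.members


class TestSubfamilySimilarity:
    def _setup(self):
        subs = [af.Subfamily("sub00000", "A", frozenset({"A", "B"})),
                af.Subfamily("sub00001", "C", frozenset({"C", "D"})),
                af.Subfamily("sub00002", "E", frozenset({"E"}))]
        ssn = nx.Graph()
        ssn.add_nodes_from("ABCDE")
        ssn.add_edge("A", "B", bitscore=0.99, coverage=0.9)
        ssn.add_edge("C", "D", bitscore=0.99, coverage=0.9)
        ssn.add_edge("B", "C", bitscore=0.97, coverage=0.8)
        ssn.add_edge("A", "E", bitscore=0.99, coverage=0.99)
        return subs, ssn

    def test_builtin_probability_is_best_cross_pair(self):
        subs, ssn = self._setup()
        (edge,) = af.subfamily_similarity(subs, ssn, mode="builtin")
        assert edge.probability == pytest.approx(97.0)
        assert edge.coverage == pytest.approx(0.8)
        assert edge.weight == pytest.approx(77.6)

    def test_singletons_excluded_in_builtin(self):
        subs, ssn = self._setup()
        edges = af.subfamily_similarity(subs, ssn, mode="builtin")
        assert not any("sub00002" in (e.subfamily_a, e.subfamily_b) for e in edges)

    def test_table_mode_threshold(self):
        subs, _ = self._setup()
        table = pd.DataFrame({
            "query_subfamily": ["sub00000", "sub00000"],
            "target_subfamily": ["sub00001", "sub00002"],
            "probability": [96.0, 90.0],
            "coverage": [0.6, 0.9]})
        edges = af.subfamily_similarity(subs, mode="table", table=table)
        assert len(edges) == 1 and edges[0].probability == 96.0

    def test_table_unknown_subfamily(self):
        subs, _ = self._setup()
        table = pd.DataFrame({"query_subfamily": ["nope"],
                              "target_subfamily": ["sub00000"],
                              "probability": [99.0], "coverage": [0.9]})
        with pytest.raises(ValueError, match="unknown"):
            af.subfamily_similarity(subs, mode="table", table=table)


class TestBuildFamilies:
    def test_composition_and_wide_flag(self):
        subs = [af.Subfamily("sub00000", "A", frozenset({"A", "B"})),
                af.Subfamily("sub00001", "C", frozenset({"C", "D"})),
                af.Subfamily("sub00002", "E", frozenset({"E", "F"}))]
        edges = [af.SubfamilyEdge("sub00000", "sub00001", 99.0, 0.9),
                 af.SubfamilyEdge("sub00001", "sub00002", 99.0, 0.9)]
        genome_of = dict(zip("ABCDEF", ("g1", "g2", "g3", "g4", "g5", "g6")))
        (famly,) = af.build_families(subs, edges, genome_of, min_genomes=5)
        assert famly.proteins == frozenset("ABCDEF")
        assert famly.genomes_present == frozenset(f"g{i}" for i in range(1, 7))
        assert famly.is_wide

    def test_singleton_family_not_wide(self):
        subs = [af.Subfamily("sub00000", "A", frozenset({"A"}))]
        (famly,) = af.build_families(subs, [], {"A": "g1"})
        assert famly.proteins == frozenset({"A"}) and not famly.is_wide

    def test_min_genomes_monotonicity(self):
        subs = [af.Subfamily(f"sub{i:05d}", p, frozenset({p}))
                for i, p in enumerate("ABCDE")]
        genome_of = {p: f"g{i}" for i, p in enumerate("ABCDE")}
        wide_at = [sum(f.is_wide for f in
                       af.build_families(subs, [], genome_of, min_genomes=k))
                   for k in (1, 2, 3)]
        assert wide_at == sorted(wide_at, reverse=True)

    def test_partition_laws(self, small_world):
        """Subfamilies and families both partition the proteins end to end."""
        cfg, matrix, _, truth, proteomes = small_world
        seqs = {r.id: str(r.seq) for recs in proteomes.values() for r in recs}
        hits = af.all_vs_all_kmer_hits(seqs, k=4, min_bitscore=0.2)
        ssn = af.build_ssn(hits, truth.genome_of_protein,
                           evalue_max=0.8, cover_min=0.5)
        subs = af.greedy_set_cover(ssn)
        fams = af.build_families(subs, af.subfamily_similarity(subs, ssn),
                                 truth.genome_of_protein)
        assert sum(len(s.members) for s in subs) == len(seqs)
        assert sum(len(f.proteins) for f in fams) == len(seqs)
        ids = [f.family_id for f in fams]
        assert ids == sorted(ids)
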