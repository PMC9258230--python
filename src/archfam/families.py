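"""Two-step protein family construction.

Step 1: greedy set cover over the sequence similarity network partitions the
proteins into *subfamilies* (each the closed neighborhood of an iteratively
chosen representative).  Step 2: subfamilies are compared to each other —
either via an imported profile–profile comparison table (probability on the
0–100 scale, coverage in [0, 1]) or via a built-in best-cross-pair proxy —
and the surviving edges, weighted by probability × coverage, are clustered
with the Markov Clustering algorithm (inflation 2.0).  MCL clusters of
subfamilies are the *families*; families spanning at least ``min_genomes``
distinct genomes (default 5) are flagged wide and carried into the
presence/absence analysis.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Subfamily",
    "SubfamilyEdge",
    "Family",
    "greedy_set_cover",
    "subfamily_similarity",
    "read_subfamily_table",
    "mcl",
    "build_families",
    "write_memberships",
]

PROBABILITY_MIN = 95.0   # profile-comparison probability threshold (percent)
COVERAGE_MIN = 0.50


@dataclass
class Subfamily:
    subfamily_id: str
    representative: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(
                f"representative {self.representative} not in members of "
                f"{self.subfamily_id}")


@dataclass(frozen=True)
class SubfamilyEdge:
    subfamily_a: str
    subfamily_b: str
    probability: float  # percent, [0, 100]
    coverage: float     # fraction, [0, 1]

    @property
    def weight(self) -> float:
        return self.probability * self.coverage

    def passes(self) -> bool:
        return self.probability >= PROBABILITY_MIN and self.coverage >= COVERAGE_MIN


@dataclass
class Family:
    family_id: str
    subfamilies: tuple[str, ...]
    proteins: frozenset[str]
    genomes_present: frozenset[str]
    min_genomes: int = 5

    @property
    def is_wide(self) -> bool:
        return len(self.genomes_present) >= self.min_genomes


def greedy_set_cover(ssn: nx.Graph) -> list[Subfamily]:
    """Partition SSN nodes into subfamilies by greedy set cover.

    Repeatedly select the node whose closed neighborhood (itself plus its
    SSN neighbors) contains the most still-uncovered nodes; that node
    becomes the representative of a subfamily holding exactly those
    uncovered nodes.  Ties break to the lexicographically smallest node id.
    Isolated nodes end up as singleton subfamilies.
    """
    uncovered = set(ssn.nodes)
    # Lazy greedy: gains only shrink as nodes get covered, so stale heap
    # entries are safe — pop, refresh, and reinsert if no longer maximal.
    heap = [(-(ssn.degree(v) + 1), v) for v in ssn.nodes]
    heapq.heapify(heap)
    subfamilies: list[Subfamily] = []
    while uncovered:
        neg_gain, v = heapq.heappop(heap)
        if v not in uncovered and not any(u in uncovered for u in ssn.neighbors(v)):
            continue
        gain = sum(1 for u in ssn.neighbors(v) if u in uncovered) + (v in uncovered)
        if gain < -neg_gain:
            heapq.heappush(heap, (-gain, v))
            continue
        members = {u for u in ssn.neighbors(v) if u in uncovered}
        if v in uncovered:
            members.add(v)
        uncovered -= members
        # the representative is the selected node even if it was already
        # covered earlier; keep it only as rep, not as a duplicate member
        rep = v if v in members else min(members)
        subfamilies.append(Subfamily(
            subfamily_id=f"sub{len(subfamilies):05d}",
            representative=rep, members=frozenset(members)))
    return subfamilies


def subfamily_similarity(subfams: Sequence[Subfamily], ssn: nx.Graph | None = None,
                         mode: str = "builtin",
                         table: pd.DataFrame | None = None) -> list[SubfamilyEdge]:
    """Score subfamily pairs and keep edges with probability ≥95 and coverage ≥0.50.

    mode="table": consume an external profile–profile comparison table
    (columns query_subfamily, target_subfamily, probability, coverage), as
    produced by an HMM–HMM tool.  mode="builtin": a documented desk-scale
    proxy — probability = 100 × the best cross-subfamily SSN bitscore,
    coverage = the coverage of that best pair; only subfamilies with ≥2
    members are compared (singletons have no profile).
    """
    known = {sf.subfamily_id for sf in subfams}
    if mode == "table":
        if table is None:
            raise ValueError("mode='table' requires a table")
        bad = sorted(set(table["query_subfamily"]).union(table["target_subfamily"])
                     - known)
        if bad:
            raise ValueError(f"table references unknown subfamilies: {bad[:10]}")
        edges = []
        for row in table.itertuples(index=False):
            a, b = sorted((row.query_subfamily, row.target_subfamily))
            if a == b:
                continue
            e = SubfamilyEdge(a, b, float(row.probability), float(row.coverage))
            if e.passes():
                edges.append(e)
        # reciprocal rows collapse to the best-weight edge
        best: dict[tuple[str, str], SubfamilyEdge] = {}
        for e in edges:
            key = (e.subfamily_a, e.subfamily_b)
            if key not in best or e.weight > best[key].weight:
                best[key] = e
        return [best[k] for k in sorted(best)]
    if mode != "builtin":
        raise ValueError(f"unknown mode {mode!r}")
    if ssn is None:
        raise ValueError("mode='builtin' requires the SSN")
    sub_of = {p: sf.subfamily_id for sf in subfams for p in sf.members}
    multi = {sf.subfamily_id for sf in subfams if len(sf.members) >= 2}
    best_pair: dict[tuple[str, str], tuple[float, float]] = {}
    for u, v, d in ssn.edges(data=True):
        sa, sb = sub_of[u], sub_of[v]
        if sa == sb or sa not in multi or sb not in multi:
            continue
        key = tuple(sorted((sa, sb)))
        if key not in best_pair or d["bitscore"] > best_pair[key][0]:
            best_pair[key] = (d["bitscore"], d["coverage"])
    out = []
    for (sa, sb), (bitscore, coverage) in sorted(best_pair.items()):
        e = SubfamilyEdge(sa, sb, probability=100.0 * bitscore, coverage=coverage)
        if e.passes():
            out.append(e)
    return out


def read_subfamily_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def mcl(graph: nx.Graph, inflation: float = 2.0, prune_tol: float = 1e-6,
        conv_tol: float = 1e-8, max_iter: int = 200) -> list[frozenset]:
    """Markov Clustering of a nonnegative, undirected weighted graph.

    Standard MCL: self-loops (weight = max incident edge weight) are added,
    columns are normalized to stochastic, then expansion (matrix squaring)
    alternates with inflation (entrywise power, column renormalization) and
    pruning of entries below ``prune_tol`` until the iterate changes by less
    than ``conv_tol``.  Clusters are read off the attractor structure of the
    limit matrix; nodes attracted to several systems go to the cluster
    receiving the largest flow (ties to the lowest cluster id).  Runs per
    connected component, so disconnected components are never merged.
    """
    for u, v, d in graph.edges(data=True):
        if d.get("weight", 1.0) < 0:
            raise ValueError(f"negative weight on edge ({u}, {v})")
    clusters: list[frozenset] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(frozenset(nodes))
            continue
        idx = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        m = np.zeros((n, n))
        for u, v, d in graph.subgraph(comp).edges(data=True):
            w = float(d.get("weight", 1.0))
            m[idx[u], idx[v]] = m[idx[v], idx[u]] = w
        loop = m.max(axis=0)
        loop[loop == 0] = 1.0
        np.fill_diagonal(m, loop)
        m /= m.sum(axis=0, keepdims=True)
        for _ in range(max_iter):
            expanded = m @ m
            inflated = expanded ** inflation
            inflated[inflated < prune_tol] = 0.0
            colsum = inflated.sum(axis=0, keepdims=True)
            colsum[colsum == 0] = 1.0
            inflated /= colsum
            change = np.max(np.abs(inflated - m))
            m = inflated
            if change < conv_tol:
                break
        else:
            raise RuntimeError(
                f"MCL did not converge in {max_iter} iterations "
                f"(residual {change:.2e})")
        clusters.extend(_read_clusters(m, nodes))
    return clusters


def _read_clusters(m: np.ndarray, nodes: list) -> list[frozenset]:
    """Interpret the MCL limit matrix: attractor systems and their basins."""
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    if not attractors:  # numerically wiped diagonal: fall back to row support
        attractors = [i for i in range(n) if m[i].sum() > 0]
    # union attractors whose rows overlap on attractor columns
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    att_set = set(attractors)
    for i in attractors:
        for j in np.nonzero(m[i] > 0)[0]:
            if j in att_set:
                parent[find(j)] = find(i)
    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)
    sys_list = [sorted(v) for _, v in sorted(systems.items(),
                                             key=lambda kv: min(kv[1]))]
    members: list[set[int]] = [set(s) for s in sys_list]
    for j in range(n):
        flows = [m[s, j].sum() for s in sys_list]
        best = int(np.argmax(flows))  # argmax takes the first (lowest id) on ties
        if flows[best] > 0:
            members[best].add(j)
        else:  # unreached node (fully pruned): its own singleton
            members.append({j})
            sys_list.append([j])
    return [frozenset(nodes[i] for i in s) for s in members if s]


def build_families(subfams: Sequence[Subfamily], edges: Iterable[SubfamilyEdge],
                   genome_of: Mapping[str, str], min_genomes: int = 5,
                   inflation: float = 2.0) -> list[Family]:
    """Cluster subfamilies with MCL into families and flag wide ones.

    Subfamilies absent from the (filtered) edge set become singleton
    families.  Family ids are assigned by descending protein count, then by
    the lexicographically smallest member representative.
    """
    g = nx.Graph()
    for sf in subfams:
        g.add_node(sf.subfamily_id)
    for e in edges:
        if not e.passes():
            raise ValueError(
                f"edge {e.subfamily_a}–{e.subfamily_b} violates the "
                "probability/coverage thresholds")
        g.add_edge(e.subfamily_a, e.subfamily_b, weight=e.weight)
    clusters = mcl(g, inflation=inflation)
    by_id = {sf.subfamily_id: sf for sf in subfams}
    fams = []
    for cluster in clusters:
        subs = tuple(sorted(cluster))
        proteins = frozenset(p for s in subs for p in by_id[s].members)
        genomes = frozenset(genome_of[p] for p in proteins)
        rep = min(by_id[s].representative for s in subs)
        fams.append((len(proteins), rep, subs, proteins, genomes))
    fams.sort(key=lambda t: (-t[0], t[1]))
    return [Family(family_id=f"fam{i:05d}", subfamilies=subs, proteins=proteins,
                   genomes_present=genomes, min_genomes=min_genomes)
            for i, (_, _, subs, proteins, genomes) in enumerate(fams)]


def write_memberships(subfams: Sequence[Subfamily], families: Sequence[Family],
                      genome_of: Mapping[str, str], path: str | Path) -> None:
    """Write the protein → subfamily → family membership TSV."""
    fam_of_sub = {s: f.family_id for f in families for s in f.subfamilies}
    rows = []
    for sf in subfams:
        for p in sorted(sf.members):
            rows.append({"protein_id": p, "subfamily_id": sf.subfamily_id,
                         "family_id": fam_of_sub[sf.subfamily_id],
                         "genome_id": genome_of[p]})
    pd.DataFrame(sorted(rows, key=lambda r: r["protein_id"])).to_csv(
        path, sep="\t", index=False)
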