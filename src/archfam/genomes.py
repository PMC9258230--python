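"""Genome-level analyses: family-content clustering vs. phylogeny, and
genome quality / representative-selection rules.

Genomes are clustered on the Jaccard distance between their family
presence/absence rows; the resulting dendrogram is compared to a reference
phylogeny through the cophenetic correlation — the Pearson correlation
between the two vectors of pairwise tree distances (merge heights for the
dendrogram, patristic distances for the reference tree) over shared leaves.

Quality control mirrors the 38 single-copy-gene (SCG) scheme: a non-DPANN
genome passes with more than 26 SCGs present (>70% completeness) and fewer
than 4 duplicated SCGs (<10% contamination); DPANN genomes, being naturally
reduced, pass with more than 22 SCGs.  Within an ANI cluster the most
complete, then least contaminated genome is the representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

from .pamatrix import Dendrogram, hierarchical_cluster

__all__ = [
    "ScgProfile",
    "QualityResult",
    "N_SCG",
    "cluster_genomes",
    "cophenetic_correlation",
    "scg_quality",
    "select_representative",
    "alignment_row_filter",
]

N_SCG = 38
SCG_MIN_NONDPANN = 26   # pass requires strictly more
SCG_MIN_DPANN = 22
SCG_MAX_DUPLICATED = 4  # pass requires strictly fewer


@dataclass
class ScgProfile:
    """Copy counts of the 38 single-copy marker genes for one genome."""

    genome_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = tuple(int(c) for c in self.counts)
        if len(self.counts) != N_SCG:
            raise ValueError(f"expected {N_SCG} SCG counts, got {len(self.counts)}")
        if any(c < 0 for c in self.counts):
            raise ValueError("SCG copy counts must be nonnegative")

    @property
    def n_present(self) -> int:
        return sum(c >= 1 for c in self.counts)

    @property
    def n_duplicated(self) -> int:
        return sum(c >= 2 for c in self.counts)


@dataclass
class QualityResult:
    genome_id: str
    passed: bool
    completeness: float   # percent
    contamination: float  # percent


def cluster_genomes(matrix: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Hierarchically cluster genome rows on Jaccard distance."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("need at least 2 genomes and 1 family")
    empty = matrix.index[~matrix.any(axis=1)]
    if len(empty):
        raise ValueError(f"genomes with all-false profiles: {list(empty)}")
    d = pdist(matrix.values.astype(bool), metric="jaccard")
    return hierarchical_cluster(d, matrix.index, linkage)


def _leaf_distances(tree) -> tuple[list[str], dict[frozenset, float]]:
    """Pairwise tree distances: merge heights for a Dendrogram, patristic
    distances for a newick string (unit branch lengths assumed, with a
    warning, when the tree carries none)."""
    if isinstance(tree, Dendrogram):
        leaves = list(tree.leaf_ids)
        cond = tree.cophenetic_distances()
        sq = squareform(cond)
        return leaves, {
            frozenset((leaves[i], leaves[j])): float(sq[i, j])
            for i in range(len(leaves)) for j in range(i + 1, len(leaves))}
    t = dendropy.Tree.get(data=str(tree), schema="newick",
                          preserve_underscores=True)
    lengths = [e.length for e in t.edges() if e.tail_node is not None]
    if all(l is None for l in lengths):
        warnings.warn("reference tree has no branch lengths; assuming unit lengths")
        for e in t.edges():
            if e.tail_node is not None:
                e.length = 1.0
    else:
        for e in t.edges():
            if e.tail_node is not None and e.length is None:
                e.length = 0.0
    pdm = t.phylogenetic_distance_matrix()
    taxa = list(t.taxon_namespace)
    dists = {}
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            dists[frozenset((taxa[i].label, taxa[j].label))] = float(
                pdm.patristic_distance(taxa[i], taxa[j]))
    return [tx.label for tx in taxa], dists


def cophenetic_correlation(tree_a, tree_b, method: str = "pearson") -> float:
    """Correlation of pairwise tree distances over the shared leaf set.

    Each argument is a :class:`Dendrogram` or a newick string.  Pearson by
    default (Spearman optional).  Requires ≥3 shared leaves and nonzero
    variance in both distance vectors.
    """
    leaves_a, da = _leaf_distances(tree_a)
    leaves_b, db = _leaf_distances(tree_b)
    shared = sorted(set(leaves_a) & set(leaves_b))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared leaves; need at least 3")
    pairs = [frozenset((shared[i], shared[j]))
             for i in range(len(shared)) for j in range(i + 1, len(shared))]
    x = np.array([da[p] for p in pairs])
    y = np.array([db[p] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance cophenetic distance vector")
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def scg_quality(profile: ScgProfile, is_dpann: bool) -> QualityResult:
    """Apply the draft-quality thresholds to one genome's SCG profile."""
    n_present, n_dup = profile.n_present, profile.n_duplicated
    if not 0 <= n_dup <= n_present <= N_SCG:
        raise ValueError(
            f"invalid SCG profile for {profile.genome_id}: "
            f"present={n_present}, duplicated={n_dup}")
    min_present = SCG_MIN_DPANN if is_dpann else SCG_MIN_NONDPANN
    passed = n_present > min_present and n_dup < SCG_MAX_DUPLICATED
    return QualityResult(profile.genome_id, passed,
                         completeness=100.0 * n_present / N_SCG,
                         contamination=100.0 * n_dup / N_SCG)


def select_representative(
        ani_cluster: Sequence[tuple[str, float, float]]) -> str:
    """Most complete, then least contaminated genome of an ANI cluster.

    Input tuples are (genome_id, completeness, contamination); ties are
    broken by genome id for determinism.
    """
    if not ani_cluster:
        raise ValueError("empty ANI cluster")
    ranked = sorted(ani_cluster, key=lambda t: (-t[1], t[2], t[0]))
    return ranked[0][0]


def alignment_row_filter(rows: Mapping[str, str],
                         marker_synteny: Mapping[str, bool],
                         min_fraction: float = 0.5,
                         gap_chars: str = "-.") -> tuple[list[str], list[str]]:
    """Keep genomes whose aligned marker row is ≥ ``min_fraction`` non-gap
    AND whose marker-synteny flag (all markers on one scaffold) is true.

    Returns (kept, dropped) genome id lists.
    """
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
    kept, dropped = [], []
    for g in sorted(rows):
        seq = rows[g]
        non_gap = sum(c not in gap_chars for c in seq) / len(seq)
        if non_gap >= min_fraction and marker_synteny.get(g, False):
            kept.append(g)
        else:
            dropped.append(g)
    return kept, dropped
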