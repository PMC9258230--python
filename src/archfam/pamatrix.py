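"""Genome × family presence/absence matrix, family dendrogram, and modules.

The matrix is a boolean pandas DataFrame (genomes as rows, families as
columns).  Families are hierarchically clustered on the Jaccard distance
between their genome profiles (complete linkage by default, matching the
displayed clustering); cutting that dendrogram at height 0.95 yields flat
clusters, and clusters of at least 20 families are reported as *modules* —
blocks of co-occurring families.  Each module is assigned a taxonomic
distribution by the median-m rule: with m the median number of genomes per
member family, the m genomes carrying the most member families are retained
and their phylum counts define the module's taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Dendrogram",
    "Module",
    "build_matrix",
    "jaccard_distance",
    "hierarchical_cluster",
    "family_dendrogram",
    "cut_modules",
    "assign_module_taxonomy",
    "write_matrix",
    "read_matrix",
    "write_module_report",
]

LINKAGES = ("complete", "average", "single")


@dataclass
class Dendrogram:
    """An agglomerative merge tree: scipy linkage matrix plus leaf labels."""

    leaf_ids: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    method: str

    def __post_init__(self) -> None:
        if self.method not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}, got {self.method}")
        if self.linkage_matrix.shape != (len(self.leaf_ids) - 1, 4):
            raise ValueError("linkage matrix shape does not match leaf count")

    def cophenetic_distances(self) -> np.ndarray:
        """Condensed matrix of lowest-common-merge heights between leaves."""
        return hierarchy.cophenet(self.linkage_matrix)

    def to_newick(self) -> str:
        """Serialize with branch lengths = height differences between merges."""
        n = len(self.leaf_ids)
        heights = {i: 0.0 for i in range(n)}

        def render(i: int) -> str:
            if i < n:
                return self.leaf_ids[i]
            a, b, h, _ = self.linkage_matrix[i - n]
            parts = []
            for c in (int(a), int(b)):
                parts.append(f"{render(c)}:{h - heights[c]:g}")
            heights[i] = h
            return "(" + ",".join(parts) + ")"

        for i in range(n, 2 * n - 1):
            a, b, h, _ = self.linkage_matrix[i - n]
            heights[i] = h
        return render(2 * n - 2) + ";"


@dataclass
class Module:
    module_id: str
    family_ids: tuple[str, ...]
    m: int | None = None
    retained_genomes: tuple[str, ...] = ()
    taxonomy_distribution: dict[str, int] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.family_ids)


def build_matrix(families: Sequence, genome_ids: Sequence[str],
                 wide_only: bool = True) -> pd.DataFrame:
    """Boolean genome × family matrix from built families.

    A cell is true iff at least one member protein of the family comes from
    that genome.  Row/column order follows the input order.  By default only
    wide families (≥ min_genomes genomes) become columns.
    """
    known = set(genome_ids)
    cols = {}
    for fam in families:
        if wide_only and not fam.is_wide:
            continue
        bad = sorted(set(fam.genomes_present) - known)
        if bad:
            raise ValueError(
                f"family {fam.family_id} references unknown genomes: {bad}")
        cols[fam.family_id] = [g in fam.genomes_present for g in genome_ids]
    return pd.DataFrame(cols, index=list(genome_ids), dtype=bool)


def jaccard_distance(profile_a, profile_b) -> float:
    """1 − |intersection| / |union| of two boolean profiles."""
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("Jaccard distance undefined: both profiles all-false")
    return 1.0 - np.logical_and(a, b).sum() / union


def hierarchical_cluster(distances: np.ndarray, leaf_ids: Sequence[str],
                         linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a condensed (or square) distance matrix."""
    d = np.asarray(distances, dtype=float)
    if d.ndim == 2:
        if d.shape[0] != d.shape[1]:
            raise ValueError("square distance matrix expected when 2-D")
        d = squareform(d, checks=True)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(tuple(leaf_ids), z, linkage)


def family_dendrogram(matrix: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Cluster family columns on the Jaccard distance of genome profiles."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least two families to cluster")
    d = pdist(matrix.values.T.astype(bool), metric="jaccard")
    return hierarchical_cluster(d, matrix.columns, linkage)


def cut_modules(dend: Dendrogram, cutoff: float = 0.95,
                min_module_size: int = 20) -> tuple[list[Module], list[str]]:
    """Flat-cut the family dendrogram into modules.

    Flat clusters are the maximal subtrees whose internal merge heights are
    all ≤ ``cutoff``; clusters of at least ``min_module_size`` families
    become modules, smaller ones are returned as the unassigned list.
    Module ids are ordered by descending family count, then first family id.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1] for Jaccard heights, got {cutoff}")
    labels = hierarchy.fcluster(dend.linkage_matrix, t=cutoff, criterion="distance")
    groups: dict[int, list[str]] = {}
    for leaf, lab in zip(dend.leaf_ids, labels):
        groups.setdefault(int(lab), []).append(leaf)
    clusters = sorted((sorted(fams) for fams in groups.values()),
                      key=lambda fams: (-len(fams), fams[0]))
    modules, unassigned = [], []
    for fams in clusters:
        if len(fams) >= min_module_size:
            modules.append(Module(module_id=f"M{len(modules) + 1:03d}",
                                  family_ids=tuple(fams)))
        else:
            unassigned.extend(fams)
    return modules, sorted(unassigned)


def assign_module_taxonomy(module: Module, matrix: pd.DataFrame,
                           taxonomy: Mapping[str, str],
                           include_ties: bool = False) -> Module:
    """Complete a module with its taxonomic distribution (median-m rule).

    m = the median number of genomes per member family, rounded half-up to
    an integer.  Genomes are ranked by how many member families they carry
    (descending, ties by genome id ascending); the top m are retained and
    their phylum counts define the distribution.  With ``include_ties``,
    genomes tied with the m-th rank are also retained.
    """
    if not module.family_ids:
        raise ValueError("empty module")
    sub = matrix.loc[:, list(module.family_ids)]
    per_family = sub.sum(axis=0).to_numpy()
    m = int(np.floor(np.median(per_family) + 0.5))
    per_genome = sub.sum(axis=1)
    ranked = sorted(matrix.index, key=lambda g: (-per_genome[g], g))
    retained = ranked[:m]
    if include_ties and m < len(ranked):
        cut = per_genome[ranked[m - 1]]
        retained = [g for g in ranked if per_genome[g] > cut] + \
                   [g for g in ranked if per_genome[g] == cut]
    missing = sorted(g for g in retained if g not in taxonomy)
    if missing:
        raise ValueError(f"genomes without a phylum: {missing}")
    dist: dict[str, int] = {}
    for g in retained:
        dist[taxonomy[g]] = dist.get(taxonomy[g], 0) + 1
    module.m = m
    module.retained_genomes = tuple(retained)
    module.taxonomy_distribution = dist
    return module


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_csv(path, sep="\t", index_label="genome_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome_id").astype(bool)


def write_module_report(modules: Sequence[Module], unassigned: Sequence[str],
                        out_dir: str | Path) -> None:
    """Module report TSV + unassigned-family list TSV."""
    out_dir = Path(out_dir)
    rows = [{
        "module_id": mod.module_id,
        "n_families": mod.n_families,
        "m": mod.m if mod.m is not None else "",
        "taxonomy": ";".join(f"{p}:{c}" for p, c in
                             sorted(mod.taxonomy_distribution.items())),
        "families": ",".join(mod.family_ids),
    } for mod in modules]
    pd.DataFrame(rows, columns=["module_id", "n_families", "m", "taxonomy",
                                "families"]).to_csv(
        out_dir / "modules.tsv", sep="\t", index=False)
    pd.DataFrame({"family_id": list(unassigned)}).to_csv(
        out_dir / "unassigned_families.tsv", sep="\t", index=False)
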