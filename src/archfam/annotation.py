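"""Annotation-based quality metrics, family classification, neighborhoods.

The annotation table is a pandas DataFrame indexed by protein_id with
columns kegg (label or empty), pfam (";"-separated domain accessions, DUF
domains recognized by name), has_signal_peptide (bool), tm_helix_count
(int), length (residues).  External predictors (KEGG/PFAM hmmsearch,
SignalP, TMHMM) are consumed as this table, never recomputed.

Classification thresholds: a family is a signal-peptide family when at
least 25% of members carry a predicted signal peptide (inclusive); a
transmembrane family when more than half of members have ≥1 predicted TM
helix (strict); hypothetical when no member has a KEGG label or a non-DUF
PFAM domain; and has bacterial homologs when it matches proteins of at
least 10 distinct bacterial genomes (inclusive).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FamilyClassification",
    "annotation_consistency",
    "family_admixture",
    "classify_family",
    "classify_families",
    "neighborhood_summary",
]

_DUF_RE = re.compile(r"^DUF\d*", re.IGNORECASE)

SP_FRACTION_MIN = 0.25        # inclusive
TM_FRACTION_MIN = 0.5         # strict ("more than half")
BACTERIAL_MIN_GENOMES = 10    # inclusive


@dataclass
class FamilyClassification:
    family_id: str
    is_hypothetical: bool
    signal_peptide_fraction: float
    is_sp_family: bool
    tm_fraction: float
    is_tm_family: bool
    n_bacterial_genomes_hit: int
    has_bacterial_homologs: bool
    median_length: float


def _members_of(families) -> dict[str, Sequence[str]]:
    """Accept Family objects or a mapping family_id → member proteins."""
    if isinstance(families, Mapping):
        return {fid: list(members) for fid, members in families.items()}
    return {fam.family_id: sorted(fam.proteins) for fam in families}


def annotation_consistency(families, annotations: pd.DataFrame) -> pd.Series:
    """For each KEGG label, the best within-one-family concentration.

    Returns a Series label → max over families of (members of the family
    carrying the label) / (all proteins carrying the label).  The headline
    summary — the fraction of labels whose best family holds >80% of the
    label's proteins — is ``(result > 0.8).mean()``.
    """
    fam_of: dict[str, str] = {}
    for fid, members in _members_of(families).items():
        for p in members:
            fam_of[p] = fid
    labelled = annotations[annotations["kegg"].astype(str) != ""]
    if labelled.empty:
        raise ValueError("no annotated proteins")
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for pid, label in labelled["kegg"].items():
        totals[label] = totals.get(label, 0) + 1
        fid = fam_of.get(pid)
        if fid is not None:
            by_fam = counts.setdefault(label, {})
            by_fam[fid] = by_fam.get(fid, 0) + 1
    best = {label: max(counts.get(label, {0: 0}).values()) / totals[label]
            for label in totals}
    return pd.Series(best, name="best_family_fraction").sort_index()


def family_admixture(members: Iterable[str], annotations: pd.DataFrame) -> float | None:
    """Percent of annotated members whose label differs from the dominant one.

    Returns None (undefined) when no member carries a KEGG label.
    """
    labels = [str(annotations.at[p, "kegg"]) for p in members
              if p in annotations.index and str(annotations.at[p, "kegg"]) != ""]
    if not labels:
        return None
    dominant = max(pd.Series(labels).value_counts())
    return 100.0 * (1.0 - dominant / len(labels))


def classify_family(family_id: str, members: Sequence[str],
                    annotations: pd.DataFrame,
                    bacterial_hits: Mapping[str, Iterable[str]] | None = None
                    ) -> FamilyClassification:
    """Apply the family-level classification rules to one family."""
    missing = sorted(p for p in members if p not in annotations.index)
    if missing:
        raise ValueError(
            f"family {family_id}: proteins missing from the annotation table: "
            f"{missing[:10]}" + ("…" if len(missing) > 10 else ""))
    sub = annotations.loc[list(members)]
    n = len(sub)
    sp_fraction = float(sub["has_signal_peptide"].astype(bool).sum()) / n
    tm_fraction = float((sub["tm_helix_count"].astype(int) >= 1).sum()) / n
    has_kegg = (sub["kegg"].astype(str) != "").any()
    non_duf = any(
        dom and not _DUF_RE.match(dom)
        for doms in sub["pfam"].astype(str)
        for dom in doms.split(";") if dom)
    n_bact = len(set(bacterial_hits.get(family_id, ()))) if bacterial_hits else 0
    return FamilyClassification(
        family_id=family_id,
        is_hypothetical=not has_kegg and not non_duf,
        signal_peptide_fraction=sp_fraction,
        is_sp_family=sp_fraction >= SP_FRACTION_MIN,
        tm_fraction=tm_fraction,
        is_tm_family=tm_fraction > TM_FRACTION_MIN,
        n_bacterial_genomes_hit=n_bact,
        has_bacterial_homologs=n_bact >= BACTERIAL_MIN_GENOMES,
        median_length=float(np.median(sub["length"].astype(float))),
    )


def classify_families(families, annotations: pd.DataFrame,
                      bacterial_hits: Mapping[str, Iterable[str]] | None = None
                      ) -> pd.DataFrame:
    """Classify every family; one row per family, Table-style columns."""
    rows = []
    for fid, members in _members_of(families).items():
        c = classify_family(fid, members, annotations, bacterial_hits)
        admix = family_admixture(members, annotations)
        rows.append({
            "family_id": fid, "n_proteins": len(members),
            "is_hypothetical": c.is_hypothetical,
            "signal_peptide_fraction": c.signal_peptide_fraction,
            "is_sp_family": c.is_sp_family,
            "tm_fraction": c.tm_fraction, "is_tm_family": c.is_tm_family,
            "n_bacterial_genomes_hit": c.n_bacterial_genomes_hit,
            "has_bacterial_homologs": c.has_bacterial_homologs,
            "median_length": c.median_length,
            "admixture_percent": admix if admix is not None else np.nan,
        })
    return pd.DataFrame(rows).set_index("family_id").sort_index()


def neighborhood_summary(gene_order: pd.DataFrame, query_family: str,
                         window: int = 5) -> tuple[pd.DataFrame, pd.Series]:
    """Genes around each occurrence of a family, and co-localization rates.

    ``gene_order`` needs columns genome, scaffold, position, strand,
    protein_id, family_id.  For each gene of ``query_family`` the up-to-
    ``window`` genes up- and downstream on the same scaffold are reported
    (truncated at scaffold ends).  The co-localization frequency of a
    neighbor family is the fraction of query occurrences with that family
    inside the window.
    """
    dup = gene_order.duplicated(subset=["scaffold", "position"])
    if dup.any():
        bad = gene_order.loc[dup, ["scaffold", "position"]].iloc[0]
        raise ValueError(
            f"duplicate (scaffold, position): ({bad['scaffold']}, {bad['position']})")
    rows = []
    neighbor_sets = []
    for scaffold, genes in gene_order.groupby("scaffold", sort=False):
        genes = genes.sort_values("position").reset_index(drop=True)
        for i in genes.index[genes["family_id"] == query_family]:
            lo, hi = max(0, i - window), min(len(genes) - 1, i + window)
            block = genes.iloc[list(range(lo, i)) + list(range(i + 1, hi + 1))]
            neighbor_sets.append(set(block["family_id"]))
            for _, nb in block.iterrows():
                rows.append({
                    "query_protein": genes.at[i, "protein_id"],
                    "genome": genes.at[i, "genome"], "scaffold": scaffold,
                    "offset": int(nb["position"]) - int(genes.at[i, "position"]),
                    "neighbor_protein": nb["protein_id"],
                    "neighbor_family": nb["family_id"],
                    "neighbor_strand": nb["strand"],
                })
    occurrences = pd.DataFrame(
        rows, columns=["query_protein", "genome", "scaffold", "offset",
                       "neighbor_protein", "neighbor_family", "neighbor_strand"])
    if not neighbor_sets:
        return occurrences, pd.Series(dtype=float, name="colocalization_frequency")
    all_neighbors = sorted(set().union(*neighbor_sets))
    freq = pd.Series(
        {fam: sum(fam in s for s in neighbor_sets) / len(neighbor_sets)
         for fam in all_neighbors}, name="colocalization_frequency")
    return occurrences, freq.sort_values(ascending=False)
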