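"""Synthetic pangenome generator.

Emulates the statistical structure the downstream analysis assumes: a
taxonomy of lineages, a block of broadly shared core protein families, one
lineage-specific family module per lineage with a configurable within-lineage
prevalence, sparse out-of-lineage background occurrences, per-family sequence
divergence under a simple substitution model, and functional labels with a
controlled admixture (mislabelling) rate.  Ground truth for every planted
structure is returned so parameter-recovery tests can score the pipeline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_presence_absence",
    "simulate_proteomes",
    "simulate_annotations",
    "simulate_bacterial_hits",
    "simulate_gene_order",
    "write_proteomes",
    "write_truth",
]


@dataclass
class SyntheticConfig:
    """Parameters of the planted pangenome.

    Defaults describe a pangenome of 5 lineages with 10 genomes each, a
    40-family core and one 30-family module per lineage, 90% within-lineage
    module prevalence, 95% core prevalence and 1% background occurrence —
    the conditions the recovery tests run under.
    """

    n_lineages: int = 5
    genomes_per_lineage: int = 10
    core_family_count: int = 40
    module_sizes: Sequence[int] | None = None  # default: 30 per lineage
    within_lineage_prevalence: float = 0.9
    core_prevalence: float = 0.95
    background_rate: float = 0.01
    seq_length: int = 200
    substitution_rate: float = 0.05
    kegg_label_rate: float = 0.7
    admixture_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = tuple([30] * self.n_lineages)
        else:
            self.module_sizes = tuple(int(s) for s in self.module_sizes)
        for name in ("n_lineages", "genomes_per_lineage", "core_family_count",
                     "seq_length"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if len(self.module_sizes) != self.n_lineages:
            raise ValueError(
                f"module_sizes has length {len(self.module_sizes)}, "
                f"expected n_lineages={self.n_lineages}")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        for name in ("within_lineage_prevalence", "core_prevalence",
                     "background_rate", "kegg_label_rate", "admixture_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError(
                f"substitution_rate must lie in [0, 1), got {self.substitution_rate}")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated pangenome.

    ``planted_module_of_family`` maps every family to either ``"core"`` or
    the name of its lineage; ``planted_family_of_protein`` is filled in by
    :func:`simulate_proteomes`.  ``generating_tree`` is a star of rake
    subtrees (one rake per lineage) with unit branch lengths.
    """

    planted_family_of_protein: dict[str, str] = field(default_factory=dict)
    planted_module_of_family: dict[str, str] = field(default_factory=dict)
    generating_tree: str = ""
    true_label_of_protein: dict[str, str] = field(default_factory=dict)
    true_label_of_family: dict[str, str] = field(default_factory=dict)
    genome_of_protein: dict[str, str] = field(default_factory=dict)


def _rng(seed: int, *keys: object) -> np.random.Generator:
    """Derive an independent RNG stream from (seed, keys).

    Sub-streams are keyed by a stable hash of the stage/entity identifiers so
    adding genomes or families never reshuffles earlier draws.
    """
    digest = hashlib.sha256("\x1f".join(map(str, keys)).encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, *words])


def _lineage_names(cfg: SyntheticConfig) -> list[str]:
    return [f"L{i + 1:02d}" for i in range(cfg.n_lineages)]


def _genome_ids(cfg: SyntheticConfig) -> dict[str, list[str]]:
    return {lin: [f"{lin}_g{j + 1:02d}" for j in range(cfg.genomes_per_lineage)]
            for lin in _lineage_names(cfg)}


def simulate_presence_absence(cfg: SyntheticConfig):
    """Draw the planted genome × family presence/absence matrix.

    Returns ``(matrix, taxonomy, truth)`` where *matrix* is a boolean
    DataFrame (genomes × planted families), *taxonomy* a DataFrame with
    columns genome_id/phylum/superphylum, and *truth* a
    :class:`SyntheticTruth` with the family→module map and generating tree.

    Core families are present in every genome with probability
    ``core_prevalence``; each lineage module's families are present in
    in-lineage genomes with probability ``within_lineage_prevalence`` and in
    out-of-lineage genomes with probability ``background_rate``.
    """
    lineages = _lineage_names(cfg)
    genomes_by_lineage = _genome_ids(cfg)
    genome_ids = [g for lin in lineages for g in genomes_by_lineage[lin]]
    lineage_of_genome = {g: lin for lin in lineages for g in genomes_by_lineage[lin]}

    family_ids: list[str] = []
    module_of_family: dict[str, str] = {}
    for i in range(cfg.core_family_count):
        fid = f"fam{len(family_ids):05d}"
        family_ids.append(fid)
        module_of_family[fid] = "core"
    for lin, size in zip(lineages, cfg.module_sizes):
        for _ in range(size):
            fid = f"fam{len(family_ids):05d}"
            family_ids.append(fid)
            module_of_family[fid] = lin

    cells = np.zeros((len(genome_ids), len(family_ids)), dtype=bool)
    for j, fid in enumerate(family_ids):
        rng = _rng(cfg.seed, "presence", fid)
        u = rng.random(len(genome_ids))
        mod = module_of_family[fid]
        for i, g in enumerate(genome_ids):
            if mod == "core":
                p = cfg.core_prevalence
            elif lineage_of_genome[g] == mod:
                p = cfg.within_lineage_prevalence
            else:
                p = cfg.background_rate
            cells[i, j] = u[i] < p

    matrix = pd.DataFrame(cells, index=genome_ids, columns=family_ids)
    taxonomy = pd.DataFrame({
        "genome_id": genome_ids,
        "phylum": [lineage_of_genome[g] for g in genome_ids],
        "superphylum": ["non-DPANN"] * len(genome_ids),
    })
    rakes = ",".join(
        "(" + ",".join(f"{g}:1" for g in genomes_by_lineage[lin]) + "):1"
        for lin in lineages)
    truth = SyntheticTruth(
        planted_module_of_family=module_of_family,
        generating_tree=f"({rakes});",
        true_label_of_family={fid: f"K{j:05d}" for j, fid in enumerate(family_ids)},
    )
    return matrix, taxonomy, truth


def simulate_proteomes(cfg: SyntheticConfig, matrix: pd.DataFrame,
                       truth: SyntheticTruth) -> dict[str, list[SeqRecord]]:
    """Emit one protein per (genome, present family) under a substitution model.

    Each family gets an ancestor sequence of uniform random residues; every
    genome carrying the family receives a copy in which each site is
    independently replaced, with probability ``substitution_rate``, by a
    uniformly chosen *different* residue (no indels).  Protein ids encode
    only the genome; the protein→family map lives in *truth*.
    """
    ancestors: dict[str, np.ndarray] = {}
    for fid in matrix.columns:
        rng = _rng(cfg.seed, "ancestor", fid)
        ancestors[fid] = rng.integers(0, len(AMINO_ACIDS), size=cfg.seq_length)

    proteomes: dict[str, list[SeqRecord]] = {}
    for genome in matrix.index:
        records: list[SeqRecord] = []
        counter = 0
        for fid in matrix.columns:
            if not matrix.at[genome, fid]:
                continue
            rng = _rng(cfg.seed, "mutate", genome, fid)
            seq = ancestors[fid].copy()
            if cfg.substitution_rate > 0:
                hit = rng.random(cfg.seq_length) < cfg.substitution_rate
                if hit.any():
                    # shift by 1..19 mod 20: always a different residue
                    shift = rng.integers(1, len(AMINO_ACIDS), size=int(hit.sum()))
                    seq[hit] = (seq[hit] + shift) % len(AMINO_ACIDS)
            pid = f"{genome}_p{counter:05d}"
            counter += 1
            records.append(SeqRecord(Seq("".join(AMINO_ACIDS[seq])), id=pid,
                                     description=f"genome={genome}"))
            truth.planted_family_of_protein[pid] = fid
            truth.true_label_of_protein[pid] = truth.true_label_of_family[fid]
            truth.genome_of_protein[pid] = genome
        proteomes[genome] = records
    return proteomes


def simulate_annotations(truth: SyntheticTruth, cfg: SyntheticConfig) -> pd.DataFrame:
    """Annotate proteins with their family's true label plus admixture noise.

    Each protein receives its family's label with probability
    ``kegg_label_rate``; an annotated protein is swapped to a uniformly
    chosen *wrong* label with probability ``admixture_rate``.  Signal-peptide
    flags and transmembrane-helix counts are drawn from family-level
    propensities so that family classification has both kinds of family to
    find; PFAM columns are left empty (KEGG carries the label signal here).
    """
    labels = sorted(set(truth.true_label_of_family.values()))
    rows = []
    fam_prop: dict[str, tuple[float, float]] = {}
    for pid in sorted(truth.planted_family_of_protein):
        fid = truth.planted_family_of_protein[pid]
        if fid not in fam_prop:
            frng = _rng(cfg.seed, "propensity", fid)
            sp_rate = 0.6 if frng.random() < 0.2 else 0.02
            tm_rate = 0.8 if frng.random() < 0.2 else 0.05
            fam_prop[fid] = (sp_rate, tm_rate)
        sp_rate, tm_rate = fam_prop[fid]
        rng = _rng(cfg.seed, "annotate", pid)
        kegg = ""
        if rng.random() < cfg.kegg_label_rate:
            kegg = truth.true_label_of_protein[pid]
            if rng.random() < cfg.admixture_rate and len(labels) > 1:
                wrong = [lab for lab in labels if lab != kegg]
                kegg = wrong[int(rng.integers(0, len(wrong)))]
        rows.append({
            "protein_id": pid,
            "kegg": kegg,
            "pfam": "",
            "has_signal_peptide": bool(rng.random() < sp_rate),
            "tm_helix_count": int(rng.poisson(2)) + 1 if rng.random() < tm_rate else 0,
            "length": cfg.seq_length,
        })
    return pd.DataFrame(rows).set_index("protein_id")


def simulate_bacterial_hits(truth: SyntheticTruth, cfg: SyntheticConfig,
                            hit_fraction: float = 0.2,
                            n_bacterial_genomes: int = 50) -> pd.DataFrame:
    """Emit a truth-consistent family → bacterial-genome hit table.

    A ``hit_fraction`` of families is deemed to have bacterial homologs; each
    such family hits a Poisson(15)+5 sized subset of ``n_bacterial_genomes``
    mock bacterial genomes, so some families clear the ≥10-genome rule and
    others do not.  Columns: family_id, bacterial_genome.
    """
    rows = []
    pool = [f"bact_{i:04d}" for i in range(n_bacterial_genomes)]
    for fid in sorted(truth.planted_module_of_family):
        rng = _rng(cfg.seed, "bacteria", fid)
        if rng.random() >= hit_fraction:
            continue
        n = min(int(rng.poisson(15)) + 5, n_bacterial_genomes)
        for g in rng.choice(pool, size=n, replace=False):
            rows.append({"family_id": fid, "bacterial_genome": g})
    return pd.DataFrame(rows, columns=["family_id", "bacterial_genome"])


def simulate_gene_order(matrix: pd.DataFrame, truth: SyntheticTruth,
                        cfg: SyntheticConfig) -> pd.DataFrame:
    """Lay each genome's proteins on a single scaffold in random order.

    Returns the gene-order table consumed by neighborhood summaries:
    columns genome, scaffold, position, strand, protein_id, family_id.
    """
    prot_by_genome: dict[str, list[str]] = {}
    for pid, g in truth.genome_of_protein.items():
        prot_by_genome.setdefault(g, []).append(pid)
    rows = []
    for genome in matrix.index:
        pids = sorted(prot_by_genome.get(genome, []))
        rng = _rng(cfg.seed, "gene_order", genome)
        order = rng.permutation(len(pids))
        strands = rng.choice(["+", "-"], size=len(pids))
        for pos, (idx, strand) in enumerate(zip(order, strands)):
            pid = pids[idx]
            rows.append({
                "genome": genome, "scaffold": f"{genome}_s1", "position": pos,
                "strand": strand, "protein_id": pid,
                "family_id": truth.planted_family_of_protein[pid],
            })
    return pd.DataFrame(rows)


def write_proteomes(proteomes: dict[str, list[SeqRecord]], out_dir: str | Path) -> list[Path]:
    """Write one FASTA per genome (``>proteinID genome=GENOMEID`` headers)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for genome, records in proteomes.items():
        path = out_dir / f"{genome}.faa"
        SeqIO.write(records, str(path), "fasta")
        paths.append(path)
    return paths


def read_proteomes(fasta_paths: Sequence[str | Path]):
    """Read per-genome FASTA files back into (sequences, protein→genome)."""
    seqs: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq)
            for token in rec.description.split():
                if token.startswith("genome="):
                    genome_of[rec.id] = token.split("=", 1)[1]
    return seqs, genome_of


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> None:
    """Dump the truth tables (TSV) and the generating tree (newick)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.Series(truth.planted_family_of_protein, name="family_id").rename_axis(
        "protein_id").to_csv(out_dir / "true_family_of_protein.tsv", sep="\t")
    pd.Series(truth.planted_module_of_family, name="module").rename_axis(
        "family_id").to_csv(out_dir / "true_module_of_family.tsv", sep="\t")
    pd.Series(truth.true_label_of_protein, name="label").rename_axis(
        "protein_id").to_csv(out_dir / "true_label_of_protein.tsv", sep="\t")
    (out_dir / "generating_tree.nwk").write_text(truth.generating_tree + "\n")
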