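"""End-to-end orchestration with a single declarative config.

``run_pipeline`` executes similarity search → subfamilies → families →
presence/absence matrix → modules → taxonomy → annotation metrics → genome
clustering, writing every intermediate as TSV/newick into a run directory
together with a manifest (config hash, input checksums, versions, stage
timings).  Inputs are either simulated (``config.synthetic`` set) or read
from files named in the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotation as annot
from . import families as fam
from . import genomes as gen
from . import pamatrix as pam
from . import similarity as sim
from . import simulate as synth

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults are the published values."""

    evalue_max: float = 0.001           # external-hit e-value ceiling
    cover_min: float = 0.5              # bidirectional coverage floor
    coverage_mode: str = "bidirectional"
    kmer_k: int = 4                     # built-in scorer window
    builtin_evalue_max: float = 0.8     # e-value proxy ceiling for k-mer hits
    subfamily_probability_min: float = 95.0
    subfamily_coverage_min: float = 0.5
    mcl_inflation: float = 2.0
    min_genomes: int = 5
    module_cutoff: float = 0.95
    min_module_size: int = 20
    family_linkage: str = "complete"
    genome_linkage: str = "complete"
    sp_fraction: float = 0.25
    tm_fraction: float = 0.5
    bacterial_min_genomes: int = 10
    scg_min_nondpann: int = 26
    scg_min_dpann: int = 22
    scg_max_duplicated: int = 4
    seed: int = 0
    synthetic: synth.SyntheticConfig | None = None
    # file-input mode (used when synthetic is None)
    fasta_paths: tuple[str, ...] = ()
    hit_table: str | None = None
    taxonomy_table: str | None = None
    annotation_table: str | None = None
    reference_tree: str | None = None

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.evalue_max, "evalue_max"),
            (0 <= self.cover_min <= 1, "cover_min"),
            (self.mcl_inflation > 1, "mcl_inflation"),
            (self.min_genomes >= 1, "min_genomes"),
            (0 <= self.module_cutoff <= 1, "module_cutoff"),
            (self.min_module_size >= 1, "min_module_size"),
            (0 <= self.sp_fraction <= 1, "sp_fraction"),
            (0 <= self.tm_fraction <= 1, "tm_fraction"),
            (self.bacterial_min_genomes >= 1, "bacterial_min_genomes"),
            (self.family_linkage in pam.LINKAGES, "family_linkage"),
            (self.genome_linkage in pam.LINKAGES, "genome_linkage"),
            (0 <= self.subfamily_probability_min <= 100, "subfamily_probability_min"),
            (0 <= self.subfamily_coverage_min <= 1, "subfamily_coverage_min"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"{name} outside its documented domain")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
            d["synthetic"]["module_sizes"] = list(self.synthetic.module_sizes)
        d["fasta_paths"] = list(self.fasta_paths)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        if d.get("synthetic") is not None:
            d["synthetic"] = synth.SyntheticConfig(**d["synthetic"])
        d["fasta_paths"] = tuple(d.get("fasta_paths", ()))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage; returns the run directory.

    Any stage failure is re-raised with the stage name prefixed, so the
    offending step is always identifiable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        t0 = time.perf_counter()
        truth = None
        reference_tree = None
        if config.synthetic is not None:
            stage = "simulate"
            scfg = dataclasses.replace(config.synthetic, seed=config.seed)
            matrix_true, taxonomy, truth = synth.simulate_presence_absence(scfg)
            proteomes = synth.simulate_proteomes(scfg, matrix_true, truth)
            annotations = synth.simulate_annotations(truth, scfg)
            bact = synth.simulate_bacterial_hits(truth, scfg)
            synth.write_proteomes(proteomes, out / "proteomes")
            synth.write_truth(truth, out / "truth")
            sequences = {r.id: str(r.seq) for recs in proteomes.values()
                         for r in recs}
            genome_of = dict(truth.genome_of_protein)
            reference_tree = truth.generating_tree
            stage = "similarity"
            hits = sim.all_vs_all_kmer_hits(
                sequences, k=config.kmer_k,
                min_bitscore=1.0 - config.builtin_evalue_max)
            evalue_max = config.builtin_evalue_max
            ssn_mode = "builtin"
        else:
            stage = "load"
            if not config.fasta_paths or config.taxonomy_table is None:
                raise ValueError("file mode needs fasta_paths and taxonomy_table")
            sequences, genome_of = synth.read_proteomes(config.fasta_paths)
            taxonomy = pd.read_csv(config.taxonomy_table, sep="\t")
            annotations = (pd.read_csv(config.annotation_table, sep="\t",
                                       index_col="protein_id")
                           if config.annotation_table else None)
            bact = pd.DataFrame(columns=["family_id", "bacterial_genome"])
            if config.reference_tree:
                reference_tree = Path(config.reference_tree).read_text()
            stage = "similarity"
            if config.hit_table:
                lengths = {p: len(s) for p, s in sequences.items()}
                hits = sim.read_hit_table(config.hit_table, lengths=lengths)
                evalue_max = config.evalue_max
                ssn_mode = "table"
            else:
                hits = sim.all_vs_all_kmer_hits(
                    sequences, k=config.kmer_k,
                    min_bitscore=1.0 - config.builtin_evalue_max)
                evalue_max = config.builtin_evalue_max
                ssn_mode = "builtin"
        annotations = annotations.fillna("") if annotations is not None else None
        ssn = sim.build_ssn(hits, genome_of, evalue_max=evalue_max,
                            cover_min=config.cover_min)
        sim.write_ssn(ssn, out / "ssn_edges.tsv")
        timings["similarity"] = time.perf_counter() - t0

        stage = "subfamilies"
        t0 = time.perf_counter()
        subfams = fam.greedy_set_cover(ssn)
        edges = fam.subfamily_similarity(subfams, ssn, mode="builtin")
        pd.DataFrame(
            [{"query": e.subfamily_a, "target": e.subfamily_b,
              "probability": e.probability, "coverage": e.coverage,
              "weight": e.weight} for e in edges],
            columns=["query", "target", "probability", "coverage", "weight"],
        ).to_csv(out / "subfamily_edges.tsv", sep="\t", index=False)
        timings["subfamilies"] = time.perf_counter() - t0

        stage = "families"
        t0 = time.perf_counter()
        families = fam.build_families(subfams, edges, genome_of,
                                      min_genomes=config.min_genomes,
                                      inflation=config.mcl_inflation)
        fam.write_memberships(subfams, families, genome_of,
                              out / "memberships.tsv")
        timings["families"] = time.perf_counter() - t0

        stage = "matrix"
        t0 = time.perf_counter()
        genome_ids = list(taxonomy["genome_id"])
        matrix = pam.build_matrix(families, genome_ids, wide_only=True)
        pam.write_matrix(matrix, out / "matrix.tsv")
        timings["matrix"] = time.perf_counter() - t0

        stage = "modules"
        t0 = time.perf_counter()
        phylum_of = dict(zip(taxonomy["genome_id"], taxonomy["phylum"]))
        modules: list[pam.Module] = []
        unassigned: list[str] = []
        if matrix.shape[1] >= 2:
            dend = pam.family_dendrogram(matrix, linkage=config.family_linkage)
            modules, unassigned = pam.cut_modules(
                dend, cutoff=config.module_cutoff,
                min_module_size=config.min_module_size)
            for mod in modules:
                pam.assign_module_taxonomy(mod, matrix, phylum_of)
        pam.write_module_report(modules, unassigned, out)
        timings["modules"] = time.perf_counter() - t0

        stage = "metrics"
        t0 = time.perf_counter()
        if annotations is not None:
            bact_map = {f: set(g["bacterial_genome"])
                        for f, g in bact.groupby("family_id")}
            classification = annot.classify_families(families, annotations,
                                                     bact_map)
            classification.to_csv(out / "family_classification.tsv", sep="\t")
            consistency = annot.annotation_consistency(families, annotations)
            consistency.to_csv(out / "annotation_consistency.tsv", sep="\t")
        timings["metrics"] = time.perf_counter() - t0

        stage = "genomes"
        t0 = time.perf_counter()
        report = {}
        if matrix.shape[0] >= 2 and matrix.shape[1] >= 1:
            gdend = gen.cluster_genomes(matrix, linkage=config.genome_linkage)
            (out / "genome_dendrogram.nwk").write_text(gdend.to_newick() + "\n")
            if reference_tree:
                for linkage in pam.LINKAGES:
                    d = gen.cluster_genomes(matrix, linkage=linkage)
                    report[f"cophenetic_correlation_{linkage}"] = \
                        gen.cophenetic_correlation(d, reference_tree)
        timings["genomes"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "input_checksums": {p: _sha256(Path(p)) for p in config.fasta_paths},
        "n_proteins": len(genome_of),
        "n_subfamilies": len(subfams),
        "n_families": len(families),
        "n_wide_families": int(matrix.shape[1]),
        "n_modules": len(modules),
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        **{k: round(v, 4) for k, v in report.items()},
    }
    (out / "config.yaml").write_text(config.to_yaml())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
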