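"""Detect modules of co-occurring families and assign their taxonomy.

Clusters family presence/absence profiles (Jaccard distance, complete
linkage), cuts the dendrogram at 0.95, keeps clusters of >=20 families as
modules, and assigns each module the phylum distribution of the m genomes
richest in its families (m = median genomes per family).
"""

import archfam as af

cfg = af.SyntheticConfig(core_family_count=1, within_lineage_prevalence=0.9,
                         background_rate=0.01, seed=7)
matrix, taxonomy, truth = af.simulate_presence_absence(cfg)

dend = af.family_dendrogram(matrix, linkage="complete")
modules, unassigned = af.cut_modules(dend, cutoff=0.95, min_module_size=20)
print(f"{len(modules)} modules detected, {len(unassigned)} families unassigned")

phylum_of = dict(zip(taxonomy.genome_id, taxonomy.phylum))
for mod in modules:
    af.assign_module_taxonomy(mod, matrix, phylum_of)
    dist = ";".join(f"{p}:{c}" for p, c in sorted(mod.taxonomy_distribution.items()))
    print(f"{mod.module_id}: {mod.n_families} families, m={mod.m}, taxonomy {dist}")

# each detected module should be dominated by one planted lineage
print("(each module's taxonomy should concentrate on a single lineage)")
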