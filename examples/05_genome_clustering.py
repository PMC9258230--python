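"""Cluster genomes by family content and compare to the generating tree.

Genomes sharing a lineage share its module families, so family-content
clustering should recover the lineage structure; the cophenetic correlation
against the generating phylogeny quantifies the agreement (1.0 = identical
pairwise structure, ~0 = unrelated).
"""

import archfam as af

cfg = af.SyntheticConfig(within_lineage_prevalence=0.8, background_rate=0.02,
                         seed=2)
matrix, taxonomy, truth = af.simulate_presence_absence(cfg)

for linkage in ("complete", "average", "single"):
    dend = af.cluster_genomes(matrix, linkage=linkage)
    corr = af.cophenetic_correlation(dend, truth.generating_tree)
    print(f"cophenetic correlation ({linkage:>8} linkage): {corr:.3f}")

print("\nGenome quality rules (38 single-copy genes):")
profile = af.ScgProfile("example", [1] * 27 + [0] * 11)
q = af.scg_quality(profile, is_dpann=False)
print(f"  27 SCGs, 0 duplicated, non-DPANN: pass={q.passed} "
      f"({q.completeness:.0f}% complete, {q.contamination:.0f}% contaminated)")
q = af.scg_quality(af.ScgProfile("dpann", [1] * 23 + [0] * 15), is_dpann=True)
print(f"  23 SCGs, 0 duplicated, DPANN:     pass={q.passed}")
rep = af.select_representative([("gA", 98, 2), ("gB", 95, 1), ("gC", 98, 3)])
print(f"  representative of ANI cluster [gA(98,2), gB(95,1), gC(98,3)]: {rep}")
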