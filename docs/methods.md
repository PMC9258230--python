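# Methods

## The analysis in brief

`archfam` turns a collection of proteomes into (i) protein families, (ii)
a genome × family presence/absence matrix, (iii) modules of co-occurring
families with a taxonomic assignment, and (iv) a family-content genome
clustering compared against a reference phylogeny. The defaults encode the
published parameterization of this workflow: e-value 0.001 and coverage
0.5 for the similarity network, profile probability ≥ 95% and coverage
≥ 0.50 with weight = probability × coverage for subfamily merging, MCL
inflation 2.0, the ≥ 5-genome wide-family filter, the 0.95 Jaccard cut and
≥ 20-family module rule, the median-m taxonomy rule, the 25% / 50% / 10
classification thresholds, and the 38-SCG quality scheme (> 26 or > 22
present, < 4 duplicated).

## Family construction

**Sequence similarity network.** Nodes are proteins (annotated with their
genome); edges are filtered all-vs-all hits. The production path is an
external search tool's tabular output (configurable outfmt6-like column
map). Coverage is read as min(query coverage, target coverage) — a
conservative, symmetric "bidirectional" interpretation, exposed as
`coverage_mode`; when coverage columns are absent it is recomputed as
alignment length over the shorter sequence, and hits with neither are
rejected with a warning (fail-closed). Reciprocal hits collapse to one
undirected edge keeping the maximum bitscore.

**Built-in k-mer scorer.** For self-contained runs a deliberately simple
stand-in replaces the external search: bitscore = shared k-mers over the
k-mer count of the shorter sequence (k = 4), coverage = fraction of the
shorter sequence's positions covered by shared k-mer occurrences, e-value
proxy = 1 − bitscore. For equal-length sequences coverage is evaluated on
the sequence with fewer distinct k-mers, taking the maximum of the two on
ties, which keeps the score symmetric. Because the proxy e-value of a
genuine homolog at 5% per-site divergence is ≈ 0.35 (expected shared
4-mer fraction ≈ 0.9⁴), the literature threshold e ≤ 0.001 — meant for
real e-values — would reject true homologs; builtin-scored hits therefore
use their own ceiling `builtin_evalue_max` (default 0.8, i.e. bitscore
≥ 0.2), while external tables keep 0.001. Unrelated random sequences share
≈ 0.1–0.3% of 4-mers, so the two regimes are separated by two orders of
magnitude. This scorer is not a homology search; it is adequate only for
the generator's indel-free substitution model.

**Greedy set cover.** Subfamilies are built by repeatedly selecting the
node whose closed neighborhood contains the most uncovered proteins; the
uncovered part of that neighborhood becomes a subfamily with the selected
node as representative. Ties break to the lexicographically smallest id.
Implemented as lazy greedy (max-heap with stale-entry refresh), valid
because gains only shrink. In the rare case where the selected node was
already covered in an earlier round, the lexicographically smallest member
stands in as representative so that subfamilies remain a strict partition
with representative ∈ members.

**Subfamily comparison.** Production mode ingests a profile–profile
comparison table (probability on the 0–100 scale, as HMM–HMM tools report,
so that weight = probability × coverage lands in [0, 100]). The built-in
proxy scores a subfamily pair by its best cross-pair SSN edge (probability
= 100 × bitscore, coverage of that pair) and only compares subfamilies
with ≥ 2 members, mirroring the fact that single sequences get no profile.
Singleton subfamilies and subfamilies without passing edges become
singleton families.

**Markov Clustering.** Authored here (no suitable installed
implementation): per connected component, the weighted adjacency matrix
gets self-loops equal to each node's maximum incident edge weight (a
standard regularization that also keeps singletons stable), is
column-normalized, and then alternates expansion (matrix squaring) with
inflation (entrywise power 2.0, column renormalization), pruning entries
below 1e-6, until the iterate changes by < 1e-8 (max 200 iterations, error
on non-convergence). Clusters are read from the limit matrix's attractor
structure; nodes attracted to several systems go to the cluster receiving
the largest flow, ties to the lowest cluster id. Tests cross-check against
an independently written naive dense implementation and against
analytically known partitions (disjoint cliques, weakly bridged cliques).

## Matrix, modules, taxonomy

The presence/absence matrix is boolean with stable input ordering; by
default only wide families (≥ 5 genomes) become columns. Families are
clustered on the Jaccard distance between genome profiles under complete
linkage (scipy; average/single are config options), and the dendrogram is
flat-cut at height 0.95 — every cluster's internal merge heights ≤ 0.95.
Clusters of ≥ 20 families are modules; smaller clusters are reported as
unassigned rather than discarded.

Module taxonomy follows the median-m rule: m = median of per-family genome
counts, rounded half-up to an integer (m is a genome count; half-up is the
deterministic choice for even module sizes); genomes are ranked by the
number of module families they carry (descending, ties by genome id), the
top m are retained, and their phylum counts are the module's distribution.
An `include_ties` flag optionally retains genomes tied with the m-th rank
(default off: deterministic truncation).

## Genome-level analyses

Genome rows are clustered on Jaccard distance; a genome with an all-false
row is an error (its distance is undefined). Dendrograms serialize to
newick with branch lengths equal to merge-height differences. The
cophenetic correlation between two trees is the Pearson correlation
(Spearman optional) of pairwise distances over shared leaves — merge
heights for dendrograms, patristic distances for newick references; a
reference without branch lengths gets unit lengths with a warning.
Completeness and contamination percentages use the 38-SCG denominator
(26/38 ≈ 70%, 4/38 ≈ 10%). Representative selection sorts by completeness
descending, contamination ascending, genome id — the stated priority
order; no weighted trade-off is published, so the lexicographic rule is
the default and a weighted score is left to config.

## The synthetic generator

The generator emulates exactly the structure the analysis assumes: a star
phylogeny of lineages (rake subtrees, unit branch lengths), one planted
module per lineage, a shared core block, Bernoulli presence draws (core
prevalence 0.95, within-lineage prevalence 0.9, background 0.01 by
default — within the 0.65–1.0 range reported for real lineage modules),
uniform-composition ancestor sequences of 200 residues, independent
per-site substitutions (rate 0.05) to a uniformly chosen different
residue, and family-true labels with admixture noise (label rate 0.7,
admixture 0.05 — chosen so that most families are label-pure, as observed
for real families). Every protein belongs to exactly one planted family
and every family to exactly one module ("core" or its lineage).

Randomness is one seed plus sub-streams derived by SHA-256 hashing of
(stage, entity id), so adding genomes or families never reshuffles earlier
draws and fixed seeds give bit-identical outputs.

What the generator does *not* emulate: indels, domain shuffling, rate
heterogeneity, horizontal transfer, paralogy (exactly one protein per
family per genome), realistic amino-acid composition, or genuine DPANN
reduced genomes (all synthetic lineages are labelled non-DPANN; the DPANN
quality thresholds are exercised on constructed SCG profiles). A green
recovery test therefore establishes that the pipeline's logic is correct
on data satisfying its own model assumptions — not that the built-in
scorer would resolve real remote homology.

## Numerical and policy choices

- Pairwise identity of two family members under the substitution model is
  (1−r)² + r²/19 per site — the closed form used in tests.
- Merge ties in agglomeration follow scipy's deterministic ordering;
  module ids order by descending family count, then first family id;
  family ids by descending protein count, then lexicographic
  representative.
- Admixture with a tied dominant label uses the maximal count (the value
  is the same whichever tied label is named); a family with no annotated
  member has undefined (None/NaN) admixture.
- DUF recognition: PFAM domain names matching `DUF\d*` (case-insensitive).
- Transmembrane membership counts members with ≥ 1 predicted helix; the
  published threshold is at the family level, not the helix count.
- The signal-peptide fraction is computed over all members (the
  alternative — only members with usable coordinates — is not
  distinguishable in the consumed table format).
- The module cut at 1.0 with min size 1 returns one module per connected
  dendrogram; at 0 it separates everything except exactly identical
  profiles (height-0 merges).

## Known limitations

- **Core/module separability at desk scale.** With few lineages (e.g. 5 ×
  10 genomes) a 40-family core block lies at Jaccard distance ≈ 0.82 from
  lineage-module families (intersection ≈ one lineage's genomes, union ≈
  all genomes), below the 0.95 cut, so complete linkage merges the core
  with exactly one lineage module. This is a scale effect — with hundreds
  of genomes across many lineages the complete-linkage (max-pair) distance
  between the blocks exceeds the cut — and it is pinned by a dedicated
  test. Module-recovery validation therefore runs on worlds with a minimal
  core; real-scale matrices are unaffected.
- The built-in subfamily-comparison proxy requires near-identical
  cross-subfamily sequences (bitscore ≥ 0.95) to merge subfamilies, so at
  desk scale families usually equal subfamilies; remote-homology merging
  is exercised through the table mode.
- MCL is dense per connected component: fine for subfamily graphs up to a
  few thousand nodes per component, not engineered for millions.
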