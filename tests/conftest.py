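import pandas as pd
import pytest

import archfam as af


@pytest.fixture(scope="session")
def small_world():
    """A small noisy pangenome (3 lineages x 4 genomes) with full ground truth."""
    cfg = af.SyntheticConfig(
        n_lineages=3, genomes_per_lineage=4, core_family_count=8,
        module_sizes=[6, 6, 6], within_lineage_prevalence=0.9,
        core_prevalence=0.95, background_rate=0.02, seq_length=120,
        substitution_rate=0.05, seed=11)
    matrix, taxonomy, truth = af.simulate_presence_absence(cfg)
    proteomes = af.simulate_proteomes(cfg, matrix, truth)
    return cfg, matrix, taxonomy, truth, proteomes


@pytest.fixture()
def toy_annotations():
    """Four proteins: three labelled A (famA), one labelled B (famB)."""
    return pd.DataFrame({
        "protein_id": ["p1", "p2", "p3", "p4"],
        "kegg": ["A", "A", "B", "A"],
        "pfam": ["", "", "", ""],
        "has_signal_peptide": [False, True, False, False],
        "tm_helix_count": [0, 2, 0, 1],
        "length": [100, 110, 90, 120],
    }).set_index("protein_id")
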