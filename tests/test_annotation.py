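"""Annotation consistency, admixture, family classification, neighborhoods."""

import numpy as np
import pandas as pd
import pytest

import archfam as af


class TestConsistency:
    def test_three_of_four(self):
        # label K1 on p1..p4; p1-p3 in famA, p4 in famB -> best fraction 0.75
        ann = pd.DataFrame({"kegg": ["K1"] * 4},
                           index=["p1", "p2", "p3", "p4"])
        fams = {"famA": ["p1", "p2", "p3"], "famB": ["p4"]}
        best = af.annotation_consistency(fams, ann)
        assert best["K1"] == pytest.approx(0.75)

    def test_singleton_label(self, toy_annotations):
        best = af.annotation_consistency({"famA": ["p1", "p2", "p3", "p4"]},
                                         toy_annotations)
        assert best["B"] == 1.0

    def test_counts_conserved(self, toy_annotations):
        best = af.annotation_consistency({"f1": ["p1"], "f2": ["p2", "p3", "p4"]},
                                         toy_annotations)
        assert ((best > 0) & (best <= 1)).all()

    def test_no_annotations_rejected(self):
        ann = pd.DataFrame({"kegg": [""]}, index=["p1"])
        with pytest.raises(ValueError):
            af.annotation_consistency({"f": ["p1"]}, ann)


class TestAdmixture:
    def test_two_to_one(self, toy_annotations):
        # members p1,p2 (A) + p3 (B): dominant A, admixture 33.33%
        val = af.family_admixture(["p1", "p2", "p3"], toy_annotations)
        assert val == pytest.approx(100 / 3)

    def test_pure_family_zero(self, toy_annotations):
        assert af.family_admixture(["p1", "p2"], toy_annotations) == 0.0

    def test_tie_symmetry(self):
        ann = pd.DataFrame({"kegg": ["A", "A", "B", "B"]},
                           index=["p1", "p2", "p3", "p4"])
        assert af.family_admixture(list(ann.index), ann) == pytest.approx(50.0)

    def test_undefined_without_labels(self):
        ann = pd.DataFrame({"kegg": ["", ""]}, index=["p1", "p2"])
        assert af.family_admixture(["p1", "p2"], ann) is None

    def test_range_and_zero_iff_pure(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            labels = rng.choice(["A", "B", "C"], size=8)
            ann = pd.DataFrame({"kegg": labels},
                               index=[f"p{i}" for i in range(8)])
            val = af.family_admixture(list(ann.index), ann)
            assert 0.0 <= val <= 100.0
            assert (val == 0.0) == (len(set(labels)) == 1)


def _annotation_frame(n, sp, tm, kegg=None, pfam=None):
    return pd.DataFrame({
        "kegg": kegg if kegg is not None else [""] * n,
        "pfam": pfam if pfam is not None else [""] * n,
        "has_signal_peptide": sp,
        "tm_helix_count": tm,
        "length": [100] * n,
    }, index=[f"p{i}" for i in range(n)])


class TestClassification:
    def test_signal_peptide_threshold_inclusive(self):
        ann = _annotation_frame(10, [True] * 3 + [False] * 7, [0] * 10)
        c = af.classify_family("f", list(ann.index), ann)
        assert c.signal_peptide_fraction == pytest.approx(0.30)
        assert c.is_sp_family
        ann4 = _annotation_frame(4, [True] + [False] * 3, [0] * 4)
        assert af.classify_family("f", list(ann4.index), ann4).is_sp_family  # 0.25

    def test_tm_threshold_strict(self):
        ann = _annotation_frame(10, [False] * 10, [1] * 5 + [0] * 5)
        c = af.classify_family("f", list(ann.index), ann)
        assert c.tm_fraction == pytest.approx(0.50)
        assert not c.is_tm_family  # "more than half" is strict
        ann6 = _annotation_frame(10, [False] * 10, [2] * 6 + [0] * 4)
        assert af.classify_family("f", list(ann6.index), ann6).is_tm_family

    def test_duf_only_family_is_hypothetical(self):
        ann = _annotation_frame(3, [False] * 3, [0] * 3,
                                pfam=["DUF1234", "DUF1234;DUF99", ""])
        assert af.classify_family("f", list(ann.index), ann).is_hypothetical
        ann2 = _annotation_frame(3, [False] * 3, [0] * 3,
                                 pfam=["DUF1234", "PF00001", ""])
        assert not af.classify_family("f", list(ann2.index), ann2).is_hypothetical
        ann3 = _annotation_frame(2, [False] * 2, [0] * 2, kegg=["K00001", ""])
        assert not af.classify_family("f", list(ann3.index), ann3).is_hypothetical

    def test_bacterial_homolog_threshold_inclusive(self):
        ann = _annotation_frame(2, [False] * 2, [0] * 2)
        hits10 = {"f": [f"b{i}" for i in range(10)]}
        hits9 = {"f": [f"b{i}" for i in range(9)]}
        assert af.classify_family("f", list(ann.index), ann, hits10
                                  ).has_bacterial_homologs
        assert not af.classify_family("f", list(ann.index), ann, hits9
                                      ).has_bacterial_homologs

    def test_missing_member_rejected(self):
        ann = _annotation_frame(2, [False] * 2, [0] * 2)
        with pytest.raises(ValueError, match="pX"):
            af.classify_family("f", ["p0", "pX"], ann)

    def test_median_length(self):
        ann = _annotation_frame(3, [False] * 3, [0] * 3)
        ann["length"] = [80, 100, 300]
        assert af.classify_family("f", list(ann.index), ann).median_length == 100


class TestNeighborhoods:
    def _table(self, fams, genome="g1", scaffold="s1"):
        return pd.DataFrame({
            "genome": [genome] * len(fams),
            "scaffold": [scaffold] * len(fams),
            "position": range(len(fams)),
            "strand": ["+"] * len(fams),
            "protein_id": [f"{scaffold}_p{i}" for i in range(len(fams))],
            "family_id": fams,
        })

    def test_window_one(self):
        occ, freq = af.neighborhood_summary(self._table(["f1", "f2", "f3"]),
                                            "f2", window=1)
        assert set(occ["neighbor_family"]) == {"f1", "f3"}
        assert freq["f1"] == 1.0 and freq["f3"] == 1.0

    def test_truncation_at_scaffold_edge(self):
        occ, _ = af.neighborhood_summary(
            self._table(["q", "a", "b", "c", "d", "e", "f"]), "q", window=4)
        assert len(occ) == 4  # nothing upstream, four downstream
        assert (occ["offset"] > 0).all()

    def test_perfect_colocalization(self):
        tables = [self._table(["fX", "fY", "fZ"], genome=f"g{i}",
                              scaffold=f"g{i}_s") for i in range(5)]
        table = pd.concat(tables, ignore_index=True)
        _, freq = af.neighborhood_summary(table, "fX", window=1)
        assert freq["fY"] == 1.0
        assert "fZ" not in freq.index

    def test_duplicate_position_rejected(self):
        t = self._table(["f1", "f2"])
        t.loc[1, "position"] = 0
        with pytest.raises(ValueError, match="duplicate"):
            af.neighborhood_summary(t, "f1", window=1)


class TestGeneratorMetrics:
    def test_noise_free_label_recovery(self):
        """With no admixture every label concentrates fully in one planted family."""
        cfg = af.SyntheticConfig(n_lineages=2, genomes_per_lineage=5,
                                 core_family_count=10, module_sizes=[5, 5],
                                 admixture_rate=0.0, kegg_label_rate=1.0, seed=3)
        m, _, truth = af.simulate_presence_absence(cfg)
        af.simulate_proteomes(cfg, m, truth)
        ann = af.simulate_annotations(truth, cfg)
        fams: dict[str, list[str]] = {}
        for p, f in truth.planted_family_of_protein.items():
            fams.setdefault(f, []).append(p)
        best = af.annotation_consistency(fams, ann)
        assert (best == 1.0).all()
        for members in fams.values():
            assert af.family_admixture(members, ann) == 0.0

    def test_realized_admixture_within_binomial_se(self):
        """Configured 20% admixture is realized within 3 binomial SE."""
        rate = 0.2
        truth = af.SyntheticTruth(
            planted_family_of_protein={f"p{i:03d}": ("famA" if i < 100 else "famB")
                                       for i in range(200)},
            true_label_of_family={"famA": "KA", "famB": "KB"},
        )
        truth.true_label_of_protein = {
            p: truth.true_label_of_family[f]
            for p, f in truth.planted_family_of_protein.items()}
        cfg = af.SyntheticConfig(kegg_label_rate=1.0, admixture_rate=rate, seed=1)
        ann = af.simulate_annotations(truth, cfg)
        members = [f"p{i:03d}" for i in range(100)]
        realized = af.family_admixture(members, ann)
        se = 100 * np.sqrt(rate * (1 - rate) / 100)
        assert abs(realized - 100 * rate) <= 3 * se
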