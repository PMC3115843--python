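"""Genome-scan operations, checked against hand counts, brute-force oracles
and planted synthetic truth."""

import itertools

import numpy as np
import pytest

from chlorotype import scan as gs
from chlorotype.alignment import GeneInterval, MultiAlignment
from chlorotype.olive_data import INFORMATIVE_SITE_MATRIX


def brute_force_column_classes(aln):
    """Independent column-by-column classifier (oracle for small inputs)."""
    out = {"invariant": 0, "substitution": 0, "gap_involved": 0}
    for i in range(aln.ncols):
        col = [r[i] for r in aln.rows]
        if "-" in col:
            out["gap_involved"] += 1
        elif len({c for c in col if c in "ACGT"}) >= 2:
            out["substitution"] += 1
        else:
            out["invariant"] += 1
    return out


class TestSubstitutions:
    def test_identical_rows_yield_nothing(self):
        aln = MultiAlignment(["a", "b"], ["ACGT", "ACGT"])
        assert gs.scan_substitutions(aln) == []

    def test_hand_counted_toy(self, toy_alignment):
        # mismatches at columns 3 and 8 (1-based), gap excludes column 6
        records = gs.scan_substitutions(toy_alignment)
        assert [r.ref_position for r in records] == [3, 8]
        assert all(r.type == "substitution" for r in records)

    def test_gap_columns_excluded(self):
        aln = MultiAlignment(["a", "b"], ["A-GT", "ATGT"])
        assert gs.scan_substitutions(aln) == []

    def test_informative_site_matrix_all_informative(self):
        aln = MultiAlignment(list(INFORMATIVE_SITE_MATRIX),
                             list(INFORMATIVE_SITE_MATRIX.values()))
        records = gs.scan_substitutions(aln)
        assert len(records) == 9
        assert all(r.informative for r in records)

    def test_oracle_equivalence_random_alignments(self, rng):
        """Column accounting matches a brute-force classifier and sums to
        the alignment length (<=6 taxa x <=50 columns)."""
        for _ in range(25):
            ntaxa = int(rng.integers(2, 7))
            ncols = int(rng.integers(5, 51))
            rows = [
                "".join(rng.choice(list("ACGT-"), size=ncols, p=[.22, .22, .22, .22, .12]))
                for _ in range(ntaxa)
            ]
            rows[0] = rows[0].replace("-", "A")  # keep a gap-free reference
            aln = MultiAlignment([f"t{i}" for i in range(ntaxa)], rows)
            classes = gs.classify_columns(aln)
            assert classes == brute_force_column_classes(aln)
            assert sum(classes.values()) == aln.ncols
            assert len(gs.scan_substitutions(aln)) == classes["substitution"]


class TestInformative:
    def test_singleton_not_informative(self):
        assert not gs.is_informative(["C", "C", "C", "T"])

    def test_five_three_split_informative(self):
        assert gs.is_informative(list("CCCCCTTT"))

    def test_exhaustive_against_brute_force(self):
        """All 3^4 state vectors on 4 taxa vs a direct counting oracle."""
        for states in itertools.product("ACT", repeat=4):
            counts = {s: states.count(s) for s in set(states)}
            expected = sum(1 for c in counts.values() if c >= 2) >= 2
            assert gs.is_informative(list(states)) == expected


class TestIndels:
    def test_single_gap_run(self):
        aln = MultiAlignment(["a", "b"], ["ACGTACGT", "AC---CGT"])
        events = gs.scan_indels(aln)
        assert len(events) == 1
        assert events[0].length == 3
        assert events[0].states == {"a": 1, "b": 0}

    def test_adjacent_runs_with_different_patterns_split(self):
        aln = MultiAlignment(
            ["a", "b", "c"],
            ["ACGTACGT", "AC--ACGT", "ACG--CGT"],
        )
        events = gs.scan_indels(aln)
        assert len(events) == 3  # b-only, shared column, c-only patterns

    def test_planted_long_deletion_recovered(self, simulated):
        truth_long = [
            e for e in simulated["truth"].of_type("indel")
            if e.detail["class"] == "long_deletion"
        ]
        events = gs.scan_indels(simulated["aln"])
        found = {(e.ref_position, e.length) for e in events}
        for ev in truth_long:
            assert (ev.ref_position, ev.detail["length"]) in found

    def test_classification_rules(self):
        # 1-bp gap inside a (T)12 tract -> ssr_motif
        ssr = gs.SsrAnnotation(motif="T", ref_start=3, ref_repeat_count=12)
        ev = gs.VariantRecord(ref_position=14, type="indel",
                              states={"a": 1, "b": 0}, length=1)
        assert gs.classify_indel(ev, [ssr]) == gs.SSR_MOTIF
        # 225-bp event -> long
        ev225 = gs.VariantRecord(ref_position=50, type="indel",
                                 states={"a": 1, "b": 0}, length=225)
        assert gs.classify_indel(ev225, []) == gs.LONG
        # 9-bp block duplicating the 9 bp immediately upstream
        up = "GATCCATAG"
        aln = MultiAlignment(
            ["a", "b"],
            ["AAAA" + up + up + "TTTT", "AAAA" + up + "-" * 9 + "TTTT"],
            reference="a",
        )
        ev9 = gs.scan_indels(aln)[0]
        assert ev9.length == 9
        assert gs.classify_indel(ev9, [], aln) == gs.REPEATED_MOTIF
        # same length without the duplication -> other_short
        aln2 = MultiAlignment(
            ["a", "b"],
            ["AAAA" + up + "CGTCGGTAC" + "TTTT", "AAAA" + up + "-" * 9 + "TTTT"],
            reference="a",
        )
        ev = gs.scan_indels(aln2)[0]
        assert gs.classify_indel(ev, [], aln2) == gs.OTHER_SHORT


class TestSsrDetection:
    def test_no_tract_below_threshold(self):
        assert gs.detect_ssr("ACGTACGTAAAACGT") == []

    def test_planted_mononucleotide(self):
        seq = "ACGCA" + "T" * 12 + "GACGA"
        (ann,) = gs.detect_ssr(seq)
        assert (ann.motif, ann.ref_start, ann.ref_repeat_count) == ("T", 6, 12)

    def test_dinucleotide_reported_with_primitive_canonical_motif(self):
        seq = "CCGGC" + "AT" * 6 + "GGCCG"
        (ann,) = gs.detect_ssr(seq)
        assert ann.motif == "AT"  # not TA, not A
        assert ann.ref_repeat_count == 6

    def test_per_taxon_counts_through_alignment(self, simulated):
        aln, spec = simulated["aln"], simulated["spec"]
        anns = {a.ref_start: a for a in gs.detect_ssr(aln)}
        steps = {e.ref_position: e for e in simulated["truth"].of_type("ssr_step")}
        for pos, motif, count in spec.ssr_loci:
            ann = anns[pos]
            rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
            assert ann.motif in rotations
            assert ann.repeat_counts["root"] == count
            if pos not in steps:
                assert set(ann.repeat_counts.values()) == {count}


class TestDivergence:
    def test_identical_pair_zero(self):
        aln = MultiAlignment(["a", "b"], ["ACGT", "ACGT"])
        mat = gs.pairwise_substitution_matrix(aln)
        assert mat.loc["a", "b"] == 0

    def test_hand_counted_proportion(self):
        seq = "A" * 100
        other = "C" + "A" * 50 + "C" + "A" * 48
        aln = MultiAlignment(["a", "b"], [seq, other])
        div = gs.pairwise_divergence(aln, "a", "b")
        assert div.substitutions == 2
        assert div.proportion == pytest.approx(0.02)

    def test_matrix_symmetric_zero_diagonal(self, simulated):
        mat = gs.pairwise_substitution_matrix(simulated["aln"])
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 0).all()

    def test_percent_divergence_published_values(self):
        assert gs.percent_divergence(0, 1000) == 0.00
        assert gs.percent_divergence(106, 155_531) == 0.07
        assert gs.percent_divergence(432, 155_531) == 0.28

    def test_percent_divergence_zero_length_rejected(self):
        with pytest.raises(ValueError):
            gs.percent_divergence(1, 0)


class TestSubstitutionRate:
    def test_published_bounds(self):
        low = gs.substitution_rate(417, 155_896, 22e6)
        high = gs.substitution_rate(432, 155_531, 14e6)
        assert gs.round_sig(low.rate, 2) == pytest.approx(1.2e-10)
        assert gs.round_sig(high.rate, 2) == pytest.approx(2.0e-10)

    def test_zero_substitutions(self):
        assert gs.substitution_rate(0, 1000, 1e6).rate == 0.0

    def test_monotonicity(self):
        base = gs.substitution_rate(100, 10_000, 1e6).rate
        assert gs.substitution_rate(101, 10_000, 1e6).rate > base
        assert gs.substitution_rate(100, 10_001, 1e6).rate < base
        assert gs.substitution_rate(100, 10_000, 1.1e6).rate < base

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            gs.substitution_rate(10, 0, 1e6)
        with pytest.raises(ValueError):
            gs.substitution_rate(10, 100, 0)


class TestCodingEffect:
    GENE = [GeneInterval(5, 13, "+", "toy")]
    #      1234 ATG TTA TAA 4567
    REF = "GGGG" + "ATGTTATAA" + "ACCA"

    def _record(self, pos, alt):
        ref_base = self.REF[pos - 1]
        return gs.VariantRecord(ref_position=pos, type="substitution",
                                states={"x": ref_base, "y": alt})

    def test_intergenic_is_non_coding(self):
        assert gs.coding_effect(self._record(2, "T"), self.GENE, self.REF) == "non-coding"

    def test_third_position_leucine_synonymous(self):
        # TTA -> TTG, both Leu
        assert gs.coding_effect(self._record(13, "G"), self.GENE, self.REF) == "synonymous"

    def test_first_position_change_non_synonymous(self):
        # TTA (Leu) -> GTA (Val)
        assert gs.coding_effect(self._record(11, "G"), self.GENE, self.REF) == "non-synonymous"

    def test_reverse_strand_gene(self):
        # gene on minus strand: reference GGG CAT TAA reads ATG ... on -
        ref = "TT" + "TTATAACAT"[::-1].translate(str.maketrans("ACGT", "TGCA"))[::-1] + "CC"
        gene = [GeneInterval(3, 11, "-", "rev")]
        rec = gs.VariantRecord(ref_position=7, type="substitution",
                               states={"x": ref[6], "y": "G" if ref[6] != "G" else "C"})
        assert gs.coding_effect(rec, gene, ref) in {"synonymous", "non-synonymous"}


class TestTruthRecovery:
    """On noiseless synthetic alignments every planted event is recovered."""

    def test_substitution_recall_and_precision(self, simulated):
        truth_pos = sorted(e.ref_position
                           for e in simulated["truth"].of_type("substitution"))
        found = sorted(r.ref_position
                       for r in gs.scan_substitutions(simulated["aln"]))
        assert found == truth_pos

    def test_indel_recall_with_correct_class(self, simulated):
        aln, truth = simulated["aln"], simulated["truth"]
        ssrs = gs.detect_ssr(aln)
        events = gs.scan_indels(aln)
        classified = {(e.ref_position, e.length): gs.classify_indel(e, ssrs, aln)
                      for e in events}
        expected_class = {"motif_duplication": gs.REPEATED_MOTIF,
                          "other_short": gs.OTHER_SHORT,
                          "long_deletion": gs.LONG}
        for ev in truth.of_type("indel"):
            key = (ev.ref_position, ev.detail["length"])
            assert key in classified, f"planted indel {key} not found"
            assert classified[key] == expected_class[ev.detail["class"]]

    def test_ssr_step_recall(self, simulated):
        aln, spec = simulated["aln"], simulated["spec"]
        anns = {a.ref_start: a for a in gs.detect_ssr(aln)}
        tree_leaves = set(simulated["tree"].leaf_labels)
        for ev in simulated["truth"].of_type("ssr_step"):
            ann = anns[ev.ref_position]
            counts = set(ann.repeat_counts[t] for t in tree_leaves) | {ann.repeat_counts["root"]}
            root_count = ev.detail["root_count"]
            assert counts == {root_count, root_count + ev.detail["delta"]}
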