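"""Mutation localization, coding-effect calls, copy-number calls, class assignment."""

import numpy as np
import pytest
from Bio.Seq import Seq

from reporterscreen.annotation import ReporterAnnotation
from reporterscreen.classify import (CopyNumberThresholds, TransgeneMutation,
                                     assign_class, call_copy_number,
                                     coding_effect, gc_content, locate_mutation)


class TestAnnotation:
    def test_reversed_span_rejected(self):
        with pytest.raises(ValueError):
            ReporterAnnotation((-10, -20), (1, 9), (10, 20), "ATGTGA" + "AAA",
                               tss_offset_to_atg=1)

    def test_cds_not_multiple_of_three(self):
        with pytest.raises(ValueError):
            ReporterAnnotation((-20, -1), (1, 4), (10, 20), "ATGT",
                               tss_offset_to_atg=1)

    def test_position_zero_in_span_rejected(self):
        with pytest.raises(ValueError):
            ReporterAnnotation((-20, 0), (1, 9), (10, 20), "ATGAAATGA",
                               tss_offset_to_atg=1)

    def test_synthetic_cds_translates_cleanly(self, annotation):
        protein = annotation.translate()
        assert len(protein) == 239
        assert protein.endswith("*")
        assert "*" not in protein[:-1]


class TestLocate:
    @pytest.mark.parametrize("position,region", [
        (-255, "promoter"), (-240, "promoter"), (-140, "promoter"),
        (-680, "promoter"), (-1, "promoter"),
        (34, "cds"), (348, "cds"), (750, "cds"),
        (751, "terminator"), (1000, "terminator"),
        (5, "none"), (1001, "none"), (-700, "none"),
    ])
    def test_region_membership(self, annotation, position, region):
        assert locate_mutation(position, annotation) == region

    def test_position_zero_undefined(self, annotation):
        with pytest.raises(ValueError):
            locate_mutation(0, annotation)


class TestCodingEffect:
    def _mini(self, cds):
        return ReporterAnnotation((-20, -1), (1, len(cds)), (len(cds) + 1, len(cds) + 30),
                                  cds, tss_offset_to_atg=1)

    def test_missense(self):
        ann = self._mini("ATGGAATGGTAA")  # M E W *
        # GAA -> AAA at the first base of codon 2: E -> K
        assert coding_effect(4, "G", "A", ann) == "nonsynonymous"

    def test_nonsense(self):
        ann = self._mini("ATGGAATGGTAA")
        # TGG -> TGA: W -> stop
        assert coding_effect(9, "G", "A", ann) == "nonsense"

    def test_synonymous(self):
        ann = self._mini("ATGCTGTGGTAA")
        # CTG -> CTA: L -> L
        assert coding_effect(6, "G", "A", ann) == "synonymous"

    def test_ref_mismatch_is_integrity_error(self):
        ann = self._mini("ATGGAATGGTAA")
        with pytest.raises(ValueError, match="does not match"):
            coding_effect(4, "C", "T", ann)

    def test_bundled_cds_site_348_transition_is_silent(self, annotation):
        assert coding_effect(348, "G", "A", annotation) == "synonymous"

    def test_against_full_translation_oracle(self, annotation, rng):
        # oracle: translate the whole mutated CDS with biopython and compare
        # proteins, independent of the codon-local logic under test
        cds = annotation.cds_sequence
        protein = str(Seq(cds).translate())
        transition = {"G": "A", "C": "T", "A": "G", "T": "C"}
        offsets = rng.choice(len(cds) - 3, 60, replace=False)
        for off in offsets:
            pos = annotation.cds_span[0] + int(off)
            ref = cds[off]
            alt = transition[ref]
            mutated = cds[:off] + alt + cds[off + 1:]
            mut_protein = str(Seq(mutated).translate())
            if "*" in mut_protein[:-1]:
                expected = "nonsense"
            elif mut_protein == protein:
                expected = "synonymous"
            else:
                expected = "nonsynonymous"
            assert coding_effect(pos, ref, alt, annotation) == expected


class TestCopyNumber:
    def test_single_copy_cluster(self):
        call = call_copy_number(500, 500)
        assert call.yfp_fraction == pytest.approx(0.5)
        assert call.copies == 1

    def test_duplication_cluster(self):
        call = call_copy_number(667, 333)
        assert call.yfp_fraction == pytest.approx(0.667)
        assert call.copies == 2

    def test_zero_reads(self):
        with pytest.raises(ValueError):
            call_copy_number(0, 0)

    def test_low_depth_flagged(self):
        call = call_copy_number(30, 30)
        assert call.copies == "indeterminate"
        assert call.qc_flag == "low_reads"

    def test_monotone_in_fraction(self):
        calls = [call_copy_number(y, 1000 - y).copies for y in range(400, 800, 10)]
        order = {1: 0, "indeterminate": 1, 2: 2}
        ranks = [order[c] for c in calls]
        assert ranks == sorted(ranks)

    def test_expected_fraction_increases_with_copies(self):
        fracs = [n / (n + 1) for n in range(1, 6)]
        assert fracs == sorted(fracs)

    def test_misclassification_rate_below_binomial_tail_bound(self, rng):
        # oracle: the binomial tail probability of crossing the decision
        # boundary bounds the simulated misclassification rate
        n_reads, n_rep = 1000, 10_000
        for copies, p in ((1, 0.5), (2, 2 / 3)):
            draws = rng.binomial(n_reads, p, n_rep)
            wrong = sum(
                call_copy_number(int(y), n_reads - int(y)).copies != copies
                for y in draws)
            assert wrong / n_rep < 0.001


class TestAssignClass:
    def _mut(self, region, effect="n/a", gid="g1"):
        return TransgeneMutation(gid, 100 if region == "cds" else -100,
                                 "G", "A", region=region, coding_effect=effect)

    def _cnv(self, copies, gid="g1"):
        frac = {1: 0.5, 2: 0.667}[copies]
        return call_copy_number(int(1000 * frac), int(1000 * (1 - frac)),
                                genotype_id=gid)

    def test_nonsynonymous_is_coding_regardless_of_copies(self):
        a = assign_class(self._mut("cds", "nonsynonymous"), self._cnv(1))
        assert a.class_label == "coding"
        a = assign_class(self._mut("cds", "nonsense"), self._cnv(2))
        assert a.class_label == "coding"

    def test_promoter_mutation_is_cis(self):
        assert assign_class(self._mut("promoter"), self._cnv(1)).class_label == "cis"

    def test_duplication_without_mutation_is_cnv(self):
        assert assign_class(None, self._cnv(2)).class_label == "cnv"

    def test_neither_evidence_is_ambiguous(self):
        assert assign_class(None, None, genotype_id="g").class_label == "ambiguous"

    def test_synonymous_falls_through_to_trans(self):
        a = assign_class(self._mut("cds", "synonymous"), self._cnv(1))
        assert a.class_label == "trans"

    def test_synonymous_with_duplication_is_cnv(self):
        a = assign_class(self._mut("cds", "synonymous"), self._cnv(2))
        assert a.class_label == "cnv"

    def test_strict_silent_flagged_in_evidence(self):
        a = assign_class(self._mut("cds", "synonymous"), self._cnv(1),
                         strict_silent=True)
        assert a.class_label == "trans" and a.evidence.get("silent")

    def test_conflicting_evidence_rejected(self):
        bad = TransgeneMutation("g", -100, "G", "A", region="promoter",
                                coding_effect="nonsynonymous")
        with pytest.raises(ValueError):
            assign_class(bad, None)

    def test_total_over_evidence_lattice(self):
        # every evidence combination yields exactly one class
        muts = [None, self._mut("promoter"), self._mut("cds", "nonsynonymous"),
                self._mut("cds", "synonymous")]
        cnvs = [None, self._cnv(1), self._cnv(2)]
        for m in muts:
            for c in cnvs:
                a = assign_class(m, c, genotype_id="g")
                assert a.class_label in {"coding", "cnv", "cis", "trans",
                                         "ambiguous"}


class TestGC:
    def test_extremes(self):
        assert gc_content("GGCC") == 100.0
        assert gc_content("ATAT") == 0.0

    def test_bundled_cds_direct_count_oracle(self, annotation):
        seq = annotation.cds_sequence
        oracle = 100 * sum(b in "GC" for b in seq) / len(seq)
        assert gc_content(seq) == pytest.approx(oracle)
        assert round(gc_content(seq), 2) == 35.56

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(ValueError):
            gc_content("ACGN")
        with pytest.raises(ValueError):
            gc_content("")
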