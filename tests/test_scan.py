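"""Telomere/rDNA detection and chromosome accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoscope import presets
from karyoscope._util import random_dna, revcomp
from karyoscope.scan import (
    ContigAnnotation,
    RdnaLocus,
    TelomereHit,
    account_chromosomes,
    annotate_contigs,
    detect_rdna,
    scan_telomeres,
)
from karyoscope.synthetic import generate_assembly, synthetic_rdna_unit

LEFT = "CCCCTAA"
RIGHT = "TTAGGGG"


def _random_seq(n, seed=0):
    return random_dna(np.random.default_rng(seed), n)


class TestScanTelomeres:
    def test_planted_arrays_both_ends(self):
        seq = LEFT * 8 + _random_seq(20_000, 1) + RIGHT * 8
        hits = scan_telomeres(("c1", seq))
        sides = {h.side: h for h in hits}
        assert set(sides) == {"left", "right"}
        assert sides["left"].copies == 8 and sides["right"].copies == 8
        assert sides["left"].start == 0
        assert sides["right"].end == len(seq)

    def test_random_sequence_no_hits(self):
        assert scan_telomeres(("c1", _random_seq(20_000, 2))) == []

    def test_revcomp_swaps_sides_preserves_count(self):
        seq = LEFT * 9 + _random_seq(15_000, 3)
        fwd = scan_telomeres(("c1", seq))
        rev = scan_telomeres(("c1", revcomp(seq)))
        assert len(fwd) == len(rev) == 1
        assert fwd[0].side == "left" and rev[0].side == "right"
        assert fwd[0].copies == rev[0].copies == 9

    def test_matches_generator_truth_table(self, l7_assembly):
        records, truth = l7_assembly
        tel_truth = truth[truth["feature"] == "telomere"]
        for rec in records:
            hits = scan_telomeres(rec)
            expected = tel_truth[tel_truth["contig"] == rec.id]
            assert len(hits) == len(expected)
            got = {(h.side, h.start, h.end, h.copies) for h in hits}
            want = {(r.side, r.start, r.end, r.copies)
                    for r in expected.itertuples()}
            assert got == want

    def test_mismatched_copies_within_budget(self):
        # one substituted base inside a 10-copy array: 1/70 < 10% budget
        unit = list(LEFT * 10)
        unit[3 * 7 + 2] = "G"
        seq = "".join(unit) + _random_seq(10_000, 4)
        hits = scan_telomeres(("c1", seq))
        assert len(hits) == 1 and hits[0].copies == 10

    def test_min_copies_monotonicity(self):
        seq = LEFT * 6 + _random_seq(5_000, 5) + RIGHT * 12
        counts = [len(scan_telomeres(("c1", seq), min_copies=m))
                  for m in (1, 5, 7, 13)]
        assert counts == sorted(counts, reverse=True)

    @given(copies=st.integers(min_value=5, max_value=30),
           seed=st.integers(min_value=0, max_value=1000))
    @settings(max_examples=20, deadline=None)
    def test_copy_count_recovered_exactly(self, copies, seed):
        seq = LEFT * copies + _random_seq(3_000, seed)
        hits = scan_telomeres(("c1", seq))
        assert [h.copies for h in hits if h.side == "left"] == [copies]

    def test_interstitial_array_not_terminal(self):
        seq = _random_seq(5_000, 6) + LEFT * 8 + _random_seq(5_000, 7)
        hits = scan_telomeres(("c1", seq))
        assert len(hits) == 1 and hits[0].side == "interstitial"
        assert not hits[0].terminal

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            scan_telomeres(("c1", ""))


class TestDetectRdna:
    def test_exact_embedded_copy_identity_100(self):
        unit = synthetic_rdna_unit()
        seq = _random_seq(8_000, 8) + unit + _random_seq(8_000, 9)
        loci = detect_rdna(("c1", seq), [("rdna", unit)])
        assert len(loci) == 1
        assert loci[0].identity == 1.0
        assert (loci[0].start, loci[0].end) == (8_000, 11_000)
        assert not loci[0].terminal

    def test_degraded_copy_detected_at_90_identity(self):
        rng = np.random.default_rng(10)
        unit = synthetic_rdna_unit()
        mutated = list(unit)
        pos = rng.choice(len(unit), size=int(0.05 * len(unit)), replace=False)
        for p in pos:
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        n_sub = sum(a != b for a, b in zip(unit, mutated))
        seq = _random_seq(5_000, 11) + "".join(mutated) + _random_seq(5_000, 12)
        loci = detect_rdna(("c1", seq), [("rdna", unit)], min_identity=0.9)
        assert len(loci) == 1
        # oracle: identity of the planted pair is 1 - substitutions/length
        assert loci[0].identity == pytest.approx(1 - n_sub / len(unit), abs=0.01)

    def test_no_rdna_planted_empty(self):
        loci = detect_rdna(("c1", _random_seq(10_000, 13)),
                           [("rdna", synthetic_rdna_unit())])
        assert loci == []

    def test_tandem_copies_merged_into_one_terminal_locus(self):
        unit = synthetic_rdna_unit()
        seq = _random_seq(10_000, 14) + unit * 3
        loci = detect_rdna(("c1", seq), [("rdna", unit)])
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (10_000, 19_000)
        assert loci[0].terminal

    def test_reverse_strand_match(self):
        unit = synthetic_rdna_unit()
        seq = _random_seq(4_000, 15) + revcomp(unit) + _random_seq(4_000, 16)
        loci = detect_rdna(("c1", seq), [("rdna", unit)])
        assert len(loci) == 1 and loci[0].strand == "-"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_rdna(("c1", "ACGT" * 100), [("rdna", "")])


class TestAccounting:
    def test_l7_plan_accounting(self, l7_assembly):
        records, _ = l7_assembly
        ann = annotate_contigs(records,
                               rdna_references=[("rdna", synthetic_rdna_unit())])
        acct = account_chromosomes(ann)
        assert acct.n_double_sided == 14
        assert acct.n_single_plus_rdna == 1
        assert acct.chromosome_count_strict == 14
        assert acct.chromosome_count_extended == 15

    def test_pr2c_plan_accounting(self):
        records, _ = generate_assembly(presets.pr2c_assembly_truth(), seed=43)
        ann = annotate_contigs(records,
                               rdna_references=[("rdna", synthetic_rdna_unit())])
        acct = account_chromosomes(ann)
        assert acct.n_double_sided == 13
        assert acct.n_single_plus_rdna == 1
        assert acct.n_single_only == 2
        assert acct.chromosome_count_extended == 14

    def test_no_telomeres_zero_counts(self):
        ann = [ContigAnnotation("c1", 1000), ContigAnnotation("c2", 1000)]
        acct = account_chromosomes(ann)
        assert acct.chromosome_count_strict == 0
        assert acct.chromosome_count_extended == 0
        assert acct.n_none == 2

    def test_revcomp_assembly_same_accounting(self, l7_assembly):
        records, _ = l7_assembly
        flipped = [(r.id, revcomp(str(r.seq))) for r in records]
        a1 = account_chromosomes(annotate_contigs(records))
        a2 = account_chromosomes(annotate_contigs(flipped))
        assert a1.to_dict() == a2.to_dict()

    def test_duplicate_contig_ids_rejected(self):
        ann = [ContigAnnotation("c1", 1000), ContigAnnotation("c1", 2000)]
        with pytest.raises(ValueError, match="duplicate"):
            account_chromosomes(ann)

    def test_three_telomere_contig_flagged_anomalous(self):
        # a terminal array on each end plus a false join leaving an extra
        # terminal array within the right end-window
        seq = (LEFT * 8 + _random_seq(20_000, 17) + LEFT * 8 + "A" * 500
               + RIGHT * 8 + "A" * 100)
        hits = scan_telomeres(("c1", seq), end_window=1_500)
        ann = ContigAnnotation("c1", len(seq), hits)
        assert ann.n_terminal_arrays == 3
        acct = account_chromosomes([ann])
        assert acct.n_anomalous == 1

    def test_single_telomere_rdna_same_side_is_partial(self):
        # rDNA terminal on the SAME end as the telomere does not complete it
        unit = synthetic_rdna_unit()
        tel = TelomereHit("c1", "left", 0, 70, LEFT, 10, "+")
        locus = RdnaLocus("c1", 100, 3_100, "rdna", 1.0, True, "+")
        ann = ContigAnnotation("c1", 50_000, [tel], [locus])
        assert ann.completeness == "partial"
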