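import numpy as np
import pytest

from conftest import make_genome
from isohap.genomic_io import LongReadAlignment, _cigar_to_blocks
from isohap.phasing import (
    MASK_REF,
    MASK_ROI_ORIGINAL,
    MASK_SGS_CORRECTED,
    MASK_SNP_MARKED,
    CorrectedRoi,
    MappedMate,
    PhasingConfig,
    SnpRegistry,
    SnpSite,
    build_linkage_and_rescue,
    build_linkage_table,
    build_pseudo_long_read,
    call_snp_positions,
    correct_pseudo_read,
    fix_and_phase_roi,
    map_short_reads_to_pseudo,
    phase_isoforms,
    pileup_short_reads,
)

GENOME_SEQ = "ACGTACGTACGTACGTACGTTTTTCCCCGGGGAAAATTTTACGTACGTACGT"


def aln(cigar, start, read_seq, strand="+", read_id="roi1", contig="chrT"):
    codes = {"M": 0, "I": 1, "D": 2, "N": 3}
    tuples = [(codes[op], n) for n, op in cigar]
    return LongReadAlignment(read_id, contig, strand,
                             _cigar_to_blocks(tuples, start), read_seq)


class TestPseudoLongRead:
    def test_substitution_replaced_by_reference(self):
        genome = make_genome(GENOME_SEQ)
        read = "AGGTACGTAC"  # C->G substitution at read position 1
        pseudo = build_pseudo_long_read(aln([(10, "M")], 0, read), genome)
        assert pseudo.sequence == GENOME_SEQ[:10]
        assert (pseudo.mask == MASK_REF).all()

    def test_identity_read_unchanged(self):
        genome = make_genome(GENOME_SEQ)
        read = GENOME_SEQ[4:14]
        pseudo = build_pseudo_long_read(aln([(10, "M")], 4, read), genome)
        assert pseudo.sequence == read

    def test_insertion_dropped(self):
        genome = make_genome(GENOME_SEQ)
        read = GENOME_SEQ[0:5] + "TT" + GENOME_SEQ[5:10]
        pseudo = build_pseudo_long_read(
            aln([(5, "M"), (2, "I"), (5, "M")], 0, read), genome
        )
        assert len(pseudo) == len(read) - 2
        assert pseudo.sequence == GENOME_SEQ[:10]

    def test_deletion_filled_with_reference(self):
        genome = make_genome(GENOME_SEQ)
        read = GENOME_SEQ[0:5] + GENOME_SEQ[7:12]
        pseudo = build_pseudo_long_read(
            aln([(5, "M"), (2, "D"), (5, "M")], 0, read), genome
        )
        assert pseudo.sequence == GENOME_SEQ[:12]
        assert pseudo.roi_pos[5] == -1  # deletion-filled position has no ROI base

    def test_intron_skipped(self):
        genome = make_genome(GENOME_SEQ)
        read = GENOME_SEQ[0:5] + GENOME_SEQ[35:40]
        pseudo = build_pseudo_long_read(
            aln([(5, "M"), (30, "N"), (5, "M")], 0, read), genome
        )
        assert pseudo.sequence == GENOME_SEQ[0:5] + GENOME_SEQ[35:40]
        assert list(pseudo.genome_pos[:5]) == list(range(5))
        assert list(pseudo.genome_pos[5:]) == list(range(35, 40))

    def test_reference_n_positions_keep_roi_base(self):
        genome = make_genome("ACGTNNACGT")
        read = "ACGTGGACGT"
        pseudo = build_pseudo_long_read(aln([(10, "M")], 0, read), genome)
        assert pseudo.sequence == "ACGTGGACGT"
        assert list(pseudo.mask[4:6]) == [MASK_ROI_ORIGINAL, MASK_ROI_ORIGINAL]

    def test_mask_partition_is_exhaustive(self, default_sim):
        _, _, result = default_sim
        for pseudo in result.pseudo_reads[:20]:
            assert len(pseudo.mask) == len(pseudo.sequence)
            counted = sum(
                int((pseudo.mask == m).sum())
                for m in (MASK_REF, MASK_SGS_CORRECTED, MASK_ROI_ORIGINAL,
                          MASK_SNP_MARKED)
            )
            assert counted == len(pseudo)


def _pseudo(seq, genome_start=0):
    genome = make_genome(seq)
    return build_pseudo_long_read(aln([(len(seq), "M")], genome_start, seq), genome)


class TestPileup:
    def test_counts_per_position(self):
        pseudo = _pseudo("A" * 30)
        mates = [MappedMate("roi1", 5, "C" * 10)] * 3
        counts = pileup_short_reads(pseudo, mates, end_trim=0)
        assert counts[1, 10] == 3  # C at position 10
        assert counts[:, 4].sum() == 0

    def test_overlapping_mates_count_twice(self):
        pseudo = _pseudo("A" * 30)
        mates = [MappedMate("roi1", 0, "A" * 20), MappedMate("roi1", 10, "A" * 20)]
        counts = pileup_short_reads(pseudo, mates, end_trim=0)
        assert counts[0, 15] == 2

    def test_no_coverage_is_empty(self):
        pseudo = _pseudo("A" * 30)
        counts = pileup_short_reads(pseudo, [], end_trim=0)
        assert counts.sum() == 0

    def test_out_of_bounds_mate_skipped(self):
        pseudo = _pseudo("A" * 30)
        counts = pileup_short_reads(pseudo, [MappedMate("roi1", 25, "A" * 10)],
                                    end_trim=0)
        assert counts.sum() == 0

    def test_end_trim_removes_outer_bases(self):
        pseudo = _pseudo("A" * 30)
        counts = pileup_short_reads(pseudo, [MappedMate("roi1", 0, "A" * 20)],
                                    end_trim=3)
        assert counts[:, 0].sum() == 0 and counts[:, 19].sum() == 0
        assert counts[0, 3] == 1 and counts[0, 16] == 1


class TestSnpCalling:
    def _call(self, seq, counts_dict):
        pseudo = _pseudo(seq)
        counts = np.zeros((4, len(seq)), dtype=np.int32)
        for pos, per_base in counts_dict.items():
            for base, depth in per_base.items():
                counts["ACGT".index(base), pos] = depth
        return call_snp_positions(pseudo, counts)

    def test_heterozygous_site(self):
        (site,) = self._call("G" * 20, {10: {"A": 6, "G": 5}})
        assert site.kind == "het"
        assert set(site.alleles) == {"A", "G"}
        assert site.genome_pos == 10

    def test_homozygous_different(self):
        (site,) = self._call("G" * 20, {10: {"A": 10}})
        assert site.kind == "hom_diff" and site.alleles == ("A",)

    def test_low_minor_fraction_not_called(self):
        sites = self._call("A" * 20, {10: {"A": 9, "G": 1}})
        assert sites == []

    def test_three_strong_bases_unreliable(self):
        sites = self._call("G" * 20, {10: {"A": 4, "C": 4, "G": 4}})
        assert sites == []

    def test_depth_below_threshold_not_called(self):
        sites = self._call("G" * 20, {10: {"A": 2, "G": 1}})
        assert all(s.kind != "het" for s in sites)


class TestCorrection:
    def _correct(self, ref, roi, counts_dict, snps=()):
        genome = make_genome(ref)
        pseudo = build_pseudo_long_read(aln([(len(ref), "M")], 0, roi), genome)
        counts = np.zeros((4, len(ref)), dtype=np.int32)
        for pos, per_base in counts_dict.items():
            for base, depth in per_base.items():
                counts["ACGT".index(base), pos] = depth
        return correct_pseudo_read(pseudo, counts, list(snps), roi)

    def test_consistent_coverage_replaces(self):
        out = self._correct("TTTTT", "TTTTT", {2: {"C": 3}})
        assert out.sequence == "TTCTT"
        assert out.mask[2] == MASK_SGS_CORRECTED

    def test_single_read_keeps_roi_base(self):
        out = self._correct("TTTTT", "TTGTT", {2: {"C": 1}})
        assert out.sequence == "TTGTT"
        assert out.mask[2] == MASK_ROI_ORIGINAL

    def test_inconsistent_coverage_keeps_roi_base(self):
        out = self._correct("TTTTT", "TTGTT", {2: {"C": 1, "A": 1}})
        assert out.sequence == "TTGTT"

    def test_het_snp_restores_roi_allele(self):
        snp = SnpSite("roi1", 2, 2, "het", ("C", "T"), (5, 5))
        out = self._correct("TTTTT", "TTCTT", {2: {"C": 5, "T": 5}}, [snp])
        assert out.sequence == "TTCTT"
        assert out.mask[2] == MASK_SNP_MARKED
        assert out.snp_positions == {2: 2}

    def test_hom_diff_takes_short_read_base(self):
        snp = SnpSite("roi1", 2, 2, "hom_diff", ("A",), (9,))
        out = self._correct("TTTTT", "TTTTT", {2: {"A": 9, "T": 1}}, [snp])
        assert out.sequence == "TTATT"
        assert out.mask[2] == MASK_SGS_CORRECTED


def _registry(sites):
    registry = SnpRegistry()
    for contig, gpos, alleles in sites:
        registry.add(contig, SnpSite("p", 0, gpos, "het", alleles, (5, 5)))
    return registry


def _roi(roi_id, seq, snp_positions, fixed=None, contig="chrT"):
    roi = CorrectedRoi(
        roi_id=roi_id, contig=contig, strand="+", sequence=seq,
        mask=np.zeros(len(seq), dtype=np.uint8), snp_positions=dict(snp_positions),
    )
    roi.fixed = dict(fixed or {})
    return roi


class TestFixAndPhase:
    def test_all_positions_fixed_phases(self):
        registry = _registry([("chrT", 10, ("A", "G")), ("chrT", 20, ("C", "T")),
                              ("chrT", 30, ("A", "C"))])
        roi = _roi("r", "A" + "C" + "A", {0: 10, 1: 20, 2: 30})
        out = fix_and_phase_roi(roi, registry)
        assert out.fixed == {10: "A", 20: "C", 30: "A"}
        assert out.phased

    def test_single_fix_is_not_phased(self):
        registry = _registry([("chrT", 10, ("A", "G")), ("chrT", 20, ("C", "T"))])
        roi = _roi("r", "AG", {0: 10, 1: 20})  # G not in {C,T} at position 20
        out = fix_and_phase_roi(roi, registry)
        assert out.fixed == {10: "A"}
        assert not out.phased

    def test_non_allele_base_left_unfixed(self):
        registry = _registry([("chrT", 10, ("A", "G"))])
        roi = _roi("r", "T", {0: 10})
        assert fix_and_phase_roi(roi, registry).fixed == {}


class TestLinkageRescue:
    def test_unique_linkage_rescues(self):
        registry = _registry([("chrT", 10, ("A", "G")), ("chrT", 20, ("C", "T"))])
        phased = [
            _roi(f"p{i}", "AC", {0: 10, 1: 20}, fixed={10: "A", 20: "C"})
            for i in range(5)
        ]
        # erroneous base at position 20 that matches neither allele
        broken = _roi("b", "AN", {0: 10, 1: 20}, fixed={10: "A"})
        _, rois = build_linkage_and_rescue(phased + [broken], registry)
        rescued = next(r for r in rois if r.roi_id == "b")
        assert rescued.fixed == {10: "A", 20: "C"}
        assert rescued.sequence == "AC"
        assert rescued.phased

    def test_tied_linkage_is_no_action(self):
        registry = _registry([("chrT", 10, ("A", "G")), ("chrT", 20, ("C", "T"))])
        phased = [
            _roi(f"p{i}", "AC", {0: 10, 1: 20}, fixed={10: "A", 20: "C"})
            for i in range(3)
        ] + [
            _roi(f"q{i}", "AT", {0: 10, 1: 20}, fixed={10: "A", 20: "T"})
            for i in range(3)
        ]
        broken = _roi("b", "AN", {0: 10, 1: 20}, fixed={10: "A"})
        _, rois = build_linkage_and_rescue(phased + [broken], registry)
        rescued = next(r for r in rois if r.roi_id == "b")
        assert 20 not in rescued.fixed

    def test_rescue_is_monotone(self, default_sim):
        """Rescue only ever adds fixed positions, never removes one."""
        _, _, result = default_sim
        before = {r.roi_id: dict(r.fixed) for r in result.corrected}
        from copy import deepcopy

        _, after = build_linkage_and_rescue(
            deepcopy(result.corrected), result.registry
        )
        for roi in after:
            for gpos, allele in before[roi.roi_id].items():
                assert roi.fixed.get(gpos) == allele


class TestPhaseIsoforms:
    def test_two_haplotypes_assembled(self):
        registry = _registry([("chrT", 10, ("A", "G")), ("chrT", 20, ("C", "T"))])
        rois = (
            [_roi(f"a{i}", "AC", {0: 10, 1: 20}, fixed={10: "A", 20: "C"})
             for i in range(2)]
            + [_roi(f"b{i}", "GT", {0: 10, 1: 20}, fixed={10: "G", 20: "T"})
               for i in range(2)]
        )
        mapping = {r.roi_id: "iso1" for r in rois}
        (pair,) = phase_isoforms(rois, mapping, registry)
        assert pair.phased
        assert pair.positions == [10, 20]
        assert {pair.haplotype_a, pair.haplotype_b} == {"AC", "GT"}
        assert {len(pair.support_a), len(pair.support_b)} == {2}

    def test_single_haplotype_not_phased(self):
        registry = _registry([("chrT", 10, ("A", "G")), ("chrT", 20, ("C", "T"))])
        rois = [_roi(f"a{i}", "AC", {0: 10, 1: 20}, fixed={10: "A", 20: "C"})
                for i in range(4)]
        (pair,) = phase_isoforms(rois, {r.roi_id: "iso1" for r in rois}, registry)
        assert not pair.phased

    def test_recurrent_third_pattern_flags_conflict(self):
        registry = _registry([("chrT", 10, ("A", "G")), ("chrT", 20, ("C", "T"))])
        rois = (
            [_roi(f"a{i}", "AC", {0: 10, 1: 20}, fixed={10: "A", 20: "C"})
             for i in range(2)]
            + [_roi(f"b{i}", "GT", {0: 10, 1: 20}, fixed={10: "G", 20: "T"})
               for i in range(2)]
            + [_roi(f"c{i}", "AT", {0: 10, 1: 20}, fixed={10: "A", 20: "T"})
               for i in range(2)]
        )
        (pair,) = phase_isoforms(rois, {r.roi_id: "iso1" for r in rois}, registry)
        assert pair.conflicting and not pair.phased

    def test_lone_stray_roi_excluded_without_conflict(self):
        registry = _registry([("chrT", 10, ("A", "G")), ("chrT", 20, ("C", "T"))])
        rois = (
            [_roi(f"a{i}", "AC", {0: 10, 1: 20}, fixed={10: "A", 20: "C"})
             for i in range(3)]
            + [_roi(f"b{i}", "GT", {0: 10, 1: 20}, fixed={10: "G", 20: "T"})
               for i in range(3)]
            + [_roi("c0", "AT", {0: 10, 1: 20}, fixed={10: "A", 20: "T"})]
        )
        (pair,) = phase_isoforms(rois, {r.roi_id: "iso1" for r in rois}, registry)
        assert pair.phased and pair.excluded == {"c0"}


class TestMapper:
    def test_exact_and_mismatch_hits(self):
        pseudo = _pseudo("ACGT" * 30)
        seq = "ACGT" * 10
        from isohap.genomic_io import ShortReadPair

        pairs = [ShortReadPair("p1", seq, "TT" + seq[2:])]
        hits = map_short_reads_to_pseudo(pairs, [pseudo])
        starts = sorted(m.start for m in hits["roi1"])
        assert 0 in starts  # mate 1 maps exactly at 0 (and periodically)

    def test_junction_overhang_is_clipped(self):
        pseudo = _pseudo("A" * 60 + "C" * 60)
        from isohap.genomic_io import ShortReadPair

        # 34 matching bases then a 6-base overhang with two chance matches
        read = "A" * 34 + "GAAGAA"
        pairs = [ShortReadPair("p1", read, read)]
        hits = map_short_reads_to_pseudo(pairs, [pseudo])
        assert hits["roi1"]
        for mate in hits["roi1"]:
            assert "G" not in mate.sequence  # overhang clipped away
            assert len(mate.sequence) == 34
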