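import numpy as np
import pytest

from conftest import make_genome
from isohap.genomic_io import AnnotatedTranscript, GenomicInterval, ValidationError
from isohap.isoform_classify import (
    AnnotationIndex,
    CSMM,
    ME_CANONICAL,
    ME_NON_CANONICAL,
    MULTI_EXON,
    NON_CSMM,
    NOVEL,
    SINGLE_EXON,
    IsoformModel,
    attribute_to_gene,
    classify_exon_structure,
    classify_junctions,
    collapse_equivalent,
    completeness_distances,
    extract_junctions,
    filter_quality,
    match_annotated_transcript,
)
from oracles import brute_attribute, brute_match


def iso(exons, strand="+", contig="chrT", iso_id="i", **kw):
    kw.setdefault("fl_count", 2)
    kw.setdefault("accuracy", 1.0)
    kw.setdefault("roi_ids", {iso_id})
    return IsoformModel(iso_id, contig, strand,
                        [GenomicInterval(contig, s, e, strand) for s, e in exons], **kw)


def tx(tid, gene, exons, strand="+", contig="chrT", biotype="protein_coding"):
    return AnnotatedTranscript(
        tid, gene, contig, strand,
        [GenomicInterval(contig, s, e, strand) for s, e in exons], biotype
    )


class TestFilterQuality:
    @pytest.mark.parametrize(
        "fl,acc,expected",
        [
            (3, 0.995, "high"),       # both criteria met
            (2, 0.99, "high"),        # boundary accuracy
            (1, 0.97, "consensus"),   # single full-length read, 95-99% band
            (1, 0.995, "consensus"),  # accurate but only one full-length read
            (2, 0.96, "consensus"),
            (0, 0.99, "rejected"),    # no full-length support at all
            (5, 0.90, "rejected"),    # below the consensus accuracy floor
        ],
    )
    def test_cluster_tiers(self, fl, acc, expected):
        model = iso([(0, 100)], fl_count=fl, accuracy=acc)
        high, consensus, rejected = filter_quality([model])
        got = "high" if high else ("consensus" if consensus else "rejected")
        assert got == expected

    def test_accuracy_out_of_range(self):
        with pytest.raises(ValidationError):
            filter_quality([iso([(0, 100)], accuracy=1.5)])


class TestExonStructure:
    @pytest.mark.parametrize("n,expected", [(1, SINGLE_EXON), (2, MULTI_EXON),
                                            (12, MULTI_EXON)])
    def test_exon_count_split(self, n, expected):
        exons = [(i * 200, i * 200 + 100) for i in range(n)]
        assert classify_exon_structure(iso(exons)) == expected


class TestJunctions:
    def _genome_with_intron(self, donor, acceptor):
        # exon [0,10) + 30nt intron + exon [40,50)
        intron = donor + "A" * 26 + acceptor
        return make_genome("C" * 10 + intron + "G" * 10)

    @pytest.mark.parametrize("donor,acceptor,canonical", [
        ("GT", "AG", True), ("GC", "AG", True), ("AT", "AC", True),
        ("GA", "AG", False), ("GT", "AC", False), ("CC", "GG", False),
    ])
    def test_plus_strand_motifs(self, donor, acceptor, canonical):
        genome = self._genome_with_intron(donor, acceptor)
        (j,) = extract_junctions(iso([(0, 10), (40, 50)]), genome)
        assert (j.donor_motif, j.acceptor_motif) == (donor, acceptor)
        assert j.canonical is canonical

    def test_minus_strand_reads_reverse_complement(self):
        # genomic CT..AC is GT-AG in transcription direction on the minus strand
        genome = self._genome_with_intron("CT", "AC")
        (j,) = extract_junctions(iso([(0, 10), (40, 50)], strand="-"), genome)
        assert (j.donor_motif, j.acceptor_motif) == ("GT", "AG")
        assert j.canonical

    def test_all_canonical_required(self):
        genome = make_genome(
            "C" * 10 + "GT" + "A" * 26 + "AG" + "G" * 10 + "GA" + "A" * 26 + "AG" + "T" * 10
        )
        model = iso([(0, 10), (40, 50), (80, 90)])
        junctions = extract_junctions(model, genome)
        assert [j.canonical for j in junctions] == [True, False]
        assert classify_junctions(junctions) == ME_NON_CANONICAL
        assert classify_junctions(junctions[:1]) == ME_CANONICAL

    def test_short_intron_is_an_error(self):
        genome = make_genome("A" * 100)
        with pytest.raises(ValidationError, match="intron"):
            extract_junctions(iso([(0, 10), (20, 30)]), genome)


class TestGeneAttribution:
    def setup_method(self):
        self.annotation = [
            tx("tA1", "A", [(100, 200), (300, 400), (500, 600)]),
            tx("tB1", "B", [(300, 400), (500, 650)]),
            tx("tC1", "C", [(5000, 5400)]),
            tx("tC2", "C", [(5000, 5100), (5300, 5400)]),
        ]
        self.index = AnnotationIndex(self.annotation)

    def test_most_shared_sites_wins(self):
        # shares sites 200/300 (gene A only) and 400/500 (A and B)
        model = iso([(150, 200), (300, 400), (500, 550)])
        assert attribute_to_gene(model, self.index) == (CSMM, "A")

    def test_locus_overlap_without_shared_sites(self):
        model = iso([(5050, 5150), (5250, 5350)])
        attribution, gene = attribute_to_gene(model, self.index)
        assert (attribution, gene) == (NON_CSMM, "C")

    def test_intergenic_is_novel(self):
        model = iso([(20000, 20100), (20300, 20400)])
        assert attribute_to_gene(model, self.index) == (NOVEL, None)

    def test_strand_mismatch_never_shares(self):
        model = iso([(150, 200), (300, 400)], strand="-")
        attribution, _ = attribute_to_gene(model, self.index)
        assert attribution != CSMM


class TestTranscriptMatch:
    def setup_method(self):
        self.index = AnnotationIndex([
            tx("t1", "A", [(100, 200), (300, 400)]),
            tx("t2", "A", [(100, 200), (300, 400), (500, 600)]),
        ])

    def test_intron_chain_governs_not_ends(self):
        model = iso([(20, 200), (300, 480)])  # ends differ by 80 nt
        assert match_annotated_transcript(model, self.index) == (["t1"], False)

    def test_extra_intron_prevents_match(self):
        model = iso([(100, 150), (170, 200), (300, 400)])
        assert match_annotated_transcript(model, self.index) == ([], False)

    def test_single_exon_not_applicable(self):
        assert match_annotated_transcript(iso([(100, 400)]), self.index) == ([], False)

    def test_ambiguous_when_two_share_a_chain(self):
        index = AnnotationIndex([
            tx("t1", "A", [(100, 200), (300, 400)]),
            tx("t3", "B", [(150, 200), (300, 350)]),
        ])
        matches, ambiguous = match_annotated_transcript(
            iso([(100, 200), (300, 400)]), index
        )
        assert matches == ["t1", "t3"] and ambiguous


class TestCollapse:
    def test_close_ends_merge(self):
        a = iso([(0, 200), (300, 400)], iso_id="a")
        b = iso([(150, 200), (300, 410)], iso_id="b")  # 5' differs 150, 3' differs 10
        (merged,) = collapse_equivalent([a, b])
        assert merged.roi_ids == {"a", "b"}
        assert merged.isoform_id == "a"  # longest member represents the class

    def test_boundary_200_merges_201_does_not(self):
        a = iso([(0, 300), (400, 500)], iso_id="a")
        at_limit = iso([(200, 300), (400, 500)], iso_id="b")  # Δ5' exactly 200
        past = iso([(201, 300), (400, 500)], iso_id="c")      # Δ5' of 201
        assert len(collapse_equivalent([a, at_limit])) == 1
        assert len(collapse_equivalent([a, past])) == 2

    def test_identical_models_merge(self):
        a = iso([(0, 200), (300, 400)], iso_id="a")
        b = iso([(0, 200), (300, 400)], iso_id="b")
        (merged,) = collapse_equivalent([a, b])
        assert merged.roi_ids == {"a", "b"}

    def test_different_chains_never_merge(self):
        a = iso([(0, 200), (300, 400)], iso_id="a")
        b = iso([(0, 200), (301, 400)], iso_id="b")
        assert len(collapse_equivalent([a, b])) == 2

    def test_idempotent(self, rng):
        models = [
            iso([(s, s + 200), (s + 300, s + 400)], iso_id=f"i{k}")
            for k, s in enumerate(rng.integers(0, 500, size=12))
        ]
        once = collapse_equivalent(models)
        twice = collapse_equivalent(once)
        assert sorted(sorted(m.roi_ids) for m in once) == \
            sorted(sorted(m.roi_ids) for m in twice)


class TestCompleteness:
    def test_downstream_distance(self):
        gene = [tx("t1", "A", [(100, 200), (300, 400)])]
        model = iso([(150, 200), (300, 400)])
        assert completeness_distances(model, gene) == (50, 0)

    def test_upstream_start_clamps_to_zero(self):
        gene = [tx("t1", "A", [(100, 200), (300, 400)])]
        model = iso([(90, 200), (300, 400)])
        assert completeness_distances(model, gene) == (0, 0)

    def test_exact_start_is_zero(self):
        gene = [tx("t1", "A", [(100, 400)])]
        assert completeness_distances(iso([(100, 400)]), gene) == (0, 0)

    def test_minus_strand_direction(self):
        gene = [tx("t1", "A", [(100, 400)], strand="-")]
        model = iso([(100, 350)], strand="-")  # 5' end at 349, aTSS at 399
        assert completeness_distances(model, gene) == (50, 0)

    def test_minimal_over_transcripts(self):
        gene = [
            tx("t1", "A", [(0, 400)]),
            tx("t2", "A", [(140, 400)]),
        ]
        model = iso([(150, 400)])
        assert completeness_distances(model, gene) == (10, 0)

    def test_no_same_strand_transcript(self):
        gene = [tx("t1", "A", [(100, 400)], strand="-")]
        assert completeness_distances(iso([(100, 400)]), gene) == (None, None)

    def test_biotype_filter_applies(self):
        # the excluded rRNA transcript is the nearer one
        gene = [
            tx("t1", "A", [(150, 400)], biotype="rRNA"),
            tx("t2", "A", [(100, 400)], biotype="protein_coding"),
        ]
        model = iso([(160, 400)])
        assert completeness_distances(model, gene) == (60, 0)
        assert completeness_distances(model, gene, biotypes=None) == (10, 0)


class TestOracleAgreement:
    """Spot-check agreement with brute force; the exhaustive randomized sweep
    lives in the acceptance suite."""

    def test_random_toys(self, rng):
        from oracles import random_annotation, random_isoform_near

        for _ in range(40):
            annotation = random_annotation(rng, n_transcripts=int(rng.integers(2, 9)))
            model = random_isoform_near(rng, annotation)
            index = AnnotationIndex(annotation)
            assert attribute_to_gene(model, index) == brute_attribute(model, annotation)
            assert match_annotated_transcript(model, index)[0] == \
                brute_match(model, annotation)

    def test_strand_symmetry(self):
        """Mirroring an isoform and genome to the other strand preserves labels."""
        genome = make_genome("C" * 10 + "GT" + "A" * 26 + "AG" + "G" * 10)
        from isohap.genomic_io import reverse_complement

        mirrored = make_genome(reverse_complement(genome["chrT"].sequence))
        L = len(genome["chrT"])
        fwd = iso([(0, 10), (40, 50)], strand="+")
        rev = iso([(L - 50, L - 40), (L - 10, L)], strand="-")
        jf = extract_junctions(fwd, genome)
        jr = extract_junctions(rev, mirrored)
        assert [(j.donor_motif, j.acceptor_motif) for j in jf] == \
            [(j.donor_motif, j.acceptor_motif) for j in jr]
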