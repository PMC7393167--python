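"""Synthetic diploid mini-transcriptome with full ground truth.

The generator emulates the data structure of a normalized single-molecule
RNA-seq experiment on a diploid sample: a random genome carrying genes with
canonical GT-AG introns, one to a few isoforms per gene built by exon
skipping, heterozygous SNPs in exons (haplotype A carries the reference
allele, haplotype B the alternate), allele-specific expression ratios per
isoform, error-prone and optionally 3'-truncated long reads, and accurate
short read pairs.  Truth alignments are emitted alongside the reads so the
whole pipeline can run without an external aligner.

Short reads are either sampled (fragment starts uniform along the
transcript, both haplotypes at the configured expression ratio) or laid out
as a deterministic tiling of both haplotypes — the noiseless coverage used
for closed-form zero-error checks.

Every random draw flows from the single seed in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genomic_io import (
    AnnotatedTranscript,
    Genome,
    GenomeSequence,
    GenomicInterval,
    LongReadAlignment,
    ShortReadAlignment,
    ShortReadPair,
    _cigar_to_blocks,
    reverse_complement,
)
from .isoform_classify import IsoformModel
from .phasing import HaplotypePair

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fixes every downstream draw."""

    seed: int
    n_genes: int = 20
    contig_name: str = "chrS"
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (150, 450)
    intron_length: tuple[int, int] = (80, 300)
    intergenic_gap: int = 500
    single_exon_fraction: float = 0.1
    non_canonical_fraction: float = 0.0
    minus_strand_fraction: float = 0.5
    snp_rate_per_kb: float = 2.0
    snp_edge_margin: int = 3
    differential_fraction: float = 0.2
    differential_fold: float = 4.0
    long_reads_per_isoform: int = 10
    long_substitution_rate: float = 0.015
    long_insertion_rate: float = 0.002
    long_deletion_rate: float = 0.002
    truncation_probability: float = 0.3
    truncation_mean: float = 20.0
    short_coverage: float = 30.0
    short_read_length: int = 100
    insert_size_mean: float = 250.0
    insert_size_sd: float = 30.0
    short_error_rate: float = 0.002
    short_read_mode: str = "sampled"  # or "tiling"
    tiling_stride: int = 50
    cluster_accuracy: float = 0.995

    def __post_init__(self):
        for name in (
            "single_exon_fraction", "non_canonical_fraction",
            "minus_strand_fraction", "differential_fraction",
            "long_substitution_rate", "long_insertion_rate",
            "long_deletion_rate", "truncation_probability",
            "short_error_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0,1]")

    def zero_error(self) -> "SimulationConfig":
        """The noiseless variant: error-free reads, no truncation, tiled
        short-read coverage of both haplotypes, balanced alleles."""
        return replace(
            self,
            long_substitution_rate=0.0,
            long_insertion_rate=0.0,
            long_deletion_rate=0.0,
            truncation_probability=0.0,
            short_error_rate=0.0,
            short_read_mode="tiling",
            differential_fraction=0.0,
        )


@dataclass
class TruthSnp:
    contig: str
    genome_pos: int
    allele_a: str  # reference allele (haplotype A)
    allele_b: str  # alternate allele (haplotype B)


@dataclass
class SimulatedIsoform:
    isoform_id: str
    gene_id: str
    transcript: AnnotatedTranscript
    fraction_a: float  # haplotype A share of this isoform's expression

    @property
    def differential(self) -> bool:
        return max(self.fraction_a, 1 - self.fraction_a) / max(
            1e-12, min(self.fraction_a, 1 - self.fraction_a)
        ) >= 2.0


@dataclass
class GroundTruth:
    genome: Genome
    transcripts: list[AnnotatedTranscript]
    isoforms: dict[str, SimulatedIsoform]
    snps_by_gene: dict[str, list[TruthSnp]]
    config: SimulationConfig
    read_origin: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def snp_by_pos(self) -> dict[tuple[str, int], TruthSnp]:
        return {
            (s.contig, s.genome_pos): s
            for snps in self.snps_by_gene.values()
            for s in snps
        }

    def isoform_snps(self, isoform_id: str) -> list[TruthSnp]:
        iso = self.isoforms[isoform_id]
        snps = self.snps_by_gene.get(iso.gene_id, [])
        return [
            s
            for s in snps
            if any(e.start <= s.genome_pos < e.end for e in iso.transcript.exons)
        ]

    def haplotype_sequence(
        self, isoform_id: str, haplotype: str, orientation: str = "reference"
    ) -> str:
        """Spliced sequence of one haplotype of an isoform.

        ``orientation`` is "reference" (genome forward strand, the frame of
        pseudo-long reads) or "transcription" (the molecule as sequenced).
        """
        iso = self.isoforms[isoform_id]
        t = iso.transcript
        alleles = {
            s.genome_pos: (s.allele_a if haplotype == "A" else s.allele_b)
            for s in self.snps_by_gene.get(iso.gene_id, [])
        }
        parts = []
        for exon in t.exons:
            chunk = list(self.genome.fetch(t.contig, exon.start, exon.end))
            for gpos, allele in alleles.items():
                if exon.start <= gpos < exon.end:
                    chunk[gpos - exon.start] = allele
            parts.append("".join(chunk))
        seq = "".join(parts)
        if orientation == "transcription" and t.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass
class SimulatedReads:
    long_alignments: list[LongReadAlignment]
    long_fastq: list[tuple[str, str]]  # (read id, transcription-direction seq)
    short_pairs: list[ShortReadPair]
    roi_to_isoform: dict[str, str]


# ---------------------------------------------------------------------------
# Genome and gene models
# ---------------------------------------------------------------------------


def _random_bases(rng, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=n)]


def simulate_genome_and_genes(config: SimulationConfig) -> GroundTruth:
    """Generate the genome, gene models, isoforms and heterozygous SNPs.

    Introns are canonical GT-AG by construction (in transcription
    direction); a configurable fraction is rewritten with a non-canonical
    CC..GG edge to exercise the junction classifier.  Isoforms beyond the
    first skip one distinct internal exon each.
    """
    rng = np.random.default_rng(config.seed)
    sequence: list[str] = []
    cursor = 0
    transcripts: list[AnnotatedTranscript] = []
    isoforms: dict[str, SimulatedIsoform] = {}
    snps_by_gene: dict[str, list[TruthSnp]] = {}
    contig = config.contig_name

    for g in range(config.n_genes):
        gene_id = f"G{g + 1:03d}"
        gap = config.intergenic_gap
        sequence.extend(_random_bases(rng, gap))
        cursor += gap

        single_exon = rng.random() < config.single_exon_fraction
        n_exons = (
            1
            if single_exon
            else int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        )
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        exons: list[GenomicInterval] = []
        for e in range(n_exons):
            if e > 0:
                ilen = int(
                    rng.integers(config.intron_length[0], config.intron_length[1] + 1)
                )
                intron = _random_bases(rng, ilen)
                non_canonical = rng.random() < config.non_canonical_fraction
                if non_canonical:
                    left, right = "CC", "GG"
                elif strand == "+":
                    left, right = "GT", "AG"
                else:
                    left, right = "CT", "AC"  # GT-AG read on the minus strand
                intron[0:2] = list(left)
                intron[-2:] = list(right)
                sequence.extend(intron)
                cursor += ilen
            elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            sequence.extend(_random_bases(rng, elen))
            exons.append(GenomicInterval(contig, cursor, cursor + elen, strand))
            cursor += elen

        max_isoforms = 1 + max(0, n_exons - 2)
        n_iso = min(
            int(rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1)),
            max_isoforms,
        )
        internal = list(range(1, n_exons - 1))
        skips = rng.permutation(internal)[: max(0, n_iso - 1)] if internal else []
        exon_sets = [list(exons)]
        for skip in skips:
            exon_sets.append([e for i, e in enumerate(exons) if i != skip])

        for k, exon_set in enumerate(exon_sets):
            iso_id = f"{gene_id}.I{k + 1}"
            transcript = AnnotatedTranscript(
                transcript_id=iso_id,
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                exons=exon_set,
                biotype="protein_coding",
            )
            transcripts.append(transcript)
            if rng.random() < config.differential_fraction:
                fold = config.differential_fold
                frac = fold / (fold + 1.0)
                if rng.random() < 0.5:
                    frac = 1.0 - frac
            else:
                frac = 0.5
            isoforms[iso_id] = SimulatedIsoform(iso_id, gene_id, transcript, frac)

        exonic = sorted(
            {
                pos
                for e in exons
                for pos in range(e.start + config.snp_edge_margin,
                                 e.end - config.snp_edge_margin)
            }
        )
        exonic_kb = len(exonic) / 1e3
        n_snps = int(rng.poisson(config.snp_rate_per_kb * exonic_kb))
        gene_snps = []
        if n_snps and exonic:
            chosen = rng.choice(len(exonic), size=min(n_snps, len(exonic)), replace=False)
            for idx in sorted(chosen):
                gpos = exonic[idx]
                ref = sequence[gpos]
                alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
                gene_snps.append(TruthSnp(contig, gpos, ref, alt))
        snps_by_gene[gene_id] = gene_snps

    sequence.extend(_random_bases(rng, config.intergenic_gap))
    genome = Genome({contig: GenomeSequence(contig, "".join(sequence))})
    return GroundTruth(genome, transcripts, isoforms, snps_by_gene, config)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def _truncate_3prime(exons: list[GenomicInterval], strand: str, cut: int,
                     min_keep: int = 200) -> list[GenomicInterval]:
    """Remove ``cut`` nt from the 3' end of a transcription-ordered model."""
    total = sum(len(e) for e in exons)
    cut = min(cut, max(0, total - min_keep))
    out = list(exons)
    while cut > 0 and out:
        idx = -1 if strand == "+" else 0
        exon = out[idx]
        if len(exon) <= cut:
            cut -= len(exon)
            out.pop(idx)
        else:
            if strand == "+":
                out[idx] = GenomicInterval(exon.contig, exon.start, exon.end - cut, strand)
            else:
                out[idx] = GenomicInterval(exon.contig, exon.start + cut, exon.end, strand)
            cut = 0
    return out


def _long_read(truth, iso: SimulatedIsoform, haplotype: str, read_id: str,
               rng, config) -> tuple[LongReadAlignment, str]:
    """One ROI: haplotype bases under the isoform frame, with errors.

    Returns the truth alignment (reference orientation) and the FASTQ
    sequence (transcription orientation).
    """
    t = iso.transcript
    exons = list(t.exons)
    if rng.random() < config.truncation_probability:
        cut = int(rng.exponential(config.truncation_mean))
        if cut:
            exons = _truncate_3prime(exons, t.strand, cut)
    alleles = {
        s.genome_pos: (s.allele_a if haplotype == "A" else s.allele_b)
        for s in truth.snps_by_gene.get(iso.gene_id, [])
    }

    cigar: list[tuple[int, int]] = []
    read_chars: list[str] = []

    def add(code: int, length: int = 1):
        if cigar and cigar[-1][0] == code:
            cigar[-1] = (code, cigar[-1][1] + length)
        else:
            cigar.append((code, length))

    prev_end = None
    for exon in exons:
        if prev_end is not None:
            add(3, exon.start - prev_end)
        n = len(exon)
        for i in range(n):
            gpos = exon.start + i
            base = alleles.get(gpos, truth.genome.fetch(t.contig, gpos, gpos + 1))
            interior = 0 < i < n - 1
            r = rng.random()
            if interior and r < config.long_deletion_rate:
                add(2)
                continue
            if r < config.long_deletion_rate + config.long_substitution_rate:
                base = _BASES[(_BASES.index(base) + int(rng.integers(1, 4))) % 4]
            read_chars.append(base)
            add(0)
            if interior and rng.random() < config.long_insertion_rate:
                read_chars.append(_BASES[int(rng.integers(0, 4))])
                add(1)
        prev_end = exon.end

    seq_ref = "".join(read_chars)
    aln = LongReadAlignment(
        read_id=read_id,
        contig=t.contig,
        strand=t.strand,
        blocks=_cigar_to_blocks(cigar, exons[0].start),
        read_sequence=seq_ref,
    )
    fastq_seq = seq_ref if t.strand == "+" else reverse_complement(seq_ref)
    return aln, fastq_seq


def _genomic_positions(exons: list[GenomicInterval]) -> np.ndarray:
    return np.concatenate(
        [np.arange(e.start, e.end, dtype=np.int64) for e in exons]
    )


def _mate_alignment(gpos_slice: np.ndarray, contig: str, strand: str) -> ShortReadAlignment:
    """Splice-aware truth alignment of one mate from its genomic positions.

    Read coordinates refer to the alignment orientation (ascending genome),
    matching what a SAM record would carry.
    """
    from .genomic_io import AlignedBlock

    order = np.sort(gpos_slice)
    blocks = []
    run_start = 0
    for i in range(1, len(order) + 1):
        if i == len(order) or order[i] != order[i - 1] + 1:
            blocks.append(
                AlignedBlock("M", run_start, i, int(order[run_start]),
                             int(order[i - 1]) + 1)
            )
            run_start = i
    return ShortReadAlignment(reference=contig, strand=strand, blocks=blocks)


def _add_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        chars[i] = _BASES[(_BASES.index(chars[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def _short_pairs_for(
    truth, iso: SimulatedIsoform, haplotype: str, fragments: list[tuple[int, int]],
    rng, config, start_index: int,
) -> list[ShortReadPair]:
    """Build read pairs for given (start, length) fragments on one haplotype."""
    t = iso.transcript
    rl = config.short_read_length
    hap_seq = truth.haplotype_sequence(iso.isoform_id, haplotype, "transcription")
    gpos = _genomic_positions(t.exons)
    if t.strand == "-":
        gpos = gpos[::-1]  # transcription order
    pairs = []
    for n, (start, frag) in enumerate(fragments, start=start_index):
        end = start + frag
        t1 = hap_seq[start : start + rl]
        t2 = hap_seq[end - rl : end]
        read1 = _add_errors(t1, config.short_error_rate, rng)
        read2 = _add_errors(reverse_complement(t2), config.short_error_rate, rng)
        pair_id = f"sp_{iso.isoform_id}_{haplotype}_{n}"
        strand1 = "+" if t.strand == "+" else "-"
        strand2 = "-" if t.strand == "+" else "+"
        aln1 = _mate_alignment(gpos[start : start + rl], t.contig, strand1)
        aln2 = _mate_alignment(gpos[end - rl : end], t.contig, strand2)
        pairs.append(
            ShortReadPair(
                pair_id=pair_id,
                sequence1=read1,
                sequence2=read2,
                alignments1=[aln1],
                alignments2=[aln2],
            )
        )
        truth.read_origin[pair_id] = (iso.isoform_id, haplotype)
    return pairs


def simulate_reads(truth: GroundTruth, config: SimulationConfig | None = None) -> SimulatedReads:
    """Draw long reads and short read pairs with truth alignments.

    Long reads are drawn per isoform at the configured allele ratio with the
    configured error and 3'-truncation profile.  Short-read fragments are
    placed uniformly ("sampled") or on a fixed stride over both haplotypes
    ("tiling").
    """
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if not truth.isoforms:
        raise ValueError("nothing to express: no isoforms simulated")

    long_alignments = []
    long_fastq = []
    short_pairs = []
    roi_to_isoform = {}
    rl = config.short_read_length

    for iso_id in sorted(truth.isoforms):
        iso = truth.isoforms[iso_id]
        t = iso.transcript
        tlen = sum(len(e) for e in t.exons)

        n_long = config.long_reads_per_isoform
        n_a = int(rng.binomial(n_long, iso.fraction_a))
        for n in range(n_long):
            hap = "A" if n < n_a else "B"
            read_id = f"roi_{iso_id}_{n}"
            aln, fastq_seq = _long_read(truth, iso, hap, read_id, rng, config)
            long_alignments.append(aln)
            long_fastq.append((read_id, fastq_seq))
            roi_to_isoform[read_id] = iso_id
            truth.read_origin[read_id] = (iso_id, hap)

        if config.short_read_mode == "tiling":
            frag = min(tlen, int(config.insert_size_mean))
            starts = list(range(0, max(1, tlen - frag + 1), config.tiling_stride))
            fragments = [(s, frag) for s in starts]
            short_pairs.extend(
                _short_pairs_for(truth, iso, "A", fragments, rng, config, 0)
            )
            short_pairs.extend(
                _short_pairs_for(truth, iso, "B", fragments, rng, config, 0)
            )
        else:
            n_pairs = int(round(config.short_coverage * tlen / (2 * rl)))
            n_pairs_a = int(rng.binomial(n_pairs, iso.fraction_a))
            for hap, n_hap, offset in (("A", n_pairs_a, 0),
                                       ("B", n_pairs - n_pairs_a, n_pairs_a)):
                fragments = []
                for _ in range(n_hap):
                    frag = int(
                        np.clip(
                            rng.normal(config.insert_size_mean, config.insert_size_sd),
                            rl,
                            tlen,
                        )
                    )
                    start = int(rng.integers(0, tlen - frag + 1))
                    fragments.append((start, frag))
                short_pairs.extend(
                    _short_pairs_for(truth, iso, hap, fragments, rng, config, offset)
                )

    return SimulatedReads(long_alignments, long_fastq, short_pairs, roi_to_isoform)


# ---------------------------------------------------------------------------
# Truth-derived pipeline inputs
# ---------------------------------------------------------------------------


def isoform_alignments(truth: GroundTruth) -> list[LongReadAlignment]:
    """Perfect genome alignments of the clustered isoform models themselves.

    These stand in for the aligned full-length high-quality consensus
    sequences that enter classification (read id = isoform id).
    """
    out = []
    for iso_id in sorted(truth.isoforms):
        t = truth.isoforms[iso_id].transcript
        cigar: list[tuple[int, int]] = []
        prev_end = None
        for exon in t.exons:
            if prev_end is not None:
                cigar.append((3, exon.start - prev_end))
            cigar.append((0, len(exon)))
            prev_end = exon.end
        seq = "".join(truth.genome.fetch(t.contig, e.start, e.end) for e in t.exons)
        out.append(
            LongReadAlignment(
                read_id=iso_id,
                contig=t.contig,
                strand=t.strand,
                blocks=_cigar_to_blocks(cigar, t.exons[0].start),
                read_sequence=seq,
            )
        )
    return out


def truth_gene_clusters(truth: GroundTruth) -> dict[str, list[IsoformModel]]:
    """Isoform models grouped per gene, as the classifier would supply them."""
    clusters: dict[str, list[IsoformModel]] = {}
    for iso in truth.isoforms.values():
        model = IsoformModel(
            isoform_id=iso.isoform_id,
            contig=iso.transcript.contig,
            strand=iso.transcript.strand,
            exons=list(iso.transcript.exons),
            fl_count=truth.config.long_reads_per_isoform,
            accuracy=truth.config.cluster_accuracy,
        )
        clusters.setdefault(iso.gene_id, []).append(model)
    return clusters


def truth_haplotype_pairs(truth: GroundTruth) -> dict[str, HaplotypePair]:
    """Ground-truth haplotype pairs (haplotype A = reference alleles)."""
    out = {}
    for iso_id in sorted(truth.isoforms):
        snps = truth.isoform_snps(iso_id)
        if len(snps) < 2:
            continue
        positions = [s.genome_pos for s in snps]
        out[iso_id] = HaplotypePair(
            isoform_id=iso_id,
            contig=truth.isoforms[iso_id].transcript.contig,
            positions=positions,
            haplotype_a="".join(s.allele_a for s in snps),
            haplotype_b="".join(s.allele_b for s in snps),
            phased=True,
        )
    return out


# ---------------------------------------------------------------------------
# Ground-truth evaluation
# ---------------------------------------------------------------------------


def snp_recall(truth: GroundTruth, result, min_depth: int = 4) -> tuple[int, int]:
    """(called, qualified) heterozygous SNPs among truth sites with adequate
    short-read depth.

    A truth SNP qualifies when the deepest pileup observed across the
    pseudo-long reads covering it reaches ``min_depth``; it counts as called
    when the unified SNP set contains a reliable site at its position with
    the correct allele pair.
    """
    called = qualified = 0
    for (contig, gpos), snp in sorted(truth.snp_by_pos.items()):
        if result.max_depth_at(contig, gpos) < min_depth:
            continue
        qualified += 1
        pair = result.registry.alleles(contig, gpos)
        if pair == frozenset({snp.allele_a, snp.allele_b}):
            called += 1
    return called, qualified


def phased_isoform_accuracy(truth: GroundTruth, result) -> tuple[int, int]:
    """(exact, phased) isoforms whose haplotype pair matches the truth.

    A phased isoform is exact when every reported SNP position is a true
    heterozygous site of that isoform and the two reported allele strings
    equal the true haplotype strings over those positions (in either order).
    """
    exact = phased = 0
    for pair in result.haplotypes:
        if not pair.phased:
            continue
        phased += 1
        if pair.isoform_id not in truth.isoforms:
            continue
        by_pos = {s.genome_pos: s for s in truth.isoform_snps(pair.isoform_id)}
        if not all(g in by_pos for g in pair.positions):
            continue
        a = "".join(by_pos[g].allele_a for g in pair.positions)
        b = "".join(by_pos[g].allele_b for g in pair.positions)
        if (pair.haplotype_a, pair.haplotype_b) in ((a, b), (b, a)):
            exact += 1
    return exact, phased


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tables(truth: GroundTruth, snp_path, origin_path, ratio_path) -> None:
    with open(snp_path, "w") as fh:
        fh.write("gene_id\tcontig\tpos\tallele_a\tallele_b\n")
        for gene_id in sorted(truth.snps_by_gene):
            for s in truth.snps_by_gene[gene_id]:
                fh.write(
                    f"{gene_id}\t{s.contig}\t{s.genome_pos + 1}\t"
                    f"{s.allele_a}\t{s.allele_b}\n"
                )
    with open(origin_path, "w") as fh:
        fh.write("read_id\tisoform_id\thaplotype\n")
        for read_id in sorted(truth.read_origin):
            iso, hap = truth.read_origin[read_id]
            fh.write(f"{read_id}\t{iso}\t{hap}\n")
    with open(ratio_path, "w") as fh:
        fh.write("isoform_id\tgene_id\tfraction_a\n")
        for iso_id in sorted(truth.isoforms):
            iso = truth.isoforms[iso_id]
            fh.write(f"{iso_id}\t{iso.gene_id}\t{iso.fraction_a:.4f}\n")
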