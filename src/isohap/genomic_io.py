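"""Readers, writers and the coordinate model shared by every stage.

All coordinates are 0-based half-open internally; conversion to and from the
1-based inclusive conventions of GTF/SAM happens only at file boundaries.
FASTA parsing goes through Biopython, GTF through gffutils and SAM/BAM through
pysam; this module wraps them in the small set of domain types the rest of the
toolkit consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pysam
from Bio import SeqIO

logger = logging.getLogger("isohap")

#: Genome gaps at least this long in an alignment are introns, not deletions.
#: Mirrors the minimum intron length used when the long reads were mapped.
MIN_INTRON_LENGTH = 25

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string (involution: rc(rc(s)) == s)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when parsed records violate a domain invariant."""


# ---------------------------------------------------------------------------
# Sequence and interval types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """One contig: an uppercase nucleotide string over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """The single uppercase base at a 0-based position."""
        return self.sequence[position]

    def fetch(self, start: int, end: int) -> str:
        if not (0 <= start <= end <= len(self.sequence)):
            raise ValidationError(
                f"{self.name}: fetch [{start},{end}) outside contig of length "
                f"{len(self.sequence)}"
            )
        return self.sequence[start:end]


class Genome(dict):
    """Mapping of contig name to :class:`GenomeSequence`."""

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self[contig].fetch(start, end)


def read_genome(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased and U is normalised to T.  Duplicate contig
    names are a parse error.
    """
    genome = Genome()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ParseError(f"duplicate FASTA record name: {record.id}")
        seq = str(record.seq).upper().replace("U", "T")
        genome[record.id] = GenomeSequence(record.id, seq)
    return genome


def write_fasta(records, path) -> None:
    """Write (name, sequence) pairs as FASTA, sorted by name."""
    with open(path, "w") as fh:
        for name, seq in sorted(records):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand of a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"empty interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# ---------------------------------------------------------------------------
# Transcript annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedTranscript:
    """A transcript model from the annotation: ordered exons on one strand.

    Exons are stored sorted by genomic start and must not overlap; the gaps
    between consecutive exons are the introns.  The annotated transcription
    start site (aTSS) is the first nucleotide in transcription direction and
    the annotated transcription termination site (aTTS) the last.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[GenomicInterval]
    biotype: str = ""

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
            if b.start - a.end < 1:
                raise ValidationError(
                    f"{self.transcript_id}: zero-length intron between exons"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def atss(self) -> int:
        """Genomic 0-based coordinate of the first transcribed nucleotide."""
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def atts(self) -> int:
        """Genomic 0-based coordinate of the last transcribed nucleotide."""
        if self.strand == "+":
            return self.exons[-1].end - 1
        return self.exons[0].start

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.contig, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (start, end) pairs of the introns; the collapse/match key."""
        return tuple((i.start, i.end) for i in self.introns)

    @property
    def splice_sites(self) -> frozenset[int]:
        """Genomic coordinates of all intron boundaries (donors + acceptors)."""
        sites = set()
        for i in self.introns:
            sites.add(i.start)
            sites.add(i.end)
        return frozenset(sites)

    def spliced_sequence(self, genome: Genome) -> str:
        """Exon-concatenated sequence in transcription direction."""
        seq = "".join(genome.fetch(self.contig, e.start, e.end) for e in self.exons)
        return seq if self.strand == "+" else reverse_complement(seq)


def read_annotation(path) -> list[AnnotatedTranscript]:
    """Read a GENCODE-dialect GTF into transcripts, one per transcript_id.

    Only ``exon`` features are used.  1-based inclusive GTF coordinates are
    converted to 0-based half-open.  An exon feature without a transcript_id
    is a parse error; overlapping exons within a transcript are a validation
    error.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"cannot parse GTF {path}: {exc}") from exc

    by_transcript: dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        attrs = feat.attributes
        if "transcript_id" not in attrs:
            raise ParseError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks transcript_id"
            )
        tid = attrs["transcript_id"][0]
        gene = attrs.get("gene_id", [tid])[0]
        biotype = (
            attrs.get("transcript_biotype", attrs.get("transcript_type", [""]))[0]
            or attrs.get("gene_biotype", attrs.get("gene_type", [""]))[0]
        )
        rec = by_transcript.setdefault(
            tid,
            {"gene": gene, "contig": feat.seqid, "strand": feat.strand, "exons": [],
             "biotype": biotype},
        )
        rec["exons"].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    return [
        AnnotatedTranscript(
            transcript_id=tid,
            gene_id=rec["gene"],
            contig=rec["contig"],
            strand=rec["strand"],
            exons=rec["exons"],
            biotype=rec["biotype"],
        )
        for tid, rec in by_transcript.items()
    ]


def write_annotation(transcripts, path) -> None:
    """Write transcripts as GTF exon features in deterministic order."""
    rows = sorted(
        transcripts, key=lambda t: (t.contig, t.span.start, t.transcript_id)
    )
    with open(path, "w") as fh:
        for t in rows:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                )
                if t.biotype:
                    attrs += f' transcript_biotype "{t.biotype}";'
                fh.write(
                    f"{t.contig}\tisohap\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

#: Block operations: M consumes read and genome, I only read, D and N only
#: genome.  N is an intron skip (genome gap >= MIN_INTRON_LENGTH).
OP_MATCH = "M"
OP_INSERTION = "I"
OP_DELETION = "D"
OP_INTRON = "N"


@dataclass(frozen=True)
class AlignedBlock:
    op: str
    read_start: int
    read_end: int
    genome_start: int
    genome_end: int

    @property
    def read_length(self) -> int:
        return self.read_end - self.read_start

    @property
    def genome_length(self) -> int:
        return self.genome_end - self.genome_start


@dataclass
class LongReadAlignment:
    """One primary alignment of a long read (ROI) to the genome."""

    read_id: str
    contig: str
    strand: str
    blocks: list[AlignedBlock]
    read_sequence: str
    is_unique: bool = True
    mapping_quality: int = 60

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig,
            self.blocks[0].genome_start,
            self.blocks[-1].genome_end,
            self.strand,
        )

    @property
    def exons(self) -> list[GenomicInterval]:
        """Genomic exons: maximal runs of M/I/D blocks between intron skips."""
        exons, cur_start, cur_end = [], None, None
        for b in self.blocks:
            if b.op == OP_INTRON:
                if cur_start is not None:
                    exons.append(
                        GenomicInterval(self.contig, cur_start, cur_end, self.strand)
                    )
                cur_start = cur_end = None
                continue
            if b.genome_length == 0 and b.op == OP_INSERTION:
                continue
            if cur_start is None:
                cur_start = b.genome_start
            cur_end = b.genome_end
        if cur_start is not None:
            exons.append(GenomicInterval(self.contig, cur_start, cur_end, self.strand))
        return exons


def _cigar_to_blocks(cigartuples, genome_start: int) -> list[AlignedBlock]:
    blocks = []
    rpos, gpos = 0, genome_start
    for op, length in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            blocks.append(AlignedBlock(OP_MATCH, rpos, rpos + length, gpos, gpos + length))
            rpos += length
            gpos += length
        elif op in (1, 4):  # I, S: read bases not aligned to the genome
            blocks.append(AlignedBlock(OP_INSERTION, rpos, rpos + length, gpos, gpos))
            rpos += length
        elif op == 2:  # D
            blocks.append(AlignedBlock(OP_DELETION, rpos, rpos, gpos, gpos + length))
            gpos += length
        elif op == 3:  # N
            kind = OP_INTRON if length >= MIN_INTRON_LENGTH else OP_DELETION
            blocks.append(AlignedBlock(kind, rpos, rpos, gpos, gpos + length))
            gpos += length
        elif op in (5, 6):  # H, P: consume nothing we track
            continue
        else:
            raise ParseError(f"unsupported CIGAR op code {op}")
    return blocks


def _blocks_to_cigar(blocks) -> list[tuple[int, int]]:
    out = []
    for b in blocks:
        if b.op == OP_MATCH:
            code, length = 0, b.read_length
        elif b.op == OP_INSERTION:
            code, length = 1, b.read_length
        elif b.op == OP_DELETION:
            code, length = 2, b.genome_length
        else:
            code, length = 3, b.genome_length
        if out and out[-1][0] == code:
            out[-1] = (code, out[-1][1] + length)
        else:
            out.append((code, length))
    return out


def read_long_read_alignments(path) -> list[LongReadAlignment]:
    """Read primary long-read alignments from SAM/BAM.

    A read is flagged non-unique when any of its records is secondary or
    supplementary, or when its primary record has mapping quality 0.  Records
    whose CIGAR does not account for the full read sequence are skipped with
    a warning.
    """
    multi: set[str] = set()
    primaries = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.is_secondary or rec.is_supplementary:
                multi.add(rec.query_name)
                continue
            primaries.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    "-" if rec.is_reverse else "+",
                    rec.cigartuples,
                    rec.reference_start,
                    rec.query_sequence or "",
                    rec.mapping_quality,
                )
            )
    out = []
    for name, contig, strand, cigar, start, seq, mapq in primaries:
        blocks = _cigar_to_blocks(cigar, start)
        read_len = sum(b.read_length for b in blocks)
        if seq and read_len != len(seq):
            logger.warning(
                "read %s: CIGAR covers %d bases but sequence has %d; skipped",
                name, read_len, len(seq),
            )
            continue
        out.append(
            LongReadAlignment(
                read_id=name,
                contig=contig,
                strand=strand,
                blocks=blocks,
                read_sequence=seq,
                is_unique=(name not in multi and mapq > 0),
                mapping_quality=mapq,
            )
        )
    return out


def _sam_header(contig_lengths: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in sorted(contig_lengths.items())
            ],
        }
    )


def write_long_read_alignments(alignments, path, contig_lengths: dict[str, int]) -> None:
    """Write alignments as a SAM file sorted by (contig, start, read id)."""
    header = _sam_header(contig_lengths)
    rows = sorted(alignments, key=lambda a: (a.contig, a.span.start, a.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in rows:
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.read_id
            rec.query_sequence = aln.read_sequence or None
            rec.reference_name = aln.contig
            rec.reference_start = aln.blocks[0].genome_start
            rec.cigartuples = _blocks_to_cigar(aln.blocks)
            rec.mapping_quality = aln.mapping_quality
            rec.flag = 16 if aln.strand == "-" else 0
            out.write(rec)


@dataclass
class ShortReadAlignment:
    """One alignment of one mate, to the genome or to a pseudo-long read."""

    reference: str
    strand: str
    blocks: list[AlignedBlock]

    @property
    def reference_start(self) -> int:
        return self.blocks[0].genome_start

    @property
    def reference_end(self) -> int:
        return self.blocks[-1].genome_end

    def match_blocks(self):
        return [b for b in self.blocks if b.op == OP_MATCH]


@dataclass
class ShortReadPair:
    """A read pair: both mates carry the same pair id."""

    pair_id: str
    sequence1: str
    sequence2: str
    alignments1: list[ShortReadAlignment] = field(default_factory=list)
    alignments2: list[ShortReadAlignment] = field(default_factory=list)


def read_short_read_alignments(path) -> list[ShortReadPair]:
    """Read paired short-read alignments from SAM/BAM, grouped by pair id.

    Mate 1/2 is taken from the FLAG; unpaired records are treated as mate 1.
    Sequences are stored in the orientation of the original read (reverse
    alignments are flipped back).
    """
    pairs: dict[str, ShortReadPair] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            pair = pairs.setdefault(rec.query_name, ShortReadPair(rec.query_name, "", ""))
            mate2 = rec.is_paired and rec.is_read2
            seq = rec.query_sequence or ""
            strand = "-" if rec.is_reverse else "+"
            if rec.is_reverse:
                seq = reverse_complement(seq)
            if mate2:
                pair.sequence2 = pair.sequence2 or seq
            else:
                pair.sequence1 = pair.sequence1 or seq
            if rec.is_unmapped:
                continue
            aln = ShortReadAlignment(
                reference=rec.reference_name,
                strand=strand,
                blocks=_cigar_to_blocks(rec.cigartuples, rec.reference_start),
            )
            (pair.alignments2 if mate2 else pair.alignments1).append(aln)
    return sorted(pairs.values(), key=lambda p: p.pair_id)


def write_short_read_alignments(pairs, path, contig_lengths: dict[str, int]) -> None:
    """Write pairs as SAM; aligned mates only, deterministic order."""
    header = _sam_header(contig_lengths)
    rows = []
    for pair in pairs:
        for mate, seq, alns in (
            (1, pair.sequence1, pair.alignments1),
            (2, pair.sequence2, pair.alignments2),
        ):
            for aln in alns:
                rows.append((aln.reference, aln.reference_start, pair.pair_id, mate, seq, aln))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ref, start, pid, mate, seq, aln in rows:
            rec = pysam.AlignedSegment(header)
            rec.query_name = pid
            rec.flag = 0x1 | (0x40 if mate == 1 else 0x80)
            if aln.strand == "-":
                rec.flag |= 0x10
                seq = reverse_complement(seq)
            rec.query_sequence = seq or None
            rec.reference_name = ref
            rec.reference_start = start
            rec.cigartuples = _blocks_to_cigar(aln.blocks)
            rec.mapping_quality = 60
            out.write(rec)
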