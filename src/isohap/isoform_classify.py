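"""Full-length isoform classification, collapsing and completeness analysis.

Pipeline order: cluster quality filtering -> single/multi-exon split ->
splice-junction canonicality -> gene attribution (CSMM / Non-CSMM / Novel) ->
exact intron-chain matching against the annotation -> collapsing of
equivalent molecules -> distances to annotated transcript start/termination
sites (aTSS/aTTS) for CSMMs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .genomic_io import (
    AnnotatedTranscript,
    Genome,
    GenomicInterval,
    LongReadAlignment,
    ValidationError,
    reverse_complement,
)

#: Splice-junction motifs considered canonical, read in transcription
#: direction as (donor dinucleotide, acceptor dinucleotide).
CANONICAL_MOTIFS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})

#: Maximum 5'/3' end difference (nt, inclusive) for two molecules with the
#: same intron chain to be collapsed into one transcript.
END_TOLERANCE = 200

#: Transcript biotypes retained for the completeness (aTSS/aTTS) analysis.
COMPLETENESS_BIOTYPES = frozenset(
    {
        "protein_coding",
        "processed_transcript",
        "retained_intron",
        "nonsense_mediated_decay",
        "processed_pseudogene",
        "lncRNA",
    }
)

SINGLE_EXON = "single_exon"
MULTI_EXON = "multi_exon"
ME_CANONICAL = "ME_canonical"
ME_NON_CANONICAL = "ME_non_canonical"
NOT_APPLICABLE = "not_applicable"
CSMM = "CSMM"
NON_CSMM = "Non_CSMM"
NOVEL = "Novel"


@dataclass
class IsoformModel:
    """One long-read-derived isoform with its cluster metadata."""

    isoform_id: str
    contig: str
    strand: str
    exons: list[GenomicInterval]
    roi_ids: set[str] = field(default_factory=set)
    fl_count: int = 0
    accuracy: float = 1.0

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"{self.isoform_id}: empty exon chain")
        self.exons = sorted(self.exons, key=lambda e: e.start)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.contig, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((i.start, i.end) for i in self.introns)

    @property
    def splice_sites(self) -> frozenset[int]:
        sites = set()
        for i in self.introns:
            sites.add(i.start)
            sites.add(i.end)
        return frozenset(sites)

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def start_in_transcription_direction(self) -> int:
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end - 1

    @property
    def end_in_transcription_direction(self) -> int:
        return self.exons[-1].end - 1 if self.strand == "+" else self.exons[0].start


def isoform_from_alignment(aln: LongReadAlignment, **meta) -> IsoformModel:
    """Build an isoform model from a long-read alignment's exon structure."""
    return IsoformModel(
        isoform_id=meta.pop("isoform_id", aln.read_id),
        contig=aln.contig,
        strand=aln.strand,
        exons=aln.exons,
        **meta,
    )


@dataclass(frozen=True)
class SpliceJunction:
    """One intron with its edge dinucleotides in transcription direction."""

    donor: int
    acceptor: int
    strand: str
    donor_motif: str
    acceptor_motif: str

    @property
    def canonical(self) -> bool:
        return (self.donor_motif, self.acceptor_motif) in CANONICAL_MOTIFS


@dataclass
class ClassificationRecord:
    isoform_id: str
    exon_class: str
    junction_class: str = NOT_APPLICABLE
    attribution: str | None = None
    gene_id: str | None = None
    matched_transcripts: list[str] = field(default_factory=list)
    ambiguous_match: bool = False
    dist_atss: int | None = None
    dist_atts: int | None = None


# ---------------------------------------------------------------------------
# Cluster quality filtering
# ---------------------------------------------------------------------------

HIGH_QUALITY_MIN_FL = 2
HIGH_QUALITY_MIN_ACCURACY = 0.99
CONSENSUS_MIN_ACCURACY = 0.95


def filter_quality(clusters) -> tuple[list, list, list]:
    """Split isoform clusters into high-quality, consensus-only and rejected.

    High quality requires at least two full-length supporting reads and
    predicted accuracy >= 99%.  Consensus requires at least one full-length
    read and accuracy in the 95-99% band; a cluster with a single full-length
    read and accuracy >= 99% also only reaches consensus level, because the
    full-length-support requirement dominates.
    """
    high, consensus, rejected = [], [], []
    for c in clusters:
        if not (0.0 <= c.accuracy <= 1.0):
            raise ValidationError(
                f"{c.isoform_id}: accuracy {c.accuracy} outside [0,1]"
            )
        if c.fl_count >= HIGH_QUALITY_MIN_FL and c.accuracy >= HIGH_QUALITY_MIN_ACCURACY:
            high.append(c)
        elif c.fl_count >= 1 and c.accuracy >= CONSENSUS_MIN_ACCURACY:
            consensus.append(c)
        else:
            rejected.append(c)
    return high, consensus, rejected


# ---------------------------------------------------------------------------
# Exon structure and splice junctions
# ---------------------------------------------------------------------------


def classify_exon_structure(isoform: IsoformModel) -> str:
    return MULTI_EXON if len(isoform.exons) >= 2 else SINGLE_EXON


def extract_junctions(isoform: IsoformModel, genome: Genome) -> list[SpliceJunction]:
    """One junction per intron, motifs read in transcription direction.

    On the minus strand the donor side of the junction lies at the genomic
    *end* of the intron, and both dinucleotides are reverse-complemented.
    """
    from .genomic_io import MIN_INTRON_LENGTH

    junctions = []
    for intron in isoform.introns:
        if len(intron) < MIN_INTRON_LENGTH:
            raise ValidationError(
                f"{isoform.isoform_id}: intron of {len(intron)} nt shorter than "
                f"minimum intron length {MIN_INTRON_LENGTH}"
            )
        left = genome.fetch(isoform.contig, intron.start, intron.start + 2)
        right = genome.fetch(isoform.contig, intron.end - 2, intron.end)
        if isoform.strand == "+":
            donor_motif, acceptor_motif = left, right
        else:
            donor_motif = reverse_complement(right)
            acceptor_motif = reverse_complement(left)
        junctions.append(
            SpliceJunction(
                donor=intron.start,
                acceptor=intron.end,
                strand=isoform.strand,
                donor_motif=donor_motif,
                acceptor_motif=acceptor_motif,
            )
        )
    return junctions


def classify_junctions(junctions) -> str:
    """ME_canonical iff every junction motif is canonical."""
    if not junctions:
        raise ValidationError("no junctions to classify")
    return ME_CANONICAL if all(j.canonical for j in junctions) else ME_NON_CANONICAL


# ---------------------------------------------------------------------------
# Gene attribution and transcript matching
# ---------------------------------------------------------------------------


class AnnotationIndex:
    """Per-gene splice sites, spans and intron chains from an annotation."""

    def __init__(self, transcripts):
        self.transcripts = list(transcripts)
        self.gene_sites: dict[tuple, dict[str, set[int]]] = defaultdict(dict)
        self.gene_spans: dict[tuple, dict[str, tuple[int, int]]] = defaultdict(dict)
        self.gene_transcripts: dict[str, list[AnnotatedTranscript]] = defaultdict(list)
        self.chain_index: dict[tuple, list[str]] = defaultdict(list)
        for t in self.transcripts:
            key = (t.contig, t.strand)
            sites = self.gene_sites[key].setdefault(t.gene_id, set())
            sites.update(t.splice_sites)
            lo, hi = t.span.start, t.span.end
            if t.gene_id in self.gene_spans[key]:
                a, b = self.gene_spans[key][t.gene_id]
                lo, hi = min(lo, a), max(hi, b)
            self.gene_spans[key][t.gene_id] = (lo, hi)
            self.gene_transcripts[t.gene_id].append(t)
            if t.intron_chain:
                self.chain_index[(key, t.intron_chain)].append(t.transcript_id)


def attribute_to_gene(
    isoform: IsoformModel, index: AnnotationIndex
) -> tuple[str, str | None]:
    """Attribute a multi-exon canonical isoform to an annotated gene.

    CSMM: shares at least one splice site with a spliced transcript of the
    gene; among several genes the one sharing most sites wins, ties broken by
    largest genomic overlap with the gene span, then smallest gene id.
    Non-CSMM: no shared site but the isoform span overlaps a same-strand gene
    locus (largest overlap wins).  Novel: neither.
    """
    key = (isoform.contig, isoform.strand)
    iso_sites = isoform.splice_sites
    span = isoform.span

    def overlap(gene_id: str) -> int:
        lo, hi = index.gene_spans[key][gene_id]
        return max(0, min(span.end, hi) - max(span.start, lo))

    shared = {
        g: len(iso_sites & sites)
        for g, sites in index.gene_sites.get(key, {}).items()
        if iso_sites & sites
    }
    if shared:
        best = max(shared.items(), key=lambda kv: (kv[1], overlap(kv[0]), _neg_id(kv[0])))
        return CSMM, best[0]

    overlapping = {
        g: overlap(g)
        for g in index.gene_spans.get(key, {})
        if overlap(g) > 0
    }
    if overlapping:
        best = max(overlapping.items(), key=lambda kv: (kv[1], _neg_id(kv[0])))
        return NON_CSMM, best[0]
    return NOVEL, None


class _neg_id(str):
    """Order-reversing wrapper so max() picks the lexicographically smallest id."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def match_annotated_transcript(
    isoform: IsoformModel, index: AnnotationIndex
) -> tuple[list[str], bool]:
    """Transcripts whose intron chain is identical to the isoform's.

    Returns (matching transcript ids, ambiguous flag).  Single-exon isoforms
    have no intron chain and never match.
    """
    if len(isoform.exons) < 2:
        return [], False
    key = (isoform.contig, isoform.strand)
    matches = sorted(index.chain_index.get((key, isoform.intron_chain), []))
    return matches, len(matches) > 1


# ---------------------------------------------------------------------------
# Collapsing
# ---------------------------------------------------------------------------


def _ends_close(a: IsoformModel, b: IsoformModel, tolerance: int) -> bool:
    return (
        abs(a.exons[0].start - b.exons[0].start) <= tolerance
        and abs(a.exons[-1].end - b.exons[-1].end) <= tolerance
    )


def collapse_equivalent(isoforms, tolerance: int = END_TOLERANCE) -> list[IsoformModel]:
    """Collapse molecules with identical intron chains and close ends.

    Two molecules are equivalent when they share the composition and
    structure of all introns and their 5' and 3' ends each differ by at most
    ``tolerance`` nt; classes are the connected components of this pairwise
    relation (single linkage).  Each class is reported once, represented by
    its longest member, with supporting-read sets unioned, full-length counts
    summed and the best accuracy retained.
    """
    by_chain: dict[tuple, list[IsoformModel]] = defaultdict(list)
    for iso in isoforms:
        by_chain[(iso.contig, iso.strand, iso.intron_chain)].append(iso)

    out = []
    for _, members in sorted(by_chain.items()):
        members = sorted(members, key=lambda m: m.isoform_id)
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if _ends_close(members[i], members[j], tolerance):
                    parent[find(i)] = find(j)
        groups: dict[int, list[IsoformModel]] = defaultdict(list)
        for i, m in enumerate(members):
            groups[find(i)].append(m)
        for group in groups.values():
            rep = max(group, key=lambda m: (m.length, m.isoform_id))
            out.append(
                IsoformModel(
                    isoform_id=rep.isoform_id,
                    contig=rep.contig,
                    strand=rep.strand,
                    exons=list(rep.exons),
                    roi_ids=set().union(*(m.roi_ids for m in group)),
                    fl_count=sum(m.fl_count for m in group),
                    accuracy=max(m.accuracy for m in group),
                )
            )
    out.sort(key=lambda m: (m.contig, m.span.start, m.isoform_id))
    return out


def group_novel_loci(isoforms) -> list[list[IsoformModel]]:
    """Group novel isoforms into loci by single-linkage same-strand overlap."""
    by_key: dict[tuple, list[IsoformModel]] = defaultdict(list)
    for iso in isoforms:
        by_key[(iso.contig, iso.strand)].append(iso)
    loci = []
    for _, members in sorted(by_key.items()):
        members.sort(key=lambda m: m.span.start)
        current, current_end = [], None
        for iso in members:
            if current and iso.span.start < current_end:
                current.append(iso)
                current_end = max(current_end, iso.span.end)
            else:
                if current:
                    loci.append(current)
                current, current_end = [iso], iso.span.end
        if current:
            loci.append(current)
    return loci


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------


def completeness_distances(
    isoform: IsoformModel,
    gene_transcripts,
    biotypes: frozenset[str] | None = COMPLETENESS_BIOTYPES,
) -> tuple[int | None, int | None]:
    """Distances of a CSMM to the nearest aTSS and aTTS of its gene.

    The aTSS distance is the minimal downstream distance (in transcription
    direction) from any same-strand transcript's start site to the isoform's
    start; the aTTS distance is the minimal upstream distance from the
    isoform's end to any transcript's termination site.  A negative minimum
    means the isoform extends beyond every annotated end and is recorded as
    zero (full length).  Transcripts are restricted to ``biotypes`` when the
    annotation carries biotype tags (pass None to disable the filter).
    """
    candidates = [t for t in gene_transcripts if t.strand == isoform.strand]
    if biotypes is not None:
        filtered = [t for t in candidates if not t.biotype or t.biotype in biotypes]
        candidates = filtered
    if not candidates:
        return None, None
    sign = 1 if isoform.strand == "+" else -1
    iso_start = isoform.start_in_transcription_direction
    iso_end = isoform.end_in_transcription_direction
    d_tss = min(sign * (iso_start - t.atss) for t in candidates)
    d_tts = min(sign * (t.atts - iso_end) for t in candidates)
    return max(0, d_tss), max(0, d_tts)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def classify_isoforms(
    isoforms,
    annotation,
    genome: Genome,
    biotypes: frozenset[str] | None = COMPLETENESS_BIOTYPES,
) -> list[ClassificationRecord]:
    """Run the full classification for a set of (collapsed) isoforms."""
    index = AnnotationIndex(annotation)
    records = []
    for iso in sorted(isoforms, key=lambda m: (m.contig, m.span.start, m.isoform_id)):
        rec = ClassificationRecord(iso.isoform_id, classify_exon_structure(iso))
        if rec.exon_class == MULTI_EXON:
            rec.junction_class = classify_junctions(extract_junctions(iso, genome))
            if rec.junction_class == ME_CANONICAL:
                rec.attribution, rec.gene_id = attribute_to_gene(iso, index)
                rec.matched_transcripts, rec.ambiguous_match = (
                    match_annotated_transcript(iso, index)
                )
                if rec.attribution == CSMM:
                    rec.dist_atss, rec.dist_atts = completeness_distances(
                        iso, index.gene_transcripts[rec.gene_id], biotypes
                    )
        records.append(rec)
    return records


def write_classification_tsv(records, path) -> None:
    header = [
        "isoform_id", "exon_class", "junction_class", "attribution", "gene_id",
        "matched_transcripts", "ambiguous", "dist_atss", "dist_atts",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.isoform_id,
                        r.exon_class,
                        r.junction_class,
                        r.attribution or ".",
                        r.gene_id or ".",
                        ",".join(r.matched_transcripts) or ".",
                        "yes" if r.ambiguous_match else "no",
                        "." if r.dist_atss is None else str(r.dist_atss),
                        "." if r.dist_atts is None else str(r.dist_atts),
                    ]
                )
                + "\n"
            )


def read_cluster_metadata(path) -> dict[str, tuple[int, float]]:
    """Read the cluster metadata TSV: cluster_id, fl_count, accuracy."""
    meta = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "cluster_id":
                continue
            if len(parts) < 3:
                raise ValidationError(f"{path}:{line_no}: expected 3 columns")
            meta[parts[0]] = (int(parts[1]), float(parts[2]))
    return meta
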