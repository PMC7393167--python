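"""Independent brute-force re-implementations used as test oracles.

Everything here is written as plain, explicit loops over all pairs, kept
deliberately separate from the package's indexed implementations.
"""

from isohap.genomic_io import AnnotatedTranscript, GenomicInterval
from isohap.isoform_classify import IsoformModel


def transcript_sites(t: AnnotatedTranscript) -> set[int]:
    sites = set()
    for a, b in zip(t.exons, t.exons[1:]):
        sites.add(a.end)
        sites.add(b.start)
    return sites


def brute_attribute(iso: IsoformModel, transcripts) -> tuple[str, str | None]:
    iso_sites = set()
    for a, b in zip(iso.exons, iso.exons[1:]):
        iso_sites.add(a.end)
        iso_sites.add(b.start)

    span_by_gene: dict[str, list[int]] = {}
    gene_site_union: dict[str, set[int]] = {}
    for t in transcripts:
        if t.contig != iso.contig or t.strand != iso.strand:
            continue
        lo, hi = t.exons[0].start, t.exons[-1].end
        if t.gene_id in span_by_gene:
            span_by_gene[t.gene_id][0] = min(span_by_gene[t.gene_id][0], lo)
            span_by_gene[t.gene_id][1] = max(span_by_gene[t.gene_id][1], hi)
        else:
            span_by_gene[t.gene_id] = [lo, hi]
        gene_site_union.setdefault(t.gene_id, set()).update(transcript_sites(t))

    def overlap(gene_id):
        lo, hi = span_by_gene[gene_id]
        return max(0, min(iso.exons[-1].end, hi) - max(iso.exons[0].start, lo))

    best_gene, best_key = None, None
    for gene_id, sites in gene_site_union.items():
        n = len(iso_sites & sites)
        if n == 0:
            continue
        key = (n, overlap(gene_id))
        if (
            best_key is None
            or key > best_key
            or (key == best_key and gene_id < best_gene)
        ):
            best_gene, best_key = gene_id, key
    if best_gene is not None:
        return "CSMM", best_gene

    best_gene, best_key = None, None
    for gene_id in span_by_gene:
        ov = overlap(gene_id)
        if ov <= 0:
            continue
        if (
            best_key is None
            or ov > best_key
            or (ov == best_key and gene_id < best_gene)
        ):
            best_gene, best_key = gene_id, ov
    if best_gene is not None:
        return "Non_CSMM", best_gene
    return "Novel", None


def brute_match(iso: IsoformModel, transcripts) -> list[str]:
    if len(iso.exons) < 2:
        return []
    chain = [(a.end, b.start) for a, b in zip(iso.exons, iso.exons[1:])]
    out = []
    for t in transcripts:
        if t.contig != iso.contig or t.strand != iso.strand:
            continue
        t_chain = [(a.end, b.start) for a, b in zip(t.exons, t.exons[1:])]
        if t_chain and t_chain == chain:
            out.append(t.transcript_id)
    return sorted(out)


def brute_collapse_partition(isoforms, tolerance: int = 200) -> list[frozenset]:
    """Connected components of the pairwise equivalence relation."""
    isoforms = list(isoforms)
    n = len(isoforms)

    def related(a, b):
        chain_a = [(x.end, y.start) for x, y in zip(a.exons, a.exons[1:])]
        chain_b = [(x.end, y.start) for x, y in zip(b.exons, b.exons[1:])]
        return (
            a.contig == b.contig
            and a.strand == b.strand
            and chain_a == chain_b
            and abs(a.exons[0].start - b.exons[0].start) <= tolerance
            and abs(a.exons[-1].end - b.exons[-1].end) <= tolerance
        )

    seen = [False] * n
    components = []
    for i in range(n):
        if seen[i]:
            continue
        stack, members = [i], set()
        seen[i] = True
        while stack:
            u = stack.pop()
            members.add(isoforms[u].isoform_id)
            for v in range(n):
                if not seen[v] and related(isoforms[u], isoforms[v]):
                    seen[v] = True
                    stack.append(v)
        components.append(frozenset(members))
    return components


def brute_completeness(iso: IsoformModel, transcripts, tolerate_biotypes=None):
    candidates = [t for t in transcripts if t.strand == iso.strand]
    if not candidates:
        return None, None
    best_tss = None
    best_tts = None
    for t in candidates:
        if iso.strand == "+":
            d_tss = iso.exons[0].start - t.exons[0].start
            d_tts = (t.exons[-1].end - 1) - (iso.exons[-1].end - 1)
        else:
            d_tss = (t.exons[-1].end - 1) - (iso.exons[-1].end - 1)
            d_tts = iso.exons[0].start - t.exons[0].start
        if best_tss is None or d_tss < best_tss:
            best_tss = d_tss
        if best_tts is None or d_tts < best_tts:
            best_tts = d_tts
    return max(0, best_tss), max(0, best_tts)


# ---------------------------------------------------------------------------
# Random toy generators
# ---------------------------------------------------------------------------


def random_transcript(rng, contig, strand, tid, gene_id, window=20000):
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, window // 2))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(50, 300))
        exons.append(GenomicInterval(contig, pos, pos + length, strand))
        pos += length + int(rng.integers(30, 400))
    return AnnotatedTranscript(tid, gene_id, contig, strand, exons, "protein_coding")


def random_annotation(rng, n_transcripts=8, contig="toy"):
    transcripts = []
    n_genes = int(rng.integers(1, max(2, n_transcripts // 2 + 1)))
    for i in range(n_transcripts):
        gene = f"g{int(rng.integers(0, n_genes))}"
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            random_transcript(rng, contig, strand, f"t{i}", gene)
        )
    return transcripts


def random_isoform_near(rng, transcripts, contig="toy"):
    """An isoform that may share sites with the annotation, or be intergenic."""
    mode = rng.random()
    if mode < 0.6 and transcripts:
        base = transcripts[int(rng.integers(0, len(transcripts)))]
        exons = []
        for e in base.exons:
            jitter = int(rng.integers(-40, 41))
            start = max(0, e.start + (jitter if rng.random() < 0.4 else 0))
            end = max(start + 20, e.end + (int(rng.integers(-40, 41)) if rng.random() < 0.4 else 0))
            exons.append(GenomicInterval(contig, start, end, base.strand))
        fixed = []
        last_end = -1
        for e in exons:
            start = max(e.start, last_end + 1)
            end = max(e.end, start + 10)
            fixed.append(GenomicInterval(contig, start, end, base.strand))
            last_end = end
        return IsoformModel("iso", contig, base.strand, fixed, roi_ids={"iso"},
                            fl_count=2, accuracy=1.0)
    strand = "+" if rng.random() < 0.5 else "-"
    t = random_transcript(rng, contig, strand, "iso", "iso", window=60000)
    return IsoformModel("iso", contig, strand, list(t.exons), roi_ids={"iso"},
                        fl_count=2, accuracy=1.0)
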