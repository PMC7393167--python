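"""Library-comparison summaries: detection rates, expression bins, coverage.

These are the bookkeeping metrics used to compare sequencing libraries:
isoforms detected per 100k long reads, FPKM-binned detection and read
occupancy, the fraction of each isoform's length covered by short reads, and
the arithmetic of the phasing summary (share of SNP pairs phaseable only by
long reads).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

#: Default FPKM bin edges; the last bin is open-ended.
DEFAULT_FPKM_EDGES = (0.0, 10.0, 50.0, 100.0, 500.0)

COVERAGE_FULL_THRESHOLD = 0.9

COVER_FULL = "full"
COVER_PARTIAL = "partial"
COVER_NONE = "none"


def detection_rate(isoform_count: int, roi_count: int) -> float:
    """Isoforms detected per 100k long reads, rounded to whole isoforms."""
    if roi_count <= 0:
        raise ValueError("ROI count must be positive")
    return round(isoform_count * 1e5 / roi_count)


def detection_rate_fold(rate_a: float, rate_b: float) -> float:
    """Fold difference between two detection rates, 2 decimal places."""
    if rate_b == 0:
        raise ValueError("cannot compute a fold against a zero rate")
    return round(rate_a / rate_b, 2)


def fpkm(fragments: int, transcript_length: int, total_fragments: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if transcript_length <= 0 or total_fragments <= 0:
        raise ValueError("transcript length and library size must be positive")
    return fragments / (transcript_length / 1e3) / (total_fragments / 1e6)


@dataclass
class ExpressionBin:
    low: float
    high: float          # inf for the open top bin
    isoform_count: int = 0
    roi_count: int = 0
    rate: float = 0.0
    occupancy: float = 0.0

    @property
    def label(self) -> str:
        if self.high == float("inf"):
            return f">={self.low:g}"
        return f"[{self.low:g},{self.high:g})"


def bin_by_expression(
    genes: dict[str, float],
    isoforms_per_gene: dict[str, int],
    rois_per_gene: dict[str, int],
    edges=DEFAULT_FPKM_EDGES,
) -> list[ExpressionBin]:
    """Bin genes by FPKM (left-closed, right-open) and summarise per bin.

    For each bin: the number of isoforms of its genes, the detection rate per
    100k of the total ROI count, and the share of mapped ROIs (occupancy).
    Occupancies form a probability vector over the bins.
    """
    edges = sorted(edges)
    bins = [
        ExpressionBin(lo, hi)
        for lo, hi in zip(edges, list(edges[1:]) + [float("inf")])
    ]
    total_rois = sum(rois_per_gene.values())
    for gene, value in genes.items():
        if value < 0:
            raise ValueError(f"negative FPKM for {gene}")
        for b in bins:
            if b.low <= value < b.high:
                b.isoform_count += isoforms_per_gene.get(gene, 0)
                b.roi_count += rois_per_gene.get(gene, 0)
                break
    for b in bins:
        if total_rois:
            b.rate = round(b.isoform_count * 1e5 / total_rois)
            b.occupancy = b.roi_count / total_rois
    return bins


@dataclass
class CoverageClass:
    isoform_id: str
    fraction: float
    coverage_class: str = field(init=False)

    def __post_init__(self):
        if self.fraction >= COVERAGE_FULL_THRESHOLD:
            self.coverage_class = COVER_FULL
        elif self.fraction > 0:
            self.coverage_class = COVER_PARTIAL
        else:
            self.coverage_class = COVER_NONE


def coverage_class(isoform, short_read_pairs) -> CoverageClass:
    """Fraction of an isoform's exonic bases covered by >= 1 short-read base.

    A base is covered when any aligned match block of any mate includes its
    genomic coordinate (junction-aware: only exonic bases count).
    """
    covered_total = 0
    length = 0
    blocks = []
    for pair in short_read_pairs:
        for aln in list(pair.alignments1) + list(pair.alignments2):
            if aln.reference != isoform.contig:
                continue
            blocks.extend(
                (b.genome_start, b.genome_end) for b in aln.match_blocks()
            )
    blocks.sort()
    merged = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    for exon in isoform.exons:
        length += len(exon)
        for s, e in merged:
            if e <= exon.start:
                continue
            if s >= exon.end:
                break
            covered_total += min(e, exon.end) - max(s, exon.start)
    fraction = covered_total / length if length else 0.0
    return CoverageClass(isoform.isoform_id, fraction)


@dataclass
class PhasingSummary:
    total_snp_pairs: int
    sgs_phased_pairs: int
    phased_isoforms: int = 0
    sms_only_pairs: int = field(init=False)
    sms_only_percent: float = field(init=False)

    def __post_init__(self):
        if not (0 <= self.sgs_phased_pairs <= self.total_snp_pairs):
            raise ValueError("SGS-phased pairs must be a subset of all pairs")
        self.sms_only_pairs = self.total_snp_pairs - self.sgs_phased_pairs
        if self.total_snp_pairs == 0:
            raise ValueError("phasing percentage undefined for zero SNP pairs")
        self.sms_only_percent = round(
            100.0 * self.sms_only_pairs / self.total_snp_pairs, 1
        )


def summarize_phasing(
    total_snp_pairs: int, sgs_phased_pairs: int, phased_isoforms: int = 0
) -> PhasingSummary:
    """Share of phased SNP pairs that only the long reads could connect."""
    return PhasingSummary(total_snp_pairs, sgs_phased_pairs, phased_isoforms)


@dataclass
class DetectionMetrics:
    library_id: str
    roi_count: int
    isoform_count: int
    rate: float = field(init=False)
    bins: list[ExpressionBin] = field(default_factory=list)

    def __post_init__(self):
        self.rate = detection_rate(self.isoform_count, self.roi_count)


def write_metrics_json(metrics: DetectionMetrics, path) -> None:
    payload = {
        "library_id": metrics.library_id,
        "roi_count": metrics.roi_count,
        "isoform_count": metrics.isoform_count,
        "isoforms_per_100k_rois": metrics.rate,
        "bins": [
            {
                "bin": b.label,
                "isoform_count": b.isoform_count,
                "rate_per_100k": b.rate,
                "roi_occupancy": b.occupancy,
            }
            for b in metrics.bins
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
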