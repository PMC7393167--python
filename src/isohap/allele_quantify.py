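"""Isoform-specific short-read counting and allele-specific classification.

Isoforms of one gene are told apart by the junctions and exonic regions each
possesses alone; read pairs hitting exactly one isoform's unique features are
counted for it, split between the two phased alleles by the SNP bases they
carry, and the resulting allele counts are classified as differentially or
equally expressed.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .genomic_io import GenomicInterval, OP_INTRON, ValidationError, reverse_complement
from .phasing import HaplotypePair

logger = logging.getLogger("isohap")

#: Minimum overlap (nt) of a mate with a unique exon region to count.
MIN_EXON_OVERLAP = 10

#: Total assigned read pairs required before an allele-balance call is made.
MIN_TOTAL_PAIRS = 30

#: Fold-change thresholds: differential at >= 2, equal within [1, 1.105].
DIFFERENTIAL_FOLD = 2.0
EQUAL_FOLD_HIGH = 1.105

DIFFERENTIAL = "differential"
EQUAL = "equal"
UNDETERMINED = "undetermined"


@dataclass
class IsoformSpecificFeatures:
    """Junctions and exonic intervals found in exactly one isoform of a gene."""

    isoform_id: str
    unique_junctions: set[tuple[int, int]]
    unique_exon_regions: list[GenomicInterval]


@dataclass
class AlleleQuantRecord:
    isoform_id: str
    count_a: int
    count_b: int
    unassignable: int = 0
    fold: float = float("nan")
    asi_class: str = UNDETERMINED

    @property
    def total_assigned(self) -> int:
        return self.count_a + self.count_b


# ---------------------------------------------------------------------------
# Feature derivation
# ---------------------------------------------------------------------------


def _subtract_intervals(keep: list[GenomicInterval], remove) -> list[GenomicInterval]:
    """Interval subtraction: parts of ``keep`` covered by no interval in ``remove``."""
    out = []
    for iv in keep:
        pieces = [(iv.start, iv.end)]
        for r in remove:
            if r.contig != iv.contig:
                continue
            nxt = []
            for s, e in pieces:
                if r.end <= s or r.start >= e:
                    nxt.append((s, e))
                    continue
                if s < r.start:
                    nxt.append((s, r.start))
                if r.end < e:
                    nxt.append((r.end, e))
            pieces = nxt
        out.extend(GenomicInterval(iv.contig, s, e, iv.strand) for s, e in pieces)
    return out


def derive_specific_features(cluster) -> dict[str, IsoformSpecificFeatures]:
    """Unique junctions and exon regions for each isoform of one gene cluster.

    A junction is unique when present in exactly one isoform; an exonic base
    is unique when covered by exactly one isoform's exons.  A single-isoform
    cluster contributes its whole model.  Two structurally identical isoforms
    (which collapsing should have merged) are a validation error.
    """
    cluster = list(cluster)
    seen = set()
    for iso in cluster:
        key = tuple((e.start, e.end) for e in iso.exons)
        if key in seen:
            raise ValidationError(
                f"identical isoform models in one cluster (near {iso.isoform_id}); "
                "no unique features exist"
            )
        seen.add(key)

    junction_counts = Counter()
    for iso in cluster:
        for j in iso.intron_chain:
            junction_counts[j] += 1

    features = {}
    for iso in cluster:
        unique_junctions = {j for j in iso.intron_chain if junction_counts[j] == 1}
        others = [e for other in cluster if other is not iso for e in other.exons]
        unique_regions = _subtract_intervals(iso.exons, others)
        features[iso.isoform_id] = IsoformSpecificFeatures(
            iso.isoform_id, unique_junctions, unique_regions
        )
    return features


# ---------------------------------------------------------------------------
# Read-pair counting
# ---------------------------------------------------------------------------


def _mate_junctions(aln) -> set[tuple[int, int]]:
    return {
        (b.genome_start, b.genome_end) for b in aln.blocks if b.op == OP_INTRON
    }


def _mate_matches_isoform(alignments, feats: IsoformSpecificFeatures,
                          min_overlap: int) -> bool:
    for aln in alignments:
        if _mate_junctions(aln) & feats.unique_junctions:
            return True
        for region in feats.unique_exon_regions:
            overlap = sum(
                max(0, min(b.genome_end, region.end) - max(b.genome_start, region.start))
                for b in aln.match_blocks()
            )
            if overlap >= min_overlap:
                return True
    return False


def count_specific_pairs(
    features: dict[str, IsoformSpecificFeatures],
    pairs,
    min_overlap: int = MIN_EXON_OVERLAP,
) -> tuple[dict[str, int], dict[str, list]]:
    """Count pairs mapping specifically to one isoform's unique features.

    A pair counts for an isoform when at least one mate spans a unique
    junction or overlaps a unique exon region by >= ``min_overlap`` nt, and
    matches no other isoform's unique features; ambiguous pairs are dropped.
    Returns per-isoform counts and the matched pairs themselves (for the
    allele split).
    """
    counts = {iso: 0 for iso in features}
    matched_pairs: dict[str, list] = {iso: [] for iso in features}
    for pair in pairs:
        hits = [
            iso
            for iso, feats in features.items()
            if _mate_matches_isoform(pair.alignments1, feats, min_overlap)
            or _mate_matches_isoform(pair.alignments2, feats, min_overlap)
        ]
        if len(hits) == 1:
            counts[hits[0]] += 1
            matched_pairs[hits[0]].append(pair)
        elif len(hits) > 1:
            logger.debug("pair %s matches unique features of %s; dropped", pair.pair_id, hits)
    return counts, matched_pairs


# ---------------------------------------------------------------------------
# Allele split and classification
# ---------------------------------------------------------------------------


def _pair_snp_bases(pair, positions: list[int]) -> dict[int, set[str]]:
    """Bases observed by either mate at the given genomic SNP positions."""
    observed: dict[int, set[str]] = defaultdict(set)
    for seq, alignments in (
        (pair.sequence1, pair.alignments1),
        (pair.sequence2, pair.alignments2),
    ):
        for aln in alignments:
            oriented = seq if aln.strand == "+" else reverse_complement(seq)
            for b in aln.match_blocks():
                for gpos in positions:
                    if b.genome_start <= gpos < b.genome_end:
                        idx = b.read_start + (gpos - b.genome_start)
                        if idx < len(oriented):
                            observed[gpos].add(oriented[idx])
    return observed


def split_by_allele(pairs, haplotype: HaplotypePair) -> AlleleQuantRecord:
    """Assign isoform-specific pairs to the two phased alleles.

    A pair goes to a haplotype when every phased SNP position it covers shows
    that haplotype's allele; pairs covering no SNP, observing discordant
    bases, or mixing haplotypes are unassignable.
    """
    count_a = count_b = unassignable = 0
    positions = haplotype.positions
    allele_a = dict(zip(positions, haplotype.haplotype_a))
    allele_b = dict(zip(positions, haplotype.haplotype_b))
    for pair in pairs:
        observed = _pair_snp_bases(pair, positions)
        if not observed:
            unassignable += 1
            continue
        flat = {}
        consistent = True
        for gpos, bases in observed.items():
            if len(bases) != 1:
                consistent = False
                break
            flat[gpos] = next(iter(bases))
        if not consistent:
            unassignable += 1
            continue
        matches_a = all(flat[g] == allele_a[g] for g in flat)
        matches_b = all(flat[g] == allele_b[g] for g in flat)
        if matches_a and not matches_b:
            count_a += 1
        elif matches_b and not matches_a:
            count_b += 1
        else:
            unassignable += 1
    return AlleleQuantRecord(haplotype.isoform_id, count_a, count_b, unassignable)


def classify_asi(
    record: AlleleQuantRecord,
    min_total: int = MIN_TOTAL_PAIRS,
    include_unassignable: bool = False,
) -> AlleleQuantRecord:
    """Classify an allele count pair as differential, equal or undetermined.

    Fold change is max/min of the two allele counts (infinite when one
    allele is unobserved).  Differential: total >= ``min_total`` and fold >=
    2; equal: total >= ``min_total`` and fold within [1, 1.105].  By default
    the total counts only allele-assigned pairs; set ``include_unassignable``
    to also count pairs carrying no allele information.
    """
    a, b = record.count_a, record.count_b
    if a == 0 and b == 0:
        record.fold = float("nan")
    elif min(a, b) == 0:
        record.fold = math.inf
    else:
        record.fold = max(a, b) / min(a, b)
    total = a + b + (record.unassignable if include_unassignable else 0)
    if total >= min_total and record.fold >= DIFFERENTIAL_FOLD:
        record.asi_class = DIFFERENTIAL
    elif total >= min_total and 1.0 <= record.fold <= EQUAL_FOLD_HIGH:
        record.asi_class = EQUAL
    else:
        record.asi_class = UNDETERMINED
    return record


# ---------------------------------------------------------------------------
# Driver and writers
# ---------------------------------------------------------------------------


def quantify_alleles(
    gene_clusters: dict[str, list],
    pairs,
    haplotypes: dict[str, HaplotypePair],
    min_overlap: int = MIN_EXON_OVERLAP,
    min_total: int = MIN_TOTAL_PAIRS,
    include_unassignable: bool = False,
) -> list[AlleleQuantRecord]:
    """Feature derivation, counting, allele split and classification per gene."""
    records = []
    for gene_id in sorted(gene_clusters):
        features = derive_specific_features(gene_clusters[gene_id])
        counts, matched = count_specific_pairs(features, pairs, min_overlap)
        for isoform_id in sorted(features):
            hap = haplotypes.get(isoform_id)
            if hap is None or not hap.phased:
                continue
            record = split_by_allele(matched[isoform_id], hap)
            records.append(
                classify_asi(record, min_total, include_unassignable)
            )
    return records


def write_allele_quant_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("isoform_id\thap_a\thap_b\tunassignable\tfold\tclass\n")
        for r in sorted(records, key=lambda r: r.isoform_id):
            fold = "NA" if math.isnan(r.fold) else ("inf" if math.isinf(r.fold) else f"{r.fold:.3f}")
            fh.write(
                f"{r.isoform_id}\t{r.count_a}\t{r.count_b}\t{r.unassignable}\t"
                f"{fold}\t{r.asi_class}\n"
            )


def write_feature_bed(features_by_gene: dict[str, dict[str, IsoformSpecificFeatures]],
                      contig_of: dict[str, str], path) -> None:
    """Unique junctions and exon regions per isoform as a BED file."""
    rows = []
    for gene_id, features in features_by_gene.items():
        for iso_id, feats in features.items():
            contig = contig_of[iso_id]
            for start, end in sorted(feats.unique_junctions):
                rows.append((contig, start, end, f"{gene_id}|{iso_id}|junction"))
            for region in feats.unique_exon_regions:
                rows.append((region.contig, region.start, region.end,
                             f"{gene_id}|{iso_id}|exon"))
    rows.sort()
    with open(path, "w") as fh:
        for contig, start, end, name in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")
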