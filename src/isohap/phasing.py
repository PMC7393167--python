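"""Hybrid long/short-read SNP calling, error correction and isoform phasing.

The engine rewrites each uniquely mapped long read (ROI) into a *pseudo-long
read*: the ROI's splice frame filled with reference-genome bases.  Accurate
short reads are piled up on the pseudo-long reads to call heterozygous SNPs
and to correct sequencing errors; at heterozygous positions the ROI's own
base is restored, revealing which allele the single molecule carried.  ROIs
fixed at two or more SNP positions are phased; the linkage of allele
combinations observed across phased ROIs is then used to rescue additional
ROIs with residual errors at SNP positions.  Finally the phased ROIs of each
isoform cluster are assembled into the isoform's two haplotype strings.

Positions inside this module are pseudo-long-read coordinates unless a
variable is explicitly genomic; the same genomic SNP observed on several
pseudo-long reads is unified by genomic coordinate in the registry.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .genomic_io import (
    AlignedBlock,
    Genome,
    LongReadAlignment,
    OP_MATCH,
    reverse_complement,
)

logger = logging.getLogger("isohap")

# Per-position provenance of a pseudo-long-read / corrected-ROI base.
MASK_REF = 0            # reference genome base under the ROI frame
MASK_SGS_CORRECTED = 1  # replaced with the consistent short-read base
MASK_ROI_ORIGINAL = 2   # retained / restored from the original ROI
MASK_SNP_MARKED = 3     # heterozygous SNP position (carries the ROI allele)

MASK_NAMES = {
    MASK_REF: "REF",
    MASK_SGS_CORRECTED: "SGS_CORRECTED",
    MASK_ROI_ORIGINAL: "ROI_ORIGINAL",
    MASK_SNP_MARKED: "SNP_MARKED",
}

_BASES = "ACGT"
_BASE_TO_ROW = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_TO_ROW[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _decode(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


@dataclass
class PhasingConfig:
    """Thresholds of the SNP caller, corrector and linkage rescue."""

    min_snp_depth: int = 4          # total depth to consider a het SNP
    min_allele_depth: int = 2       # per-allele depth for a het SNP
    min_minor_fraction: float = 0.2  # minor-allele fraction for a het SNP
    hom_fraction: float = 0.8       # majority fraction for homozygous-different
    min_correction_depth: int = 2   # depth for non-SNP short-read correction
    rescue_min_support: int = 2     # phased-ROI support behind a linkage rescue
    rescue_conflict_fraction: float = 0.2  # tolerated conflicting linkage share
    mapper_seed_length: int = 20
    mapper_max_mismatches: int = 3
    mapper_clip_window: int = 8     # end mismatches within this window are clipped
    # Mate end bases ignored in pileups.  Must cover the clip window: clipping
    # removes mismatching end bases but keeps matching ones, and counting the
    # survivors alone would bias shallow pileups toward the reference allele.
    pileup_end_trim: int = 8


# ---------------------------------------------------------------------------
# Pseudo-long reads
# ---------------------------------------------------------------------------


@dataclass
class PseudoLongRead:
    """An ROI re-expressed with reference bases under the ROI's splice frame.

    ``genome_pos[i]`` is the genomic coordinate of position i (or -1 for the
    rare reference-N fill without a genomic base assignable), ``roi_pos[i]``
    the coordinate in the original ROI sequence (-1 where the ROI had a
    deletion).  Sequence, mask and the two coordinate arrays all have equal
    length.
    """

    roi_id: str
    contig: str
    strand: str
    sequence: str
    mask: np.ndarray
    genome_pos: np.ndarray
    roi_pos: np.ndarray
    source: LongReadAlignment | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def build_pseudo_long_read(aln: LongReadAlignment, genome: Genome) -> PseudoLongRead:
    """Replace every aligned ROI base with the reference base.

    Match blocks contribute reference bases; ROI insertions are dropped; ROI
    deletions are filled with reference bases; intron skips contribute
    nothing.  Positions where the reference is N keep the ROI's own base
    (provenance ROI_ORIGINAL) and are excluded from SNP calling.
    """
    seq_parts: list[str] = []
    mask_parts: list[np.ndarray] = []
    gpos_parts: list[np.ndarray] = []
    rpos_parts: list[np.ndarray] = []
    for b in aln.blocks:
        if b.op == OP_MATCH or (b.op == "D"):
            ref = genome.fetch(aln.contig, b.genome_start, b.genome_end)
            n = len(ref)
            mask = np.full(n, MASK_REF, dtype=np.uint8)
            gpos = np.arange(b.genome_start, b.genome_end, dtype=np.int64)
            if b.op == OP_MATCH:
                rpos = np.arange(b.read_start, b.read_end, dtype=np.int64)
            else:
                rpos = np.full(n, -1, dtype=np.int64)
            if "N" in ref:
                ref_list = list(ref)
                for i, base in enumerate(ref_list):
                    if base == "N":
                        mask[i] = MASK_ROI_ORIGINAL
                        if rpos[i] >= 0 and aln.read_sequence:
                            ref_list[i] = aln.read_sequence[rpos[i]]
                ref = "".join(ref_list)
            seq_parts.append(ref)
            mask_parts.append(mask)
            gpos_parts.append(gpos)
            rpos_parts.append(rpos)
        # insertions and intron skips contribute no pseudo-read positions
    return PseudoLongRead(
        roi_id=aln.read_id,
        contig=aln.contig,
        strand=aln.strand,
        sequence="".join(seq_parts),
        mask=np.concatenate(mask_parts) if mask_parts else np.empty(0, np.uint8),
        genome_pos=np.concatenate(gpos_parts) if gpos_parts else np.empty(0, np.int64),
        roi_pos=np.concatenate(rpos_parts) if rpos_parts else np.empty(0, np.int64),
        source=aln,
    )


# ---------------------------------------------------------------------------
# Short-read mapping to pseudo-long reads (self-contained test mapper)
# ---------------------------------------------------------------------------


@dataclass
class MappedMate:
    """One mate aligned to a pseudo-long read, sequence in alignment orientation."""

    reference: str
    start: int
    sequence: str

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


def _clip_ends(mismatches: np.ndarray, length: int, window: int) -> tuple[int, int]:
    """Soft-clip bounds [lo, hi) chasing mismatches near either end."""
    lo = 0
    for m in mismatches:
        if m < lo + window:
            lo = int(m) + 1
        else:
            break
    hi = length
    for m in mismatches[::-1]:
        if m >= hi - window:
            hi = int(m)
        else:
            break
    return lo, max(lo, hi)


def map_short_reads_to_pseudo(
    pairs,
    pseudo_reads,
    config: PhasingConfig | None = None,
    all_hits: bool = True,
) -> dict[str, list[MappedMate]]:
    """Exact-seed, mismatch-tolerant mapper of read pairs to pseudo-long reads.

    A deliberately simple substitute for a genuine short-read aligner, meant
    for self-contained runs on simulated data: seeds of ``seed_length`` at
    both ends of each mate are looked up exactly; candidate placements fully
    contained in a pseudo-long read with at most ``max_mismatches``
    substitutions are reported.  Mismatches within ``clip_window`` of either
    end are soft-clipped (iteratively, chasing runs of near-end mismatches):
    a mate whose source molecule used a different splice junction aligns
    with a short mismatching overhang at the junction edge, and without
    clipping those bases would masquerade as variants.  With ``all_hits``
    every matching pseudo-long read receives the mate (so every copy of a
    shared exon is piled up); gapped placements are not considered.
    """
    config = config or PhasingConfig()
    k = config.mapper_seed_length
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    encoded: list[np.ndarray] = []
    ids: list[str] = []
    for idx, pseudo in enumerate(pseudo_reads):
        ids.append(pseudo.roi_id)
        encoded.append(_encode(pseudo.sequence))
        seq = pseudo.sequence
        for pos in range(0, len(seq) - k + 1):
            index[seq[pos : pos + k]].append((idx, pos))

    hits: dict[str, list[MappedMate]] = defaultdict(list)
    for pair in pairs:
        for seq in (pair.sequence1, pair.sequence2):
            if len(seq) < k:
                continue
            placements: dict[tuple[int, int], str] = {}
            for oriented in (seq, reverse_complement(seq)):
                enc = _encode(oriented)
                for offset in (0, len(oriented) - k):
                    seed = oriented[offset : offset + k]
                    for idx, pos in index.get(seed, ()):
                        start = pos - offset
                        if start < 0 or start + len(oriented) > len(encoded[idx]):
                            continue
                        target = encoded[idx][start : start + len(oriented)]
                        mismatches = np.nonzero(target != enc)[0]
                        if mismatches.size > config.mapper_max_mismatches:
                            continue
                        lo, hi = _clip_ends(
                            mismatches, len(oriented), config.mapper_clip_window
                        )
                        if hi - lo >= k:
                            placements[(idx, start + lo)] = oriented[lo:hi]
            if not all_hits and placements:
                best = min(placements)
                placements = {best: placements[best]}
            for (idx, start), clipped in placements.items():
                hits[ids[idx]].append(MappedMate(ids[idx], start, clipped))
    return hits


# ---------------------------------------------------------------------------
# Pileup and SNP calling
# ---------------------------------------------------------------------------


def pileup_short_reads(
    pseudo: PseudoLongRead, mates, end_trim: int = 3
) -> np.ndarray:
    """Per-position A/C/G/T counts (shape 4 x len) from mapped mates.

    Both mates of a pair are counted independently; bases other than ACGT
    are ignored; a mate extending past the pseudo-read end is skipped with a
    warning.  The outermost ``end_trim`` bases of every mate are excluded —
    a mate whose source molecule used a different splice junction can align
    with a few overhanging bases at a junction edge, and those bases would
    otherwise masquerade as variant positions.
    """
    counts = np.zeros((4, len(pseudo)), dtype=np.int32)
    for mate in mates:
        if mate.start < 0 or mate.end > len(pseudo):
            logger.warning(
                "mate on %s at %d-%d outside pseudo-long read of length %d; skipped",
                pseudo.roi_id, mate.start, mate.end, len(pseudo),
            )
            continue
        rows = _BASE_TO_ROW[_encode(mate.sequence)]
        if end_trim and len(rows) > 2 * end_trim:
            rows = rows[end_trim:-end_trim]
            start = mate.start + end_trim
        else:
            start = mate.start
        valid = rows != 255
        positions = np.arange(start, start + len(rows))[valid]
        np.add.at(counts, (rows[valid], positions), 1)
    return counts


@dataclass(frozen=True)
class SnpSite:
    """A variant position on one pseudo-long read."""

    pseudo_id: str
    position: int
    genome_pos: int
    kind: str                      # "het" or "hom_diff"
    alleles: tuple[str, ...]       # two bases (het) or one base (hom_diff)
    depths: tuple[int, ...]


def call_snp_positions(
    pseudo: PseudoLongRead, counts: np.ndarray, config: PhasingConfig | None = None
) -> list[SnpSite]:
    """Call heterozygous and homozygous-different positions from a pileup.

    Heterozygous: total depth >= ``min_snp_depth``, exactly two bases with
    depth >= ``min_allele_depth`` each, minor fraction >= ``min_minor_fraction``.
    Three bases passing the depth filter flag the position unreliable and it
    is excluded.  Homozygous-different: a single base with fraction >=
    ``hom_fraction`` and depth >= ``min_allele_depth`` differing from the
    pseudo-read base.  Reference-N positions are never called.
    """
    config = config or PhasingConfig()
    depth = counts.sum(axis=0)
    passing = (counts >= config.min_allele_depth).sum(axis=0)
    pseudo_rows = _BASE_TO_ROW[_encode(pseudo.sequence)]
    top_row = counts.argmax(axis=0)
    candidate = (depth > 0) & ((passing >= 2) | (top_row != pseudo_rows))
    candidate &= pseudo.mask != MASK_ROI_ORIGINAL

    sites = []
    for pos in np.nonzero(candidate)[0]:
        col = counts[:, pos]
        total = int(depth[pos])
        strong = [i for i in range(4) if col[i] >= config.min_allele_depth]
        if len(strong) > 2:
            continue  # three alleles pass the depth filter: unreliable
        if len(strong) == 2 and total >= config.min_snp_depth:
            minor = min(col[strong])
            if minor / total >= config.min_minor_fraction:
                order = sorted(strong, key=lambda i: (-col[i], i))
                sites.append(
                    SnpSite(
                        pseudo_id=pseudo.roi_id,
                        position=int(pos),
                        genome_pos=int(pseudo.genome_pos[pos]),
                        kind="het",
                        alleles=tuple(_BASES[i] for i in order),
                        depths=tuple(int(col[i]) for i in order),
                    )
                )
                continue
        major = int(top_row[pos])
        if (
            col[major] >= config.min_allele_depth
            and col[major] / total >= config.hom_fraction
            and major != pseudo_rows[pos]
        ):
            sites.append(
                SnpSite(
                    pseudo_id=pseudo.roi_id,
                    position=int(pos),
                    genome_pos=int(pseudo.genome_pos[pos]),
                    kind="hom_diff",
                    alleles=(_BASES[major],),
                    depths=(int(col[major]),),
                )
            )
    return sites


class SnpRegistry:
    """Heterozygous SNPs unified by genomic coordinate across pseudo reads."""

    def __init__(self):
        self.sites: dict[tuple[str, int], dict] = {}

    def add(self, contig: str, site: SnpSite) -> None:
        if site.kind != "het" or site.genome_pos < 0:
            return
        key = (contig, site.genome_pos)
        alleles = frozenset(site.alleles)
        rec = self.sites.setdefault(
            key, {"alleles": alleles, "depth": Counter(), "unreliable": False}
        )
        if rec["alleles"] != alleles:
            rec["unreliable"] = True
        for a, d in zip(site.alleles, site.depths):
            rec["depth"][a] += d

    def alleles(self, contig: str, genome_pos: int) -> frozenset[str] | None:
        rec = self.sites.get((contig, genome_pos))
        if rec is None or rec["unreliable"]:
            return None
        return rec["alleles"]

    def other_allele(self, contig: str, genome_pos: int, allele: str) -> str | None:
        pair = self.alleles(contig, genome_pos)
        if pair is None or allele not in pair:
            return None
        (other,) = pair - {allele}
        return other

    def het_positions(self, contig: str) -> list[int]:
        return sorted(
            pos
            for (c, pos), rec in self.sites.items()
            if c == contig and not rec["unreliable"]
        )


# ---------------------------------------------------------------------------
# Correction, fixing, phasing of individual ROIs
# ---------------------------------------------------------------------------


@dataclass
class CorrectedRoi:
    """An ROI after short-read correction, with its SNP-position state."""

    roi_id: str
    contig: str
    strand: str
    sequence: str
    mask: np.ndarray
    snp_positions: dict[int, int]          # pseudo position -> genomic coordinate
    fixed: dict[int, str] = field(default_factory=dict)  # genomic coord -> allele
    pseudo: PseudoLongRead | None = None

    @property
    def phased(self) -> bool:
        return len(self.fixed) >= 2


def correct_pseudo_read(
    pseudo: PseudoLongRead,
    counts: np.ndarray,
    snps: list[SnpSite],
    roi_sequence: str,
    config: PhasingConfig | None = None,
) -> CorrectedRoi:
    """Produce the short-read-corrected ROI from a pseudo-long read.

    Non-SNP positions covered by >= ``min_correction_depth`` mates showing a
    single base take that base; homozygous-different positions take the
    short-read base; heterozygous SNP positions restore the ROI's original
    base (provenance SNP_MARKED) — this base is the molecule's allele; all
    remaining positions (uncovered, depth 1, or inconsistent) restore the
    ROI's original base.  Positions the ROI deleted keep the reference fill.
    """
    config = config or PhasingConfig()
    seq = _encode(pseudo.sequence)
    mask = pseudo.mask.copy()
    roi_enc = _encode(roi_sequence) if roi_sequence else np.empty(0, np.uint8)

    # Default: restore the original ROI base wherever the ROI has one.
    has_roi = pseudo.roi_pos >= 0
    if roi_enc.size:
        seq[has_roi] = roi_enc[pseudo.roi_pos[has_roi]]
    mask[has_roi] = MASK_ROI_ORIGINAL

    # Short-read correction of consistently covered non-SNP positions.
    depth = counts.sum(axis=0)
    single = (counts > 0).sum(axis=0) == 1
    correctable = (depth >= config.min_correction_depth) & single
    correctable &= pseudo.mask != MASK_ROI_ORIGINAL  # reference-N positions stay
    top = counts.argmax(axis=0)
    het_pos = np.array([s.position for s in snps if s.kind == "het"], dtype=int)
    if het_pos.size:
        correctable[het_pos] = False
    sgs_base = np.frombuffer(_BASES.encode(), dtype=np.uint8)[top]
    seq[correctable] = sgs_base[correctable]
    mask[correctable] = MASK_SGS_CORRECTED

    # Homozygous-different positions take the short-read base even when the
    # coverage pattern did not qualify as "consistent non-SNP".
    for s in snps:
        if s.kind == "hom_diff":
            seq[s.position] = ord(s.alleles[0])
            mask[s.position] = MASK_SGS_CORRECTED

    snp_positions = {}
    for s in snps:
        if s.kind == "het":
            mask[s.position] = MASK_SNP_MARKED
            snp_positions[s.position] = s.genome_pos

    return CorrectedRoi(
        roi_id=pseudo.roi_id,
        contig=pseudo.contig,
        strand=pseudo.strand,
        sequence=_decode(seq),
        mask=mask,
        snp_positions=snp_positions,
        pseudo=pseudo,
    )


def fix_and_phase_roi(roi: CorrectedRoi, registry: SnpRegistry) -> CorrectedRoi:
    """Fix SNP positions whose ROI base matches a called allele.

    A position is *fixed* when the corrected ROI's base at a heterozygous SNP
    equals one of the two alleles in the unified SNP set; the ROI is *phased*
    when more than one position is fixed.
    """
    for pos, gpos in sorted(roi.snp_positions.items()):
        pair = registry.alleles(roi.contig, gpos)
        if pair is None:
            continue
        base = roi.sequence[pos]
        if base in pair:
            roi.fixed[gpos] = base
    return roi


# ---------------------------------------------------------------------------
# Linkage rescue
# ---------------------------------------------------------------------------

LinkageTable = dict[tuple[str, int, int], Counter]


def build_linkage_table(rois) -> LinkageTable:
    """Allele-combination counts per genomic SNP-position pair, phased ROIs only."""
    table: LinkageTable = defaultdict(Counter)
    for roi in rois:
        if not roi.phased:
            continue
        positions = sorted(roi.fixed)
        for i, p in enumerate(positions):
            for q in positions[i + 1 :]:
                table[(roi.contig, p, q)][(roi.fixed[p], roi.fixed[q])] += 1
    return table


def _implied_allele(
    table: LinkageTable,
    contig: str,
    fixed_pos: int,
    fixed_allele: str,
    target_pos: int,
    config: PhasingConfig,
) -> str | None:
    p, q = sorted((fixed_pos, target_pos))
    combos = table.get((contig, p, q))
    if not combos:
        return None
    side = 0 if fixed_pos == p else 1
    relevant = Counter()
    for combo, n in combos.items():
        if combo[side] == fixed_allele:
            relevant[combo[1 - side]] += n
    if not relevant:
        return None
    ranked = relevant.most_common()
    best_allele, best_n = ranked[0]
    total = sum(relevant.values())
    if best_n < config.rescue_min_support:
        return None
    if len(ranked) > 1:
        if ranked[1][1] == best_n:  # tied support: no action
            return None
        if ranked[1][1] > config.rescue_conflict_fraction * total:
            return None
    return best_allele


def build_linkage_and_rescue(
    rois: list[CorrectedRoi],
    registry: SnpRegistry,
    config: PhasingConfig | None = None,
) -> tuple[LinkageTable, list[CorrectedRoi]]:
    """Correct residual errors at SNP positions using phased-ROI linkage.

    For every unfixed SNP position of an ROI that has at least one fixed
    position, the linkage table is consulted: when the observed allele
    combinations imply a unique allele (majority with >=
    ``rescue_min_support`` phased ROIs, no conflicting combination above
    ``rescue_conflict_fraction`` of the pair's support, and agreement across
    all fixed anchor positions), the position is corrected and fixed.  The
    procedure iterates to a fixed point; fixes are only ever added, so it
    terminates.
    """
    config = config or PhasingConfig()
    changed = True
    while changed:
        changed = False
        table = build_linkage_table(rois)
        for roi in rois:
            if not roi.fixed:
                continue
            unfixed = [
                (pos, gpos)
                for pos, gpos in roi.snp_positions.items()
                if gpos not in roi.fixed
                and registry.alleles(roi.contig, gpos) is not None
            ]
            for pos, gpos in sorted(unfixed, key=lambda t: t[1]):
                implied = {
                    _implied_allele(table, roi.contig, fp, fa, gpos, config)
                    for fp, fa in roi.fixed.items()
                }
                implied.discard(None)
                if len(implied) != 1:
                    continue
                (allele,) = implied
                if allele not in registry.alleles(roi.contig, gpos):
                    continue
                seq = list(roi.sequence)
                seq[pos] = allele
                roi.sequence = "".join(seq)
                roi.fixed[gpos] = allele
                changed = True
    return build_linkage_table(rois), rois


# ---------------------------------------------------------------------------
# Isoform-level haplotype assembly
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePair:
    """The two phased allele strings of one isoform over its SNP positions."""

    isoform_id: str
    contig: str
    positions: list[int]               # genomic coordinates, ascending
    haplotype_a: str
    haplotype_b: str
    support_a: set[str] = field(default_factory=set)
    support_b: set[str] = field(default_factory=set)
    excluded: set[str] = field(default_factory=set)
    conflicting: bool = False
    phased: bool = False
    linkage: dict = field(default_factory=dict)

    def allele(self, haplotype: str, genome_pos: int) -> str:
        i = self.positions.index(genome_pos)
        return (self.haplotype_a if haplotype == "A" else self.haplotype_b)[i]


def phase_isoforms(
    rois: list[CorrectedRoi],
    roi_to_isoform: dict[str, str],
    registry: SnpRegistry,
    linkage: LinkageTable | None = None,
) -> list[HaplotypePair]:
    """Assemble per-isoform haplotype pairs from phased supporting ROIs.

    Because every registry site is heterozygous with a known allele pair,
    placing one ROI determines both haplotypes over its positions: haplotype
    B is the allele-pair complement of haplotype A.  Each phased ROI joins
    the haplotype it is fully consistent with; ROIs consistent with neither
    (recombinant-looking patterns) are excluded, and when two or more
    excluded ROIs share an identical pattern the isoform is flagged
    conflicting and reported unphased.  An isoform is phased when it has at
    least two SNP positions and both haplotypes have supporting ROIs.
    """
    groups: dict[str, list[CorrectedRoi]] = defaultdict(list)
    for roi in rois:
        iso = roi_to_isoform.get(roi.roi_id)
        if iso is not None:
            groups[iso].append(roi)

    out = []
    for isoform_id in sorted(groups):
        members = [r for r in groups[isoform_id] if r.phased]
        if not members:
            continue
        contig = members[0].contig
        members.sort(key=lambda r: (-len(r.fixed), r.roi_id))
        hap_a: dict[int, str] = {}
        support_a: set[str] = set()
        support_b: set[str] = set()
        excluded_patterns: Counter = Counter()
        excluded: set[str] = set()
        for roi in members:
            votes_a = votes_b = 0
            for gpos, allele in roi.fixed.items():
                if gpos in hap_a:
                    if allele == hap_a[gpos]:
                        votes_a += 1
                    else:
                        votes_b += 1
            if votes_a and votes_b:
                excluded.add(roi.roi_id)
                excluded_patterns[tuple(sorted(roi.fixed.items()))] += 1
                continue
            if votes_a:
                target = "A"
            elif votes_b:
                target = "B"
            elif not (support_a or support_b):
                target = "A"  # first ROI seeds haplotype A
            else:
                # no position overlap with the established haplotypes:
                # the ROI cannot be placed deterministically
                excluded.add(roi.roi_id)
                continue
            for gpos, allele in roi.fixed.items():
                if gpos not in hap_a:
                    if target == "A":
                        hap_a[gpos] = allele
                    else:
                        other = registry.other_allele(contig, gpos, allele)
                        if other is None:
                            continue
                        hap_a[gpos] = other
            (support_a if target == "A" else support_b).add(roi.roi_id)

        kept_positions, a_chars, b_chars = [], [], []
        for g in sorted(hap_a):
            other = registry.other_allele(contig, g, hap_a[g])
            if other is None:
                continue
            kept_positions.append(g)
            a_chars.append(hap_a[g])
            b_chars.append(other)
        a_string, b_string = "".join(a_chars), "".join(b_chars)
        conflicting = any(n >= 2 for n in excluded_patterns.values())
        phased = (
            len(kept_positions) >= 2
            and bool(support_a)
            and bool(support_b)
            and not conflicting
        )
        pair_linkage = {}
        if linkage:
            for i, p in enumerate(kept_positions):
                for q in kept_positions[i + 1 :]:
                    combos = linkage.get((contig, p, q))
                    if combos:
                        pair_linkage[(p, q)] = dict(combos)
        out.append(
            HaplotypePair(
                isoform_id=isoform_id,
                contig=contig,
                positions=kept_positions,
                haplotype_a=a_string,
                haplotype_b=b_string,
                support_a=support_a,
                support_b=support_b,
                excluded=excluded,
                conflicting=conflicting,
                phased=phased,
                linkage=pair_linkage,
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class PhasingResult:
    pseudo_reads: list[PseudoLongRead]
    registry: SnpRegistry
    corrected: list[CorrectedRoi]
    linkage: LinkageTable
    haplotypes: list[HaplotypePair]
    depths: dict[str, np.ndarray] = field(default_factory=dict)

    def max_depth_at(self, contig: str, genome_pos: int) -> int:
        """Deepest short-read pileup observed at a genomic position."""
        best = 0
        for pseudo in self.pseudo_reads:
            if pseudo.contig != contig:
                continue
            hit = np.nonzero(pseudo.genome_pos == genome_pos)[0]
            if hit.size:
                best = max(best, int(self.depths[pseudo.roi_id][hit[0]]))
        return best


def run_phasing(
    genome: Genome,
    roi_alignments,
    short_read_pairs,
    roi_to_isoform: dict[str, str],
    config: PhasingConfig | None = None,
    mapped_mates: dict[str, list[MappedMate]] | None = None,
) -> PhasingResult:
    """Run the complete engine: pseudo reads -> pileup -> SNPs -> phasing.

    ``short_read_pairs`` are mapped with the built-in mapper unless
    ``mapped_mates`` (pseudo-read id -> mates) is supplied, e.g. parsed from
    an external aligner's SAM.
    """
    config = config or PhasingConfig()
    unique = [a for a in sorted(roi_alignments, key=lambda a: a.read_id) if a.is_unique]
    pseudo_reads = [build_pseudo_long_read(a, genome) for a in unique]
    if mapped_mates is None:
        mapped_mates = map_short_reads_to_pseudo(short_read_pairs, pseudo_reads, config)

    registry = SnpRegistry()
    depths: dict[str, np.ndarray] = {}
    per_read: list[tuple[PseudoLongRead, np.ndarray, list[SnpSite]]] = []
    for pseudo in pseudo_reads:
        counts = pileup_short_reads(
            pseudo, mapped_mates.get(pseudo.roi_id, ()), config.pileup_end_trim
        )
        depths[pseudo.roi_id] = counts.sum(axis=0)
        snps = call_snp_positions(pseudo, counts, config)
        for site in snps:
            registry.add(pseudo.contig, site)
        per_read.append((pseudo, counts, snps))

    corrected = []
    for pseudo, counts, snps in per_read:
        roi = correct_pseudo_read(
            pseudo, counts, snps, pseudo.source.read_sequence if pseudo.source else "",
            config,
        )
        # Positions whose per-read call was not replicated registry-wide are
        # dropped from the ROI's SNP set (unreliable or conflicting pairs).
        roi.snp_positions = {
            pos: gpos
            for pos, gpos in roi.snp_positions.items()
            if registry.alleles(roi.contig, gpos) is not None
        }
        corrected.append(fix_and_phase_roi(roi, registry))

    linkage, corrected = build_linkage_and_rescue(corrected, registry, config)
    haplotypes = phase_isoforms(corrected, roi_to_isoform, registry, linkage)
    return PhasingResult(pseudo_reads, registry, corrected, linkage, haplotypes, depths)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_snp_tsv(registry: SnpRegistry, genome: Genome, path) -> None:
    """Write the unified SNP set: contig, 1-based position, ref, alt, depths."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tdepth_ref\tdepth_alt\n")
        for (contig, gpos), rec in sorted(registry.sites.items()):
            if rec["unreliable"]:
                continue
            ref = genome.fetch(contig, gpos, gpos + 1)
            alleles = sorted(rec["alleles"])
            alts = [a for a in alleles if a != ref] or [alleles[-1]]
            ref_allele = ref if ref in alleles else alleles[0]
            fh.write(
                f"{contig}\t{gpos + 1}\t{ref_allele}\t{','.join(alts)}\t"
                f"{rec['depth'][ref_allele]}\t"
                f"{','.join(str(rec['depth'][a]) for a in alts)}\n"
            )


def write_phased_isoforms_tsv(haplotypes, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "isoform_id\tcontig\tpositions\thaplotype_a\thaplotype_b\t"
            "support_a\tsupport_b\tphased\tconflicting\n"
        )
        for h in sorted(haplotypes, key=lambda h: h.isoform_id):
            fh.write(
                f"{h.isoform_id}\t{h.contig}\t"
                f"{','.join(str(p + 1) for p in h.positions)}\t"
                f"{h.haplotype_a}\t{h.haplotype_b}\t"
                f"{len(h.support_a)}\t{len(h.support_b)}\t"
                f"{'yes' if h.phased else 'no'}\t"
                f"{'yes' if h.conflicting else 'no'}\n"
            )


def write_corrected_fasta(corrected, path) -> None:
    from .genomic_io import write_fasta

    write_fasta([(r.roi_id, r.sequence) for r in corrected], path)


def write_pseudo_fasta(pseudo_reads, path) -> None:
    from .genomic_io import write_fasta

    write_fasta([(p.roi_id, p.sequence) for p in pseudo_reads], path)
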