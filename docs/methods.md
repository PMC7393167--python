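# Methods

`isohap` re-implements the computational core of a hybrid long/short-read
isoform study on a diploid transcriptome: classification and collapsing of
full-length long-read isoforms against a reference annotation, phasing of
each isoform into its two parental haplotypes, allele-specific
quantification, and library-comparison metrics.  This note records the
models, the parameters that matter, and the choices made where the design
was genuinely open.

## Isoform classification and collapsing

Cluster quality.  An isoform cluster is *high quality* when it is supported
by ≥ 2 full-length long reads and its predicted consensus accuracy is
≥ 0.99; clusters with ≥ 1 full-length read and accuracy in [0.95, 0.99) are
*consensus-only*.  A cluster with a single full-length read and accuracy
≥ 0.99 is deliberately kept at consensus level: the full-length-support
requirement dominates, since a lone read cannot corroborate its own ends.

Junctions.  Each intron's edge dinucleotides are read in transcription
direction (reverse-complemented on the minus strand); a junction is
canonical iff the pair is GT-AG, GC-AG or AT-AC.  A multi-exon isoform is
`ME_canonical` only when every junction is canonical.  The minimum intron
length is 25 nt — genome gaps shorter than that in an alignment are treated
as deletions, matching the setting used to produce the long-read
alignments.

Gene attribution.  A canonical multi-exon isoform is a CSMM of the gene with
which it shares the most splice sites (exact genomic coordinates, same
strand; fuzzy matching would silently change CSMM counts).  Ties break by
(1) largest genomic overlap with the gene span, (2) lexicographically
smallest gene id — the published rule specifies only "most shared sites",
and the extra keys make the output deterministic.  An isoform sharing no
site but overlapping annotated loci is `Non_CSMM`, assigned to the gene with
the largest overlap; an isoform with neither is `Novel`, and novel isoforms
are grouped into loci by single-linkage same-strand overlap so novel genes
can be counted.

Transcript matching and collapsing.  An isoform matches an annotated
transcript when their ordered intron chains are identical; exon ends do not
participate.  Two molecules collapse when they share the intron chain and
both the 5′ and 3′ ends differ by ≤ 200 nt (inclusive).  Because that
pairwise relation is not transitive, equivalence classes are its connected
components (single linkage); each class is represented by its longest
member, supporting-read sets are unioned, full-length counts summed and the
best accuracy kept.  The test suite checks the partition against a
brute-force all-pairs closure.

Completeness.  For a CSMM, the distance to the annotated transcription start
site (aTSS) is the minimum, over same-strand transcripts of the attributed
gene, of the downstream offset of the isoform's start from the transcript's
first nucleotide (transcription direction); the aTTS distance is the
symmetric quantity at the 3′ end.  A negative minimum means the isoform
extends beyond every annotated end and is recorded as 0.  Transcripts enter
this analysis only if their biotype is in a configurable whitelist
(protein_coding, processed_transcript, retained_intron,
nonsense_mediated_decay, processed_pseudogene, lncRNA); annotations without
biotype tags are not filtered.  Whether other biotypes should also be
excluded from gene *attribution* is left open upstream; attribution here
uses all transcripts.

## Phasing engine

The engine exploits the complementary error profiles of the two read types:
long reads carry the haplotype connectivity but ~1–2 % errors; short reads
are accurate but cannot span distant SNPs.

1. **Pseudo-long reads.**  Every uniquely mapped long read (primary
   alignment, no secondary/supplementary records, mapping quality > 0) is
   rewritten as the reference sequence under its own splice frame: matched
   bases are replaced by reference bases, read insertions dropped, read
   deletions filled with reference bases.  Reference-N positions keep the
   read's own base and are excluded from calling.  The pseudo-long read is
   kept in reference orientation; per-position arrays record the genomic
   coordinate and the source position in the original read.

2. **Pileup.**  Short-read pairs are aligned to the pseudo-long reads (all
   hits, so every copy of a shared exon is piled up) and counted per
   position; both mates of a pair count independently.

3. **SNP calling.**  A position is heterozygous when total depth ≥ 4,
   exactly two bases have depth ≥ 2 each, and the minor fraction is ≥ 0.2;
   three bases passing the depth filter mark the position unreliable.  A
   single base with fraction ≥ 0.8 and depth ≥ 2 differing from the
   reference base is homozygous-different.  The thresholds are conservative
   defaults, exposed in `PhasingConfig`; calls from different pseudo-long
   reads are unified by genomic coordinate, and positions whose allele pairs
   disagree across reads are dropped as unreliable.

4. **Correction.**  Non-SNP positions covered by ≥ 2 mates showing a single
   base take that base; homozygous-different positions take the short-read
   base; heterozygous positions restore the *original long-read base* —
   which is the molecule's allele; everything else (uncovered, depth 1,
   inconsistent) also restores the original read base.

5. **Fixing and phasing.**  At each heterozygous position the corrected
   read's base is *fixed* if it equals one of the two called alleles; a read
   is *phased* when more than one position is fixed.

6. **Linkage rescue.**  Allele combinations per SNP-position pair are
   tallied over phased reads.  An unfixed position in a read with at least
   one fixed anchor is corrected when the linkage implies a unique allele:
   majority combination with ≥ 2 supporting reads, largest conflicting
   combination ≤ 20 % of the pair's support, and agreement across all
   anchors; ties take no action.  The procedure iterates to a fixed point;
   fixes are only added, so it terminates and is monotone.

7. **Isoform haplotypes.**  Within an isoform cluster, every called site is
   heterozygous with a known allele pair, so placing one read determines
   both haplotypes over its positions (haplotype B is the allele-pair
   complement of haplotype A).  Reads join the haplotype they are fully
   consistent with; a read matching neither is excluded, and when two or
   more excluded reads share an identical allele pattern — evidence of a
   third haplotype rather than scattered errors — the isoform is flagged
   conflicting and reported unphased.  An isoform is phased when it has
   ≥ 2 SNP positions and both haplotypes have supporting reads.

### Built-in short-read mapper

For self-contained runs a simple seed-and-verify mapper aligns pairs to the
pseudo-long reads: exact 20-mer seeds at both mate ends, ungapped extension,
at most 3 substitutions.  Two safeguards matter for calling accuracy:

* **End clipping.**  A mate whose source molecule used a different splice
  junction can align with a short mismatching overhang at a junction edge.
  Mismatches within 8 nt of either end are therefore soft-clipped,
  iteratively chasing runs of near-end mismatches — the same reasoning that
  makes production aligners soft-clip junction overhangs.
* **Symmetric end trim.**  Clipping removes mismatching end bases but keeps
  matching ones; counting the survivors alone would bias shallow pileups
  toward the reference allele (the variant-bearing mate is clipped, its
  reference-matching sibling is not).  The pileup therefore ignores the
  outer 8 nt of *every* mate, restoring symmetry between alleles at the
  price of ~16 % nominal depth.

The mapper is intended for simulated data; real data should be mapped with
a production aligner and supplied as SAM/BAM.

## Allele-specific quantification

For each gene, an isoform's discriminating features are the junctions
present in it alone and the exonic intervals covered by it alone (interval
subtraction).  A read pair counts for an isoform when a mate spans a unique
junction or overlaps a unique exon region by ≥ 10 nt (the floor suppresses
1–2 nt spillover; no minimum is published, so it is configurable) and
matches no other isoform's features; ambiguous pairs are dropped.  Counted
pairs are assigned to a haplotype when every phased SNP they cover matches
that haplotype's allele; pairs covering no SNP or showing mixed matches are
unassignable.

Classification: fold change is max/min of the two allele counts (infinite
when one allele is unseen).  With ≥ 30 informative pairs, fold ≥ 2 is
*differential* and fold in [1, 1.105] is *equal*; everything else is
*undetermined* (the gap between the bands is undetermined by construction —
the two published classes are disjoint).  "Informative" defaults to
allele-assigned pairs only, since only those can support an allele claim;
a switch includes unassignable pairs for the stricter reading.  Allele
counts within one isoform share a library, so library-size normalisation
cancels and raw counts are compared directly.

## Library metrics

Detection rate is isoforms per 100 000 long reads.  Expression bins are
left-closed right-open (a gene with FPKM exactly 10 falls in [10, 50); the
published outer edges "< 10" and "≥ 500" imply the convention, which
interior edges follow for consistency; the interior edges are configurable).
Short-read coverage of an isoform counts exonic bases under aligned match
blocks (junction-aware); ≥ 90 % covered is *full*, anything in (0, 0.9) is
*partial*.  The phasing summary reports the share of long-read-phased SNP
pairs that short reads could not phase: 100 × (total − short-read-phased) /
total, to one decimal.

## Synthetic data

The generator emulates the structure of the study's data, not its scale:
one contig carrying `n_genes` genes (default 20) of 3–6 exons (150–450 nt,
introns 80–300 nt, canonical GT-AG edges by construction, an optional
non-canonical fraction, ~10 % single-exon genes), 1–3 isoforms per gene by
internal exon skipping, heterozygous SNPs at 2 per exonic kb (margin 3 nt
from exon edges; haplotype A carries the reference allele), and per-isoform
allele ratios.  Defaults for reads: 10 long reads per isoform with 1.5 %
substitutions and 0.2 % insertions/deletions, 3′ truncation with
probability 0.3 and exponential mean 20 nt (the published end-degradation
effect is small); short-read pairs at 30× per transcript, 100 nt mates,
250 ± 30 nt inserts, 0.2 % error, fragment starts uniform within the
transcript.

Allele ratios: 20 % of isoforms are 4-fold imbalanced (random direction),
the rest balanced — strong allele-specific expression is a minority of
genes in surveyed tissues, and 4-fold is a clearly detectable effect.  The
`zero_error()` variant — error-free reads, no truncation, balanced alleles,
and short reads laid out as a deterministic tiling of *both* haplotypes —
is the noiseless limit used for closed-form checks: under it, corrected
reads provably equal the true haplotype transcripts byte for byte.

What the generator does **not** model: platform-specific error profiles
(homopolymer bias), coverage biases (GC, positional), more than two
haplotypes, indels as variants, multi-mapping across paralogs, and
intergenic transcription.  Passing tests therefore demonstrate algorithmic
correctness under idealised sampling, not performance on real libraries.

Known boundary: at 4-fold imbalance the expected minor-allele fraction
equals the 0.2 calling threshold, so roughly half of the SNPs whose entire
local coverage is 4-fold imbalanced (e.g. single-isoform genes) fall below
it; sites shared by balanced isoforms of the same gene are unaffected.
This is inherent to the threshold, and overall recall on the default mix
is ~90–100 % depending on the seed.  Detected haplotype pairs are
essentially always exact, because the allele-pair complement constraint
leaves no freedom once the sites are called correctly.

## Numerical and testing choices

All coordinates are 0-based half-open internally; conversion happens only at
file boundaries.  Every tie (linkage rescue, haplotype placement) resolves
to "no action", and inputs are processed in sorted order, so the entire
pipeline is deterministic for a fixed seed; simulator outputs are
byte-identical across runs.  Randomness flows exclusively from the single
seed in `SimulationConfig`.

Test and acceptance problem sizes are chosen to exercise every code path at
desk scale: 20-gene simulations (~350 long reads, ~7 000 read pairs) for
end-to-end checks, 500 randomized toy annotations for the classification
oracles, 200 toys for completeness distances, and 100 seeded 3-gene
replicates for allele-ratio recovery.  The published headline counts from
full sequencing runs are not reproducible at this scale; the summary
*arithmetic* on the published count pairs is reproduced exactly.

## Known limitations

Indels are neither called nor phased (insertion/deletion support is visible
in alignments but not used); conflicting third haplotypes are flagged, not
resolved; the multi-mapping filter is the simple primary/secondary/MAPQ
rule; cross-sample isoform comparisons emit raw counts plus a
median-of-ratios size factor rather than a full normalisation model; the
built-in mapper is not a substitute for a production aligner on real data.
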