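# isohap

Full-length isoform classification, allele-specific phasing and
quantification for hybrid long/short-read RNA-seq of diploid samples.

Long reads capture complete transcript isoforms but carry percent-level
errors; short reads are accurate but cannot connect distant heterozygous
SNPs on one molecule.  `isohap` combines the two: it classifies and
collapses full-length long-read isoforms against a reference annotation,
rewrites each long read as a reference-base *pseudo-long read* to pile up
short reads, calls heterozygous SNPs, corrects the long reads, phases each
isoform into its two parental haplotypes, and quantifies allele-specific
isoform expression from isoform-specific read pairs.  It is aimed at people
analysing (in particular cDNA-normalized) single-molecule transcriptome
libraries with matched short-read data, and at method developers who need a
fully synthetic, ground-truthed playground for such pipelines.

## The core procedure

For a uniquely mapped long read (ROI) with splice frame *F*, the pseudo-long
read is `ref(F)` — the exon-concatenated reference sequence under *F*.
Short reads are piled on `ref(F)`; a position is a heterozygous SNP when

    depth ≥ 4,  exactly two bases with depth ≥ 2,  minor fraction ≥ 0.2.

Correction replaces consistently covered non-SNP positions with the
short-read base and *restores the original ROI base at SNP positions* — that
base is the molecule's allele.  An ROI is phased when > 1 SNP position is
fixed (its base matches a called allele); the linkage of allele combinations
across phased ROIs rescues further ROIs with residual errors.  Per isoform,
phased ROIs are partitioned into the two haplotypes (haplotype B is the
allele-pair complement of haplotype A), and isoform-specific read pairs are
split by allele:

    fold = max(n_A, n_B) / min(n_A, n_B)
    differential:  n_A + n_B ≥ 30 and fold ≥ 2
    equal:         n_A + n_B ≥ 30 and fold ∈ [1, 1.105]

Classification follows the standard full-length isoform rules: single- vs
multi-exon; canonical junctions (GT-AG, GC-AG, AT-AC in transcription
direction); CSMM / Non-CSMM / Novel gene attribution by shared splice
sites; exact intron-chain matching to annotated transcripts; collapsing of
molecules with identical intron chains and ends within 200 nt; and
aTSS/aTTS completeness distances (negative → 0).  See `docs/methods.md` for
the full model description and design rationale.

## Worked example

Everything runs end-to-end on the bundled diploid simulator — no downloads:

```
$ isohap all --seed 7 --genes 8 --out run/
simulated 17 isoforms over 8 genes -> run/simulate
classified 17 collapsed isoforms -> run/classify
phased 10 isoforms -> run/phase
quantified 10 phased isoforms -> run/quantify
sim-7: 10000 isoforms/100k ROIs; coverage full/partial/none = 17/0/0 -> run/metrics
```

The simulator wrote a genome, GTF annotation, error-prone long reads and
accurate paired short reads with truth alignments; the pipeline then
classified, phased and quantified them.  `run/phase/phased_isoforms.tsv`
holds the phased haplotype pairs:

```
isoform_id  contig  positions             haplotype_a  haplotype_b  support_a  support_b  phased  conflicting
G001.I1     chrS    1061,1592             TT           AC           3          7          yes     no
G002.I1     chrS    3479,3634,...,5466    GTTAAA       ACCGCG       2          7          yes     no
G003.I1     chrS    6241,7073             AG           GC           6          4          yes     no
```

Each row is one isoform: the genomic SNP positions (1-based), the two
assembled allele strings, and how many corrected long reads support each
haplotype.  `run/quantify/allele_quant.tsv` then splits isoform-specific
short-read pairs by allele:

```
isoform_id  hap_a  hap_b  unassignable  fold   class
G001.I1     8      12     76            1.500  undetermined
G002.I1     6      14     71            2.333  undetermined
```

G001.I1 drew 8 vs 12 allele-informative pairs (fold 1.5) — below the
30-pair floor, so no allele-balance call is made.  The final line of the
run reports the library metric: 17 isoforms from 170 simulated long reads
is 10 000 isoforms per 100k ROIs, and every isoform is fully (≥ 90 %)
covered by short reads.

The same stages are importable as a library
(`isohap.run_phasing`, `isohap.classify_isoforms`,
`isohap.quantify_alleles`, …), and each CLI stage reads and writes plain
files (FASTA/GTF/SAM/FASTQ/TSV), so any stage input can come from a real
aligner instead of the simulator.

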