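# Methods

`regland` reconstructs a genome's regulatory landscape from bulk chromatin
data for organisms where antibody-based TF mapping is impractical: ATAC-seq
fragments, four histone-mark ChIP peak sets, a gene annotation and gene-level
expression counts, across three phenotypes sharing one genome (the motivating
system is an insect brain with queen/worker/drone polyphenism; the code calls
them Q, W and D). This note documents the models, parameters, numerical
choices and limitations.

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3 (1-based inclusive) is
converted at the read boundary; narrowPeak `-log10` p/q columns become linear
probabilities on read. Fragment files (TSV or BEDPE) are the entry point;
converting aligned BAM records to fragments (duplicate handling, MAPQ
filtering) is an upstream step outside this package.

## Fragment classes

ATAC fragment lengths are classified by the standard sub-nucleosomal bands:
0–100 bp nucleosome-free (NFR), 150–247 bp mono-nucleosome, 315–473 bp
di-nucleosome, all bounds inclusive. Lengths in the printed gaps (101–149,
248–314, >473) are left `unassigned` rather than force-assigned: the bands
are a deliberate conservative partition, not a tiling.

## NFR peak calling

A windowed scan over NFR-class fragment midpoints, not a MACS2 port (parity
with MACS2 is explicitly not a goal). Windows of 200 bp, stepped by 50 bp,
are tested against a Poisson background with

    lambda = max(genome-wide rate, 1 kb local rate, 10 kb local rate) x window

p-values are Benjamini–Hochberg corrected over all windows genome-wide;
windows with q <= 0.05 are merged when overlapping or adjacent, and the peak
summit is the maximum-fragment-coverage bp. The tiered local lambda absorbs
regional background variation the way local-bias models in standard callers
do. The effective genome size defaults to the observed genome; for real
insect-scale data the conventional value is 2.7x10^8 bp.

Replicate consensus keeps peaks with >= 1 bp overlap in the other replicate
and merges each overlapping group into its union interval. Consensus is
idempotent on identical inputs.

Tn5 cut sites are fragment ends shifted +4/−5 bp (standard ATAC convention;
the choice matters only jointly with the bias-model window, both are
configurable).

## Differential accessibility

Counts of NFR fragments in the phenotype-union consensus peak set are
normalized by median-of-ratios size factors; each peak gets a two-sided
z-test on normalized group means under a quadratic mean–variance model
`var = mu + phi*mu^2` with a pooled method-of-moments dispersion floored at
0.01, then BH correction (significant at q <= 0.05). A z-test over a full
negative-binomial GLM is a deliberate trade: deterministic, closed-form and
easily oracle-testable, adequate at n = 2 replicates where GLM dispersion
estimation is itself unstable. The fold change is first group over second in
sorted label order, so relabeling negates it.

## Chromatin states

The chromatin state of a region is the subset of {H3K4me1, H3K4me3, H3K27ac,
H3K27me3} covering it. Consensus peaks per mark are flattened into disjoint
bp-resolved segments with boundaries at every peak edge — the UpSet-style
exhaustive decomposition; both segment-count and bp percentages are emitted
because either can serve as the unit. Feature enrichment is

    log2( (state bp in feature / state bp) / (feature bp / genome bp) )

with a 1 bp pseudocount on empty cells only, so exact ratios stay exact.
Feature assignment uses the interval midpoint with priority
promoter > 5'UTR > exon > intron > 3'UTR > intergenic; the promoter is the
200 bp window upstream of the TSS (same width as the TSS classification
window, configurable). Because GFF3 exons contain their UTRs, the priority
rule gives 5'UTR labels precedence over exons but masks 3'UTRs that lie
inside exons — a property of the stated priority order, kept as-is.

NFR peaks are split into `tss` (>= 1 bp overlap with TSS +- 200 bp,
strand-oriented and symmetric) and `non_tss`. Each NFR takes the state at
its summit (midpoint when no summit was called); per-class state percentages
include an `unmarked` row and sum to 100.

Mark co-occurrence (e.g. H3K4me3 x H3K27ac) is a Fisher exact test on the
bp-weighted 2x2 table over the genome. bp weighting, not segment counting,
is used in the pipeline report: replicate boundary jitter creates thin
single-mark sliver segments at every state edge which would dominate a
segment-count table.

## Footprinting

Motif sites come from a log-odds PWM scan of both strands within accessible
regions. The PWM is the JASPAR convention:
`log2(((count + 0.8*bg) / (col_total + 0.8)) / bg)` with uniform background;
the hit threshold defaults to 0.8 x the maximum attainable bits. Overlapping
same-motif hits keep the higher score (ties prefer the leftmost, then the +
strand).

Tn5 sequence bias is corrected by a k-mer rate model (k = 6; the window for
a cut at position i is [i-3, i+3)): each k-mer's rate is its observed
cut count divided by its genomic frequency, normalized to usage-weighted
mean 1; corrected signal is observed/(expected + 0.01). Positions with
non-ACGT bases pass through unchanged.

The footprint score of a site is

    FS = log2( (mean corrected cuts over 20 bp flanks + 0.1) / (mean over motif core + 0.1) )

A bound factor protects its core from insertion, so FS grows with core
depletion and is 0 on flat signal. Sites are called bound at FS >= tau,
where tau is an exact Otsu threshold (the split of the sorted FS values
maximizing between-class variance; >= 50 sites required, or pass tau
explicitly). Occupancy per motif is 100 x bound/sites over sites inside NFR
peaks, ranked descending. The alternative occupancy notion (fraction of
NFRs containing a bound site) is derivable from the per-site table.

Differential occupancy between phenotypes scores the shared site set in
both, takes per-motif dFS = mean FS difference, and compares it to a null of
100 motif-blind random site subsets of matching size:
`z = (dFS - null mean) / (null sd * sqrt(1 + 1/draws))` with a two-sided
t(draws-1) p-value (the prediction-error scaling accounts for the null
moments being estimates) and BH correction over motifs. Under exchangeable
phenotypes this is calibrated to within ~1 percentage point of nominal at
alpha = 0.05 (verified by the test suite's 500-run null study; residual
inflation reflects the non-normality of few-site means).

## TF–TF network

An edge A -> B exists when >= 1 bound site of motif A lies in the gene
encoding TF B or in its promoter window, defined for network purposes as
−2 kb..+200 bp around the TSS, strand-oriented. This window is deliberately
a separate named constant from the 200 bp TSS-classification window so the
two definitions cannot collide. Edge class is `tss` (all supporting sites in
the window), `non_tss` (all elsewhere within the gene) or `both`; self-loops
are allowed and flagged. Per-phenotype networks are merged into a combined
network carrying a phenotype set per edge. Root-anchored subnetworks follow
edge direction breadth-first with deterministic (depth, lexical) ordering.
Motifs mapping to the same gene would merge into parallel edges keyed by the
target gene. Exports: TSV and Graphviz DOT (edge color by class).

## Synthetic data generator

The generator is first-class, tested code that defines the study conditions;
every planted element is recorded in a manifest for truth scoring.

Defaults (one value per row; all configurable via `SimConfig`):

| parameter | default | why |
|---|---|---|
| genome | 2 Mb over 4 chromosomes | desk-scale analogue of a 2.3x10^8 bp genome |
| genes | 200, fixed 3-exon structure (2.8 kb) | enough hosts for planted elements |
| fragment mixture | N(55,18) truncated >0 / N(200,25) / N(400,35), weights 0.5/0.35/0.15 | tri-modal ATAC size distribution with nucleosomal periodicity |
| fragments/replicate | 4x10^5 (x3 phenotypes x2 replicates) | NFR coverage comparable to high-coverage real data |
| planted NFRs | 240 x 300 bp; 35% at TSSs, 64% of the rest in introns | matches the predominantly intronic, then promoter/5'UTR placement of accessible regions |
| NFR enrichment | 10x coverage rate ratio | clearly super-threshold but not trivial |
| phenotype sharing | 80% of NFRs shared; 20% specific (cycled Q/W/D) | gives the differential stages true positives |
| chromatin states | NFR +- 300 bp; TSS states mostly K4me3/K27ac, intronic mostly K27ac-centric, intergenic K27me3-centric; 10% unmarked | mirrors the reported state geography |
| ChIP noise | boundary jitter U(-50,50) per replicate; 10% false peaks in exactly one replicate | exercises the consensus step |
| motifs | 12 synthetic 10-bp PFMs (97:1 counts), near-palindromes excluded | single-mismatch rejection at the 0.8 threshold keeps planted-site recovery identifiable |
| binding | 2 sites per shared NFR; motif 1 bound at 0.95 (the planted top), motifs 2..10 at 0.25–0.55, last two phenotype-specific at 0.7 | a clear occupancy ranking plus differential truth |
| footprints | bound cores keep cuts at 0.25x by rejection sampling | the minimal mechanism the flank/core score detects |
| nucleosome phasing | half of mono-class fragments centered TSS+250 +- N(0,30) | the well-positioned +1 nucleosome in TSS metaprofiles |
| expression | NB, dispersion 0.1, +1 log2 shift for NFR-containing genes | the planted accessibility–expression link |

Near-palindromic motif consensi (exact self-reverse-complement alignment
within a +-6 bp shift) are rejected: planting the reverse strand of such a
motif creates an overlapping equal-scoring forward hit that wins scan
deduplication and makes site recovery ambiguous.

All randomness flows from one root seed through named substreams
(`SeedSequence([seed, crc32(name), ...])`), so each stage is independently
reproducible and skipping one stage never shifts another's draws. The
noiseless configuration (`SimConfig.noiseless()`: zero jitter, zero false
peaks, full core protection, all NFR-class fragments on planted NFRs) is the
dial-to-zero limit in which chromatin-state segments, the bound-site set and
the TF–TF edge network are recovered exactly. Peak *intervals* are never
bit-identical to planted NFRs — the windowed caller quantizes boundaries to
the 50 bp step grid — so NFR recovery is scored as the fraction of planted
bp covered.

What the generator does **not** emulate: read-level sequences and sequencing
error, Tn5 sequence preference (the genome is unbiased, so the bias model is
exercised as a calibrated near-identity, plus a planted-rate unit test),
mappability structure, overdispersed/correlated fragment placement, partial
or graded occupancy dynamics, and realistic motif information content
degradation. Passing tests therefore demonstrate the pipeline's correctness
and statistical calibration on data that satisfy its model assumptions, not
performance on real libraries.

## Test and verification sizes

Oracle-equivalence checks (windowed caller vs per-window enumeration,
segment decomposition vs per-bp labeling, PWM scan vs all-window scoring,
Fisher vs hypergeometric enumeration, rank test vs full enumeration) run on
<= 50 kb toy inputs where brute force is exact. Truth-recovery checks run
one full default-size dataset plus a noiseless one; ranking-stability
Monte-Carlo uses 100 seeded runs of a reduced configuration (0.5 Mb genome,
60 genes, 60 NFRs, 4 motifs, 2x10^5 fragments per run — chosen to keep both
per-motif site counts and per-bp cut coverage near the default conditions,
so score separation is comparable) and the type-I calibration studies
use 500 seeded reduced-size null datasets. These sizes are the package's own
verification design.

## Known limitations

* The peak caller's boundaries are step-grid quantized and systematically
  ~1 window wider than the underlying accessible region.
* The differential accessibility z-test assumes the quadratic mean–variance
  model; with many replicates a count GLM would be preferable.
* Otsu thresholding presumes a genuinely bimodal FS distribution; datasets
  with very low binding rates should pass an explicit `tau`.
* `gene contains an NFR` means >= 1 bp overlap of the gene span plus its
  200 bp promoter window — other boundary conventions change the gene
  percentages by a few points.
* Expression normalization is median-of-ratios on gene-level counts; no
  attempt is made to reproduce transcript-level quantification pipelines.
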