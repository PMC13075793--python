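# Methods

This note documents the models and procedures implemented in `nucphase`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Nucleosome dyad calling and phasing

MNase protects ~147 bp of nucleosomal DNA, so a paired-end fragment midpoint
approximates the nucleosome dyad. `midpoint_density` bins midpoints at base
resolution and smooths with a Gaussian kernel (σ = `bandwidth`, default
20 bp; kernel truncated at 6σ with constant-zero boundary, so the genome-wide
integral equals the fragment count minus edge loss). The kernel family and
default are this package's choice — dyad-mapping tools in the field do not
agree on one — and are exposed as parameters.

`call_dyads` takes local maxima of the smoothed density above `min_score`
and accepts them greedily in descending score with a `min_separation`
exclusion zone (default 120 bp, just under one nucleosome footprint, to
prevent double-calling a single nucleosome). Score ties break toward the
leftmost position, making the output order-deterministic.

`plus_one_anchors` assigns each gene the first called dyad at or downstream
of its TSS in the gene's strand frame, searching 300 bp; genes without one
are skipped and counted. The 300 bp window is a package default — annotation
conventions for the +1 nucleosome vary — and is a parameter.

`metaplot` builds an anchors × relative-position matrix with +x pointing
downstream in each anchor's strand frame (minus-strand rows reversed).
Normalization modes: `none`, and `library-mean-1` (track rescaled to
genome-wide mean 1 before extraction), the latter used for "normalized
nucleosome density" style profiles. Both global and per-gene interpretations
of such profiles exist in the literature; the matrix of per-anchor rows is
returned so either can be computed.

`phasing_score` measures periodicity of a mean profile as the maximum of its
mean-subtracted, *unbiased* (overlap-corrected) normalized autocorrelation
over lags 100–220 bp; the lag attaining it is the period. The unbiased form
makes a pure cosine of period L score amplitude 1 at lag L regardless of
window length. The score is invariant to affine rescaling of the profile. A
flat profile reports amplitude 0 and no period.

`dyad_gc` reports (G+C)/(A+C+G+T) × 100 over ±50 bp dyad windows, N bases
excluded from numerator and denominator, windows clipped at chromosome ends.

## Antisense transcript annotation

`collapse_transcripts` merges redundant long-read transcript models: two
models merge when they share the chromosome and strand, have identical
internal exon-junction chains, and have 5' and 3' ends within 100 bp each
(single-exon models must additionally overlap). Merging is single-linkage
(transitive closure), and each group is represented by its longest-span
member, ties to the leftmost. Tolerances mirror common long-read collapse
practice and are parameters.

`classify_antisense` labels a model `antisense_exonic` when ≥1 bp of one of
its exons overlaps ≥1 bp of a reference exon on the opposite strand and the
model has no same-strand exonic overlap; intron-only opposite-strand overlap
does not qualify. Same-strand evidence takes precedence when a model touches
exons on both strands (counted and logged) — the conservative choice, since
such a model is plausibly a sense read-through. No requirement is placed on
where the transcript starts, so antisense units that initiate intergenically
and extend into gene bodies are naturally included. `derive_as_tss` returns
deduplicated strand-aware 5'-end anchors of the antisense calls.

## Window quantification and the occupancy–initiation relationship

`window_mean` averages per-base signal over a strand-framed window
[rel_start, rel_end) around each anchor; for a minus-strand anchor at p the
genomic window is [p − rel_end + 1, p − rel_start + 1). The two standard
windows are initiation = mean antisense-strand signal over [0, 200)
downstream of the As-TSS, and occupancy = mean (unstranded) nucleosome
density over [−500, 0) upstream. Windows are clipped at chromosome ends and
the clip fraction logged; a fully clipped window yields NaN.

`occupancy_initiation_correlation` takes the per-condition means (one point
per condition/strain, as a severity series is summarized) and reports
Spearman and Pearson correlation plus a least-squares line. The headline
statistic is the rank correlation; with only ~4 condition points its
magnitude should be read qualitatively (the package's acceptance checks ask
for ≤ −0.8, not a specific value). A per-anchor mode is available through
`window_stats` for exploratory scatter.

`stratify_quartiles` uses empirical quartile cut points with ties assigned
to the lower quartile, so an all-tied vector is all Q1 and tie-free vectors
split 25/25/25/25 (±1). `partition_signal` reports the fraction of total
track signal inside gene spans; paired raw genic/intergenic sums from two
tracks form the 2×2 table for `fisher_enrichment`.

## Promoters, PWMs, and exact match p-values

Promoters are the 500 bp upstream of a TSS or As-TSS, reported 5'→3' in the
anchor strand frame (minus-strand windows reverse-complemented), clipped at
chromosome ends.

A `Pwm` stores strictly positive column probabilities (pseudocount 0.25 per
cell when built from counts) and a background distribution; scores are
log2(p/background) summed over the window. Builders exist for count
matrices, JASPAR PFM files, MEME minimal files, and IUPAC consensus strings
(within-code uniform weights), so TATAWAWR-based analyses run without any
external matrix file.

Match significance is P(score of a background-drawn W-mer ≥ s). For widths
≤ 10 this is computed exactly: the score distribution is built by
convolving one column at a time and merging identical partial sums (at most
4^W states, in practice far fewer). For wider motifs a discretized dynamic
program on a 1e-4-bit grid is used, with one grid tick of slack per column
so no qualifying W-mer is ever dropped; the p-value error is bounded by the
probability mass within W ticks below the threshold. `scan_pwm` scans both
strands by default, skips windows containing N, and thresholds at p ≤ 1e-4.
The background is uniform, estimated from the scanned sequence set (0-order,
the FIMO default family), or an explicit frequency vector.

A statistical caveat documented here because it shapes every TATA analysis:
a width-8 consensus motif like TATAWAWR has 8 tied top-scoring 8-mers, so
its minimum attainable p-value under a uniform background is 8/4^8 ≈
1.22e-4 — *above* the conventional 1e-4 threshold — and under an AT-rich
background the motif is even less surprising. Finding a TATA box in 70%-AT
sequence is statistically unremarkable. Quantitative TATA statements in this
package are therefore made against backgrounds GC-richer than the motif
(the planted-promoter fixture uses a GC 0.80 carrier scanned against an
explicit 60%-GC background), where every consensus word is significant and
chance hits are negligible (~4e-4 expected per 500 bp promoter). Published
TATA-fraction estimates that use full-length curated TBP matrices are not
directly comparable to consensus-PWM scans and are not asserted here.

Positional histograms bin match centers (offset + ⌊W/2⌋, mapped to −500..−1
with 0 the TSS) into half-open 5-bp bins anchored at −500.

## Enrichment, differential expression, growth

`hypergeom_overlap` is the upper-tail hypergeometric test P(X ≥ k) for the
overlap of two sets in a universe, with a sample odds ratio (Haldane 0.5
correction when a cell is zero) and a log-OR Wald CI. `fisher_enrichment`
is the two-sided conditional exact test (scipy) with the same OR convention.

The DE engine is deliberately simple and fully documented: median-of-ratios
size factors (features positive in all samples form the reference), a
negative-binomial dispersion per feature estimated by method of moments from
pooled within-condition residuals, shrunk geometrically halfway toward the
across-feature median (with 2–3 replicates the raw per-feature estimate is
far too noisy to test against; shrinking toward a central value is the
standard remedy in this model family), and a Wald test on the log fold
change with variance Var(mean of normalized counts)/mean², BH-corrected.
All-zero features are excluded; a condition with an all-zero mean gets a 0.5
continuity guard. `vst_like` is log2(count/size-factor + 1), a declared
variance-flattening stand-in, monotone in counts. The engine's contract is
its operating characteristics, asserted by the test suite: on null NB
simulations (2,000 features, n = 3) the BH-0.05 positive fraction stays
~1% (bound 7.5%), and planted 4-fold antisense changes at mean 100,
dispersion 0.05, n = 3 are recovered with ≥ 80% (observed ~100%) recall.

Growth fitness is the empirical trapezoidal AUC of an OD time course
(OD·h); a logistic-fit AUC (K/(1+((K−N0)/N0)e^(−rt)) fitted by least
squares, integrated analytically) is available for noisy curves. Mutant
fitness is log2(AUC_mutant/AUC_WT) under matched media/condition.

## The synthetic genome: what it emulates, and what it does not

Defaults (all in `SimConfig`): 2 chromosomes × 200 kb; 60 genes of 2–4 kb
with 200–600 bp intergenic gaps; background GC 0.36 (fission-yeast-like);
one 500 bp AT-rich island (AT 0.70) mid-gene in one third of genes (20
islands); 10% of genes emitted as convergently nested opposite-strand guests
(400–800 bp, ≥100 bp margins) inside non-island hosts; nucleosome spacing
150 bp with the +1 dyad 75 bp into the gene; fragment lengths
Normal(147, 10) truncated to [120, 180]; antisense TSS at the island edge so
that its 500 bp upstream window is the island, with a TATAWAWR word planted
30 bp upstream (promoter frame) with probability 0.2; antisense coupling
κ = 40 expected initiation events per As-TSS at full upstream depletion,
each laid down as a 50 bp downstream extension; sense signal = Poisson
per-base body rate 0.2 plus a pausing bump (+3.0) in the first 200 bp;
counts negative binomial with dispersion 0.05, sense mean 100, antisense
baseline mean/4, antisense fold change 4 at island genes in the mutant.

Positional disorder is modeled as a *capped random walk* along each array:
the +1/+2 nucleosomes keep a tight SD (σ_wt = 10 bp) and dyad k ≥ 2 has SD
σ·√min(k−1, 4), with σ interpolated from σ_wt toward σ_mut = 25 bp in
proportion to the condition severity δ. This choice is load-bearing: arrays
are statistically positioned against the +1 barrier, so positional noise
should accumulate with distance (phasing decays "beyond the +2"), yet
flanking barriers re-phase arrays, so the blur must saturate (the cap)
for wild-type dyads to stay individually callable. Independent per-dyad
jitter — the obvious alternative — leaves the mean profile perfectly
periodic at any blur and cannot reproduce severity-dependent loss of
phasing amplitude. Mutant conditions additionally drop island-overlapping
dyads with probability δ; δ = 0 reproduces the wild type exactly.

Antisense initiation is coupled to chromatin as
rate = κ · max(0, 1 − occupancy/reference), where occupancy is the mean
fragment coverage over the 500 bp upstream of the As-TSS and the reference
is the median coverage at non-island planted dyads of the same sample (the
sample's own full-occupancy scale). The linear form and κ are stand-ins —
no quantitative occupancy→initiation law is established — chosen so the
*sign and strength regime* of the occupancy–initiation correlation is
recoverable, not its magnitude.

Random streams are split per data layer (genome, MNase, PRO-seq, counts)
and keyed by condition and severity, so changing the fragment count of one
layer never perturbs another; every output is byte-reproducible from the
seed.

Deliberately not emulated: sequencing error and read-level artifacts, MNase
sequence bias, replicate batch effects, multi-isoform genes, heterogeneous
island counts per gene, and any coupling between sense expression and
chromatin state. Passing tests on this generator demonstrate that the
analysis recovers planted structure under the stated generative model; they
do not validate the generative model itself against real chromatin.

## Problem sizes used for verification

The end-to-end study runs 4 severity conditions (δ = 0, 0.3, 0.6, 0.9) at
50,000 fragments each on the 2 × 200 kb genome (~1,100 planted dyads, 20
antisense TSSs); the whole chain takes a few seconds. DE operating
characteristics use 2,000 null features and 1,000 features with 20% planted
changes at 3 replicates per condition. Oracle-equivalence checks use
randomized fixtures of 200–500 items against brute-force enumeration.

## Known limitations

- The dyad caller assumes well-separated density modes; closely spaced
  alternative positioning (<120 bp) is reported as one call.
- Phasing amplitude from a mean profile conflates positional disorder with
  occupancy heterogeneity across anchors; per-anchor spectra are not
  implemented.
- The DE engine has no outlier handling, no independent filtering, and no
  shrinkage of fold changes; it is meant for well-behaved designs with 2+
  replicates, not as a general replacement for the established frameworks.
- `classify_antisense` uses exon overlap only; it does not model readthrough
  or overlapping UTR annotation quality.
- Quantitative TATA fractions depend strongly on the matrix and background
  used (see above); only fixture-calibrated statements are asserted.
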