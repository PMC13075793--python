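# nucphase

Analysis toolkit for a question at the heart of chromatin biology in compact
fungal genomes: how phased gene-body nucleosome arrays suppress cryptic
antisense transcription, and what happens when the chromatin remodeler that
maintains them is lost.

It is written for genomicists working with MNase-seq, nascent-transcription
data (PRO-seq), long-read transcript models, and genome annotation in
*Schizosaccharomyces pombe*-sized genomes, and covers the full analysis
chain:

- **Nucleosome organization** (`nucphase.nucleosome`) — Gaussian-smoothed
  fragment-midpoint (dyad) density from MNase fragments; greedy dyad calling
  with a minimum separation; strand-framed metaplots around arbitrary
  anchors; a phasing score (period and amplitude of the mean profile's
  normalized autocorrelation in the 100–220 bp nucleosome-repeat band); GC%
  of ±50 bp dyad windows, computed as (G+C)/(A+C+G+T) × 100 with N excluded.
- **Antisense annotation** (`nucphase.antisense`) — redundancy collapse of
  long-read transcript models (identical junction chains, 5'/3' ends within
  100 bp, transitive closure) and classification of antisense transcripts by
  ≥1 bp exonic overlap with an opposite-strand reference gene; strand-aware
  antisense TSS (As-TSS) anchors.
- **Window quantification** (`nucphase.signal_quant`) — mean antisense
  PRO-seq signal in the 200 bp downstream of each As-TSS, mean nucleosome
  occupancy in the 500 bp upstream, per-condition summaries with SEM, and
  their cross-condition Spearman/Pearson correlation; expression quartiles;
  genic/intergenic signal partitioning.
- **Gene architecture** (`nucphase.architecture`) — the catalog of
  convergently nested genes: protein-coding genes entirely embedded within,
  and transcribed opposite to, longer host genes.
- **Promoters and motifs** (`nucphase.promoter_motifs`) — 500 bp upstream
  promoter windows in the anchor strand frame, GC composition, PWM scanning
  with *exact* score-distribution p-values (dynamic programming; FIMO-style
  p ≤ 1e-4 threshold), TATA-box (TATAWAWR) fraction and 5-bp positional
  histograms.
- **Statistics** (`nucphase.stats_fitness`) — hypergeometric set-overlap and
  Fisher exact enrichment; median-of-ratios size factors; a transparent
  NB-Wald differential-expression engine with moderated method-of-moments
  dispersion and BH correction; growth-curve AUC and log2 AUC relative to WT.
- **Synthetic data** (`nucphase.synthetic`) — a miniature genome with known
  ground truth: +1-anchored nucleosome arrays with ~150 bp spacing, AT-rich
  intragenic "cryptic islands" optionally carrying a TATA box upstream of a
  planted As-TSS, condition-dependent occupancy loss at islands, sense
  pausing peaks, antisense initiation coupled to local nucleosome depletion,
  negative-binomial counts, and convergently nested gene pairs.

## The model in brief

Nucleosome dyads are estimated as smoothed MNase fragment midpoints. For a
gene with TSS-anchored array, the +1 dyad is the first called dyad within
300 bp downstream of the TSS; phasing amplitude is
max<sub>lag ∈ [100,220]</sub> of the unbiased normalized autocorrelation of
the mean ±800 bp profile. Antisense initiation is quantified per As-TSS as
mean signal over [0, 200) downstream (anchor strand) and nucleosome
occupancy as mean density over [−500, 0) upstream; the package tests the
occupancy–initiation relationship as a rank correlation across conditions
(the regime of interest is strongly negative, r ≈ −0.9 to −1). Motif match
significance is P(log-odds of a background-drawn W-mer ≥ score), computed
exactly from the score distribution.

## Worked example

```python
from nucphase.pipeline import run_synthetic_study
from nucphase.synthetic import SimConfig

result = run_synthetic_study(SimConfig(seed=1), deltas=(0.0, 0.3, 0.6, 0.9),
                             n_fragments=50_000)
print(f"dyad recovery      {result.dyad_recovery:.3f}")
print(f"phasing amplitudes {[round(a, 3) for a in result.phasing_amplitudes]}")
print(f"spearman r         {result.correlation.spearman_r:.2f}")
print(result.summary[["occupancy_mean", "initiation_mean"]].round(2))
```

prints

```
dyad recovery      0.996
phasing amplitudes [0.838, 0.813, 0.782, 0.749]
spearman r         -1.00
           occupancy_mean  initiation_mean
condition
delta_0             43.72             0.26
delta_0.3           31.88             3.29
delta_0.6           21.04             5.76
delta_0.9           10.52             8.04
```

Reading it: 99.6% of the planted dyads are re-called within ±10 bp; as the
severity δ of island occupancy loss rises from 0 (wild type) to 0.9, the
+1-anchored phasing amplitude decays monotonically, mean nucleosome
occupancy upstream of the antisense TSSs falls ~4-fold, antisense initiation
downstream rises ~30-fold, and the four condition means are perfectly
anti-ranked (Spearman r = −1): nucleosome loss over intragenic AT-rich
islands exposes cryptic promoters that fire in the antisense direction.

A command-line layer mirrors the library (`nucphase simulate`, `nucphase
dyads`, `nucphase metaplot`, `nucphase antisense`, `nucphase nested`,
`nucphase motifs`, `nucphase de`, `nucphase growth`, `nucphase io validate`).

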