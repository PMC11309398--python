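# Methods

## Study design and model

The pipeline targets a 2×2 factorial bulk RNA-seq design: each sample is a
(Fraction, Condition) combination, Fraction ∈ {synaptosome, homogenate},
Condition ∈ {case, control}. Counts for gene *g* in sample *s* are modeled
as negative binomial with mean

    μ_gs = m_s · 2^( β0_g + βF_g·[syn] + βC_g·[case] + βI_g·[syn ∧ case] )

and variance μ + α_g μ² (α = 0 is Poisson). βI is the mislocalization
effect: a nonzero interaction means the case-vs-control fold change differs
between fractions. The synthetic generator draws from exactly this model and
records the planted βI as truth, so downstream sensitivity and FDR can be
scored without re-deriving parameters.

## Differential expression engine

A deliberately simplified stand-in for a full NB GLM framework, sufficient
to supply the (log2fc, SE) pairs the localization statistic consumes:

* **Size factors**: median-of-ratios. The reference profile is the
  per-feature geometric mean over samples, restricted to features with no
  zero count anywhere; each sample's factor is its median ratio to the
  reference. When no feature is everywhere-positive the default is a hard
  error; an explicit `allow_pseudo_reference` flag switches to a
  positive-counts geometric mean.
* **Filtering**: keep features with ≥ `min_count` in ≥ `min_samples`
  samples (inclusive thresholds). Defaults 10 and 9 for mRNA, 4 and 5 for
  circRNA junctions.
* **Per-feature test**: normalized counts y = count/size factor; group
  means μ̂_A, μ̂_B; pooled method-of-moments dispersion (within-group sample
  variance minus the shot-noise term, pooled by df, floored at 1e-8 — no
  trend fitting or shrinkage); log2fc = log2(μ̂_B + c) − log2(μ̂_A + c) with
  pseudo-count c = 0.5/geometric-mean size factor (bounds the fold change
  of features with a zero group mean without dropping them; the difference-
  of-logs form makes contrast swap negate log2fc bit-exactly); SE by the
  delta method from the NB variance of the group means; Wald = log2fc/SE.
* **Tails**: two-sided Student *t* with nA+nB−2 df. The SE rests on a
  dispersion estimated from nA+nB−2 residual df, so the Wald statistic is
  t-like in small samples: with normal tails the measured null level at
  n = 6 per group is 0.078 at nominal 0.05 — exactly P(|t₁₀| > 1.96) —
  while t tails give 0.050. At n = 20+ the two coincide to within
  Monte-Carlo error.
* **Multiple testing**: Benjamini–Hochberg throughout.
* **Degenerate guard**: a feature with zero counts in both groups reports
  log2fc 0, SE 1, p 1.

Externally produced (log2fc, SE) tables can be fed directly to the
mislocalization stage in place of this engine.

## Mislocalization statistic

Per feature, with the two case-vs-control contrasts:

    Rw  = lfc_syn/SE_syn − lfc_hom/SE_hom
    T_i = Rw_i / sqrt( (Σ_j Rw_j²/G) / N )

The denominator is the root-mean-square of Rw over the G features tested,
shrunk by √N. T is therefore scale-free in Rw (invariant to global
rescaling, sign-equivariant), and p-values are two-tailed Student *t* with
N−1 df by default; a `normal` option exists because either reading of the
historical description is defensible, and the choice is exposed in
`AnalysisConfig.p_null`.

**Choice of N.** N is the number of samples contributing to the two
contrasts; `n_samples_N="auto"` resolves to the total sample count of the
filtered dataset, the only sample count common to both contrasts. It can be
overridden.

**Calibration.** Because T is standardized by the empirical RMS, the mean of
T² equals N identically. Under a global null with approximately normal Rw,
T then behaves like a normal with variance N rather than 1, so the test is
anti-conservative: the package's own null benchmark (2000 genes, 3
replicates per cell, N = 12) measures P(p < 0.05) ≈ 0.47. This is a
structural property of the statistic, not an implementation artifact — no
choice of the DE engine can alter it, since the exceedance probability
depends only on the shape of the Rw distribution. Consequently the
statistic should be paired with a stringent FDR cutoff (0.001 default;
0.01 preset for smaller designs), and ranked results (the planted-effect
benchmark measures sensitivity ≈ 0.98 at q < 0.01) are more trustworthy
than the nominal error rate. Users who need calibrated interaction
p-values should fit a joint NB GLM with an interaction term instead; that
alternative is deliberately out of scope here.

Zero Rw never counts as evidence: p is forced to 1 when Rw = 0, and an
all-zero Rw vector returns the degenerate t = 0, p = 1 with a logged
warning. Direction calls (up/down/ns) partition features by the sign of Rw
at the chosen FDR.

## circRNA discovery

* **Junction reference**: for every transcript with E exons, all E(E+1)/2
  donor ≥ acceptor pairings, including single-exon circles (donor =
  acceptor). The junction sequence is the last min(flank, C) nt of the
  circle (ending at the donor 3′ end) followed by the first min(flank, C)
  nt (starting at the acceptor 5′ end), flank 150 nt by default, C the
  circle length. Flanks are clamped to the circularized region and never
  wrap, so no genomic base appears more than twice and a read cannot hit
  one junction at two offsets. Junctions identical at (gene, donor exon
  genomic span, acceptor exon genomic span) across redundant transcripts
  are emitted once.
* **Alignment contract**: ungapped, full-read-length, Hamming mismatches
  only, both orientations; implemented with pigeonhole k-mer seeding and
  vectorized verification. This matches the synthetic read model (exact
  substrings with substitution errors); gapped alignment of real reads is
  out of scope.
* **Partitioning**: a read is linearly mapped iff it aligns full-length to
  any spliced transcript with ≤ `max_mismatch` mismatches; only the
  unmapped remainder is searched against the junction reference.
* **Counting rule**: a read counts toward a junction iff its alignment
  covers ≥ `min_anchor` (default 10) nt on each side of the breakpoint.
  Among qualifying junctions the unique best (fewest mismatches) wins;
  ties across distinct junction ids discard the read into a per-sample
  `ambiguous_discarded` tally — a deterministic alternative to an aligner's
  arbitrary single placement.
* **Joint normalization**: junction counts are appended to the linear count
  matrix before size-factor estimation so circular features are normalized
  in the context of the whole transcriptome; the circRNA filter (≥4 in ≥5
  samples) is applied to the junction rows only, and DE results are
  reported for circular features only. Appending junction rows never
  changes which linear features pass their own filter.
* **Isoform switches**: a gene is reported when ≥2 of its junctions are
  significant (raw p below the cutoff, 0.05 default) with at least one
  pair of opposite-sign fold changes; every opposite-sign pair is listed.
* **Exon spans**: histogram of donor − acceptor over junctions with nonzero
  counts (0 = single-exon circle).

## miRNA site enrichment

Site counting is consumed as precomputed per-gene tables (the synthetic
generator stands in for an external target predictor). For miRNA m with
s_m/S shortlist sites and b_m/B background sites, log2fc =
log2((s_m/S)/(b_m/B)) — observed over expected share — with a +0.5
continuity offset (flagged) when s_m or b_m is zero. Significance is a 1-df
Pearson χ² on [[s_m, S−s_m], [b_m, B−b_m]] without continuity correction
(the correction is toggleable only by editing the 2×2 statistic; it is
omitted deliberately), upper tail, BH-adjusted. The background is the full
transcriptome table with shortlist genes included, matching the
observed-vs-expected construction; a disjoint background simply means
passing a table with the shortlist genes removed. Exchanging shortlist and
background negates log2fc and preserves χ² exactly.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume —
NB factorial counts with planted effects and library-size variation
(lognormal multipliers, σ ≈ 0.15), uniform read sampling from linear
transcripts and circles with wrap-around and i.i.d. substitution errors,
Poisson site counts with planted fold enrichment. They do not model
paired-end reads, indels, GC or positional bias, fragment-length effects,
strandedness, batch effects, or correlated biological replicates.
Consequently, passing recovery tests demonstrates correctness of the
statistical machinery under its stated model, not robustness to the
artifacts of real libraries.

Desk-scale defaults (2000 genes, 3–6 replicates per cell, 10–20
transcripts, 20k reads per sample) keep each end-to-end benchmark in
seconds while leaving Monte-Carlo error well inside the tolerances tested.

In the circRNA benchmark, planted circles carry per-circle weights of 0.16
(synaptosome) vs 0.04 (homogenate) against 1.0 per linear transcript — a
4-fold planted enrichment with circular reads a small minority of each
library, as in real ribodepleted total-RNA data. That minority status is
load-bearing: median-of-ratios normalization of the combined matrix must be
anchored by the linear features, otherwise the planted effect is absorbed
into the size factors. Single-exon circles keep the junction-spanning share
of circular reads high so little circular signal leaks into host linear
counts. Two small known biases remain — the pseudo-count shrinks fold
changes at the low homogenate counts, and leaked circular reads inflate
synaptosome linear counts slightly — leaving the recovered mean log₂ fold
change near 1.83 for a planted 2.0 at these conditions.

## Numerical choices

* Dispersion floor 1e-8; negative method-of-moments estimates floor there.
* NB sampling uses the gamma–Poisson form except α < 1e-12, which is drawn
  Poisson directly.
* Internal coordinates are 0-based half-open; annotation IO converts from
  1-based inclusive records at the boundary, exactly and invertibly. Exon
  numbering is 1-based in transcript order regardless of genomic strand.
* Sample metadata is an explicit 3-column table (sample_id, fraction,
  condition); nothing is inferred from sample names.
* Results tables are written with ≥12 significant digits; orchestrated runs
  are byte-identical given identical config and inputs.
* Reads shorter than 2·min_anchor can never satisfy the anchor rule and are
  skipped; reads longer than every reference sequence are unmapped by
  definition.

## Limitations

* The mislocalization statistic's anti-conservatism (above) is inherited
  from its definition; the package documents and measures it rather than
  redefining the statistic.
* The DE engine has no dispersion shrinkage, outlier handling, or
  multi-level GLMs; it is not a general-purpose replacement for a mature
  DE framework, and the overall two-factor model used for QC in study
  designs of this kind is intentionally not implemented.
* Junction alignment has no indel handling, and junction enumeration is
  per-transcript (with gene-level deduplication), not across pooled exons
  of a gene, so circles joining exons never co-occurring in one annotated
  isoform are not enumerated.
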