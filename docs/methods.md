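# Methods

`mgslong` implements a longitudinal quantitative-metagenomics analysis
for single-arm treatment studies with repeated stool sampling: a
35-subject, 5-visit design (screening D-30 and D-14, baseline D-1,
on-treatment D8 and D35) is the reference shape throughout, but every
visit set is configurable through `VisitSchedule` (free-form labels
mapped to integer day offsets; ordering always comes from the offsets,
never from the labels).

## Quantification model

The unit of analysis is the metagenomic species (MGS): a cluster of
co-abundant catalog genes treated as one microbial species, quantified
through a designated subset of *marker* genes (50 by default).

1. **Downsizing (rarefaction).** Samples differ in sequencing depth and
   mapping rate, which biases richness and presence/absence calls.
   Every sample is subsampled without replacement to a common mapped-read
   depth — a multivariate-hypergeometric draw per sample, seeded and
   reproducible. A sample already at the target is returned unchanged;
   shallower samples are dropped (or rejected, configurable). Row sums
   equal the target exactly.
2. **FPKM.** Downsized counts are normalized to reads per kilobase per
   million mapped reads: `freq = count / (length_kb × depth_millions)`.
   This is the standard FPKM constant: 1450 reads on a 1 kb gene at
   14.5 M depth gives 100 FPKM.
3. **MGS abundance.** The relative abundance of an MGS in a sample is
   the arithmetic mean FPKM of its marker genes. Detection rule: if
   strictly fewer than 10% of the markers have positive frequency, the
   abundance is set to exactly 0 ("seen" means frequency > 0; the
   threshold is strict, so 5 detected of 50 — exactly 10% — is kept).
   An MGS whose marker set is not exactly 50 genes is accepted with a
   warning and its actual marker count becomes the rule's denominator.
4. **Taxon roll-up.** Higher-rank abundances are sums over member MGS.
   MGS unannotated at a rank pool into an `unclassified <parent>` bucket
   (parent = nearest annotated ancestor), so total abundance is conserved
   at every rank.
5. **Richness.** Gene richness = genes with positive count after
   downsizing; MGS richness = MGS with positive abundance after the
   zero rule. Richness is counted over all genes/MGS present in the
   input table; no additional filtering is applied first.

## Community stability

Bray–Curtis dissimilarity is computed on log10-transformed MGS
abundances. Zeros are handled by the transform
`x -> log10(1 + x/pseudo)`, which maps 0 to 0, is strictly monotone, and
equals `log10(x + pseudo) − log10(pseudo)`; `pseudo` defaults to the
smallest positive abundance in the table. A pair of all-zero samples has
undefined Bray–Curtis; it is defined as 0 with a warning. Ordination is
classical PCoA (double-centering + eigendecomposition, delegated to
scikit-bio); negative eigenvalues are reported and their axes carry zero
coordinates. ANOSIM is implemented in-package so the permutation stream
is seeded: R = (mean between-group rank − mean within-group rank)/(M/2)
over the M = n(n−1)/2 ranked dissimilarities, and the p-value includes
the observed labelling, p = (b+1)/(B+1) with B = 999 by default — p can
therefore never be exactly 0.

The phylum-stability check is a chi-squared test on the visits × phyla
table of mean relative abundances scaled to row percentages. The
construction of this contingency table is an interpretation (percentage
profiles rather than counts); it is intended as a descriptive
stability summary, not a calibrated test.

## The AUC evolution statistic

For one subject, one feature and one *period* (an ordered visit set
whose first visit is the reference — D-30 for the pre-treatment period,
D-1 for the on-treatment period), the trajectory is the log10 fold
change `v(T) = log10((a(T)+pseudo)/(a(T0)+pseudo))`, anchored at 0 at
the initial visit. The evolution statistic is the signed trapezoidal
integral of `v` over time, divided (by default) by the period span in
days so the 29-day pre-treatment and 36-day on-treatment periods are
comparable; the normalized statistic is a time-averaged log10 fold
change. It is exactly 0 for a constant trajectory, positive for a net
rise from the initial value, negative for a net fall, linear in the
trajectory, and invariant to shifting all day offsets by a constant.
Time can alternatively be visit index (`time="index"`); day offsets are
the default since visit spacing is highly uneven. Subjects missing the
initial visit, or with fewer than 2 samples in a period, are skipped for
that period; missing intermediate visits are simply dropped from the
quadrature.

**Pre/on-treatment contrast.** Per feature, the per-subject AUCs of the
two periods are compared with a paired Wilcoxon signed-rank test (zero
differences dropped — Pratt handling configurable; exact distribution
for fewer than 26 informative pairs, normal approximation with tie
correction otherwise), BH-adjusted across features. Features with raw
p ≤ 0.05 are followed up with Friedman tests of raw abundances within
each period (complete cases; in-package implementation with mid-rank tie
correction, valid for k ≥ 2 and equal to scipy's for k ≥ 3), and are
flagged `changed_before` / `changed_during` when the within-period
Friedman is also significant at 0.05. Nemenyi pairwise comparisons on
the within-subject rank sums are available for post-hoc localization.
Significance conventions: raw p < 0.05, BH-adjusted p < 0.1; both are
always reported. BH families are per feature-set × rank × test battery.
Features with fewer than 5 paired subjects, or no informative pairs at
all, are reported untested (NaN) rather than given a fabricated p.

An experimental rank-based ANOVA-type statistic for one group ×
repeated measures (the LD-F1 design: joint mid-ranks, relative effects
`(Rbar_j − ½)/N`, box-type degrees of freedom, referred to F(f̂, ∞))
offers a confirmation route independent of the AUC reduction. It is
validated by null calibration and degenerate-input tests only; no
reference implementation is bundled.

**Symptom correlation.** Spearman correlation of features (or richness)
with the Bristol stool scale is computed at each visit separately over
subjects, BH-adjusted within visit, with a cross-visit consistency
report (at how many visits each feature is significant and whether the
significant correlation signs agree). For three independent visits,
sign agreement alone occurs at a 25% chance rate — the consistency
screen is descriptive, not a test.

## Responder stratification

Subjects are clustered by Lloyd's k-means (k = 3, 10 seeded restarts,
best inertia) on the post-baseline deltas of their Bristol stool scale
(BSS at D8, D35, … minus BSS at D-1). Subjects with any required BSS
missing are excluded, not imputed. Clusters are relabelled
semantically — *early* = largest mean drop at the first post-baseline
visit, *non* = smallest overall drop among the rest, *late* = the
remainder — a rule invented here because drop timing is what
distinguishes the archetypes; the relabelling is invariant to cluster
index permutation and deterministic given the seed. Degenerate inputs
(fewer distinct delta profiles than clusters) are flagged and labelled
arbitrarily with a warning.

Group contrasts: pairwise Mann–Whitney with Cliff's delta effect sizes
(|d| thresholds 0.147/0.33/0.474 for negligible/small/medium/large) on
quantitative baseline variables; chi-squared without continuity
correction (flag available) on sex and country; Kruskal–Wallis across
groups on every prevalence-filtered MGS at each pre-treatment visit,
with a consistency screen (significant at *all* pre-treatment visits)
followed by Dunn post-hoc z-tests on joint ranks. The evolution
contrast is rerun within each group; groups below the paired-subject
minimum are skipped.

## Synthetic data generator

The generator emulates the study shape with known ground truth; it is a
modelling device, not a claim about real stool metagenomes.

* **Catalog**: `n_mgs` MGS × 60 genes (first 50 are markers), log-normal
  gene lengths around 1 kb (σ = 0.35 log), a 5-phylum nested taxonomy
  with a configurable unclassified fraction at species level.
* **Abundances**: log10 abundance of a carried MGS = per-MGS grand mean
  (SD 1.0 log10) + subject effect (SD 0.5) + temporal noise (SD 0.25)
  whose correlation decays as `exp(−drift_rate·Δdays)` (default 0.05/day,
  so communities drift apart with the sampling gap; 0 disables temporal
  variation entirely). Per-subject carriage is Bernoulli with per-MGS
  prevalences drawn Beta around `richness_mean/n_mgs` and a per-subject
  richness propensity calibrated by quadrature + bisection so per-sample
  richness hits the configured mean and SD. Profiles are normalized to
  relative abundance *before* treatment effects are applied, so an
  injected fold change is realized exactly; effect features are forced
  present in every subject so planted signals are scoreable.
* **Counts**: MGS abundance spread over member genes proportionally to
  length, one multinomial draw per sample at depth ~
  Normal(depth_mean, depth_sd).
* **BSS**: archetype levels (early 6.2 → 4.2 from D8; late 5.6 → 3.6
  from D35; non 4.9 flat — whole-point drops, baselines ordered as in
  real responder cohorts) + a persistent per-subject offset (SD 0.7,
  the between-subject spread) + per-visit measurement noise (SD 0.5),
  rounded and clamped to 1..7. Missing samples are removed consistently
  from metadata and counts.

Defaults are desk scale — 35 subjects, 200 MGS, richness 120 ± 24,
~500k reads/sample — chosen so a full pipeline run takes seconds while
preserving the features the analysis leans on (subject individuality,
temporal drift, prevalence heterogeneity, detection loss at finite
depth). `SimulationConfig.study_shape()` switches to the real
dimensions (1438 MGS, richness 215 ± 49, 22.3 M ± 0.8 M reads).
Richness defaults derive from `n_mgs` (60%, SD = mean/5) when not set
explicitly. Everything is deterministic given (config, seed).

What the generator does *not* model: strain/pangenome structure,
compositional coupling beyond closure, read-level errors, depth-dependent
mapping bias, non-stationary subject trajectories, and any real
taxon–symptom biology. Passing tests therefore demonstrate the
*procedures* behave as specified under a plausible statistical model,
not that the biological conclusions transfer to any particular dataset.

## Calibration results and known limitations

* Under the null generator (no treatment effects), the per-feature AUC
  contrast rejects at 4.5% (pooled over 200 studies) and BH at 0.1
  leaves essentially nothing. The shortfall from the nominal 5% is the
  discreteness of the conditionally exact Wilcoxon test: a feature with
  fewer than 6 informative (nonzero-difference) pairs has a minimum
  attainable two-sided p of 0.0625 and can never reject at 0.05, so
  low-prevalence features contribute zero rejections. This is inherent
  to any deterministic rank test with zeros dropped; only a randomized
  test attains exact nominal size. The direction is conservative —
  fewer false positives — never anticonservative.
* Planted 4-fold on-treatment shifts in prevalent features are detected
  with power near 1 at n = 35; pre-treatment-only shifts localize to
  the pre-treatment flag, with on-treatment false flags at the chance
  level of the calibrated within-period Friedman test (~5%) — a floor
  no calibrated procedure can undercut.
* Responder label recovery from noiseless archetypes is exact. At
  measurement noise SD 0.3 the integer quantization of BSS puts a
  ceiling on any clusterer: assigning subjects to the nearest *true*
  archetype centroid recovers 89.1% of labels, and k-means recovers
  87.5% (pooled over 100 replicate studies). Accuracies above ~89%
  under these conditions are not achievable without removing the
  rounding or the fractional archetype levels.
* The phylum chi-squared and the BSS sign-consistency screen are
  descriptive summaries, not calibrated tests (see above).
* `select_markers` (picking markers by mean intra-MGS Spearman
  correlation) is a convenience helper; marker sets are expected as
  curated input and pipeline correctness never depends on the helper.
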