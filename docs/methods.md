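# Methods

## The experimental design being modeled

A between-subjects two-state microdialysis study: each mouse is sampled in
exactly one behavioral state (wakefulness, n = 12, or isoflurane
anesthesia at ~1.3%, n = 11). Five sequential dialysate fractions
(25 µL at 1.0 µL/min, i.e., 25 min each, 125 min total) are collected per
mouse and eight small-molecule neurotransmitters are quantified in every
fraction (nM): acetylcholine, adenosine, dopamine, GABA, glutamate,
histamine, norepinephrine, serotonin. The five fractions of one mouse are
subsamples of the same experimental unit, not independent replicates —
every inferential choice below follows from that.

## Synthetic-data generator

The generator produces the common-currency long table (one row per mouse ×
sample × analyte) with the statistical structure the analysis stages
assume.

**Marginals.** Concentrations are positive and right-skewed, so each
state × analyte marginal is lognormal, moment-matched to a target mean and
SD via `sigma^2 = ln(1 + (sd/mean)^2)`, `mu = ln(mean) − sigma^2/2`. The
targets for ACh, Ado, DA and NE are the published group summaries for this
design (e.g., Ado 29.456 ± 29.756 nM awake vs. 101.321 ± 38.603 nM
anesthetized); GABA, GLU, HA and 5-HT group values are not published as
text, so their defaults (15 ± 6, 150 ± 60, 3 ± 1.2, 1 ± 0.4 nM,
state-invariant) are plausible cortical-microdialysis scales chosen to be
consistent with the published time-trend magnitudes — they are **not**
literature-anchored values and are fully configurable.

**Interpretation of the printed SDs.** The published mean ± SD summarize
per-mouse averages; we treat them as the *mouse-level* marginal. Each
sample then multiplies the mouse level by unit-mean lognormal noise,
`exp(tau·e − tau^2/2)` with `tau^2 = sigma^2 (1 − icc)/icc`, where `icc`
(default 0.5) is the fraction of log-scale variance that is between-mouse.
The unit-mean construction keeps both the mouse-level marginal and the
expected per-mouse sample mean exactly on target (a plain additive latent
shift would inflate the concentration-scale mean by up to ~30% for
high-CV analytes). Because `tau` is undefined at `icc = 0`, `icc` must lie
strictly inside (0, 1).

**Dependence.** Cross-analyte structure is a Gaussian copula: the
mouse-level latent vector and each sample's noise vector are drawn with
the same state-specific correlation matrix, so the latent correlation at
the sample level equals the target regardless of `icc` (exactly so at
icc = 0.5). Defaults plant r = 0.7 on the fully connected wake module
{ACh, DA, GABA, NE} and, under anesthesia, on the NE–Ado–DA triangle plus
the GABA–GLU pair — the state-dependent reorganization the downstream
network stages are meant to detect. Matrices are repaired to the nearest
PSD correlation by eigenvalue clipping and diagonal renormalization.
Targets are specified on the latent (copula) scale; the observable
Pearson correlation of two lognormals is attenuated to
`(exp(rho·s1·s2) − 1)/sqrt((exp(s1^2) − 1)(exp(s2^2) − 1))`, which the
test suite uses as a closed-form oracle. For the printed ACh wake CV of
0.89 this attenuation is substantial (0.7 → ≈0.6 at the sample level) —
see Limitations.

**Time trends.** Each state × analyte has a linear trend (nM per sample
interval; defaults are the published per-state slopes, e.g., Ado −8.953
awake vs. −13.71 anesthetized), centered on the middle sample so the trend
never shifts the mouse-level mean.

**Censoring.** Values below the analyte's LLOQ are flagged and their
concentrations dropped. Default LLOQs are calibrated at config-build time:
for each analyte we solve, by bisection on the closed-form mixture CDF
(states weighted 12:11, the five trend offsets averaged), for the
concentration whose expected censoring fraction is 10.5% — the overall
missingness reported for this assay. No simulation is involved, so the
calibration is deterministic. Realized missingness varies by seed
(roughly 5–16%).

**Probe sites.** One (AP, ML, DV) coordinate triple per mouse, independent
Gaussians with the published per-state means/SDs (wake 2.6 ± 0.1 /
1.4 ± 0.2 / 1.9 ± 0.3 mm; anesthesia 2.6 ± 0.2 / 1.4 ± 0.2 / 1.7 ± 0.2).

**What the generator does not emulate:** non-LLOQ data loss (failed
chromatography), nonlinear time courses, probe-recovery drift,
anesthetic pharmacokinetics, and any within-mouse autocorrelation beyond
the single shared mouse factor. Passing tests therefore demonstrate that
the pipeline recovers structure of this idealized form, not that real
dialysate panels satisfy these assumptions.

## Statistical stages

**Imputation.** Below-LLOQ values are imputed at the analyte's LLOQ (the
standard for this assay class), flagged `imputed`; any other absence is an
error. Imputation is idempotent and never touches observed values.

**Rank nested ANOVA.** Per analyte, all 115 observations (both states) are
mid-ranked; the state effect is tested against mouse-within-state
variance:
`F = [Σ_g N_g (R̄_g − R̄)^2] / [Σ_m n_m (R̄_m − R̄_g(m))^2 / (n_mice − 2)]`,
df = (1, n_mice − 2) = (1, 21) at the default design. With unbalanced
per-mouse counts the error term uses per-mouse mean ranks weighted by
sample count (a documented approximation; no Satterthwaite correction).
Raw p-values are Benjamini–Hochberg adjusted across the 8-analyte panel.
Outliers are never removed or winsorized — robustness comes from the
ranks.

**Fisher's LSD** is computed on per-mouse mean ranks with the pooled
(unweighted) mouse-level variance, so for two groups the decision
coincides exactly with an unpaired t test at α = 0.05 on the per-mouse
mean ranks (verified against scipy in the tests).

**Slope comparison.** Concentration is regressed on sample index with
separate intercepts and slopes per state (mice pooled — one published
slope per state per analyte); the slope difference is the interaction
coefficient, tested on N − 4 df with the pooled residual variance. A
noise-free fit (zero residual variance) reports p = 1 when the slopes are
equal and p = 0 otherwise, rather than dividing by a zero standard error.

**Probe-placement test.** Each mouse's site is reduced to the Euclidean
norm of its bregma-relative (AP, ML, DV) vector; states are compared with
a pooled-variance two-tailed t test (df = n1 + n2 − 2 = 21). The norm is
origin-dependent — "distance to the stereotaxic target (3.0, 1.6,
2.0) mm" is available via `reference="target"` because either reading of
"3-D Euclidean position" is defensible.

## Correlation networks

Per state, Pearson correlations are computed over the (mouse, sample)
observation rows — 60 wake, 55 anesthesia — on raw imputed nM by default
(the scaling is a flag; ranks/z-scores change nothing for z-scores and are
available via the feature matrix). Networks keep edges with r ≥ τ,
boundary inclusive, default τ = 0.5 signed (positive correlations only);
an absolute-value mode exists. Thresholding is monotone: raising τ can
only remove edges.

The **RMT selector** generalizes threshold choice for larger panels: for
each candidate τ it zeroes sub-threshold entries, computes nearest-
neighbor eigenvalue spacings (tails trimmed 5% per side, spacings unfolded
by a 7-point moving-average local mean), and compares their distribution
with the Poisson law `1 − exp(−s)` versus the Wigner–Dyson surmise
`1 − exp(−πs²/4)` by Kolmogorov–Smirnov distance, returning the smallest τ
whose spacings are closer to Poisson (independent blocks). Panels under
20 nodes — including the default 8 — have too few spacings for a stable
decision; the selector then warns and returns the fixed 0.5.

**Topological overlap** uses the standard unweighted form
`TOM_ij = (Σ_k a_ik a_kj + a_ij)/(min(k_i, k_j) + 1 − a_ij)` with
0/0 := 0 and a unit diagonal. The exact cross-network overlap variant of
the method this study cites is not reproducible from the text, so the
cross-network report is a documented stand-in: edge Jaccard, cosine
similarity of vectorized off-diagonal TOMs, and per-node degree change.

## The iRF engine

Written from scratch (scikit-learn appears only as an independent
cross-check in the tests).

- **Trees**: CART with exact midpoint split search (vectorized cumulative
  sums), Gini impurity for classification, variance for regression; ties
  broken by lowest feature index then lowest threshold, so fits are
  deterministic given the generator state. `min_leaf` is enforced on both
  children; candidate features are sampled per node without replacement
  with probability proportional to the feature weights (zero-weight
  features can never be selected).
- **Forests**: bootstrap of the rows per tree; importance = impurity
  decrease × node size, summed over nodes, averaged over trees,
  normalized to 1. Out-of-bag predictions supply model quality (R² for
  regression targets) without a second fit.
- **iRF**: iteration 1 uses uniform feature weights; iteration t + 1
  samples features proportionally to iteration t's importances. K = 1
  reproduces a plain forest on the same random stream. Defaults follow
  the iRF literature (n_trees = 500, K = 5, mtry = ⌈√p⌉ classification /
  ⌈p/3⌉ regression, min_leaf = 1 / 5), since the study reports none;
  every output records the parameters used.
- **RIT**: paths are root-to-leaf split-feature sets weighted by leaf
  size; each of M = 100 random intersection trees (depth 5, 2 children)
  intersects freshly sampled paths; survivors of size ≥ 2 are candidate
  interactions with leaf-weighted path prevalence.
- **Stability**: B outer bootstrap bags, each refitting the iRF and
  rerunning RIT. On a panel of only 8 features fully grown trees place
  most features on most paths, so bare survival is uninformative — every
  pair eventually survives some intersection. An interaction therefore
  counts as recovered in a bag only if its prevalence reaches 0.5; in
  planted-interaction simulations true pairs ride ≥ ~90% of paths while
  null survivors sit near 0.3–0.5, which is the contrast the gate was
  designed on. Stability is the fraction of bags recovering the set.

All randomness flows from one `numpy.random.Generator`; trees and bags
receive independent child streams via `Generator.spawn`, making every fit
bit-reproducible for a fixed seed.

## iRF-LOOP and state prediction

Rows for machine learning are per-(mouse, sample) observations, z-scored
by pooling both states so state signal survives scaling (a per-mouse-mean
aggregation exists as an option). iRF-LOOP fits one regression iRF per
target analyte on the remaining seven; normalized importances give the
directed edge weights (each target's incoming weights sum to 1). The
drawn-network threshold is not knowable from the source figures, so the
default keeps edges ≥ 1.5× the uniform expectation, 1.5/(p − 1), and the
full importance matrix is always emitted for re-thresholding. Networks
are computed per state, mirroring the two-panel figure layout.

The state classifier trains on 75% of the data. Because the five samples
of a mouse are strongly dependent, a literal row-level split would leak
information across partitions; the default split is therefore grouped by
mouse (stratified by state, floor(0.75·n) mice per state), with an
`ungrouped` flag to mimic the literal protocol. Accuracy, confusion
counts, normalized importances and the top-k features are reported.

## Numerical choices and degenerate inputs

- SD = 0 marginals degenerate to point masses (the all-zero-SD,
  zero-slope, zero-LLOQ config reproduces the means exactly).
- A state effect with zero mouse-level variance reports F = ∞, p = 0 (or
  F = 0, p = 1 when the state SS is also zero).
- BH adjustment validates p ∈ [0, 1] and delegates to statsmodels'
  step-up implementation.
- Pearson cells require ≥ 3 complete pairs; constant columns raise an
  error naming the analyte.
- PSD repair tolerance is 1e−8 on the minimum eigenvalue.

## Limitations

- **Printed summaries understate the original effect for dopamine.** The
  DA group summaries imply a per-mouse standardized effect near 0.9,
  which after FDR across eight analytes yields only ~35–40% power at
  n = 12 + 11 — so a median simulated panel reproduces the ACh/Ado/NE
  findings but not always the (originally borderline) DA one. This is a
  property of simulating from marginal summaries, not of the test.
- **Lognormal attenuation caps recoverable correlations.** With the
  printed ACh wake CV (0.89), a latent 0.7 maps to an observable Pearson
  near 0.6; at ~60 rows per state the full wake K4 module then clears the
  0.5 threshold in slightly under half of seeds even though every
  individual edge does so in a large majority. Rank-based correlation
  would largely remove the attenuation but is deliberately not the
  default.
- The exact F statistics, correlation tables and drawn network edge sets
  of the original data are not reproducible (raw per-mouse data are
  unpublished); properties, not values, are the verification target.
- Ranking across all observations (not per-mouse means) and the use of
  the LLOQ-imputed table for both the ANOVA and the ML features are
  documented interpretations of an underspecified protocol.
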