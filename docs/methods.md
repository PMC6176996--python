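# Methods

## Quantification model

Peptide peak areas are treated as multiplicative: for peptide *k* of
protein *i* in sample *s*,

    area = abundance(i, s) · response(k) · scale(s) · batch(run(s)) · noise

where `response(k)` is a fixed peptide-specific detection efficiency,
`scale(s)` a per-sample processing/loading factor, `batch(r)` a run-level
offset, and `noise` mean-1 lognormal measurement error.  The quantification
chain inverts this layer by layer:

1. **Rollup.**  The protein response is the geometric mean √(a₁·a₂) of its
   two peptide areas.  The geometric mean is the right average for
   multiplicative signals: it turns the two response factors into a single
   per-protein constant √(r₁·r₂) instead of biasing toward the hotter
   peptide.  A cell with a single detected peptide is treated as missing by
   default (`missing_policy="drop"`): a lone peptide halves the evidence
   and shifts the rollup by its own response factor.  `"single"` keeps it.
2. **Standards.**  Division by the sample's BSA spike-in response removes
   `scale(s)` exactly (the spike-in receives the same processing), and the
   subsequent division by the reference protein MDH1 removes residual
   sample-level biology/loading; MDH1 becomes identically 1, a checkable
   invariant.  The two divisions commute, so they are implemented
   sequentially.
3. **Batch anchoring.**  Samples are acquired in two runs with only some
   groups present in both.  Within each run every protein is divided by its
   median over the run's *anchor* samples — by default the groups present
   in every run (auto-detected from the sample sheet).  Under the
   multiplicative batch model this removes `batch(r)` exactly and is
   idempotent.  The per-protein median (default) is preferred over a single
   grand median (`mode="global"`) because batch effects in targeted MS are
   protein-specific; both are available since the original procedure's
   granularity is not documented.
   A consequence worth knowing: anchoring fixes each protein's anchor
   median to 1 *per run*, so even noise-free data are recovered up to one
   constant per (protein, run) — the tests compare against anchor-
   normalized truth rather than raw truth.
4. **Quantifiability filter.**  Proteins detected in fewer than
   `min_detect_fraction` (default 1.0) of any group's samples are dropped.
   The original panel's detection criterion is not documented, so the
   threshold is a parameter rather than a constant.

The whole chain is invariant to scaling all areas of any one sample by any
c > 0.

## Group testing policy

Per feature (protein abundance or gene expression): optional log2
transform (abundances are positive and multiplicative), then a
Brown–Forsythe test (median-centered Levene, the robust default among
homoscedasticity checks) at the same alpha as the omnibus test.
Homogeneous variances → one-way ANOVA with Tukey HSD post hoc; otherwise →
Kruskal–Wallis with Dunn post hoc (z on mean ranks with tie correction,
BH-adjusted).  Post hocs run only when the omnibus p < alpha.  Across
features, Benjamini–Hochberg FDR is optional (`fdr="features" | "none"`):
FDR across features is the defensible default for a 100-protein panel, but
`"none"` reproduces the raw-p selection rule used for molecular panels in
many animal studies; the choice is recorded in the output.  Constant or
otherwise untestable features are reported as such and excluded from the
FDR family m, since they contribute no p-value.

## Relative expression

2^−ΔCt with ΔCt = Ct_target − arithmetic mean of three reference-gene Cts
(equivalently, expression relative to the geometric mean of the reference
expressions).  No ΔΔCt calibrator is used — without longitudinal or control
samples there is nothing to calibrate against — and amplification
efficiency is fixed at 2.0/cycle.  Additive per-sample Ct shifts common to
all genes cancel exactly.

## Correlation networks

Within each group, Pearson correlations are computed on log2 abundances
(flag for linear; Pearson on strongly right-skewed linear abundances is
dominated by high points, and log2 matches the multiplicative model).
Two-sided p-values use the exact null transform t = r·√(n−2)/√(1−r²) with
df = n−2.  Proteins with any missing value or zero variance in the group
are excluded from that group's network: pairwise-complete correlations
would give each pair its own n and break the fixed-df p model.

Edges satisfy |r| ≥ r_min (default 0.8) and p ≤ alpha (default 0.05).  At
n = 8 the p clause is mathematically redundant: the critical |r| at
p = 0.05, df = 6 is ≈ 0.707 < 0.8.  It is kept because both thresholds are
parameters and the redundancy only holds for r_min above the critical
value.

Topology: density 2L/(N(N−1)) with N = nodes of degree ≥ 1, matching the
convention that a network "node" is a protein with at least one significant
correlation; the density over all quantified proteins is also reported
(`universe_size`), since sparse networks inflate the connected-node
density.  Transitivity is the global clustering coefficient
3·triangles/connected-triples on the unsigned graph; diameter is the
longest shortest path within the largest connected component (diameter is
undefined on disconnected graphs).  Pathway-intrinsic density is the
induced-subgraph density over the pathway members present in the node set.
Hub ranking sorts by degree with lexicographic tie-breaks for determinism.
Edge overlap across groups ignores correlation sign by default (a
"correlated pair" is the same pair whether the sign flips between diets);
`signed=True` distinguishes them.

## Threshold stability

The sweep recomputes full-data metrics over a threshold grid (link counts
are non-increasing by construction).  Stability is quantified by
leave-one-sample-out jackknifing — deterministic and exhaustive at n = 8,
unlike random subsampling — summarized as the coefficient of variation of
density, transitivity and diameter (CV = 0 when the mean is 0).  The
recommendation is the smallest threshold above a floor (default 0.5) whose
density CV is within 20% of its value at the next grid point (a plateau);
no plateau → grid maximum with a warning.  This procedure is a
reconstruction: the underlying studies cite "sample-size effects on
stability" without specifying a protocol.

Two properties of this statistic deserve care:

* Below the p-critical correlation (≈0.707 at n = 8, alpha 0.05) the p
  clause, not the r threshold, determines the edge set, so CV comparisons
  across low thresholds must be run with alpha = 1 to actually vary the
  threshold.
* Jackknife CV decreases with sample size **only when the planted
  correlation exceeds the edge threshold**.  With within-block correlation
  0.9 and threshold 0.8, mean CV falls ≈ 0.19 → 0.09 → 0.05 → 0.01 over
  n ∈ {6, 8, 16, 32} (100 seeds each).  With correlation 0.7 — *below* the
  threshold — the large-n edge set concentrates into an ever-sparser tail
  event (the per-pair pass probability falls from ≈ 0.34 at n = 6 toward
  ≈ 0.11 at n = 32) and the relative jitter *grows* (CV ≈ 0.28, 0.23,
  0.31, 0.44).  More samples stabilize the network only if the signal one
  thresholds for is really there.

## Synthetic-data generator

Ground-truth log2 abundance follows a single-latent-factor block model:

    x(i, s) = baseline(i) + effect(g, path(i)) + λ·F(g, path(i), s) + ε(i, s)

with F standard normal shared by all proteins of one pathway within one
group's samples, ε ~ N(0, σ²) with σ = 0.5 log2 units, and
λ = σ·√(ρ/(1−ρ)) so two same-pathway proteins have expected Pearson
correlation exactly ρ (`block_rho`).  The single-factor construction was
chosen for its closed-form pairwise correlation, which makes recovery
tests exact.  Peptide areas multiply the truth by per-peptide response
factors (lognormal, σ = 1 log2 by default), per-sample scales (σ = 0.25
log2), run batch factors, and mean-1 lognormal noise with CV 0.15.  Ct
values are baseline − log2(expression) + per-sample offset + N(0, 0.2)
noise, with three reference genes at expression 1.

Defaults encode the emulated study design: groups LFLS/LFHS/HFLS × 8
replicates; 100 proteins in six categories (glycolysis 16, β-oxidation 18,
TCA cycle 16, electron transport chain 20, antioxidant 14, proteostasis
16) plus the MDH1 reference; run 1 = 3 LFHS + 5 HFLS, run 2 = 8 LFLS +
5 LFHS + 3 HFLS.  Block correlations (LFHS 0.65 everywhere, LFLS 0.50,
HFLS 0.30 with β-oxidation 0.60) and mean shifts (LFHS: glycolysis −0.5,
TCA −0.4, antioxidant −0.8; HFLS: β-oxidation +0.8, antioxidant −0.3 log2)
reproduce the qualitative findings the design is known for — the densest
network under high sucrose, the sparsest under high fat with relatively
strong fatty-acid co-regulation, sucrose-lowered antioxidant/glycolytic
enzymes, fat-raised β-oxidation enzymes.  The magnitudes are assumptions:
no distributional description of the real abundance data exists, so the
lognormal/factor model and these effect sizes are choices, and passing
tests demonstrate correctness of the *pipeline* under this model, not
properties of real cartilage data.  Features of real SRM data the
generator does not emulate: missing values/detection limits, correlated
peptide interference, heavy-tailed outliers, and any between-pathway
correlation structure.

All randomness flows through explicit integer seeds via
`numpy.random.default_rng([stream, seed])`; identical (config, seed) gives
bit-identical outputs.

## Numerical choices and degenerate inputs

* Geometric mean is undefined for non-positive areas → error; zero areas
  are treated as missing at table level.
* Brown–Forsythe on groups whose deviations are all zero (constant groups)
  returns p = 1 (no dispersion to compare); Kruskal–Wallis on all-identical
  data returns H = 0, p = 1; ANOVA on zero total variance raises.
* Correlation r is clipped to [−1, 1] before the t transform; |r| = 1 maps
  to p = 0.
* Empty networks have density/transitivity 0 and diameter 0; single-member
  pathways have intrinsic density 0.
* Jackknife CV is defined as 0 when the mean is 0; subsets yielding empty
  networks contribute metric value 0.
* BH adjustment is the standard step-up (monotone, capped at 1), via
  statsmodels.

## Problem sizes used by the tests and the acceptance script

Null edge-rate calibration uses 200 features (19,900 pairs) at n = 8;
graph-metric cross-validation uses 100 random graphs of ≤ 20 nodes against
an independent adjacency-matrix/Floyd–Warshall implementation;
planted-block recovery uses 500–1000 simulations of the two-group design;
type-I calibration uses 1000 null features; the sample-size stability scan
uses 100 seeds per n ∈ {6, 8, 16, 32} on a 12-protein block.  These sizes
give Monte-Carlo standard errors comfortably below the asserted tolerances
while keeping the default suite fast.

## Known limitations

* The quantifiability criterion, batch-median granularity, correlation
  scale (log vs linear), and density universe of the original analyses are
  undocumented; each is parameterized with the more defensible option as
  default, and the alternatives are one flag away.
* Correlation p-values assume bivariate normality on the chosen scale; at
  n = 8 they are calibration devices more than inferential guarantees.
* The threshold recommendation is a plateau heuristic, not an optimality
  criterion.
* Networks are marginal-correlation graphs: they make no claim about
  direct interactions (no partial correlations or graphical models).
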