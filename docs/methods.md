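# Methods

This note documents the models, defaults and numerical choices behind
`chronobef`, and what the synthetic-data generator does and does not
emulate.

## Analysis pipeline

### Rarefaction and multidiversity

OTU tables are rarefied once per sample to an even, group-specific
depth (invertebrates 300, protists 800, fungi 2000, bacteria 5000
reads) by a multivariate hypergeometric draw — subsampling without
replacement, so a column whose total equals the depth is returned
unchanged. Samples below depth are dropped with a warning. Each
column's draw is seeded from `(seed, sample id)`, making rarefaction
column-independent: permuting or subsetting samples does not change any
retained sample's counts. The analysis uses a single seeded draw rather
than an average over repeated draws; repeated rarefaction would shrink
the sampling noise of richness slightly but not change any estimator.

Richness (count of OTUs with nonzero reads) per group is 0–1 normalised
**across the whole sample set** — not per chronosequence — so that
multidiversity, the arithmetic mean of the four normalised richnesses,
is comparable between plots and chronosequences. A per-label
normalisation scope is available as a configuration switch. A constant
richness vector normalises to 0.5 everywhere (with a warning), keeping
that group's contribution to the four-group mean neutral instead of
pinning it to an extreme.

### Multifunctionality

Two of the 13 function proxies (fungal plant pathogen abundance,
antibiotic-resistance-gene abundance) arrive on an inverted-benefit
scale and are multiplied by −1 before normalisation; orientation is an
involution so applying it twice restores the input. Averaged
multifunctionality is the per-sample mean of the normalised, oriented
proxies. Threshold multifunctionality counts, per sample, the functions
whose value exceeds t × (per-function maximum observed value) for
t ∈ {0.10, 0.25, 0.50, 0.75, 0.90}. Two knobs deserve note:

- **Comparison.** The count uses strict `>` by default; `>=` is
  available because both conventions circulate. With continuous data
  they coincide almost surely; they differ exactly at threshold ties.
- **Reference.** The anchor is the per-function maximum observed value;
  a top-k mean ("robust max", k = 3) is available for long-tailed
  proxies but off by default. On the normalised scale the maximum is 1,
  so the cut point equals the threshold itself.

MF_t is nonincreasing in t per sample and invariant to function order —
both are enforced by tests.

### Within-plot BEF coefficients

The local BEF relationship of a plot is the Spearman correlation across
the plot's replicate samples between a diversity index (multidiversity
or a group richness) and a function target (MF_avg, each MF_t, or an
individual oriented proxy). Spearman rho is the Pearson correlation of
average ranks, so ties are handled. With n = 5 samples the asymptotic
p-value is unreliable, so for n ≤ 8 the two-sided p is computed exactly
by enumerating all n! rank permutations (120 at n = 5; the enumeration
respects the tie structure of both arguments). Constant inputs yield an
undefined rho; such records are flagged `degenerate` and excluded from
trends rather than imputed at 0, which would shrink slope estimates.

P-values are Benjamini–Hochberg adjusted. The default multiple-testing
family is one (diversity index, function target) pair across plots; a
single global family is available, and the choice is recorded in the
output metadata, since family definitions are rarely stated precisely
enough to be unambiguous.

Distributional diagnostics per family report moment-based skewness g1,
excess kurtosis g2, and (for n ≥ 8) the Shapiro–Wilk statistic.

### Age trend

Per-plot rho is regressed on log10(soil age). Age enters on the log10
scale because chronosequence stages are spaced in decades of years and
raw ages would hand all leverage to the 10⁷-year plots. Random
intercepts for parent material, climate class, vegetation type and
location enter as crossed variance components estimated by REML
(statsmodels `MixedLM` with a single dummy group). "Location" is the
chronosequence, not the plot: the plot is the unit of analysis and has
one record per family, so a plot-level component would be confounded
with the residual. Factors with one observed level are dropped up
front; a variance component that collapses below 1e−6, or a fit that
fails to converge, triggers a reduction chain whose last resort is OLS.
The fitted method and dropped factors are always reported — the
estimator degrades gracefully instead of erroring, and when every
component is zero the fixed-effect slope equals the OLS slope.

Power-series age groups: group g spans [10^(g−1), 10^g) years for
g = 3..7 (half-open on the right, so exactly 10³ years falls in group
4), and group 2 covers everything below 10² years. Ages above 10⁷ are
clamped to group 7 with a warning. Group means ± SE are fitted with
degree-1 and degree-2 polynomials in the group index.

Dryland stratification: plots with aridity index (AI) < 0.5 are
drylands; AI ≥ 0.5 non-drylands. The boundary value itself is assigned
to the wetter class — the two defining half-lines exclude 0.5, so a
convention is needed and is recorded in the outputs.

### Drivers

*Akaike importance.* Every subset of ≤ 12 candidate predictors is fitted
by least squares; AICc (the small-sample correction, counting the
residual variance as a parameter) gives weights
w_m = exp(−Δ_m/2)/Σ exp(−Δ/2), and a predictor's importance is the sum
of weights of models containing it, flagged significant at ≥ 0.8. This
is the defined, reproducible core of weight-based multimodel inference;
a random-effects meta-variance (plots weighted by the sampling variance
of rho) is out of scope and would mostly reweight, not reorder,
importances here because every plot has the same n. Perfectly collinear
predictor pairs and duplicate columns are rejected, never silently
merged.

*Path analysis.* The structural model is a recursive DAG over observed,
standardized variables. OLS per equation is the maximum-likelihood
estimator for recursive systems, so no iterative fitting is needed. The
implied covariance Σ̂ = (I−B)⁻¹ Ψ (I−B)⁻ᵀ (B = path coefficients, Ψ =
exogenous covariance plus endogenous residual variances) is compared
with the observed covariance S via χ² = (n−1)·F_ML with
df = p(p+1)/2 − free parameters, and RMSEA =
sqrt(max(χ²−df, 0)/(df·(n−1))). A saturated model reproduces S exactly
(χ² = 0, df = 0; p and RMSEA undefined). Direct effects are the path
coefficients; total effects come from (I−B)⁻¹ − I (path tracing along
directed edges only); indirect = total − direct. Latent variables and
additional fit indices (CFI/TLI) are out of scope.

*Dominant-taxon proportions* are taxon reads / total reads per sample
within each group's table; plot-level means feed the same Pearson
screens used for environmental covariates.

### Co-occurrence networks

One network per plot: within-group relative abundances, OTUs filtered
to those present in every sample of the plot, all pairs tested by
Spearman across the plot's samples, edges kept at |ρ| ≥ 0.6 and
p ≤ 0.05, signed by the sign of ρ. The source method states no
cutoffs, so these defaults follow common practice for abundance
networks and are mandatory, logged configuration — every output records
them. With five samples the exact two-sided p has a floor of
2/5! ≈ 0.017 reached only at |ρ| = 1, so the default cutoffs admit only
perfectly concordant/discordant pairs; these defaults therefore
characterise the pipeline's behaviour rather than reproduce any
particular field network. The graph keeps nodes incident to at least
one edge; the count of prevalence-passing candidates is reported
separately. Metrics: node and edge counts, positive/negative edge
counts, average degree 2E/N, density 2E/(N(N−1)), Freeman degree
centralization Σ(d_max−d_i)/((N−1)(N−2)), and modularity of the
partition found by deterministic greedy (Clauset–Newman–Moore)
agglomeration on the unsigned graph — signs are reported separately,
signed-modularity variants are out of scope. Empty networks report zero
counts with a flag; centralization needs ≥ 3 nodes, modularity ≥ 1
edge, otherwise NaN.

## The synthetic generator

The generator emulates the reference survey design: 16 chronosequences
(7 of 6 stages, 9 of 5), 87 plots, 5 composite samples per plot, soil
ages log-uniform over 10–10⁷ years. Log-uniform ages match the decadal
power-series grouping of chronosequence stages. Climate (MAT, MAP,
aridity index) and the categorical soil-forming factors (parent
material, vegetation, climate class) are drawn once per chronosequence
and held fixed — within a chronosequence only time since soil formation
varies.

Per plot, latent resources (plant cover, soil organic carbon, microbial
biomass) increase with a saturating function of log10(age), scale
upward with MAP, and carry lognormal plot-level heterogeneity (SD 0.25)
plus sample-level noise proportional to `noise_sd`. Each group's
richness target grows near-linearly in log10(age) with a modest MAP
boost; OTU counts are multinomial draws from a geometric (Motomura)
rank-abundance profile truncated to the richness target, at a per-sample
depth 1.3–1.8× the group's rarefaction depth. The geometric profile was
chosen over steeper heavy-tailed profiles (e.g. log-series) because its
deep ranks remain detectable at the configured rarefaction depths: with
a steeper tail, observed richness saturates in old (species-rich) plots
and the diversity readout attenuates with age, which would leak an
artificial negative age trend into the null (`coupling_slope = 0`)
design. With the geometric profile the null design recovers a slope
within 2 SE of zero.

Function f in sample j is
`alpha_f + kappa(plot) · z_div_j + beta_f · z_res_j + eps`, with
`kappa(plot) = coupling_intercept + coupling_slope · log10(age)`
(defaults 0.8 and −0.1: strong coupling in century-old soils decaying
toward ~0.1 at 10⁷ years). `z_div_j` is a unit-normal per-sample latent
diversity score that also modulates the richness target (±12% per SD) —
the within-plot design variation of the five composite samples, which
is genuinely unknown for real surveys and deliberately independent of
`noise_sd`; `noise_sd` (default 0.3) scales the function residual and
the within-plot resource noise. The two inverted-benefit proxies are
emitted as positive abundances `exp(−(benefit − alpha_f))` — higher =
worse — and re-oriented downstream, mirroring the ×−1 step instead of
pre-orienting. An optional `dryland_coupling_slope` overrides the decay
in chronosequences with AI < 0.5, to exercise the stratified analysis.

OTU pool sizes default to 120/250/400/800 (invertebrates / protists /
fungi / bacteria). These are modest relative to field amplicon data —
they keep the full pipeline, including 87 per-plot networks, at about a
minute on one core — and are per-group configurable. Taxon labels for
the composition-shift analyses are assigned per OTU with probabilities
that drift along the rank axis, so truncation-driven composition change
with age is built in. A `truth` block records every generative quantity
(per-plot kappa, latent scores, richness targets) for
parameter-recovery tests.

What the generator does **not** emulate: sequencing error and chimeras,
phylogenetic structure among OTUs, spatial autocorrelation between
chronosequences, compositionality corrections, and disturbance
history. Passing tests therefore demonstrate that the estimators
recover known structure under the stated sampling design — not that
field data meet these assumptions.

## Numerical choices and degenerate inputs

- Exact Spearman p-values cache the n! permutation array per n (n ≤ 8);
  tie-free pairs in network construction share one universal
  distribution per n, tied pairs are enumerated individually.
- Equality comparisons against cutoffs use a 1e−12 tolerance so edges
  at exactly the cutoff are kept and permutation counts include exact
  ties.
- Constant vectors: normalisation → 0.5 with warning; Spearman → NaN +
  flag; normality and trend fits → explicit rejection.
- Empty age groups are omitted from group fits and reported; the
  quadratic fit needs ≥ 4 populated groups.
- All randomness flows from explicit integer seeds; per-sample streams
  are derived via CRC32 of the sample id so results are independent of
  sample order. Identical configuration → bit-identical outputs.

## Problem sizes

Defaults were sized for interactive use on a single core: the full
default pipeline (435 samples, four groups, 87 networks) completes in
roughly a minute; the parameter-recovery suite runs ten full studies in
under a minute; the acceptance script regenerates everything from
scratch in about a minute.

## Known limitations

- The mixed model estimates four crossed variance components from 87
  plots across 16 chronosequences; components are often weakly
  identified and the reduction chain (documented per fit) is exercised
  routinely. The fixed-effect slope is stable across the chain.
- Network defaults at n = 5 admit only |ρ| = 1 edges (see above).
- The Akaike importance analysis treats plots as independent units;
  chronosequence-level grouping enters only through the mixed-model
  trend, not the importance screen.
- Threshold multifunctionality anchored at the observed maximum is
  sensitive to outliers in a function's distribution; the robust-max
  reference exists for that case but changes the interpretation of t.
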