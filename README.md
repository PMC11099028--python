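# chronobef

Within-site biodiversity–ecosystem-function (BEF) analysis along soil
chronosequences.

## The problem

A chronosequence is a set of sites that share climate, parent material
and topography but differ in time since soil formation — a
space-for-time substitution for pedogenesis. Surveys built on this
design ask whether the dependence of ecosystem functioning on soil
biodiversity weakens as soils age and accumulate plant cover, organic
carbon and microbial biomass. `chronobef` implements the full analysis
chain for such surveys, from community tables and function proxies to
per-plot BEF coefficients, their trend with soil age, their
environmental drivers, and per-plot co-occurrence network traits. It is
aimed at soil ecologists and microbiome researchers who have (or want to
simulate) plot-replicated amplicon and function data along environmental
gradients.

## The statistics at the core

- **Multidiversity**: per sample, richness S_g of each organism group
  g ∈ {invertebrates, protists, fungi, bacteria} is computed from OTU
  tables rarefied to group-specific depths (300 / 800 / 2000 / 5000
  reads), 0–1 normalised across all samples, and averaged:
  MD = (1/4) Σ_g norm(S_g).
- **Multifunctionality**: 13 function proxies are benefit-oriented
  (pathogen and antibiotic-resistance-gene abundances are multiplied by
  −1), 0–1 normalised, and summarised as the per-sample mean (MF_avg)
  and as threshold counts MF_t = Σ_i 1[r_i(f_i) > t_i], where t_i is a
  fixed proportion t ∈ {10, 25, 50, 75, 90}% of function i's maximum
  observed value.
- **Local BEF**: within each plot, the Spearman rank correlation ρ
  between a diversity index and a function index across the plot's five
  replicate samples, with exact permutation p-values (n ≤ 8) and
  Benjamini–Hochberg FDR adjustment per (index, target) family.
- **Age trend**: per-plot ρ regressed on log10(soil age) by a
  mixed-effects model with crossed random intercepts for parent
  material, climate class, vegetation type and location, plus
  power-series age-group fits (groups 2–7 spanning <10² to 10⁷ years)
  and dryland (aridity index < 0.5) stratification.
- **Drivers**: summed-Akaike-weight importance over an exhaustive model
  set (AICc), Pearson screens, dominant-taxon proportion analyses, and
  recursive path analysis with χ² and RMSEA fit statistics.
- **Networks**: per-plot co-occurrence graphs over all four groups
  (Spearman edges at |ρ| and p cutoffs) with eight topological traits:
  nodes, edges, positive/negative edge counts, average degree, density,
  Freeman degree centralization, modularity.

A synthetic chronosequence generator reproduces the reference survey
layout — 16 chronosequences, 87 plots, 5 composite samples per plot
(435 samples), soil ages 10–10⁷ years — with a diversity–function
coupling that decays with log10(age) by construction, so every stage is
testable end to end without external data.

## Worked example

```python
from chronobef.synthetic_data import StudyDesign, generate_study
from chronobef.community import diversity_profile
from chronobef.functions import multifunctionality_table
from chronobef.bef_stats import bef_per_plot, adjust_bef
from chronobef.trend_models import bef_family, fit_bef_age_lmm

study = generate_study(StudyDesign(seed=1))        # 435 samples, 87 plots
div = diversity_profile(study.otu_tables, seed=1)  # rarefy + multidiversity
mf = multifunctionality_table(study.functions)     # MF_avg + MF_t10..t90
bef = adjust_bef(bef_per_plot(div[["multidiversity"]], mf, None, study.samples))

fam = bef_family(bef, "multidiversity", "MF_avg")
print(f"{len(fam)} plots; mean within-plot rho = {fam['rho'].mean():.3f}")
fit = fit_bef_age_lmm(fam, study.samples)
print(f"BEF trend on log10(age): slope = {fit.slope:.4f} (SE {fit.se:.4f}, "
      f"p = {fit.p:.2e}, method = {fit.method})")
```

prints

```
87 plots; mean within-plot rho = 0.860
BEF trend on log10(age): slope = -0.0372 (SE 0.0092, p = 5.20e-05, method = REML)
```

i.e. the diversity–function correlation is strongly positive on average
but declines by about 0.04 rank-correlation units per decade of soil
age — the generator's built-in coupling decay, recovered by the mixed
model.

The same pipeline runs from the shell:

```bash
chronobef all --outdir run1 --seed 1          # synthetic default design
chronobef bef --config cfg.yaml --outdir run2 # your own TSV inputs
```

Each stage writes TSV outputs (`diversity.tsv`, `mf.tsv`, `bef.tsv`,
`network_metrics.tsv`, `trend.tsv`, `importance.tsv`, `path_fit.json`,
…) with provenance headers; re-running the same configuration is
bit-identical.

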