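# richcomp

Variance-component analysis of multi-site grassland biodiversity
experiments that manipulate both **species richness** and **species
composition**. The package asks how important each explanatory variable
is for plot-level aboveground productivity (ANPP), using three fitted
views of the same hierarchical model:

1. **Stratified least-squares ANOVA** (`stratified_anova`) — Type-I
   sequential sums of squares over the term order *experiment, block,
   richness, composition, experiment×richness, experiment×composition*,
   with an explicit error-stratum map for the F tests (unconstrained
   school by default), R² percentages, and per-site OLS slopes with 95%
   confidence intervals. Aliasing between terms is resolved purely by
   incremental rank.
2. **REML mixed model** (`reml_varcomp`) — dense restricted maximum
   likelihood over the six random variance components (five effect
   batches + residual) with a fixed overall log₂-richness slope;
   Wald-type fixed-effect F, likelihood-ratio tests for random terms
   (boundary-aware: naive χ²₁ and 50:50 mixture P side by side), and
   shrunken BLUP slopes per site.
3. **Bayesian multilevel model** (`gibbs_anova`) — a purpose-built Gibbs
   sampler with vague priors (uniform on SDs, diffuse normal on the
   grand mean and slope) that reports **finite-population SDs for every
   source, fixed or random**, with posterior medians, SE, 2.5/16/84/97.5%
   quantiles, percent shares, and Brooks–Gelman–Rubin convergence
   diagnostics. The aliased composition and site×composition batches are
   updated jointly (collapsed Gibbs) for usable mixing at short chain
   lengths.

Supporting modules: `study_data` (canonical CSV schema, validation,
cross-site composition deduplication via species sets, design
summaries), `synthetic_data` (design-skeleton builder — including a
12-site / 29-block / 778-plot / 359-composition reference layout with
tunable cross-site composition sharing — and a forward simulator with
known ground truth), and the reporting layer (`figures`, `pipeline`,
`cli`): graphical ANOVA (nested 68%/95% intervals on the SD scale),
per-site slope panels, and a config-driven end-to-end pipeline.

## Command line

```sh
richcomp simulate --out data.csv --seed 1 --sharing-fraction 0.17
richcomp anova data.csv --out anova.csv
richcomp reml data.csv --out-prefix reml
richcomp bayes data.csv --chains 3 --iter 20000 --burnin 2000 --thin 20 \
    --seed 1 --out-prefix bayes
richcomp report config.yaml --out report_dir    # configured stages
richcomp all config.yaml --out report_dir       # every stage
```

A pipeline config is YAML:

```yaml
input:
  synthetic: {sharing_fraction: 0.17, seed: 1}   # or  csv: path/to/data.csv
stages: [anova, reml, bayes, figures]
seed: 1
bayes: {chains: 3, iter: 20000, burn_in: 2000, thin: 20}
```

Input tables are delimited text with columns
`site, block, plot, richness, composition, anpp` (empty `anpp` = missing,
never zero; all fits use complete cases). An optional `composition_code`
column carries cross-site composition identity; otherwise supply a
long-format species membership table and run
`study_data.deduplicate_compositions`.

## Notes

- The model: plot response = grand mean + experiment + block +
  (overall slope + per-site deviation)·centered log₂ richness +
  composition + experiment×composition + residual, every effect batch
  drawn from its own zero-mean normal.
- Finite-population SDs are SDs of realized level effects (J−1
  denominator); for the continuous richness sources they are SDs of
  plot-level slope contributions. Super-population σ draws are retained
  alongside.
- REML percent shares follow the variance-scale convention; the Bayesian
  summary uses SD-scale shares.
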