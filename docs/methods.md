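# Methods

## Overview

`coordshift` quantifies age-related change in gene-expression
coordination in four stages:

1. **Model training** (optional — a model may be supplied): for each
   target gene, stability selection over L1-regularized regressions
   identifies persistently informative predictor genes; final weights are
   ordinary-least-squares coefficients on centered data.
2. **Network processing**: reciprocal-edge pruning, optional removal of
   predictors on the target's chromosome arm (guarding against local
   effects such as shared copy-number changes in training data), and
   restriction to the largest weakly connected component.
3. **Predictability**: each gene is reconstructed from its regulatory
   neighbors with the frozen weights; the Spearman correlation between
   observed and reconstructed expression within each age group is the
   gene's predictability there. Genes enter the age analysis only if
   their mean predictability clears a null threshold derived from a
   degree-preserving randomization of the network.
4. **Age trends and decomposition**: per-gene OLS of predictability on
   group age with a two-sided t-test on the slope, calibrated against
   permutations of the age vector; driver classification by mean and
   variance trends; and within- versus between-gene-set decomposition of
   neighbor-correlation changes.

The central premise is that the regulatory model is *external, frozen
knowledge*: weights are never refit on the data being scored, so a
change in predictability reports a change in the data's regulatory
structure, not in the model.

## Assumptions

- Gene–gene relationships are modeled as **linear** combinations of
  predictor expression on log-scale data. Nonlinear or interaction
  effects are outside the model class.
- Predictability compares **inter-individual variation**: the model
  predicts deviations from each gene's mean across the provided sample
  set, not absolute levels. Centering is computed on the sample set
  passed in (e.g., one tissue), not on global training means.
- Spearman correlation is used for observed-vs-predicted agreement
  because of its robustness to outlying individuals; Pearson is used for
  within-group gene-pair correlations in the decomposition stage
  (configurable).
- Age enters every regression as the **numeric group average** (e.g., 25
  for a 20–29 decade), in years.

## Key parameters

| Parameter | Default | Units / meaning |
|---|---|---|
| `n_subsamples` | 100 | stability-selection subsets |
| `subsample_fraction` | 0.5 | fraction of samples per subset |
| `selection_threshold` | 0.6 | minimum selection frequency |
| `max_predictors_per_fit` | 20 | per-subsample complexity cap |
| `ratio_threshold` | 0.1 | reciprocal-edge min/sum pruning |
| calibration `quantile` | 0.95 | null predictability percentile |
| `n_perm` | 100 | age-vector permutations |
| driver `cutoff` | 0.001 | absolute slope, log2-units/yr (expression) or variance-units/yr (variance) |
| `n_top` | 100 | high-confidence hit count |
| `n_strongest` | 20 | subnetwork seed hits |
| propagation `alpha` | 0.2 | smoothing weight, in [0, 1) |
| `min_mean_count` | 100 | count filter (strictly-below removed) |
| poor-prediction threshold | 0.2 | mean Spearman below ⇒ excluded |

### Penalty selection within stability selection

The per-subsample L1 penalty is chosen from a grid (by default a
30-point geometric grid from the subsample's maximal penalty
`max|Xᵀy|/m` down to 1% of it). Among grid points whose fit keeps at
most `max_predictors_per_fit` nonzero coefficients, the BIC-minimal one
is used (ties prefer the sparser, then the more penalized model). The
complexity cap alone is not sufficient: when the candidate count does
not exceed the cap, every grid point is feasible and the smallest
penalty — an essentially unregularized fit that selects all candidates —
would always win. The information criterion keeps the selected set
honest in that regime while leaving transcriptome-scale behavior (cap
binding) unchanged.

### Final weights

Stable predictors are refit by OLS on centered, *unscaled* data, so
weights live in expression units and reconstruction needs no intercept.
Collinear predictor sets fall back to ridge with penalty 1e-8 (warned).
Candidate pre-filtering to the top genes by absolute Pearson correlation
(500 above 1,000 genes, off below) bounds cost at transcriptome scale.

## The synthetic-data generator

`simulate_network` draws a sparse directed acyclic graph in a random
topological order: genes are partitioned into contiguous modules, each
ordered pair receives an edge with a within- or between-module
probability, edge weights are Uniform(±[0.3, 1.5]) (no near-zero
couplings), and any gene left predictor-less is wired to an earlier gene
of its own module, so roots are rare. A DAG in topological order makes
expression a single forward pass — appropriate because the model is a
set of per-target linear equations, not a dynamical system. An optional
`max_in_degree` caps each gene's predictor count.

`simulate_expression` generates, for each sample of age $a$ (six decade
groups, ages 25…75, 40 samples per group by default):

$$x_t = m_{t,g}\sum_p e_{pt,g}\,w_{pt}\,x_p \;+\; \mu_t\,(a-a_0)\;+\;
\varepsilon,\qquad \varepsilon \sim N\!\big(0,\ [\sigma\,(1+\nu_t(a-a_0))]^2\big)$$

with a per-gene coupling multiplier schedule $m_{t,g}$ (coordination
gain/loss; applied to the whole predictor sum, matching the "gene loses
coordination with its neighborhood" phenotype), an optional per-edge
schedule $e_{pt,g}$, a per-year mean drift $\mu_t$ (log2 units), and a
per-year noise-scale drift $\nu_t$ (variance trend). Root genes are
$N(\mu_t(a-a_0), (\sigma_\mathrm{root}\cdot\mathrm{scale})^2)$ with
$\sigma_\mathrm{root}=1$; regulatory noise is $\sigma=0.5$. Ground truth
labels each gene by the monotonicity of its coupling schedule and
records planted mean/variance changers.

`between_decoupling_study` builds the specific scenario of pure
between-module change: per module, "bridge" leaf genes whose predictors
all sit in other modules, with every bridge coupling declining 1 → 0
across the age groups while no within-module relationship is touched.

**What the generator emulates:** a sparse modular dependency structure,
age-stratified sampling with realistic group sizes, age-dependent
coupling/mean/variance changes, and (via `to_counts`) Poisson count
noise with sample size factors for testing the preprocessing path.
**What it does not emulate:** tissue composition and its age drift,
ischemic-time-like technical covariates correlated with age, single-cell
dropout, heavy-tailed count overdispersion, and trans-acting batch
structure. Passing tests therefore demonstrate that the *inference
machinery* is correct and calibrated under the stated generative model,
not that real-tissue confounding is handled.

## Numerical choices

- **Median-of-ratios size factors**: reference = per-gene geometric mean
  over samples, computed on genes positive in all samples; the median is
  taken in linear ratio space (for even gene counts this differs from
  exponentiating a log-space median).
- **Count filter boundary**: a mean of exactly 100 is kept; only
  strictly-below is removed.
- **Reciprocal pruning**: for an edge pair, $r=\min(|w_{ij}|,|w_{ji}|)/
  (|w_{ij}|+|w_{ji}|)$; below threshold the weaker edge is removed. A tie
  at equal magnitudes removes the lexicographically larger
  (predictor, target) pair — deterministic, though unreachable for
  thresholds ≤ 0.5.
- **Component tie-break**: among equal-size components, the one
  containing the lexicographically smallest gene id.
- **Target-swap randomization**: one full pass pairs shuffled edges and
  exchanges their targets (weights stay with predictors); swaps that
  would create self-edges or duplicates are pooled and re-paired for a
  bounded number of rounds. In- and out-degrees are preserved exactly.
- **Quantiles**: linear interpolation between order statistics
  (`numpy.quantile` default).
- **Degenerate regressions**: a constant response gets slope 0, p = 1; a
  perfect fit reports p = 0 with infinite t.
- **Propagation**: the symmetrized weight is the sum $w_{ij}+w_{ji}$
  (exact zero sums drop the edge); rows are normalized by the sum of
  *absolute* weights so negative couplings do not produce signless
  mixing; isolated nodes keep their own score; fixed-point iteration to
  1e-8 equals the closed form $(1-\alpha)(I-\alpha A)^{-1}F_0$.
- **Permutations** shuffle the (six) group ages, not individual samples:
  predictability is a per-group statistic, so the exchangeable unit is
  the group. Permutations are sampled with replacement.
- **Contribution weighting** uses the *signed* model coefficient
  ($w \cdot \mathrm{slope}$), because a negatively coupled pair whose
  correlation decays toward zero has a positive slope, and the signed
  product registers it as the coordination loss it is; absolute-weight
  aggregation makes such pairs cancel genuine losses (observed directly
  on planted-decoupling simulations) and is kept as an option
  (`weight_mode="absolute"`). The additivity
  within + between = total is exact by construction.
- **Multi-set membership**: sharing any gene set makes a pair "within".
- One global seed derives per-stage seeds by hashing stage names, so any
  stage can be rerun in isolation with identical results.

## Problem sizes in the test suite

Simulation-based tests use sizes chosen to give stable statistics at
desk scale: null calibration and planted-signal recovery use 500–520
genes with 6 × 40 samples; the between-module decomposition uses 20
replicate studies of 6 modules × (40 core + 10 bridge) genes; network
recovery by stability selection is evaluated on a 150-gene, 300-sample
study with true in-degree ≤ 3 (undirected-pair sensitivity ≈ 0.8–0.85,
FDR ≈ 0.13–0.18 across seeds). At several hundred genes the recovery
frontier flattens near sensitivity 0.8 / FDR 0.2: the residual false
pairs are almost entirely two-hop Markov-blanket relatives (spouses and
grandparents), which no marginal-plus-L1 procedure fully separates, and
the missed edges concentrate at the weak end of the weight distribution.

## Known limitations

- **The driver cutoff is a point-estimate threshold, not a test.** The
  0.001/yr expression-slope cutoff is compared against an OLS estimate
  whose sampling error at ~240 samples is of the same order or larger
  whenever per-gene variability is large enough for variance trends to
  be measurable on the same scale. On synthetic data this makes the
  expression-change flag noise-dominated for hits with sizable variance
  (the measured false-flag rate is reported by the acceptance script);
  the variance-change flag, whose planted effects are an order of
  magnitude above the cutoff, is essentially noise-free. Users wanting a
  calibrated expression-change call should pair the cutoff with the
  reported p-values rather than rely on the threshold alone.
- Directionality of trained edges is not causally identifiable from
  observational data; evaluation and downstream use treat edge pairs as
  undirected where appropriate (symmetrization, density, components).
- Empirical-Bayes moderation of expression slopes is deliberately not
  implemented; plain OLS is used. Point estimates — which all thresholds
  act on — are unchanged by moderation; only shrinkage of the standard
  errors would differ.
- The external enrichment step is out of scope: the package exports
  ranked `.rnk` lists for preranked GSEA instead of running it.
- Balanced subsampling is generic per-group downsampling; acquisition
  idiosyncrasies of specific cohorts (e.g., multi-region donor
  prioritization) are not modeled.
- Whether the within/between sums should be normalized per hit before
  pooling is genuinely open; pooled sums are the default and the
  per-set weighted average is also reported.
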