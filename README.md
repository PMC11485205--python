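# coordshift

Detecting age-related gains and losses of **gene-expression coordination**
with a sparse gene–gene regulatory model.

## The problem

Aging changes not only how much individual genes are expressed, but how
well their expression stays *coordinated* with the genes that normally
co-regulate them. Pairwise differential co-expression compares young and
old correlation matrices directly, but it cannot say whether a change
reflects loss of regulatory control or an orderly, regulated shift.
`coordshift` takes a different route: it learns a sparse linear model of
gene–gene relationships on reference data, freezes it, and then asks, for
each gene and each age group, how well the frozen model still predicts
that gene's expression across individuals. The per-gene, per-age-group
agreement is the gene's **predictability**; its trend over age separates
genes that drift away from their regulatory neighborhood (coordination
loss) from genes that align with it more tightly (coordination gain).

It is written for computational biologists working with bulk expression
matrices stratified by donor age (or any ordered condition), and it ships
a synthetic-data generator with planted ground truth so the entire
pipeline is testable without external data.

## The model

For each target gene $a$, stability selection over L1-regularized
regressions (repeated fits on random half-size sample subsets) picks the
candidate genes whose expression is persistently informative for $a$;
ordinary least squares on centered data then gives the final weights
$w_{pa}$:

$$\hat{x}_a = \sum_{p \in \mathrm{pred}(a)} w_{pa}\,(x_p - \bar{x}_p).$$

The trained network is post-processed (reciprocal-edge pruning at a
min/sum ratio of 0.1, optional same-chromosome-arm removal, largest
connected component). On study data the frozen weights reconstruct each
gene, and predictability in age group $g$ is

$$\rho_{a,g} = \mathrm{Spearman}\big(x_a, \hat{x}_a\big)\ \text{across samples of } g,$$

followed by the regression $\rho_{a,g} \sim \beta_0 + \beta_1\,
\mathrm{age}_g$ with a two-sided t-test on $\beta_1$ (df = groups − 2).
Calibration instruments: a degree-preserving target-swap randomization of
the network fixes the gene-inclusion threshold (95th percentile of the
null predictability distribution), and 100 permutations of the age vector
provide the null for the p-value histogram. Hits are classified by their
drivers (mean-expression slope, within-group variance slope, cutoff
0.001/yr with sign consistency excluding the oldest group), and each
hit's neighbor-correlation trends are decomposed into within- versus
between-gene-set contributions weighted by the model coefficients.

## Worked example

Simulate a 200-gene study (six age decades, 40 samples each) in which 20
genes progressively lose coupling to their regulatory inputs (multiplier
declining 1 → 0.2 from the youngest to the oldest group), then recover
them:

```python
import numpy as np
from coordshift import *
from coordshift.simulate import SimulationConfig, simulate_network, simulate_expression

base = SimulationConfig(n_genes=200, n_modules=4, seed=42)
network, modules = simulate_network(base)
planted = list(network.edges["target"].value_counts().index[:20])
config = SimulationConfig(
    n_genes=200, n_modules=4, seed=42,
    coupling_schedule={t: tuple(np.linspace(1.0, 0.2, 6)) for t in planted},
)
network, modules = simulate_network(config)
expr, meta, truth = simulate_expression(network, config)

recon = reconstruct_expression(network, expr)
table = predictability_by_group(expr, recon, meta)
print(table.rho.loc[planted[0]].round(3))

trends = fit_predictability_slopes(table)
hits = select_top_hits(trends, n_top=40, require_consistency=True)
print(len(set(planted) & set(hits.index)) / len(planted))
```

Output:

```
20-29    0.959
30-39    0.949
40-49    0.937
50-59    0.759
60-69    0.784
70-79    0.523
0.95
```

The planted gene is almost perfectly predicted by its neighbors in the
youngest decade (ρ = 0.96) and poorly in the oldest (ρ = 0.52); the
negative Predictability ~ Age slope puts it among the top hits, and 95%
of the planted genes are recovered in the top 40. On the same study,
`calibrate_predictability_threshold` (target-swapped network, 95th
percentile) returns 0.585, retaining 96% of genes under the true model.

The GRN is also available as a scikit-learn estimator:

```python
from coordshift import GeneRegulatoryNetwork
est = GeneRegulatoryNetwork(n_subsamples=50, selection_threshold=0.6, seed=0)
est.fit(X_train)          # samples x genes DataFrame, log-space
X_hat = est.predict(X_new)  # centered reconstructions from frozen weights
```

A `coordshift` CLI wraps every stage (`simulate`, `preprocess`, `train`,
`prune`, `lcc`, `randomize`, `density`, `propagate`, `reconstruct`,
`quality`, `predictability`, `trend`, `null`, `drivers`, plus `run` for
the whole pipeline from a YAML config with a hashed run manifest).

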