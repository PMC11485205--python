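"""Synthetic expression studies with a known regulatory network.

The generator builds a sparse gene-gene dependency structure with modular
organization (a DAG generated in a random topological order, so expression
is a single forward pass), then simulates samples stratified into age
groups.  Age acts on the data in three ways, each plantable per gene:

* a *coupling schedule* scales the regulatory input of a target per age
  group, weakening (coordination loss) or strengthening (gain) the gene's
  agreement with its regulatory neighborhood;
* a *mean trend* adds a per-year drift to the gene's expression (log2
  units per year);
* a *variance trend* scales the noise standard deviation per year,
  producing age-dependent inter-individual variability.

Defaults emulate a bulk-tissue study: six decade-wide age groups
(25 ... 75 years), 40 samples per group, unit-variance root genes and
Gaussian noise of SD 0.5 on log-scale values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, RegulatoryModel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_network",
    "simulate_expression",
    "simulate_study",
    "to_counts",
    "module_gene_sets",
]

#: six decade-wide age groups, ages coded as the group average
DEFAULT_AGE_GROUPS = (
    ("20-29", 25.0),
    ("30-39", 35.0),
    ("40-49", 45.0),
    ("50-59", 55.0),
    ("60-69", 65.0),
    ("70-79", 75.0),
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated study; see the module docstring."""

    n_genes: int = 500
    n_modules: int = 8
    within_module_edge_prob: float = 0.06
    between_module_edge_prob: float = 0.002
    age_groups: tuple = DEFAULT_AGE_GROUPS
    n_samples_per_group: int = 40
    coupling_schedule: dict = field(default_factory=dict)
    edge_coupling_schedule: dict = field(default_factory=dict)
    mean_trend: dict = field(default_factory=dict)
    variance_trend: dict = field(default_factory=dict)
    noise_sd: float = 0.5
    root_sd: float = 1.0
    weight_low: float = 0.3
    weight_high: float = 1.5
    max_in_degree: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_module_edge_prob", "between_module_edge_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 1 <= self.n_modules <= self.n_genes:
            raise ValueError("need n_genes >= n_modules >= 1")
        ages = [a for _, a in self.age_groups]
        if not all(b > a for a, b in zip(ages, ages[1:])):
            raise ValueError("numeric ages must be strictly increasing")
        if self.n_samples_per_group < 3:
            raise ValueError("n_samples_per_group must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.max_in_degree is not None and self.max_in_degree < 1:
            raise ValueError("max_in_degree must be >= 1 when set")
        n_groups = len(self.age_groups)
        for sched in (self.coupling_schedule, self.edge_coupling_schedule):
            for key, mult in sched.items():
                mult = np.asarray(mult, float)
                if mult.shape != (n_groups,):
                    raise ValueError(f"coupling schedule for {key!r} must have one value per age group")
                if (mult < 0).any():
                    raise ValueError(f"coupling multipliers for {key!r} must be non-negative")

    @property
    def group_labels(self) -> list:
        return [lab for lab, _ in self.age_groups]

    @property
    def group_ages(self) -> np.ndarray:
        return np.asarray([a for _, a in self.age_groups], float)


@dataclass
class GroundTruth:
    """What was planted: the generating network and per-gene labels.

    ``labels`` maps every simulated gene to ``coordination_loss`` /
    ``coordination_gain`` / ``stable`` from the monotonicity of its
    coupling schedule; ``mean_changers`` and ``variance_changers`` are the
    genes with nonzero planted mean / variance trends.
    """

    true_network: RegulatoryModel
    labels: dict
    mean_changers: set
    variance_changers: set

    def genes_labeled(self, label: str) -> list:
        return sorted(g for g, l in self.labels.items() if l == label)


def _gene_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_network(config: SimulationConfig):
    """Draw the sparse regulatory DAG and module assignment.

    Genes are partitioned into contiguous modules, a random topological
    order is drawn, and each ordered pair (earlier -> later) receives an
    edge with the within- or between-module probability.  Weights are
    Uniform(weight_low, weight_high) in magnitude with random sign, so no
    coupling sits near zero.  Any gene left without a predictor is given
    one from an earlier gene of its own module when available (keeping
    ``between_module_edge_prob == 0`` airtight), so roots are essentially
    limited to the first gene of each module in topological order.

    Returns
    -------
    (RegulatoryModel, pandas.Series)
        The model and the module label per gene.
    """
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_names(config.n_genes)
    module_of = {}
    for m, chunk in enumerate(np.array_split(np.asarray(genes), config.n_modules)):
        for g in chunk:
            module_of[g] = f"M{m}"
    order = [genes[i] for i in rng.permutation(config.n_genes)]

    preds: list = []
    targs: list = []
    for j in range(1, config.n_genes):
        t = order[j]
        mine: list = []
        for i in range(j):
            p = order[i]
            prob = (
                config.within_module_edge_prob
                if module_of[p] == module_of[t]
                else config.between_module_edge_prob
            )
            if rng.random() < prob:
                mine.append(p)
        if config.max_in_degree is not None and len(mine) > config.max_in_degree:
            keep = rng.choice(len(mine), config.max_in_degree, replace=False)
            mine = [mine[i] for i in sorted(keep)]
        preds.extend(mine)
        targs.extend([t] * len(mine))
        if not mine:
            same = [order[i] for i in range(j) if module_of[order[i]] == module_of[t]]
            pool = same if same else (order[:j] if config.between_module_edge_prob > 0 else [])
            if pool:
                preds.append(pool[int(rng.integers(len(pool)))])
                targs.append(t)

    n_edges = len(preds)
    mags = rng.uniform(config.weight_low, config.weight_high, n_edges)
    signs = rng.choice([-1.0, 1.0], n_edges)
    edges = pd.DataFrame(
        {"predictor": preds, "target": targs, "weight": mags * signs}
    )
    model = RegulatoryModel(edges, {"source": "simulate_network", "seed": config.seed})
    modules = pd.Series({g: module_of[g] for g in genes}, name="module")
    return model, modules


def _ground_truth(model: RegulatoryModel, config: SimulationConfig) -> GroundTruth:
    labels = {}
    for g in _gene_names(config.n_genes):
        sched = config.coupling_schedule.get(g)
        if sched is None:
            labels[g] = "stable"
            continue
        d = np.diff(np.asarray(sched, float))
        if (d < 0).all():
            labels[g] = "coordination_loss"
        elif (d > 0).all():
            labels[g] = "coordination_gain"
        else:
            labels[g] = "stable"
    return GroundTruth(
        true_network=model,
        labels=labels,
        mean_changers={g for g, v in config.mean_trend.items() if v != 0},
        variance_changers={g for g, v in config.variance_trend.items() if v != 0},
    )


def simulate_expression(model: RegulatoryModel, config: SimulationConfig):
    """Forward-simulate expression through the DAG for every age group.

    For sample s in age group k (numeric age ``a``), a non-root gene t is

        x_t = m_tk * sum_p  e_ptk * w_pt * x_p  +  mu_t*(a - a0)  +  eps,

    with ``m_tk`` the gene-level coupling multiplier, ``e_ptk`` an optional
    per-edge multiplier, ``mu_t`` the per-year mean trend relative to the
    youngest group age ``a0``, and ``eps ~ N(0, sd_t(a)^2)`` where
    ``sd_t(a) = noise_sd * max(0, 1 + nu_t*(a - a0))`` encodes the variance
    trend ``nu_t``.  Root genes are ``N(mu_t*(a-a0), (root_sd*scale)^2)``.

    Returns ``(ExpressionMatrix, SampleMetadata, GroundTruth)``; the matrix
    is log-scale residual-like data ready for reconstruction.
    """
    genes = _gene_names(config.n_genes)
    extra = set(model.genes) - set(genes)
    if extra:
        raise ValueError(f"model contains genes outside the config: {sorted(extra)[:5]}")

    dig = model.to_digraph()
    dig.add_nodes_from(genes)
    try:
        topo = list(nx.topological_sort(dig))
    except nx.NetworkXUnfeasible as err:
        raise ValueError("model has cycles; the generator requires a DAG") from err

    pred_map = model.predictor_map()
    rng = np.random.default_rng([config.seed, 1])
    n_per = config.n_samples_per_group
    a0 = config.group_ages[0]

    sample_ids: list = []
    meta_rows: list = []
    blocks: list = []
    for k, (label, age) in enumerate(config.age_groups):
        ids = [f"{label}_s{j:03d}" for j in range(n_per)]
        sample_ids.extend(ids)
        for sid in ids:
            meta_rows.append({"sample_id": sid, "age_group": label, "age_numeric": age, "tissue": "synthetic"})

        x = {}
        for t in topo:
            mu = config.mean_trend.get(t, 0.0) * (age - a0)
            scale = max(0.0, 1.0 + config.variance_trend.get(t, 0.0) * (age - a0))
            if t not in pred_map:
                x[t] = mu + rng.normal(0.0, config.root_sd * scale, n_per)
                continue
            preds, weights = pred_map[t]
            m = config.coupling_schedule.get(t)
            mult = 1.0 if m is None else float(m[k])
            total = np.zeros(n_per)
            for p, w in zip(preds, weights):
                e = config.edge_coupling_schedule.get((p, t))
                ew = 1.0 if e is None else float(e[k])
                total += ew * w * x[p]
            x[t] = mult * total + mu + rng.normal(0.0, config.noise_sd * scale, n_per)
        blocks.append(pd.DataFrame(x, index=ids).T.loc[genes])

    values = pd.concat(blocks, axis=1)
    expr = ExpressionMatrix(values, "residual")
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    meta["age_group"] = pd.Categorical(meta["age_group"], categories=config.group_labels, ordered=True)
    return expr, meta, _ground_truth(model, config)


def simulate_study(config: SimulationConfig):
    """Convenience wrapper: network + expression in one call.

    Returns ``(model, modules, expr, meta, truth)``.
    """
    model, modules = simulate_network(config)
    expr, meta, truth = simulate_expression(model, config)
    return model, modules, expr, meta, truth


def between_decoupling_study(
    n_modules: int = 6,
    module_size: int = 40,
    n_bridges_per_module: int = 10,
    bridge_in_degree: int = 3,
    within_module_edge_prob: float = 0.1,
    n_samples_per_group: int = 40,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """A study planting *between-module decoupling only*.

    Each module holds ``module_size`` core genes wired by a random
    within-module DAG.  On top, every module owns ``n_bridges_per_module``
    "bridge" genes — leaf targets whose predictors all sit in *other*
    modules, so every bridge edge is a between-module relationship.  The
    coupling of every bridge edge declines linearly from 1 (youngest
    group) to 0 (oldest), while no within-module relationship is touched.
    Bridges therefore lose coordination with their cross-module
    neighborhood with age; core genes age neutrally.

    Returns ``(model, config, gene_sets, expr, meta, bridge_genes)``.
    """
    rng = np.random.default_rng([seed, 2])
    n_core = n_modules * module_size
    n_genes = n_core + n_modules * n_bridges_per_module
    genes = _gene_names(n_genes)
    module_of = {}
    for i in range(n_core):
        module_of[genes[i]] = f"M{i // module_size}"
    bridges = genes[n_core:]
    for k, b in enumerate(bridges):
        module_of[b] = f"M{k % n_modules}"

    def _weights(size):
        return rng.uniform(0.3, 1.5, size) * rng.choice([-1.0, 1.0], size)

    preds: list = []
    targs: list = []
    for m in range(n_modules):
        members = genes[m * module_size : (m + 1) * module_size]
        for j in range(1, module_size):
            for i in range(j):
                if rng.random() < within_module_edge_prob:
                    preds.append(members[i])
                    targs.append(members[j])
    schedule = {}
    decline = tuple(np.linspace(1.0, 0.0, len(DEFAULT_AGE_GROUPS)))
    for b in bridges:
        other = [g for g in genes[:n_core] if module_of[g] != module_of[b]]
        chosen = rng.choice(len(other), bridge_in_degree, replace=False)
        for c in chosen:
            preds.append(other[c])
            targs.append(b)
            schedule[(other[c], b)] = decline

    edges = pd.DataFrame(
        {"predictor": preds, "target": targs, "weight": _weights(len(preds))}
    )
    model = RegulatoryModel(edges, {"source": "between_decoupling_study", "seed": seed})
    config = SimulationConfig(
        n_genes=n_genes,
        n_modules=n_modules,
        n_samples_per_group=n_samples_per_group,
        noise_sd=noise_sd,
        edge_coupling_schedule=schedule,
        seed=seed,
    )
    expr, meta, _ = simulate_expression(model, config)
    gene_sets: dict = {}
    for g, m in module_of.items():
        gene_sets.setdefault(m, []).append(g)
    gene_sets = {m: sorted(v) for m, v in gene_sets.items()}
    return model, config, gene_sets, expr, meta, list(bridges)


def to_counts(expr: ExpressionMatrix, size_factors=None, seed: int = 0) -> ExpressionMatrix:
    """Export log-scale values as count-like data for preprocessing tests.

    Counts are Poisson with mean ``sf_s * 2**x_gs``; size factors default
    to 1 for every sample.
    """
    rng = np.random.default_rng(seed)
    lam = np.exp2(expr.values.to_numpy(float))
    if size_factors is not None:
        sf = np.asarray([size_factors[s] for s in expr.samples], float)
        if (sf <= 0).any():
            raise ValueError("size factors must be positive")
        lam = lam * sf[None, :]
    counts = rng.poisson(lam).astype(float)
    if (counts == 0).all(axis=1).any():
        warnings.warn("some exported genes have all-zero counts", stacklevel=2)
    return ExpressionMatrix(
        pd.DataFrame(counts, index=expr.genes, columns=expr.samples), "counts"
    )


def module_gene_sets(modules: pd.Series) -> dict:
    """Turn a module assignment into a gene-set collection (one set per module)."""
    return {m: sorted(sub.index) for m, sub in modules.groupby(modules)}
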