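"""Post-processing, randomization, scoring and smoothing on the model.

* Reciprocal-edge pruning: for an edge pair i->j / j->i whose weaker
  member is tiny relative to the pair (min/sum of absolute weights below a
  threshold, default 0.1), the weaker edge is treated as residual and
  removed.
* Same-chromosome-arm removal guards against local (e.g., copy-number)
  effects masquerading as regulation.
* Target-swap randomization builds a degree-preserving null model by
  exchanging the targets of random edge pairs.
* Gene-set edge density normalizes connected unordered pairs within a set
  by k(k-1)/2 and compares sets against the whole-network background with
  a one-sample t-test.
* Propagation smooths per-gene scores over the symmetrized, row-normalized
  network: F <- alpha * A F + (1 - alpha) * F0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import RegulatoryModel

__all__ = [
    "PruneConfig",
    "PropagationConfig",
    "prune_residual_edges",
    "remove_same_arm_predictors",
    "largest_connected_component",
    "randomize_targets",
    "gene_set_edge_density",
    "symmetrize",
    "propagate_scores",
]


@dataclass
class PruneConfig:
    """Reciprocal-edge pruning threshold on min/sum of absolute weights."""

    ratio_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_threshold <= 0.5:
            raise ValueError("ratio_threshold must be in [0, 0.5]")


@dataclass
class PropagationConfig:
    """Fixed-point smoothing parameters; alpha < 1 guarantees convergence."""

    alpha: float = 0.2
    tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


def prune_residual_edges(model: RegulatoryModel, config: PruneConfig | None = None) -> RegulatoryModel:
    """Remove the weaker edge of strongly asymmetric reciprocal pairs.

    For each reciprocal pair, ``r = min(|w_ij|, |w_ji|) / (|w_ij| + |w_ji|)``;
    when ``r`` is below the threshold the edge with the smaller absolute
    weight is dropped (tie at equal |w|: the lexicographically larger
    (predictor, target) pair is dropped).  Unpaired edges are untouched.
    """
    config = config or PruneConfig()
    edges = model.edges
    w = dict(zip(zip(edges["predictor"], edges["target"]), edges["weight"]))
    drop = set()
    for (i, j), wij in w.items():
        if (j, i) not in w or (j, i) in drop or (i, j) in drop:
            continue
        wji = w[(j, i)]
        lo, hi = sorted([abs(wij), abs(wji)])
        r = lo / (lo + hi)
        if r < config.ratio_threshold:
            if abs(wij) < abs(wji):
                drop.add((i, j))
            elif abs(wji) < abs(wij):
                drop.add((j, i))
            else:
                drop.add(max((i, j), (j, i)))
    keep = [
        (p, t) not in drop
        for p, t in zip(edges["predictor"], edges["target"])
    ]
    return RegulatoryModel(edges.loc[keep], dict(model.provenance))


def remove_same_arm_predictors(model: RegulatoryModel, annotation: pd.DataFrame) -> RegulatoryModel:
    """Drop edges whose predictor and target share chromosome and arm.

    ``annotation`` is indexed by gene id with columns ``chromosome`` and
    ``arm`` (p/q).  Edges touching unannotated genes are kept (with one
    warning reporting the count).
    """
    for col in ("chromosome", "arm"):
        if col not in annotation.columns:
            raise ValueError(f"annotation requires a {col!r} column")
    bad_arms = set(annotation["arm"].dropna().unique()) - {"p", "q"}
    if bad_arms:
        raise ValueError(f"malformed arm labels (expected p/q): {sorted(bad_arms)}")

    loc = {
        g: (annotation.at[g, "chromosome"], annotation.at[g, "arm"])
        for g in annotation.index
    }
    edges = model.edges
    keep = []
    n_unannotated = 0
    for p, t in zip(edges["predictor"], edges["target"]):
        if p not in loc or t not in loc:
            n_unannotated += 1
            keep.append(True)
        else:
            keep.append(loc[p] != loc[t])
    if n_unannotated:
        warnings.warn(
            f"{n_unannotated} edges kept with unannotated endpoint(s)", stacklevel=2
        )
    return RegulatoryModel(edges.loc[keep], dict(model.provenance))


def largest_connected_component(model: RegulatoryModel) -> RegulatoryModel:
    """Subgraph induced by the largest weakly connected component.

    Direction is ignored for connectivity.  Ties on component size go to
    the component containing the lexicographically smallest gene id.
    """
    if model.n_edges == 0:
        raise ValueError("model has no edges")
    g = model.to_digraph()
    comps = list(nx.weakly_connected_components(g))
    max_size = max(len(c) for c in comps)
    candidates = [c for c in comps if len(c) == max_size]
    best = min(candidates, key=lambda c: min(map(str, c)))
    edges = model.edges
    keep = [p in best and t in best for p, t in zip(edges["predictor"], edges["target"])]
    return RegulatoryModel(edges.loc[keep], dict(model.provenance))


def randomize_targets(
    model: RegulatoryModel, seed: int = 0, passes: int = 1, max_retries: int = 20
) -> RegulatoryModel:
    """Degree-preserving null model by swapping targets of random edge pairs.

    One pass shuffles the edge list, pairs consecutive edges, and swaps the
    two targets of each pair (weights stay with their predictor slot).  A
    swap that would create a self-edge or a duplicate edge sends both edges
    to a retry pool that is re-shuffled and re-paired, up to ``max_retries``
    rounds; irreducibly conflicting edges stay unswapped.  In- and
    out-degrees of every gene are preserved exactly.
    """
    if model.n_edges < 2:
        raise ValueError("need at least two edges to randomize")
    rng = np.random.default_rng(seed)
    preds = model.edges["predictor"].to_list()
    targs = model.edges["target"].to_list()
    weights = model.edges["weight"].to_list()
    n = len(preds)

    edge_set = set(zip(preds, targs))
    for _ in range(passes):
        pool = list(range(n))
        for _retry in range(max_retries):
            rng.shuffle(pool)
            leftovers = []
            for a, b in zip(pool[0::2], pool[1::2]):
                p1, t1 = preds[a], targs[a]
                p2, t2 = preds[b], targs[b]
                new1, new2 = (p1, t2), (p2, t1)
                if (
                    p1 == t2
                    or p2 == t1
                    or new1 == new2
                    or (new1 in edge_set and new1 != (p1, t1) and new1 != (p2, t2))
                    or (new2 in edge_set and new2 != (p1, t1) and new2 != (p2, t2))
                ):
                    leftovers.extend([a, b])
                    continue
                edge_set.discard((p1, t1))
                edge_set.discard((p2, t2))
                edge_set.add(new1)
                edge_set.add(new2)
                targs[a], targs[b] = t2, t1
            if len(pool) % 2 == 1:
                leftovers.append(pool[-1])
            if len(leftovers) < 2:
                break
            pool = leftovers

    edges = pd.DataFrame({"predictor": preds, "target": targs, "weight": weights})
    prov = dict(model.provenance)
    prov["randomized"] = {"seed": seed, "passes": passes}
    return RegulatoryModel(edges, prov)


def gene_set_edge_density(model: RegulatoryModel, sets: dict, min_set_size: int = 3):
    """Edge density per gene set plus a one-sample t-test against background.

    Density of a set with k usable genes = (# unordered gene pairs inside
    the set connected by an edge in either direction) / (k(k-1)/2).  Sets
    with fewer than ``min_set_size`` genes in the model are skipped with a
    warning.  The background is the same statistic over all model genes;
    the t-test is two-sided over the vector of set densities.

    Returns ``(densities: Series, background: float, test: dict | None)``.
    """
    genes = set(model.genes)
    pairs = {
        frozenset((p, t)) for p, t in zip(model.edges["predictor"], model.edges["target"])
    }

    def density(members: list) -> float:
        k = len(members)
        hits = sum(
            1
            for a_i in range(k)
            for b_i in range(a_i + 1, k)
            if frozenset((members[a_i], members[b_i])) in pairs
        )
        return hits / (k * (k - 1) / 2)

    out = {}
    for name, members in sets.items():
        usable = sorted(genes.intersection(members))
        if len(usable) < min_set_size:
            warnings.warn(
                f"set {name!r} skipped: {len(usable)} usable genes < {min_set_size}",
                stacklevel=2,
            )
            continue
        out[name] = density(usable)
    densities = pd.Series(out, name="edge_density", dtype=float)
    background = density(sorted(genes))

    test = None
    if len(densities) >= 2:
        t, p = scipy.stats.ttest_1samp(densities.to_numpy(), background)
        test = {"t_statistic": float(t), "p_value": float(p), "n_sets": int(len(densities))}
    return densities, background, test


def symmetrize(model: RegulatoryModel) -> nx.Graph:
    """Undirected graph with u_ij = w_ij + w_ji; exact zero sums drop the edge."""
    sums: dict = {}
    for p, t, w in model.edges.itertuples(index=False, name=None):
        key = (p, t) if str(p) <= str(t) else (t, p)
        sums[key] = sums.get(key, 0.0) + float(w)
    g = nx.Graph()
    g.add_nodes_from(model.genes)
    for (a, b), u in sums.items():
        if u != 0.0:
            g.add_edge(a, b, weight=u)
    return g


def propagate_scores(
    graph: nx.Graph, scores, config: PropagationConfig | None = None
) -> pd.Series:
    """Smooth per-node scores over the row-normalized network.

    Iterates ``F <- alpha * A F + (1 - alpha) * F0`` to its fixed point
    ``(1 - alpha)(I - alpha A)^(-1) F0``.  Rows of the adjacency are
    normalized by the sum of absolute edge weights, so negative regulatory
    weights do not produce signless mixing; an isolated node keeps its own
    score (identity row).  Nodes missing from ``scores`` enter as 0 with a
    warning.
    """
    config = config or PropagationConfig()
    nodes = sorted(graph.nodes, key=str)
    scores = pd.Series(scores, dtype=float)
    missing = [n for n in nodes if n not in scores.index]
    if missing:
        warnings.warn(f"{len(missing)} nodes missing a score; set to 0", stacklevel=2)
    f0 = np.asarray([float(scores.get(n, 0.0)) for n in nodes])

    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for a, b, data in graph.edges(data=True):
        w = abs(float(data.get("weight", 1.0)))
        A[idx[a], idx[b]] += w
        A[idx[b], idx[a]] += w
    rowsum = A.sum(axis=1)
    isolated = rowsum == 0
    A[~isolated] /= rowsum[~isolated, None]
    A[isolated, isolated] = 1.0

    f = f0.copy()
    for _ in range(config.max_iter):
        f_new = config.alpha * (A @ f) + (1.0 - config.alpha) * f0
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < config.tol:
            break
    else:
        warnings.warn("propagation did not reach tol within max_iter", stacklevel=2)
    return pd.Series(f, index=nodes, name="propagated")
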