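"""Within- vs between-set correlation changes and hit subnetworks.

For each predictability hit and each of its regulatory neighbors, the
Pearson correlation between the two genes is computed within every age
group and regressed on group age; the slope quantifies how that pairwise
coordination changes with age.  Pair slopes are then aggregated into
within-set and between-set contributions — a pair is "within" when target
and neighbor share at least one functional gene set — weighted by the
absolute model coefficient so strongly coupled neighbors dominate.
Finally, hit-centered subnetworks (strongest hits plus their immediate
neighbors) are extracted for inspection.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, RegulatoryModel, group_ages, validate_metadata
from .predictability import ols_slope_test

__all__ = [
    "neighbor_correlation_slopes",
    "within_between_contributions",
    "extract_hit_subnetwork",
]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def neighbor_correlation_slopes(
    expr: ExpressionMatrix,
    model: RegulatoryModel,
    targets,
    meta: pd.DataFrame,
    min_group_size: int = 3,
    use_spearman: bool = False,
) -> pd.DataFrame:
    """Per (target, neighbor-with-edge) pair: correlation-vs-age slope.

    For every edge touching a requested target, the within-group Pearson
    correlation (Spearman optional) between target and neighbor is
    computed per age group, then regressed on the group's numeric age.
    Groups where either gene has zero variance contribute a missing
    correlation; pairs with fewer than 3 usable groups are skipped.
    """
    validate_metadata(meta, expr.samples)
    targets = set(targets)
    unknown = targets - set(model.targets)
    if unknown:
        raise ValueError(f"targets absent from the model: {sorted(unknown)[:5]}")
    ages = group_ages(meta.loc[expr.samples])
    group_samples = {
        label: expr.samples[(meta.loc[expr.samples, "age_group"] == label).to_numpy()]
        for label in ages.index
    }
    group_samples = {
        k: v for k, v in group_samples.items() if len(v) >= min_group_size
    }

    vals = expr.values
    if use_spearman:
        vals = vals.rank(axis=1)
    present = set(expr.genes)

    rows = []
    for p, t, w in model.edges.itertuples(index=False, name=None):
        if t not in targets:
            continue
        if p not in present or t not in present:
            continue
        xs, cs = [], []
        for label, samples in group_samples.items():
            c = _pearson(
                vals.loc[t, samples].to_numpy(float),
                vals.loc[p, samples].to_numpy(float),
            )
            if np.isfinite(c):
                xs.append(float(ages[label]))
                cs.append(c)
        if len(cs) < 3:
            continue
        slope, *_ = ols_slope_test(np.asarray(xs), np.asarray(cs))
        rows.append({"target": t, "neighbor": p, "weight": w, "corr_slope": slope})
    return pd.DataFrame(rows, columns=["target", "neighbor", "weight", "corr_slope"])


def _shares_set(a: str, b: str, membership: dict) -> bool:
    return bool(membership.get(a, frozenset()) & membership.get(b, frozenset()))


def within_between_contributions(
    pairs: pd.DataFrame,
    hit_directions: pd.Series,
    sets: dict,
    weight_mode: str = "signed",
) -> pd.DataFrame:
    """Aggregate pair correlation slopes into (direction, scope) cells.

    ``hit_directions`` maps hit gene -> "increase"/"decrease" (sign of its
    predictability slope).  A pair is "within" iff target and neighbor
    share at least one gene set, else "between"; contributions are
    ``weighted_sum = sum w * corr_slope`` and
    ``weighted_average = weighted_sum / sum |w|`` over the cell's pairs.
    By default the *signed* model coefficient weights each slope: a
    negatively coupled pair whose correlation decays toward zero has a
    positive slope, and the signed product turns it into the loss it
    represents — with absolute weights such pairs would cancel genuine
    losses on positively coupled pairs.  ``weight_mode="absolute"``
    selects the |w| variant.  Hits absent from every set have all their
    pairs counted as "between" (warned).
    """
    if weight_mode not in ("signed", "absolute"):
        raise ValueError("weight_mode must be 'signed' or 'absolute'")
    membership: dict = {}
    for name, genes in sets.items():
        for g in genes:
            membership.setdefault(g, set()).add(name)

    orphan_hits = {
        h for h in hit_directions.index if h not in membership
    }
    if orphan_hits and sets:
        warnings.warn(
            f"{len(orphan_hits)} hit(s) absent from all gene sets; their pairs count as between",
            stacklevel=2,
        )

    cells: dict = {}
    for row in pairs.itertuples(index=False):
        if row.target not in hit_directions.index:
            continue
        direction = hit_directions[row.target]
        scope = "within" if _shares_set(row.target, row.neighbor, membership) else "between"
        cell = cells.setdefault((direction, scope), {"ws": 0.0, "aw": 0.0, "n": 0})
        w = row.weight if weight_mode == "signed" else abs(row.weight)
        cell["ws"] += w * row.corr_slope
        cell["aw"] += abs(row.weight)
        cell["n"] += 1

    rows = []
    for direction in ("increase", "decrease"):
        for scope in ("within", "between"):
            cell = cells.get((direction, scope))
            rows.append(
                {
                    "direction": direction,
                    "scope": scope,
                    "weighted_sum": cell["ws"] if cell else 0.0,
                    "weighted_average": (cell["ws"] / cell["aw"]) if cell and cell["aw"] > 0 else np.nan,
                    "n_pairs": cell["n"] if cell else 0,
                }
            )
    return pd.DataFrame(rows)


def extract_hit_subnetwork(
    model: RegulatoryModel, trends: pd.DataFrame, n_strongest: int = 20
) -> nx.DiGraph:
    """Subgraph of the strongest hits and their immediate neighbors.

    ``trends`` holds the hit list with a ``slope`` column; the
    ``n_strongest`` genes by absolute slope seed the subnetwork, which is
    completed with every gene sharing a model edge with a seed.  Node
    attribute ``slope`` carries the predictability slope where known.
    """
    hits = trends.dropna(subset=["slope"])
    if n_strongest > len(hits):
        warnings.warn(
            f"n_strongest={n_strongest} exceeds {len(hits)} hits; using all", stacklevel=2
        )
        n_strongest = len(hits)
    seeds = (
        hits.assign(_a=hits["slope"].abs())
        .sort_values(["_a"], ascending=False, kind="stable")
        .head(n_strongest)
        .index
    )
    seed_set = set(seeds)
    nodes = set(seeds)
    for p, t in zip(model.edges["predictor"], model.edges["target"]):
        if p in seed_set:
            nodes.add(t)
        if t in seed_set:
            nodes.add(p)

    g = nx.DiGraph()
    for n in sorted(nodes, key=str):
        slope = trends.at[n, "slope"] if n in trends.index else np.nan
        g.add_node(n, slope=float(slope) if np.isfinite(slope) else None, is_hit=n in seed_set)
    for p, t, w in model.edges.itertuples(index=False, name=None):
        if p in nodes and t in nodes:
            g.add_edge(p, t, weight=float(w))
    return g
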