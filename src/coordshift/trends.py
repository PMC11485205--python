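"""Age trends in mean expression and expression variance; hit drivers.

A predictability change can be driven by a change in the gene's average
expression (quantification noise at low expression), by a change in its
inter-individual variance (correlations are ill-defined on a vanishing
range), or by a genuine change of coordination with the regulatory
neighborhood.  This module quantifies the first two: a per-gene OLS slope
of expression on numeric age (log2 units per year) and a per-gene OLS
slope of within-group variance on group age (variance units per year),
then flags hits whose absolute slope clears a cutoff (default 0.001) with
a consistent sign when the oldest age group is excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, group_ages, validate_metadata
from .predictability import ols_slope_test

__all__ = ["expression_slopes", "variance_slopes", "classify_hits", "driver_counts"]


def _drop_oldest(meta: pd.DataFrame) -> pd.DataFrame:
    oldest = group_ages(meta).index[-1]
    return meta[meta["age_group"] != oldest]


def expression_slopes(
    expr: ExpressionMatrix, meta: pd.DataFrame, exclude_oldest: bool = False
) -> pd.DataFrame:
    """Per-gene OLS slope of expression on per-sample numeric age.

    Age is coded as the age-group average (e.g. 25 for 20-29).  Returns a
    frame with slope, stderr, t, p per gene; constant genes get slope 0,
    p = 1.
    """
    if expr.space not in ("normalized_log", "residual"):
        raise ValueError("expression_slopes expects log-space data")
    validate_metadata(meta, expr.samples)
    if exclude_oldest:
        meta = _drop_oldest(meta)
        expr = expr.subset_samples(expr.samples.intersection(meta.index))
    ages = meta.loc[expr.samples, "age_numeric"].to_numpy(float)
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages")
    rows = []
    for gene, vals in expr.values.iterrows():
        slope, se, t, p = ols_slope_test(ages, vals.to_numpy(float))
        rows.append((gene, slope, se, t, p))
    return pd.DataFrame(
        rows, columns=["gene", "slope", "stderr", "t_statistic", "p_value"]
    ).set_index("gene")


def variance_slopes(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    exclude_oldest: bool = False,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Per-gene OLS slope of within-group variance on group age.

    The sample variance (denominator n-1) is computed within each age
    group, then regressed on the group's numeric age.  Groups smaller than
    ``min_group_size`` are dropped; genes need at least 3 usable groups.
    """
    if expr.space not in ("normalized_log", "residual"):
        raise ValueError("variance_slopes expects log-space data")
    validate_metadata(meta, expr.samples)
    if exclude_oldest:
        meta = _drop_oldest(meta)
        expr = expr.subset_samples(expr.samples.intersection(meta.index))
    ages = group_ages(meta.loc[expr.samples])
    group_vars = {}
    for label, age in ages.items():
        samples = expr.samples[(meta.loc[expr.samples, "age_group"] == label).to_numpy()]
        if len(samples) < min_group_size:
            warnings.warn(
                f"age group {label!r} dropped: {len(samples)} < {min_group_size} samples",
                stacklevel=2,
            )
            continue
        group_vars[age] = expr.values.loc[:, samples].var(axis=1, ddof=1)
    if len(group_vars) < 3:
        raise ValueError("need at least 3 usable age groups for variance slopes")
    vmat = pd.DataFrame(group_vars)  # genes x group ages
    xs = vmat.columns.to_numpy(float)
    rows = []
    for gene, vals in vmat.iterrows():
        slope, se, t, p = ols_slope_test(xs, vals.to_numpy(float))
        rows.append((gene, slope, se, t, p))
    return pd.DataFrame(
        rows, columns=["gene", "slope", "stderr", "t_statistic", "p_value"]
    ).set_index("gene")


def classify_hits(
    hits: pd.DataFrame,
    expr_slopes: pd.DataFrame,
    expr_slopes_no_oldest: pd.DataFrame,
    var_slopes: pd.DataFrame,
    var_slopes_no_oldest: pd.DataFrame,
    cutoff: float = 0.001,
) -> pd.DataFrame:
    """Attribute each predictability hit to expression/variance drivers.

    A hit is flagged ``expression_change`` when the absolute expression
    slope reaches ``cutoff`` and keeps its sign when the oldest group is
    excluded; ``variance_change`` is analogous on the variance slope.
    ``hits`` must carry a ``slope`` column (the predictability slope); its
    sign defines ``predictability_direction``.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")

    def _flag(gene, full: pd.DataFrame, reduced: pd.DataFrame):
        if gene not in full.index or gene not in reduced.index:
            return None
        s, s0 = full.at[gene, "slope"], reduced.at[gene, "slope"]
        if not (np.isfinite(s) and np.isfinite(s0)):
            return None
        return bool(abs(s) >= cutoff and np.sign(s) == np.sign(s0))

    rows = []
    n_missing = 0
    for gene, row in hits.iterrows():
        direction = "increase" if row["slope"] > 0 else "decrease"
        e = _flag(gene, expr_slopes, expr_slopes_no_oldest)
        v = _flag(gene, var_slopes, var_slopes_no_oldest)
        if e is None or v is None:
            n_missing += 1
        rows.append(
            {
                "gene": gene,
                "predictability_direction": direction,
                "expression_change": e,
                "variance_change": v,
            }
        )
    if n_missing:
        warnings.warn(f"{n_missing} hit(s) missing a slope; flags set to None", stacklevel=2)
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["cutoff"] = cutoff
    return out


def driver_counts(classification: pd.DataFrame) -> pd.DataFrame:
    """Counts per direction: expression change, variance change, total."""
    rows = []
    for direction, sub in classification.groupby("predictability_direction"):
        rows.append(
            {
                "predictability_direction": direction,
                "expression_change": int(sub["expression_change"].fillna(False).sum()),
                "variance_change": int(sub["variance_change"].fillna(False).sum()),
                "total": int(len(sub)),
            }
        )
    return pd.DataFrame(rows).set_index("predictability_direction")
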