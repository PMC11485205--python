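"""Bulk-count preprocessing.

The sequence mirrors standard bulk RNA-seq practice: filter genes on mean
count (and optionally biotype), normalize with median-of-ratios size
factors, log2-transform with a pseudocount of 1, regress out nuisance
covariates per gene, and balance age groups by downsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, validate_metadata

__all__ = [
    "FilterConfig",
    "filter_genes",
    "normalize_and_log",
    "size_factors",
    "regress_out_covariates",
    "balance_age_groups",
]


@dataclass
class FilterConfig:
    """Gene filters applied to raw counts.

    ``min_mean_count`` removes genes whose mean count across all samples is
    strictly below the threshold (a mean exactly at the threshold is kept);
    ``allowed_biotypes`` optionally restricts to an annotation biotype set.
    """

    min_mean_count: float = 100.0
    allowed_biotypes: frozenset | None = None

    def __post_init__(self) -> None:
        if self.min_mean_count < 0:
            raise ValueError("min_mean_count must be >= 0")
        if self.allowed_biotypes is not None:
            self.allowed_biotypes = frozenset(self.allowed_biotypes)


def filter_genes(
    counts: ExpressionMatrix,
    annotation: pd.DataFrame | None = None,
    config: FilterConfig | None = None,
) -> ExpressionMatrix:
    """Drop low-count genes and, if annotation is given, disallowed biotypes."""
    if counts.space != "counts":
        raise ValueError("filter_genes expects counts-space data")
    config = config or FilterConfig()

    mean_ok = counts.values.mean(axis=1) >= config.min_mean_count
    bio_ok = pd.Series(True, index=counts.genes)
    if annotation is not None and config.allowed_biotypes is not None:
        biotype = annotation["biotype"].reindex(counts.genes)
        bio_ok = biotype.isin(config.allowed_biotypes).fillna(False)

    keep = mean_ok & bio_ok
    if not keep.any():
        raise ValueError(
            "no genes survive filtering "
            f"(mean-count filter keeps {int(mean_ok.sum())}, biotype filter keeps {int(bio_ok.sum())})"
        )
    return ExpressionMatrix(counts.values.loc[keep], "counts")


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, computed on
    genes with strictly positive counts in every sample; each sample's
    factor is the median of its count/reference ratios over those genes.
    """
    if counts.space != "counts":
        raise ValueError("size_factors expects counts-space data")
    vals = counts.values.to_numpy(float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has all-positive counts; cannot compute size factors")
    sub = vals[all_pos]
    geo_mean = np.exp(np.log(sub).mean(axis=1))
    # median taken in linear ratio space (with an even gene count the
    # median averages the two middle ratios, which differs from the
    # exponentiated log-space median)
    sf = np.median(sub / geo_mean[:, None], axis=0)
    return pd.Series(sf, index=counts.samples, name="size_factor")


def normalize_and_log(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Size-factor normalize then log2 with pseudocount 1."""
    if counts.n_samples < 2:
        raise ValueError("need at least two samples to estimate size factors")
    sf = size_factors(counts)
    norm = counts.values.div(sf, axis=1)
    return ExpressionMatrix(np.log2(norm + 1.0), "normalized_log")


def _design_matrix(meta: pd.DataFrame, covariate_names, samples) -> pd.DataFrame:
    cols = {"intercept": pd.Series(1.0, index=samples)}
    for name in covariate_names:
        if name not in meta.columns:
            raise ValueError(f"covariate {name!r} missing from metadata")
        col = meta.loc[samples, name]
        if col.isna().any():
            bad = col.index[col.isna()][0]
            raise ValueError(f"covariate {name!r} missing for sample {bad!r}")
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
        else:
            # one-hot with a dropped reference level keeps the design full rank
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
    return pd.DataFrame(cols, index=samples)


def regress_out_covariates(
    expr: ExpressionMatrix, meta: pd.DataFrame, covariate_names
) -> ExpressionMatrix:
    """Per-gene OLS residuals after regressing on the named covariates.

    The design is intercept + one-hot categoricals (reference level
    dropped) + numeric covariates; any full-rank parameterization gives
    identical residuals.
    """
    if expr.space not in ("normalized_log", "residual"):
        raise ValueError("regress_out_covariates expects log-space data")
    missing = expr.samples.difference(meta.index)
    if len(missing):
        raise ValueError(f"{len(missing)} samples lack metadata, e.g. {missing[0]!r}")
    design = _design_matrix(meta, covariate_names, expr.samples)
    D = design.to_numpy(float)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # identify offending columns by greedy rank growth
        bad = []
        kept: list = []
        for j, name in enumerate(design.columns):
            trial = D[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(name)
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    Y = expr.values.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    return ExpressionMatrix(
        pd.DataFrame(resid.T, index=expr.genes, columns=expr.samples), "residual"
    )


def balance_age_groups(
    meta: pd.DataFrame,
    exclude_from_min=(),
    min_keep_oldest: int = 10,
    n_fixed: int | None = None,
    seed: int = 0,
) -> pd.Index:
    """Downsample so every retained age group has the same sample count.

    The per-group target is ``n_fixed`` when given, otherwise the smallest
    group size among groups *not* in ``exclude_from_min``.  A group listed
    in ``exclude_from_min`` (typically the oldest, sparsest group) is
    retained only if it has at least ``min_keep_oldest`` samples, and is
    kept at ``min(its size, target)``.

    Returns the selected sample ids (original metadata order).
    """
    validate_metadata(meta)
    exclude = set(exclude_from_min)
    sizes = meta.groupby("age_group", observed=True).size()
    if len(sizes) < 2:
        raise ValueError("need at least two age groups")
    core = sizes[~sizes.index.isin(exclude)]
    if core.empty:
        raise ValueError("every age group is excluded from the minimum computation")
    target = int(n_fixed) if n_fixed is not None else int(core.min())
    if n_fixed is not None and (core < target).any():
        small = core[core < target].index.tolist()
        raise ValueError(f"n_fixed={n_fixed} exceeds the size of group(s) {small}")

    rng = np.random.default_rng(seed)
    chosen: list = []
    for group, n in sizes.items():
        ids = meta.index[meta["age_group"] == group].to_numpy()
        if group in exclude:
            if n < min_keep_oldest:
                warnings.warn(
                    f"dropping group {group!r}: {n} < {min_keep_oldest} samples", stacklevel=2
                )
                continue
            take = min(n, target)
        else:
            take = target
        picked = rng.choice(ids, size=take, replace=False)
        chosen.extend(picked.tolist())
    chosen_set = set(chosen)
    return meta.index[[s in chosen_set for s in meta.index]]
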