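"""Per-age-group predictability and its regression on age.

"Predictability" of a gene in a group of samples is the Spearman
correlation between its observed expression and the expression
reconstructed from its regulatory neighbors.  Changes with age are
captured by an ordinary least-squares regression of the per-group
predictability on the group's numeric age (coded as the group average,
e.g. 25 for 20-29), tested with a two-sided t-test on the slope and
calibrated against a permutation null built by shuffling the age vector.
The gene-inclusion threshold comes from a degree-preserving randomization
of the model: the 95th percentile of the null predictability distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import (
    ExpressionMatrix,
    PredictabilityTable,
    ReconstructedMatrix,
    RegulatoryModel,
    group_ages,
    validate_metadata,
)
from .network_ops import randomize_targets
from .reconstruct import prediction_quality, reconstruct_expression

__all__ = [
    "ThresholdCalibration",
    "predictability_by_group",
    "calibrate_predictability_threshold",
    "fit_predictability_slopes",
    "ols_slope_test",
    "permutation_null",
    "select_top_hits",
]


@dataclass
class ThresholdCalibration:
    """How the gene-inclusion threshold is derived from the randomized model."""

    quantile: float = 0.95
    n_randomizations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


def predictability_by_group(
    observed: ExpressionMatrix,
    predicted: ReconstructedMatrix,
    meta: pd.DataFrame,
    min_group_size: int = 3,
) -> PredictabilityTable:
    """Spearman rho per gene, restricted to the samples of each age group."""
    validate_metadata(meta, observed.samples)
    ages = group_ages(meta.loc[observed.samples])
    cols = {}
    sizes = {}
    for label in ages.index:
        samples = observed.samples[
            (meta.loc[observed.samples, "age_group"] == label).to_numpy()
        ]
        if len(samples) < min_group_size:
            warnings.warn(
                f"age group {label!r} dropped: {len(samples)} < {min_group_size} samples",
                stacklevel=2,
            )
            continue
        cols[label] = prediction_quality(observed, predicted, samples)
        sizes[label] = len(samples)
    if not cols:
        raise ValueError("no age group has enough samples")
    rho = pd.DataFrame(cols)
    return PredictabilityTable(
        rho=rho,
        group_ages=ages.loc[list(cols)],
        group_sizes=pd.Series(sizes, dtype=int),
    )


def calibrate_predictability_threshold(
    expr: ExpressionMatrix,
    model: RegulatoryModel,
    cal: ThresholdCalibration | None = None,
) -> float:
    """Inclusion threshold from the target-swapped (randomized) model.

    The randomized model keeps the topology's degree structure but severs
    the biological pairing of predictors and targets, so its per-gene
    predictability (computed on all samples pooled) is a null
    distribution.  The threshold is the configured upper quantile (default
    95th percentile, linear interpolation between order statistics) of
    that distribution; genes whose mean predictability across age groups
    falls below it should be excluded downstream.
    """
    cal = cal or ThresholdCalibration()
    null_rhos: list = []
    for r in range(cal.n_randomizations):
        rand = randomize_targets(model, seed=cal.seed + r)
        recon = reconstruct_expression(rand, expr)
        rho = prediction_quality(expr, recon)
        null_rhos.append(rho.dropna().to_numpy())
    pooled = np.concatenate(null_rhos)
    if pooled.size == 0:
        raise ValueError("randomized model produced no defined predictability values")
    return float(np.quantile(pooled, cal.quantile))


def ols_slope_test(x: np.ndarray, y: np.ndarray):
    """Closed-form simple OLS: slope, stderr, t, two-sided p (df = n - 2).

    A constant response returns slope 0 with p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.all(y == y[0]):
        return 0.0, 0.0, 0.0, 1.0
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    s2 = float(resid @ resid) / (n - 2)
    if s2 == 0.0:
        stderr = 0.0
        t = np.inf if slope > 0 else (-np.inf if slope < 0 else 0.0)
        p = 0.0 if slope != 0 else 1.0
    else:
        stderr = float(np.sqrt(s2 / sxx))
        t = slope / stderr
        p = float(2.0 * scipy.stats.t.sf(abs(t), n - 2))
    return slope, stderr, float(t), p


def _slopes_frame(rho: pd.DataFrame, ages: np.ndarray) -> pd.DataFrame:
    rows = []
    for gene, vals in rho.iterrows():
        v = vals.to_numpy(float)
        ok = np.isfinite(v)
        if ok.sum() < 3:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, int(ok.sum())))
            continue
        slope, se, t, p = ols_slope_test(ages[ok], v[ok])
        rows.append((gene, slope, se, t, p, int(ok.sum())))
    return pd.DataFrame(
        rows, columns=["gene", "slope", "stderr", "t_statistic", "p_value", "n_groups"]
    ).set_index("gene")


def fit_predictability_slopes(
    table: PredictabilityTable, flag_consistency: bool = True
) -> pd.DataFrame:
    """Regress each gene's per-group predictability on age.

    Returns a TrendResult frame with slope, stderr, t, two-sided p and
    ``n_groups``; genes with predictability defined in fewer than three
    groups are reported with missing statistics.  When ``flag_consistency``
    and there are at least four groups, ``slope_without_oldest`` and
    ``consistent_without_oldest`` (same slope sign with and without the
    oldest group) are added — the oldest group is typically the sparsest
    and can skew the fit.
    """
    ages = table.ages
    out = _slopes_frame(table.rho, ages)
    skipped = out.index[out["slope"].isna()]
    if len(skipped):
        warnings.warn(
            f"{len(skipped)} gene(s) skipped with <3 usable groups", stacklevel=2
        )
    if flag_consistency and table.rho.shape[1] >= 4:
        reduced = _slopes_frame(table.rho.iloc[:, :-1], ages[:-1])
        out["slope_without_oldest"] = reduced["slope"]
        out["consistent_without_oldest"] = np.sign(out["slope"]) == np.sign(
            reduced["slope"]
        )
    return out


def permutation_null(
    table: PredictabilityTable,
    n_perm: int = 100,
    seed: int = 0,
    p_grid=(0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5),
):
    """Null ensemble from repeated permutation of the age vector.

    Each permutation shuffles the assignment of numeric ages to the
    (few) age-group columns — predictability is a per-group statistic, so
    the exchangeable unit is the group, not the sample.  Permutations are
    sampled with replacement, so duplicates are allowed.

    Returns ``(null_p: DataFrame genes x permutations, summary: DataFrame)``
    where the summary compares, on a grid of p-value cutoffs, the fraction
    of genes below the cutoff in the real data against the permutation
    average.
    """
    if table.rho.shape[1] < 3:
        raise ValueError("need at least 3 age groups")
    rng = np.random.default_rng(seed)
    ages = table.ages
    real = fit_predictability_slopes(table, flag_consistency=False)["p_value"]

    cols = {}
    for b in range(n_perm):
        perm = rng.permutation(ages)
        cols[b] = _slopes_frame(table.rho, perm)["p_value"]
    null_p = pd.DataFrame(cols)

    rows = []
    for cut in p_grid:
        real_frac = float((real.dropna() < cut).mean())
        null_frac = float((null_p < cut).mean(axis=0).mean())
        rows.append((cut, real_frac, null_frac))
    summary = pd.DataFrame(rows, columns=["p_cutoff", "real_fraction", "null_fraction"])
    return null_p, summary


def select_top_hits(
    trends: pd.DataFrame, n_top: int = 100, require_consistency: bool = False
) -> pd.DataFrame:
    """The n_top genes with the most significant predictability change.

    Ranks by ascending p-value (ties: descending |slope|, then gene id).
    With ``require_consistency``, genes whose slope sign flips when the
    oldest age group is excluded are dropped before ranking.
    """
    if trends.empty:
        raise ValueError("trend table is empty")
    t = trends.dropna(subset=["p_value"]).copy()
    if require_consistency:
        if "consistent_without_oldest" not in t.columns:
            raise ValueError("consistency flags missing; fit slopes with flag_consistency=True")
        t = t[t["consistent_without_oldest"].fillna(False)]
    if n_top > len(t):
        warnings.warn(
            f"n_top={n_top} exceeds {len(t)} available genes; returning all", stacklevel=2
        )
        n_top = len(t)
    t = t.assign(_abs_slope=t["slope"].abs(), _gene=t.index.astype(str))
    t = t.sort_values(
        ["p_value", "_abs_slope", "_gene"], ascending=[True, False, True], kind="stable"
    )
    return t.drop(columns=["_abs_slope", "_gene"]).head(n_top)
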