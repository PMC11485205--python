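"""Reconstruct expression from regulatory neighbors and score agreement.

Reconstruction centers each gene at 0 over the provided sample set (e.g.,
the samples of one tissue) and forms, for every target with at least one
predictor present, the weighted sum of its predictors' centered patterns
using the frozen model weights.  Agreement between observed and
reconstructed patterns ("predictability") is the Spearman rank correlation
across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import ExpressionMatrix, ReconstructedMatrix, RegulatoryModel

__all__ = ["reconstruct_expression", "prediction_quality", "poorly_predicted_genes"]


def reconstruct_expression(model: RegulatoryModel, expr: ExpressionMatrix) -> ReconstructedMatrix:
    """Predicted centered expression of every covered target.

    For target t with predictors p (weights w_pt) present in ``expr``:
    ``yhat_t = sum_p w_pt * (x_p - mean(x_p))``, means taken over the
    samples of ``expr``.  Predictors absent from ``expr`` are dropped from
    the sum; targets with no present predictor are excluded and listed in
    :attr:`ReconstructedMatrix.excluded_targets`.  Per-target predictor
    coverage is reported so callers can filter.
    """
    if expr.space not in ("normalized_log", "residual"):
        raise ValueError("reconstruction expects log-space (normalized_log/residual) data")
    vals = expr.values
    centered = vals.sub(vals.mean(axis=1), axis=0)
    present = set(expr.genes)

    rows: dict = {}
    coverage: dict = {}
    excluded: list = []
    for target, (preds, weights) in model.predictor_map().items():
        mask = np.asarray([p in present for p in preds])
        if not mask.any():
            excluded.append(target)
            continue
        sub = centered.loc[preds[mask]].to_numpy(float)
        rows[target] = weights[mask] @ sub
        coverage[target] = float(mask.mean())

    values = pd.DataFrame.from_dict(rows, orient="index", columns=expr.samples)
    return ReconstructedMatrix(
        values=values,
        coverage=pd.Series(coverage, name="coverage", dtype=float),
        excluded_targets=excluded,
    )


def prediction_quality(
    observed: ExpressionMatrix,
    predicted: ReconstructedMatrix,
    sample_subset=None,
) -> pd.Series:
    """Per-gene Spearman rho between observed and reconstructed expression.

    Ties receive average ranks.  Genes with zero variance in either vector
    get a missing value (NaN).  ``sample_subset`` restricts the comparison
    (at least 3 samples required).
    """
    samples = list(sample_subset) if sample_subset is not None else list(observed.samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a rank correlation")
    genes = predicted.covered_genes.intersection(observed.genes)
    obs = observed.values.loc[genes, samples].to_numpy(float)
    pred = predicted.values.loc[genes, samples].to_numpy(float)

    rho = np.full(len(genes), np.nan)
    var_ok = (obs.std(axis=1) > 0) & (pred.std(axis=1) > 0)
    if var_ok.any():
        ro = scipy.stats.rankdata(obs[var_ok], axis=1)
        rp = scipy.stats.rankdata(pred[var_ok], axis=1)
        ro = ro - ro.mean(axis=1, keepdims=True)
        rp = rp - rp.mean(axis=1, keepdims=True)
        num = (ro * rp).sum(axis=1)
        den = np.sqrt((ro**2).sum(axis=1) * (rp**2).sum(axis=1))
        rho[var_ok] = num / den
    return pd.Series(rho, index=genes, name="rho")


def poorly_predicted_genes(mean_rho: pd.Series, threshold: float = 0.2) -> pd.Index:
    """Genes whose average predictability falls below ``threshold`` (default 0.2)."""
    return mean_rho.index[mean_rho < threshold]
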