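"""Sparse regulatory-model training: L1 regression + stability selection.

Each gene in turn is treated as a *target* and regressed on candidate
predictor genes.  Stability selection repeatedly fits an L1-regularized
(LASSO) regression on random half-size sample subsets and keeps candidates
whose coefficient is nonzero in a sufficient fraction of subsets; final
linear weights for the stable predictors are then refit by ordinary least
squares on centered data, so the weights live in expression units and
reconstruction needs no intercept.

The per-subsample regularization level is chosen from a penalty grid:
among grid points whose fit keeps at most ``max_predictors_per_fit``
nonzero coefficients, the BIC-best one is used.  The cap bounds model
complexity per target instead of committing to a single penalty across
genes; the information criterion keeps the choice honest when the cap
does not bind (few candidates), where the smallest feasible penalty
would otherwise select every candidate.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .datatypes import ExpressionMatrix, RegulatoryModel
from .reconstruct import reconstruct_expression

__all__ = [
    "StabilityConfig",
    "select_stable_predictors",
    "fit_target_weights",
    "train_network",
    "GeneRegulatoryNetwork",
]


@dataclass
class StabilityConfig:
    """Hyperparameters of stability selection.

    ``n_subsamples`` random subsets of ``subsample_fraction`` of the
    samples are drawn; a candidate is selected when its coefficient is
    nonzero in at least ``selection_threshold`` of the subsets.
    ``lambda_grid`` (descending or not, it is sorted internally) fixes the
    penalty grid; when None a 30-point geometric grid down to 1% of the
    per-subsample maximal penalty is used.  ``max_predictors`` caps the
    final predictor count per target; ``candidate_prefilter`` restricts
    candidates to the top-k by absolute Pearson correlation with the
    target (automatically 500 above 1,000 genes, off below).
    """

    n_subsamples: int = 100
    subsample_fraction: float = 0.5
    selection_threshold: float = 0.6
    lambda_grid: tuple | None = None
    max_predictors: int | None = None
    max_predictors_per_fit: int = 20
    candidate_prefilter: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction < 1.0:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if not 0.0 < self.selection_threshold <= 1.0:
            raise ValueError("selection_threshold must be in (0, 1]")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if self.lambda_grid is not None:
            grid = tuple(float(v) for v in self.lambda_grid)
            if any(v <= 0 for v in grid):
                raise ValueError("lambda_grid values must be positive")
            self.lambda_grid = grid


def _target_rng(seed: int, target: str) -> np.random.Generator:
    # per-target stream independent of gene order
    return np.random.default_rng([seed, zlib.crc32(str(target).encode())])


def _choose_alpha_index(
    alphas: np.ndarray,
    nnz: np.ndarray,
    cap: int,
    X: np.ndarray,
    y: np.ndarray,
    coefs: np.ndarray,
) -> int:
    """Pick the penalty: BIC-best among grid points with <= cap nonzeros.

    ``alphas`` are descending.  The cap bounds model complexity; within the
    feasible grid points the Bayesian information criterion
    ``m log(RSS/m) + nnz log(m)`` selects the penalty, so that with few
    candidates (where the cap never binds) the fit does not slide to the
    near-OLS end of the grid and select everything.  Ties prefer the
    sparser, then the more heavily penalized, model.
    """
    feasible = np.flatnonzero(nnz <= cap)
    if feasible.size == 0:
        return 0
    m = X.shape[0]
    best, best_key = None, None
    for j in feasible:
        resid = y - X @ coefs[:, j]
        rss = float(resid @ resid)
        bic = m * np.log(rss / m + 1e-12) + nnz[j] * np.log(m)
        key = (bic, nnz[j], -alphas[j])
        if best_key is None or key < best_key:
            best, best_key = int(j), key
    return best


def _stability_frequencies(
    X: np.ndarray, y: np.ndarray, config: StabilityConfig, rng: np.random.Generator
) -> np.ndarray:
    """Selection frequency per column of standardized design X (n x p)."""
    n = X.shape[0]
    m = int(np.floor(config.subsample_fraction * n))
    counts = np.zeros(X.shape[1])
    grid = None
    if config.lambda_grid is not None:
        grid = np.sort(np.asarray(config.lambda_grid, float))[::-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(config.n_subsamples):
            idx = rng.choice(n, size=m, replace=False)
            Xs, ys = X[idx], y[idx]
            if grid is not None:
                alphas = grid
            else:
                # geometric grid from the per-subsample maximal penalty
                # (smallest penalty zeroing every coefficient) down to 1% of it
                alpha_max = np.max(np.abs(Xs.T @ ys)) / m
                if alpha_max == 0:
                    continue
                alphas = np.geomspace(alpha_max, 0.01 * alpha_max, 30)
            alphas, coefs, _ = lasso_path(Xs, ys, alphas=alphas)
            nnz = (coefs != 0).sum(axis=0)
            j = _choose_alpha_index(
                alphas, nnz, config.max_predictors_per_fit, Xs, ys, coefs
            )
            counts += coefs[:, j] != 0
    return counts / config.n_subsamples


def select_stable_predictors(
    target: str,
    candidates,
    expr: ExpressionMatrix,
    config: StabilityConfig | None = None,
) -> dict:
    """Selection frequency of each candidate predictor for one target.

    Expression is z-scored per gene over the full matrix before
    subsampling.  A constant target yields an empty result with a warning.
    """
    config = config or StabilityConfig()
    candidates = [c for c in candidates]
    if target in candidates:
        raise ValueError("target must not be among candidates")
    if expr.n_samples < 10:
        raise ValueError(f"need >= 10 samples for stability selection, got {expr.n_samples}")
    if expr.space == "counts":
        raise ValueError("stability selection expects log-space data")

    y = expr.values.loc[target].to_numpy(float)
    sd = y.std()
    if sd == 0:
        warnings.warn(f"target {target!r} is constant; no predictors selected", stacklevel=2)
        return {}
    y = (y - y.mean()) / sd
    X = expr.values.loc[candidates].to_numpy(float).T
    mu, sig = X.mean(axis=0), X.std(axis=0)
    sig[sig == 0] = 1.0
    X = (X - mu) / sig

    freqs = _stability_frequencies(X, y, config, _target_rng(config.seed, target))
    return dict(zip(candidates, freqs))


def fit_target_weights(target: str, selected, expr: ExpressionMatrix) -> pd.Series:
    """OLS weights of the centered target on centered selected predictors.

    Collinear predictors trigger a ridge fallback with penalty 1e-8 and a
    warning.  Weights are in expression units (no scaling applied).
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected predictor set is empty")
    if len(selected) >= expr.n_samples:
        raise ValueError("need fewer predictors than samples for the final fit")
    y = expr.values.loc[target].to_numpy(float)
    X = expr.values.loc[selected].to_numpy(float).T
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        warnings.warn(
            f"collinear predictors for target {target!r}; ridge fallback (penalty 1e-8)",
            stacklevel=2,
        )
        pen = 1e-8
        w = np.linalg.solve(Xc.T @ Xc + pen * np.eye(Xc.shape[1]), Xc.T @ yc)
    else:
        w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    return pd.Series(w, index=selected, name=target)


def train_network(
    expr: ExpressionMatrix,
    config: StabilityConfig | None = None,
    annotation: pd.DataFrame | None = None,
) -> RegulatoryModel:
    """Train the full sparse model, every gene in turn as target.

    ``annotation`` is carried into the provenance only; positional filters
    such as same-chromosome-arm removal are applied afterwards by
    ``network_ops`` so one trained model can be reprocessed under
    different annotations.  Per-target failures (e.g., constant genes) are
    collected into the provenance, not raised.
    """
    config = config or StabilityConfig()
    if expr.n_genes < 2:
        raise ValueError("need at least two genes to train a network")
    genes = list(expr.genes)
    n_genes = len(genes)
    prefilter = config.candidate_prefilter
    if prefilter is None and n_genes > 1000:
        prefilter = 500

    # z-score once; reuse for marginal correlations and selection
    V = expr.values.to_numpy(float)
    mu = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[sd == 0] = 1.0
    Z = (V - mu) / sd  # genes x samples
    n = Z.shape[1]

    rows: list = []
    failures: dict = {}
    for gi, target in enumerate(genes):
        if constant[gi]:
            failures[target] = "constant target"
            continue
        corr = Z @ Z[gi] / n
        order = np.argsort(-np.abs(corr), kind="stable")
        cand_idx = [j for j in order if j != gi]
        if prefilter is not None:
            cand_idx = cand_idx[:prefilter]
        X = Z[cand_idx].T
        y = Z[gi]
        freqs = _stability_frequencies(
            X, y, config, _target_rng(config.seed, target)
        )
        sel = np.flatnonzero(freqs >= config.selection_threshold)
        if sel.size == 0:
            continue
        # rank by frequency, then |marginal correlation|, for the cap
        abs_corr = np.abs(corr[np.asarray(cand_idx)[sel]])
        rank_order = sorted(
            range(sel.size), key=lambda k: (-freqs[sel[k]], -abs_corr[k], genes[cand_idx[sel[k]]])
        )
        if config.max_predictors is not None:
            rank_order = rank_order[: config.max_predictors]
        chosen = [genes[cand_idx[sel[k]]] for k in rank_order]
        try:
            w = fit_target_weights(target, chosen, expr)
        except ValueError as err:
            failures[target] = str(err)
            continue
        for p, wv in w.items():
            if wv != 0:
                rows.append((p, target, float(wv)))

    edges = pd.DataFrame(rows, columns=["predictor", "target", "weight"])
    provenance = {
        "config": {
            "n_subsamples": config.n_subsamples,
            "subsample_fraction": config.subsample_fraction,
            "selection_threshold": config.selection_threshold,
            "lambda_grid": config.lambda_grid,
            "max_predictors": config.max_predictors,
            "max_predictors_per_fit": config.max_predictors_per_fit,
            "candidate_prefilter": prefilter,
            "seed": config.seed,
        },
        "n_genes": n_genes,
        "failures": failures,
    }
    return RegulatoryModel(edges, provenance)


class GeneRegulatoryNetwork(BaseEstimator):
    """Sparse gene-gene regulatory model as a scikit-learn estimator.

    ``fit`` expects a samples x genes matrix (DataFrame preferred, so gene
    names survive) in log space, trains the stability-selected linear
    model per gene, and exposes it as :attr:`model_` / :attr:`edges_`.
    ``predict`` reconstructs each covered gene's centered expression in a
    new samples x genes matrix from its regulatory neighbors, using the
    frozen training weights — the model is never refit on the data it
    scores.

    Parameters mirror :class:`StabilityConfig`.
    """

    def __init__(
        self,
        n_subsamples: int = 100,
        subsample_fraction: float = 0.5,
        selection_threshold: float = 0.6,
        lambda_grid=None,
        max_predictors=None,
        max_predictors_per_fit: int = 20,
        candidate_prefilter=None,
        seed: int = 0,
    ):
        self.n_subsamples = n_subsamples
        self.subsample_fraction = subsample_fraction
        self.selection_threshold = selection_threshold
        self.lambda_grid = lambda_grid
        self.max_predictors = max_predictors
        self.max_predictors_per_fit = max_predictors_per_fit
        self.candidate_prefilter = candidate_prefilter
        self.seed = seed

    def _config(self) -> StabilityConfig:
        return StabilityConfig(
            n_subsamples=self.n_subsamples,
            subsample_fraction=self.subsample_fraction,
            selection_threshold=self.selection_threshold,
            lambda_grid=self.lambda_grid,
            max_predictors=self.max_predictors,
            max_predictors_per_fit=self.max_predictors_per_fit,
            candidate_prefilter=self.candidate_prefilter,
            seed=self.seed,
        )

    @staticmethod
    def _as_expression(X) -> ExpressionMatrix:
        if isinstance(X, pd.DataFrame):
            df = X.T.astype(float)
        else:
            X = np.asarray(X, float)
            names = [f"g{j:04d}" for j in range(X.shape[1])]
            df = pd.DataFrame(X.T, index=names)
            df.columns = [f"s{j:04d}" for j in range(X.shape[0])]
        return ExpressionMatrix(df, "residual")

    def fit(self, X, y=None):
        expr = self._as_expression(X)
        self.n_features_in_ = expr.n_genes
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.model_ = train_network(expr, self._config())
        self.edges_ = self.model_.edges
        return self

    def predict(self, X) -> pd.DataFrame:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        expr = self._as_expression(X)
        recon = reconstruct_expression(self.model_, expr)
        return recon.values.T
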