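"""Core in-memory containers shared across the pipeline.

Expression data are held genes x samples (genes are rows, matching the
on-disk TSV layout); sample metadata are a plain :class:`pandas.DataFrame`
indexed by sample id.  The regulatory model is a sparse directed weighted
graph stored as an edge table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RegulatoryModel",
    "ReconstructedMatrix",
    "PredictabilityTable",
    "EXPRESSION_SPACES",
]

#: valid values of :attr:`ExpressionMatrix.space`
EXPRESSION_SPACES = ("counts", "normalized_log", "residual")

#: columns required in a sample-metadata frame
METADATA_COLUMNS = ("age_group", "age_numeric")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a declared value space.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.
    space
        One of ``counts`` (non-negative raw counts), ``normalized_log``
        (size-factor normalized, log2(x+1)) or ``residual`` (covariate
        regression residuals of normalized_log data).
    """

    values: pd.DataFrame
    space: str = "counts"

    def __post_init__(self) -> None:
        if self.space not in EXPRESSION_SPACES:
            raise ValueError(
                f"space must be one of {EXPRESSION_SPACES}, got {self.space!r}"
            )
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        arr = self.values.to_numpy()
        if self.space == "counts":
            if np.nanmin(arr, initial=0) < 0:
                raise ValueError("counts space requires non-negative values")
        else:
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{self.space} space requires finite values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.space)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.space)


def validate_metadata(meta: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Check a sample-metadata frame and return it.

    Requires ``age_group`` and ``age_numeric`` columns, an index of sample
    ids, and a single numeric age per age group.  When ``samples`` is given,
    every sample must have a metadata row.
    """
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in metadata")
    per_group = meta.groupby("age_group", observed=True)["age_numeric"].nunique()
    if (per_group > 1).any():
        bad = per_group[per_group > 1].index.tolist()
        raise ValueError(f"age_numeric not constant within age group(s) {bad}")
    if samples is not None:
        missing = pd.Index(samples).difference(meta.index)
        if len(missing):
            raise ValueError(f"{len(missing)} samples lack metadata, e.g. {missing[0]!r}")
    return meta


def group_ages(meta: pd.DataFrame) -> pd.Series:
    """Numeric age per age group, sorted by age (ascending)."""
    ages = meta.groupby("age_group", observed=True)["age_numeric"].first()
    return ages.sort_values()


@dataclass
class RegulatoryModel:
    """Sparse directed weighted gene-gene model.

    Each row of :attr:`edges` is one (predictor, target, weight) triple:
    the predictor's centered expression, scaled by the weight, contributes
    to the reconstruction of the target.  Weights are linear-model
    coefficients fit on centered training data, so no intercepts are stored.
    """

    edges: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    REQUIRED = ("predictor", "target", "weight")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.edges.columns:
                raise ValueError(f"edge table missing column {col!r}")
        self.edges = self.edges.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        if (self.edges["predictor"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")
        if self.edges.duplicated(["predictor", "target"]).any():
            raise ValueError("duplicate (predictor, target) pairs")
        w = self.edges["weight"].to_numpy(float)
        if not np.all(np.isfinite(w)) or np.any(w == 0):
            raise ValueError("weights must be finite and nonzero")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> pd.Index:
        return pd.Index(
            pd.unique(
                pd.concat([self.edges["predictor"], self.edges["target"]], ignore_index=True)
            )
        )

    @property
    def targets(self) -> pd.Index:
        return pd.Index(pd.unique(self.edges["target"]))

    def predictors_of(self, target) -> pd.DataFrame:
        """Edge rows whose target is ``target`` (may be empty)."""
        return self.edges[self.edges["target"] == target]

    def predictor_map(self) -> dict:
        """target -> (predictor array, weight array), built in one pass."""
        out = {}
        for target, sub in self.edges.groupby("target", sort=False):
            out[target] = (
                sub["predictor"].to_numpy(),
                sub["weight"].to_numpy(float),
            )
        return out

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_weighted_edges_from(
            self.edges[["predictor", "target", "weight"]].itertuples(index=False, name=None)
        )
        return g

    def copy(self) -> "RegulatoryModel":
        return RegulatoryModel(self.edges.copy(), dict(self.provenance))


@dataclass
class ReconstructedMatrix:
    """Reconstructed (predicted) expression on the centered scale.

    Rows exist only for targets with at least one predictor present in the
    observed matrix; :attr:`coverage` gives, per covered target, the
    fraction of its model predictors that were available.
    """

    values: pd.DataFrame
    coverage: pd.Series
    excluded_targets: list = field(default_factory=list)

    @property
    def covered_genes(self) -> pd.Index:
        return self.values.index


@dataclass
class PredictabilityTable:
    """Per-gene, per-age-group predictability (Spearman rho).

    ``rho`` is genes x groups with columns ordered by increasing numeric
    age; ``group_ages`` maps group label -> numeric age; ``group_sizes``
    maps group label -> number of samples used.
    """

    rho: pd.DataFrame
    group_ages: pd.Series
    group_sizes: pd.Series

    def __post_init__(self) -> None:
        ages = self.group_ages.loc[self.rho.columns].to_numpy(float)
        if not np.all(np.diff(ages) > 0):
            raise ValueError("group ages must be strictly increasing across columns")
        vals = self.rho.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.max() > 1 + 1e-12 or finite.min() < -1 - 1e-12):
            raise ValueError("rho values outside [-1, 1]")

    @property
    def ages(self) -> np.ndarray:
        return self.group_ages.loc[self.rho.columns].to_numpy(float)
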