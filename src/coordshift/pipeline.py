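"""End-to-end orchestration behind one YAML-configurable RunConfig.

Stage order: simulate (or load inputs) -> preprocess -> train or load
model -> network processing (reciprocal-edge pruning, optional same-arm
removal, largest component) -> reconstruction -> predictability threshold
calibration and filtering -> predictability slopes + permutation null ->
hit selection -> driver classification -> within/between contributions
and hit subnetwork.  Every output file is hashed into a run manifest, and
one global seed deterministically derives per-stage seeds so a rerun with
the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as csio
from .coordination import (
    extract_hit_subnetwork,
    neighbor_correlation_slopes,
    within_between_contributions,
)
from .datatypes import ExpressionMatrix
from .network import StabilityConfig, train_network
from .network_ops import (
    PruneConfig,
    largest_connected_component,
    prune_residual_edges,
    remove_same_arm_predictors,
)
from .predictability import (
    ThresholdCalibration,
    calibrate_predictability_threshold,
    fit_predictability_slopes,
    permutation_null,
    predictability_by_group,
    select_top_hits,
)
from .preprocess import FilterConfig, filter_genes, normalize_and_log, regress_out_covariates
from .reconstruct import prediction_quality, reconstruct_expression
from .simulate import SimulationConfig, module_gene_sets, simulate_study
from .trends import classify_hits, driver_counts, expression_slopes, variance_slopes

__all__ = ["RunConfig", "validate_config", "run_pipeline", "stage_seed"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    enabled: bool = True
    n_genes: int = Field(500, ge=2)
    n_modules: int = Field(8, ge=1)
    within_module_edge_prob: float = Field(0.06, ge=0.0, le=1.0)
    between_module_edge_prob: float = Field(0.002, ge=0.0, le=1.0)
    n_samples_per_group: int = Field(40, ge=3)
    noise_sd: float = Field(0.5, ge=0.0)
    n_loss_genes: int = Field(0, ge=0)
    loss_final_multiplier: float = Field(0.2, ge=0.0)


class InputSection(_Section):
    counts: str | None = None
    expression: str | None = None
    metadata: str | None = None
    model: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None


class PreprocessSection(_Section):
    enabled: bool = False
    min_mean_count: float = Field(100.0, ge=0.0)
    covariates: list[str] = Field(default_factory=list)


class TrainSection(_Section):
    enabled: bool = False
    n_subsamples: int = Field(100, ge=1)
    subsample_fraction: float = Field(0.5, gt=0.0, lt=1.0)
    selection_threshold: float = Field(0.6, gt=0.0, le=1.0)
    max_predictors: int | None = Field(None, ge=1)
    max_predictors_per_fit: int = Field(20, ge=1)


class NetworkSection(_Section):
    ratio_threshold: float = Field(0.1, ge=0.0, le=0.5)
    remove_same_arm: bool = False
    largest_component: bool = True
    alpha: float = Field(0.2, ge=0.0, lt=1.0)


class PredictabilitySection(_Section):
    quantile: float = Field(0.95, gt=0.0, lt=1.0)
    n_perm: int = Field(100, ge=1)
    n_top: int = Field(100, ge=1)
    poor_prediction_threshold: float = 0.2
    require_consistency: bool = True
    apply_threshold: bool = True


class DriverSection(_Section):
    cutoff: float = Field(0.001, ge=0.0)


class CoordinationSection(_Section):
    n_strongest: int = Field(20, ge=1)


class RunConfig(_Section):
    """Validated pipeline configuration; defaults mirror the method's constants."""

    seed: int = 0
    out_dir: str = "coordshift_run"
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    inputs: InputSection = Field(default_factory=InputSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    train: TrainSection = Field(default_factory=TrainSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    predictability: PredictabilitySection = Field(default_factory=PredictabilitySection)
    drivers: DriverSection = Field(default_factory=DriverSection)
    coordination: CoordinationSection = Field(default_factory=CoordinationSection)


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        written.append(path)
        return path

    # ---- stage: data -------------------------------------------------
    gene_sets = None
    annotation = None
    truth = None
    if config.inputs.gene_sets:
        gene_sets = csio.read_gmt(config.inputs.gene_sets)
    if config.inputs.annotation:
        annotation = csio.read_annotation_tsv(config.inputs.annotation)

    if config.simulate.enabled:
        s = config.simulate
        sim_seed = stage_seed(config.seed, "simulate")
        schedules = {}
        # plant coordination-loss genes on the highest-in-degree targets so
        # every planted gene actually has regulatory input to lose
        base = SimulationConfig(
            n_genes=s.n_genes,
            n_modules=s.n_modules,
            within_module_edge_prob=s.within_module_edge_prob,
            between_module_edge_prob=s.between_module_edge_prob,
            n_samples_per_group=s.n_samples_per_group,
            noise_sd=s.noise_sd,
            seed=sim_seed,
        )
        if s.n_loss_genes:
            from .simulate import simulate_network  # local to reuse the same seed

            model0, _ = simulate_network(base)
            targets = model0.edges["target"].value_counts().index[: s.n_loss_genes]
            n_groups = len(base.age_groups)
            mult = np.linspace(1.0, s.loss_final_multiplier, n_groups)
            schedules = {t: tuple(mult) for t in targets}
        sim = SimulationConfig(
            n_genes=s.n_genes,
            n_modules=s.n_modules,
            within_module_edge_prob=s.within_module_edge_prob,
            between_module_edge_prob=s.between_module_edge_prob,
            n_samples_per_group=s.n_samples_per_group,
            noise_sd=s.noise_sd,
            coupling_schedule=schedules,
            seed=sim_seed,
        )
        model, modules, expr, meta, truth = simulate_study(sim)
        if gene_sets is None:
            gene_sets = module_gene_sets(modules)
        csio.write_expression_tsv(expr, out / "expression.tsv")
        csio.write_metadata_tsv(meta, out / "metadata.tsv")
        csio.write_model_tsv(model, out / "true_network.tsv")
        written += [out / "expression.tsv", out / "metadata.tsv", out / "true_network.tsv"]
        save(
            pd.DataFrame(
                {"gene": list(truth.labels), "label": list(truth.labels.values())}
            ).set_index("gene"),
            "ground_truth.tsv",
        )
    else:
        if not config.inputs.metadata:
            raise ValueError("stage 'data' failed: metadata input required when simulation is disabled")
        meta = csio.read_metadata_tsv(config.inputs.metadata)
        if config.inputs.counts:
            expr = csio.read_expression_tsv(config.inputs.counts, "counts")
        elif config.inputs.expression:
            expr = csio.read_expression_tsv(config.inputs.expression, "residual")
        else:
            raise ValueError("stage 'data' failed: counts or expression input required")
        model = csio.read_model_tsv(config.inputs.model) if config.inputs.model else None

    # ---- stage: preprocess -------------------------------------------
    if config.preprocess.enabled and expr.space == "counts":
        expr = filter_genes(expr, annotation, FilterConfig(config.preprocess.min_mean_count))
        expr = normalize_and_log(expr)
        if config.preprocess.covariates:
            expr = regress_out_covariates(expr, meta, config.preprocess.covariates)

    # ---- stage: model ------------------------------------------------
    if config.train.enabled:
        t = config.train
        model = train_network(
            expr,
            StabilityConfig(
                n_subsamples=t.n_subsamples,
                subsample_fraction=t.subsample_fraction,
                selection_threshold=t.selection_threshold,
                max_predictors=t.max_predictors,
                max_predictors_per_fit=t.max_predictors_per_fit,
                seed=stage_seed(config.seed, "train"),
            ),
        )
    if model is None:
        raise ValueError("stage 'model' failed: no trained, loaded or simulated model available")

    model = prune_residual_edges(model, PruneConfig(config.network.ratio_threshold))
    if config.network.remove_same_arm:
        if annotation is None:
            raise ValueError("stage 'network' failed: same-arm removal needs an annotation")
        model = remove_same_arm_predictors(model, annotation)
    if config.network.largest_component:
        model = largest_connected_component(model)
    csio.write_model_tsv(model, out / "model.tsv")
    written.append(out / "model.tsv")

    # ---- stage: reconstruction + threshold ---------------------------
    recon = reconstruct_expression(model, expr)
    save(recon.values, "reconstructed.tsv", index_label="gene_id")
    table = predictability_by_group(expr, recon, meta)
    save(table.rho, "predictability.tsv", index_label="gene_id")

    threshold = calibrate_predictability_threshold(
        expr,
        model,
        ThresholdCalibration(
            quantile=config.predictability.quantile,
            seed=stage_seed(config.seed, "calibrate"),
        ),
    )
    mean_rho = table.rho.mean(axis=1)
    kept = table.rho.index[mean_rho >= threshold] if config.predictability.apply_threshold else table.rho.index
    from .datatypes import PredictabilityTable

    table_kept = PredictabilityTable(
        table.rho.loc[kept], table.group_ages, table.group_sizes
    )

    # ---- stage: predictability trends --------------------------------
    trends = fit_predictability_slopes(table_kept)
    save(trends, "trends.tsv")
    _, null_summary = permutation_null(
        table_kept,
        n_perm=config.predictability.n_perm,
        seed=stage_seed(config.seed, "null"),
    )
    save(null_summary, "null_summary.tsv", index=False)
    hits = select_top_hits(
        trends,
        n_top=config.predictability.n_top,
        require_consistency=config.predictability.require_consistency,
    )
    save(hits, "hits.tsv")
    csio.write_rnk(trends["slope"].dropna(), out / "predictability_slopes.rnk")
    written.append(out / "predictability_slopes.rnk")

    # ---- stage: drivers ----------------------------------------------
    es = expression_slopes(expr, meta)
    es0 = expression_slopes(expr, meta, exclude_oldest=True)
    vs = variance_slopes(expr, meta)
    vs0 = variance_slopes(expr, meta, exclude_oldest=True)
    classification = classify_hits(hits, es, es0, vs, vs0, cutoff=config.drivers.cutoff)
    save(classification, "drivers.tsv")
    save(driver_counts(classification), "driver_counts.tsv")

    # ---- stage: coordination -----------------------------------------
    hit_targets = [h for h in hits.index if h in set(model.targets)]
    if hit_targets and gene_sets is not None:
        pairs = neighbor_correlation_slopes(expr, model, hit_targets, meta)
        directions = pd.Series(
            ["increase" if s > 0 else "decrease" for s in hits.loc[hit_targets, "slope"]],
            index=hit_targets,
        )
        contributions = within_between_contributions(pairs, directions, gene_sets)
        save(contributions, "contributions.tsv", index=False)
    sub = extract_hit_subnetwork(model, hits, config.coordination.n_strongest)
    sub_edges = pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in sub.edges(data=True)],
        columns=["predictor", "target", "weight"],
    )
    save(sub_edges, "subnetwork_edges.tsv", index=False)
    sub_nodes = pd.DataFrame(
        [(n, d.get("slope"), d.get("is_hit")) for n, d in sub.nodes(data=True)],
        columns=["gene", "slope", "is_hit"],
    )
    save(sub_nodes, "subnetwork_nodes.tsv", index=False)

    # ---- manifest ----------------------------------------------------
    manifest = {
        "config": config.model_dump(),
        "seed": config.seed,
        "predictability_threshold": threshold,
        "n_genes_kept": int(len(kept)),
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
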