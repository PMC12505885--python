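"""End-to-end orchestration: data -> networks -> metrics -> MNC -> inference.

One co-occurrence network is built per community x depth layer over all
samples of that layer (treatments pooled); per-sample subnetworks then
carry the treatment contrasts. Cohesion is computed from the community
abundance table (threshold-free), the MNC within each depth layer, and the
inference layer fits treatment effect sizes, response shapes, soil-driver
variance partitions and metric->MNC links.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import AbundanceTable
from .cohesion import connectedness, null_corrected_correlations, sample_cohesion
from .ecofunction import mnc_index
from .inference import (
    fit_shape,
    hierarchical_partition,
    link_model,
    lmm_effect_sizes,
)
from .netbuild import (
    NoRMTTransitionError,
    build_network,
    select_rmt_threshold,
    spearman_matrix,
)
from .netmetrics import sample_metrics_table
from .synthetic_data import (
    DesignSpec,
    SyntheticDataset,
    generate_experiment,
)

logger = logging.getLogger(__name__)

COMPLEXITY_METRICS = ("n_nodes", "n_edges", "average_degree", "connectance",
                      "clustering")
STABILITY_METRICS = ("npc", "vulnerability")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")
        self.stage = stage
        self.context = context


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run (YAML-serializable)."""

    seed: int = 0
    communities: tuple[str, ...] = ("nematode", "protist", "whole")
    depth_layers: tuple[str, ...] = ("0-10cm", "10-20cm")
    n_nematode_taxa: int = 40
    n_protist_taxa: int = 40
    input_dir: str | None = None  # None -> synthetic generation
    # netbuild
    grid_start: float = 0.30
    grid_stop: float = 0.99
    grid_step: float = 0.01
    alpha_fdr: float = 0.05
    prevalence_min: float = 0.25
    fallback_threshold: float | None = 0.6
    # cohesion
    cohesion_n_iter: int = 200
    # mnc
    mnc_variables: tuple[str, ...] | None = None
    # inference scope: "effects" fits treatment effect sizes only; "full"
    # adds shape fits, soil-driver partitions and metric->MNC links
    inference: str = "full"
    partition_predictors: tuple[str, ...] = ("SM", "ST", "SOC", "MBC", "MBN", "MBP")
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for c in self.communities:
            if c not in ("nematode", "protist", "whole"):
                raise ValueError(f"unknown community {c!r}")
        if self.inference not in ("effects", "full"):
            raise ValueError("inference must be 'effects' or 'full'")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("communities", "depth_layers", "mnc_variables",
                    "partition_predictors"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ValidationIssue:
    level: str  # "fatal" | "warning"
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return any(i.level == "fatal" for i in self.issues)

    def add(self, level: str, message: str) -> None:
        self.issues.append(ValidationIssue(level, message))


@dataclass
class RunReport:
    config: PipelineConfig
    config_hash: str
    seed: int
    version: str
    networks: pd.DataFrame
    sample_metrics: pd.DataFrame
    stability: pd.DataFrame
    mnc: pd.DataFrame
    effect_sizes: pd.DataFrame
    shapes: pd.DataFrame | None = None
    partitions: pd.DataFrame | None = None
    links: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.networks.to_csv(outdir / "networks.tsv", sep="\t", index=False)
        self.sample_metrics.to_csv(outdir / "sample_metrics.tsv", sep="\t")
        self.stability.to_csv(outdir / "stability.tsv", sep="\t")
        self.mnc.to_csv(outdir / "mnc.tsv", sep="\t")
        self.effect_sizes.to_csv(outdir / "effect_sizes.tsv", sep="\t", index=False)
        for name in ("shapes", "partitions", "links"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        summary = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "n_networks": int(len(self.networks)),
            "n_samples": int(self.sample_metrics.index.nunique()),
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=2))


def validate_inputs(
    tables: dict[str, AbundanceTable],
    metadata: pd.DataFrame,
    soil: pd.DataFrame,
    closure_tol: float = 1e-6,
) -> ValidationReport:
    """Cross-table alignment, compositional closure and design-balance checks."""
    report = ValidationReport()
    meta_ids = set(metadata.index)
    for name, table in tables.items():
        missing = set(table.samples) - meta_ids
        if missing:
            report.add("fatal", f"{name}: samples missing from metadata: "
                                f"{sorted(missing)[:5]}")
        sums = table.column_sums()
        bad = sums[(sums - 1.0).abs() > closure_tol]
        for sid, s in bad.items():
            report.add("warning", f"{name}: sample {sid} sums to {s:.4g}; "
                                  "renormalization recommended")
        if (table.data.to_numpy() < 0).any():
            report.add("fatal", f"{name}: negative abundances present")
    missing_soil = meta_ids - set(soil.index)
    if missing_soil:
        report.add("fatal", f"soil table lacks samples: {sorted(missing_soil)[:5]}")
    if soil.isna().any().any():
        n = int(soil.isna().sum().sum())
        report.add("warning", f"soil table has {n} missing values")
    for depth in metadata["depth"].unique():
        sub = metadata[metadata["depth"] == depth]
        cell = sub.groupby(["block", "treatment"]).size().unstack(fill_value=0)
        if not (cell.to_numpy() == 1).all():
            report.add("fatal", f"layer {depth}: block x treatment design "
                                "is not balanced (each cell must appear once)")
    return report


def _load_dataset(config: PipelineConfig) -> SyntheticDataset | dict:
    if config.input_dir is None:
        spec = DesignSpec(seed=config.seed,
                          depth_layers=tuple(config.depth_layers),
                          n_nematode_taxa=config.n_nematode_taxa,
                          n_protist_taxa=config.n_protist_taxa)
        return generate_experiment(spec)
    indir = Path(config.input_dir)
    tables = {
        c: AbundanceTable.from_tsv(indir / f"abundance_{c}.tsv")
        for c in config.communities
    }
    metadata = pd.read_csv(indir / "metadata.tsv", sep="\t", index_col="sample_id")
    soil = pd.read_csv(indir / "soil.tsv", sep="\t", index_col="sample_id")
    return {"tables": tables, "metadata": metadata, "soil": soil}


def run(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; deterministic given the config seed."""
    data = _load_dataset(config)
    if isinstance(data, SyntheticDataset):
        tables, metadata, soil = data.tables, data.metadata, data.soil
    else:
        tables, metadata, soil = data["tables"], data["metadata"], data["soil"]

    report = validate_inputs(
        {c: tables[c] for c in config.communities}, metadata, soil
    )
    if report.fatal:
        msgs = "; ".join(i.message for i in report.issues if i.level == "fatal")
        raise PipelineStageError("validate", msgs, ValueError("invalid inputs"))

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    net_rows, metric_frames, stab_frames = [], [], []
    for community in config.communities:
        for depth in config.depth_layers:
            ctx = f"{community}/{depth}"
            sample_ids = metadata.index[metadata["depth"] == depth]
            table = tables[community].subset_samples(sample_ids)
            filtered = table.prevalence_filter(config.prevalence_min)
            try:
                corr = spearman_matrix(filtered)
                try:
                    threshold, trace = select_rmt_threshold(
                        corr, config.grid_start, config.grid_stop,
                        config.grid_step, alpha=0.05,
                    )
                    rmt_ok = True
                except NoRMTTransitionError:
                    if config.fallback_threshold is None:
                        raise
                    threshold, trace, rmt_ok = config.fallback_threshold, None, False
                    logger.warning("%s: no RMT transition; falling back to "
                                   "threshold %.2f", ctx, threshold)
                network = build_network(corr, threshold, config.alpha_fdr,
                                        diagnostics=trace)
            except PipelineStageError:
                raise
            except Exception as e:
                raise PipelineStageError("netbuild", ctx, e) from e

            try:
                metrics = sample_metrics_table(network, filtered.data)
            except Exception as e:
                raise PipelineStageError("netmetrics", ctx, e) from e
            metrics.insert(0, "community", community)
            metrics.insert(1, "depth", depth)
            metric_frames.append(metrics)

            try:
                seed_coh = int(rng.integers(0, 2**31 - 1))
                corrected = null_corrected_correlations(
                    table.data.T, n_iter=config.cohesion_n_iter, seed=seed_coh,
                )
                conn = connectedness(corrected)
                coh = sample_cohesion(table.data.T, conn)
            except Exception as e:
                raise PipelineStageError("cohesion", ctx, e) from e
            stab = pd.DataFrame({
                "community": community, "depth": depth,
                "C_pos": coh.c_pos, "C_neg": coh.c_neg, "npc": coh.npc,
            })
            stab_frames.append(stab)

            net_rows.append({
                "community": community, "depth": depth,
                "threshold": network.threshold, "rmt_selected": rmt_ok,
                "n_nodes": network.graph.number_of_nodes(),
                "n_edges": network.n_edges,
                "n_negative_edges": sum(
                    1 for *_e, d in network.graph.edges(data=True)
                    if d["sign"] == "-"
                ),
            })

    networks = pd.DataFrame(net_rows)
    sample_metrics = pd.concat(metric_frames)
    stability = pd.concat(stab_frames)

    try:
        mnc_frames = []
        for depth in config.depth_layers:
            cohort = metadata.index[metadata["depth"] == depth]
            res = mnc_index(soil, variables=config.mnc_variables, cohort=cohort)
            mnc_frames.append(pd.DataFrame({"depth": depth, "mnc": res.mnc}))
        mnc = pd.concat(mnc_frames)
    except Exception as e:
        raise PipelineStageError("mnc", "all layers", e) from e

    try:
        effect_sizes, shapes, partitions, links = _inference_tables(
            config, metadata, soil, sample_metrics, stability, mnc, tables,
        )
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("inference", "summary tables", e) from e

    out = RunReport(
        config=config, config_hash=config.config_hash(), seed=config.seed,
        version=__version__, networks=networks, sample_metrics=sample_metrics,
        stability=stability, mnc=mnc, effect_sizes=effect_sizes,
        shapes=shapes, partitions=partitions, links=links,
    )
    if config.output_dir is not None:
        try:
            out.write(config.output_dir)
        except Exception as e:
            Path(config.output_dir, "FAILED").write_text(str(e))
            raise PipelineStageError("write", config.output_dir, e) from e
    return out


def _per_sample_responses(
    config, metadata, sample_metrics, stability, mnc, tables, depth,
) -> dict[str, pd.Series]:
    """Response name -> per-sample series for one depth layer."""
    responses: dict[str, pd.Series] = {}
    for community in config.communities:
        sm = sample_metrics[(sample_metrics["community"] == community)
                            & (sample_metrics["depth"] == depth)]
        for metric in COMPLEXITY_METRICS + ("vulnerability",):
            responses[f"{community}:{metric}"] = sm[metric]
        st = stability[(stability["community"] == community)
                       & (stability["depth"] == depth)]
        responses[f"{community}:npc"] = st["npc"]
    responses["mnc"] = mnc.loc[mnc["depth"] == depth, "mnc"]
    for community in config.communities:
        if community == "whole":
            continue
        table = tables[community]
        groups = table.annotation["functional_group"]
        ga = table.data.groupby(groups).sum().T
        layer_ids = metadata.index[metadata["depth"] == depth]
        for g in ga.columns:
            responses[f"{community}:abundance:{g}"] = ga.loc[layer_ids, g]
    return responses


def _inference_tables(config, metadata, soil, sample_metrics, stability, mnc,
                      tables):
    es_rows, shape_rows, part_rows, link_rows = [], [], [], []
    for depth in config.depth_layers:
        layer = metadata[metadata["depth"] == depth]
        responses = _per_sample_responses(
            config, metadata, sample_metrics, stability, mnc, tables, depth,
        )
        for name, series in responses.items():
            series = series.reindex(layer.index)
            if series.isna().any() or np.ptp(series.to_numpy()) == 0:
                if series.isna().all():
                    continue
                series = series.fillna(series.mean())
            est = lmm_effect_sizes(
                series.to_numpy(), layer["treatment"].to_numpy(),
                layer["block"].to_numpy(), control=0.0, response_name=name,
            )
            for level, row in est.table.iterrows():
                es_rows.append({
                    "depth": depth, "response": name, "level": level,
                    "beta": row["beta"], "se": row["se"],
                    "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                    "level_stars": row["stars"], "chi2": est.chi2,
                    "p": est.p_value, "stars": est.stars,
                    "block_variance": est.block_variance,
                })
            if config.inference == "full":
                sel = fit_shape(layer["treatment"].to_numpy(), series.to_numpy(),
                                block=layer["block"].to_numpy())
                shape_rows.append({
                    "depth": depth, "response": name, "selected": sel.selected,
                    "aic_linear": sel.aic_linear,
                    "aic_quadratic": sel.aic_quadratic,
                    "delta_aic": sel.delta_aic, "decisive": sel.decisive,
                    "unimodal": sel.unimodal,
                })

        if config.inference == "full":
            preds = soil.loc[layer.index, list(config.partition_predictors)]
            mnc_layer = mnc.loc[mnc["depth"] == depth, "mnc"].reindex(layer.index)
            for community in config.communities:
                for metric in ("connectance", "npc"):
                    y = responses[f"{community}:{metric}"].reindex(layer.index)
                    if y.isna().any() or np.ptp(y.to_numpy()) == 0:
                        continue
                    part = hierarchical_partition(
                        y.to_numpy(), preds, layer["block"].to_numpy(),
                    )
                    for pred_name, c in part.contributions.items():
                        part_rows.append({
                            "depth": depth,
                            "response": f"{community}:{metric}",
                            "predictor": pred_name, "contribution": c,
                            "full_marginal_r2": part.full_marginal_r2,
                            "p": part.p_values[pred_name],
                        })
                    lk = link_model(
                        mnc_layer.to_numpy(), y.to_numpy(),
                        layer["block"].to_numpy(),
                        predictor_name=f"{community}:{metric}",
                    )
                    link_rows.append({
                        "depth": depth, "predictor": f"{community}:{metric}",
                        "shape": lk.shape.selected, "slope": lk.coefficients[1],
                        "slope_p": lk.slope_p, "decisive": lk.shape.decisive,
                    })

    effect_sizes = pd.DataFrame(es_rows)
    shapes = pd.DataFrame(shape_rows) if shape_rows else None
    partitions = pd.DataFrame(part_rows) if part_rows else None
    links = pd.DataFrame(link_rows) if link_rows else None
    return effect_sizes, shapes, partitions, links
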