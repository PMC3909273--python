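"""End-to-end pipeline: simulate (or ingest) -> preprocess -> cluster ->
heterogeneity profiles -> Boolean model report -> consensus network ->
transition statistics.

A run writes one directory with a subdirectory per stage and a JSON manifest
recording the configuration (and its hash), per-stage outputs and wall-clock
times, so any result can be traced back to the exact settings that produced
it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import (
    boolean_model,
    heterogeneity,
    network_inference,
    preprocess,
    shape_clustering,
    synthetic_data,
    transitions,
)

__all__ = ["PipelineConfig", "PipelineStageError", "run_all"]


@dataclass
class PipelineConfig:
    """Every stage parameter and seed of a pipeline run, YAML-round-trippable.

    The default scale (64 conditions x 31 cells, ~2,000 cells) keeps a full
    run interactive while preserving the structure of the emulated screen;
    the generating panel for network inference uses its own, larger
    condition count because panel generation is cheap.
    """

    # synthetic data (ignored when input_table is set)
    input_table: str | None = None
    n_tc: int = 64
    cells_per_tc: int = 31
    n_features: int = 145
    separation: float = 8.0
    within_sd: float = 1.0
    noise_sd: float = 0.1
    effect_scale: float = 1.0
    simulate_seed: int = 11
    loading_seed: int = 7
    # preprocess
    offset: float = 0.01
    n_components: int = 3
    # clustering
    k_min: int = 5
    k_max: int = 30
    gmm_restarts: int = 10
    cluster_seed: int = 23
    silhouette_threshold: float = 0.6
    knn: int = 10
    # heterogeneity
    wildtype_id: str = "EGFP"
    tchp_clusters: int = 17
    # boolean model
    rules: dict = field(
        default_factory=lambda: {
            "mutual_antagonism": True,
            "global_activity_required": True,
            "cortical_rac_forces_adhesion_activity": True,
        }
    )
    # network inference
    network_runs: int = 500
    retention: float = 0.60
    network_seed: int = 31
    # transitions
    trajectory_cells: int = 50
    trajectory_frames: int = 37
    frame_interval_min: float = 5.0
    trajectory_seed: int = 41

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


class PipelineStageError(RuntimeError):
    """A stage failed; earlier stages' outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage sequentially into ``out_dir``; returns the path.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    outputs of completed stages stay on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    state: dict = {}

    def stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            outputs = fn(out / name)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineStageError(name, exc) from exc
        manifest["stages"][name] = {
            "status": "ok",
            "outputs": outputs,
            "wall_clock_s": round(time.perf_counter() - t0, 3),
        }

    def _simulate(d: Path) -> dict:
        d.mkdir(exist_ok=True)
        if config.input_table:
            table = preprocess.FeatureTable.read_tsv(config.input_table)
            state["table"] = table
            state["true_labels"] = None
            return {"ingested": str(config.input_table), "n_cells": table.n_cells}
        archetypes = synthetic_data.default_archetypes(
            k=7, separation=config.separation, within_sd=config.within_sd
        )
        conditions = synthetic_data.generate_condition_panel(
            n_tc=config.n_tc,
            effect_scale=config.effect_scale,
            seed=config.simulate_seed,
            cells_per_tc=config.cells_per_tc,
            wildtype_id=config.wildtype_id,
        )
        table, labels = synthetic_data.generate_cells(
            archetypes,
            conditions,
            n_features=config.n_features,
            loading_seed=config.loading_seed,
            noise_sd=config.noise_sd,
            cell_seed=config.simulate_seed + 1,
        )
        table.write_tsv(d / "cells.tsv")
        synthetic_data.write_hidden_labels(table, labels, d / "true_labels.tsv")
        synthetic_data.write_condition_panel_yaml(conditions, d / "conditions.yaml")
        state["table"] = table
        state["true_labels"] = labels
        state["conditions"] = conditions
        # manifest paths are relative to the run directory for portability
        return {
            "cells": "simulate/cells.tsv",
            "n_cells": table.n_cells,
            "n_tc": len(conditions),
        }

    def _preprocess(d: Path) -> dict:
        d.mkdir(exist_ok=True)
        transformed, transform = preprocess.scale_and_log(
            state["table"], offset=config.offset
        )
        embedding = preprocess.pca_reduce(
            transformed, n_components=config.n_components, transform=transform
        )
        embedding.write(d)
        state["embedding"] = embedding
        return {
            "embedding": "preprocess",
            "variance_fractions": embedding.variance_fractions.tolist(),
        }

    def _cluster(d: Path) -> dict:
        d.mkdir(exist_ok=True)
        model, sweep = shape_clustering.sweep_and_select(
            state["embedding"],
            k_range=(config.k_min, config.k_max),
            seed=config.cluster_seed,
            restarts=config.gmm_restarts,
        )
        assignment = shape_clustering.knn_correct(
            state["embedding"],
            model,
            silhouette_threshold=config.silhouette_threshold,
            n_neighbors=config.knn,
        )
        sweep.to_csv(d / "sweep.tsv", sep="\t", index=False)
        assignment.to_frame().to_csv(d / "labels.tsv", sep="\t", index=False)
        np.savetxt(d / "shape_means.tsv", assignment.shape_means, delimiter="\t")
        (d / "selection.json").write_text(
            json.dumps(
                {
                    "method": model.method,
                    "k": model.k,
                    "mean_silhouette_before": assignment.mean_silhouette_before,
                    "mean_silhouette_after": assignment.mean_silhouette_after,
                }
            )
        )
        state["assignment"] = assignment
        state["selected"] = model
        return {
            "method": model.method,
            "k": model.k,
            "mean_silhouette_before": assignment.mean_silhouette_before,
            "mean_silhouette_after": assignment.mean_silhouette_after,
        }

    def _tchp(d: Path) -> dict:
        d.mkdir(exist_ok=True)
        assignment = state["assignment"]
        profiles = heterogeneity.compute_tchp(assignment)
        normalized = heterogeneity.normalize_tchp(profiles, config.wildtype_id)
        M = heterogeneity.ShapeDistanceMatrix.from_assignment(assignment)
        n_clusters = min(config.tchp_clusters, len(normalized))
        clustering = heterogeneity.cluster_tchps(normalized, M, n_clusters)
        heterogeneity.tchp_long_format(normalized, clustering).to_csv(
            d / "tchp_normalized_long.tsv", sep="\t", index=False
        )
        heterogeneity.tchp_long_format(profiles).to_csv(
            d / "tchp_raw_long.tsv", sep="\t", index=False
        )
        M.to_frame().to_csv(d / "shape_distance_matrix.tsv", sep="\t")
        state["profiles"] = profiles
        state["normalized"] = normalized
        state["tchp_clustering"] = clustering
        wt = next(p for p in profiles if p.tc_id == config.wildtype_id)
        return {
            "n_profiles": len(profiles),
            "n_clusters": clustering.n_clusters,
            "wildtype_shapes_present": sorted(heterogeneity.shapes_present(wt)),
            "wildtype_enriched": sorted(heterogeneity.enriched_shapes(wt)),
        }

    def _boolnet(d: Path) -> dict:
        d.mkdir(exist_ok=True)
        rules = boolean_model.RuleSet(**config.rules)
        report = boolean_model.enumeration_report(rules)
        (d / "boolean_report.json").write_text(json.dumps(report, indent=2))
        return {"n_admissible": report["n_admissible"]}

    def _bayesnet(d: Path) -> dict:
        d.mkdir(exist_ok=True)
        panel = network_inference.rescale_panel(state["profiles"])
        net = network_inference.consensus(
            panel,
            n_runs=config.network_runs,
            retention=config.retention,
            seed=config.network_seed,
        )
        net.edge_table().to_csv(d / "edges.tsv", sep="\t", index=False)
        import networkx as nx

        g = net.to_digraph()
        nx.write_graphml(g, d / "network.graphml")
        with open(d / "network.dot", "w") as fh:
            fh.write("digraph shapes {\n")
            for e in net.edges:
                fh.write(
                    f'  {e.parent} -> {e.child} [label="{e.sign} '
                    f'{e.frequency:.2f}"];\n'
                )
            fh.write("}\n")
        state["network"] = net
        return {
            "n_edges": len(net.edges),
            "is_acyclic": net.is_acyclic,
            "excluded_shapes": panel.excluded_shapes,
        }

    def _transitions(d: Path) -> dict:
        d.mkdir(exist_ok=True)
        cfg = synthetic_data.TrajectoryConfig(
            transition_matrix=synthetic_data.default_transition_matrix(),
            n_cells=config.trajectory_cells,
            n_frames=config.trajectory_frames,
            frame_interval_min=config.frame_interval_min,
        )
        traj = synthetic_data.generate_trajectories(cfg, seed=config.trajectory_seed)
        traj.write_tsv(d / "trajectories.tsv")
        matrix = transitions.estimate_transitions(traj, n_shapes=7)
        matrix.to_frame("probabilities").to_csv(d / "probabilities.tsv", sep="\t")
        matrix.to_frame("counts").to_csv(d / "counts.tsv", sep="\t")
        report = transitions.consistency_report(matrix, state["network"])
        report["stability_ranking"] = transitions.stability_ranking(matrix)
        (d / "report.json").write_text(json.dumps(report, indent=2))
        return {
            "n_transitions": matrix.n_transitions,
            "most_stable_shape": transitions.stability_ranking(matrix)[0][0],
        }

    stage("simulate", _simulate)
    stage("preprocess", _preprocess)
    stage("cluster", _cluster)
    stage("tchp", _tchp)
    stage("boolnet", _boolnet)
    stage("bayesnet", _bayesnet)
    stage("transitions", _transitions)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
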