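"""End-to-end pipeline orchestration.

Runs the stages simulate → dedup → aggregate → counts → connectome → metrics
→ stats on a run directory, each stage reading only artifacts written by
earlier stages (never mutating them) and recording a manifest (config echo,
input hashes, library versions) so every output is traceable to config +
seed. Identical config and seed give byte-identical numeric outputs.
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

from . import __version__, candidates, connectome, io, netmetrics, stats, synth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "dedup", "aggregate", "counts", "connectome", "metrics", "stats")


class DependencyError(RuntimeError):
    """An upstream artifact required by a stage is missing."""


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; echoed verbatim into the run manifest."""

    out_dir: str = "run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    # simulate
    n_cells: int = 120
    n_duplicates: int = 25
    dup_radius: float = 4.0
    min_true_sep: float = 25.0
    volume_shape: tuple[int, int, int] = (40, 40, 40)
    n_regions: int = 20
    n_white: int = 3
    voxel_size: float = 4.0
    n_animals: int = 13
    within_corr: float = 0.8
    between_corr: float = 0.0
    # dedup
    min_dist: float = candidates.DEFAULT_MIN_DIST_UM
    # connectome
    group: str = "15"
    eco_grid: tuple[float, ...] = connectome.DEFAULT_ECO_GRID
    # metrics
    louvain_seed: int | None = None
    er_n_rep: int = 1000
    z_hub: float = netmetrics.DEFAULT_Z_HUB
    p_connector_nonhub: float = netmetrics.DEFAULT_P_CONNECTOR_NONHUB
    p_connector_hub: float = netmetrics.DEFAULT_P_CONNECTOR_HUB
    clustering_low_degree: str = "exclude"
    # stats
    control_group: str = "HT"
    ss_type: int = 2
    dunnett_n_mc: int = 20000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.min_dist <= 0 or self.voxel_size <= 0:
            raise ValueError("min_dist and voxel_size must be positive")
        if self.er_n_rep < 1 or self.dunnett_n_mc < 1:
            raise ValueError("replicate counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "eco_grid", "volume_shape"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived deterministically from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} needs {path.name}, produced by stage {produced_by!r}"
        )
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config.stages]
    logger.info("running stages: %s", ", ".join(enabled))

    if "simulate" in enabled:
        _stage_simulate(config, out)
    if "dedup" in enabled:
        cands = io.read_candidates(_require(out / "candidates.csv", "dedup", "simulate"))
        kept = candidates.dedup_candidates(cands, min_dist=config.min_dist)
        io.write_candidates(kept, out / "candidates_dedup.csv")
    if "aggregate" in enabled:
        kept = io.read_candidates(
            _require(out / "candidates_dedup.csv", "aggregate", "dedup")
        )
        vol = io.read_label_volume(_require(out / "labels.nii.gz", "aggregate", "simulate"))
        table = io.read_region_table(_require(out / "regions.tsv", "aggregate", "simulate"))
        counts, discarded = candidates.assign_regions(kept, vol, table)
        density = candidates.whole_brain_density(counts.to_dict(), table)
        df = counts.rename("count").to_frame()
        io.write_table(df, out / "region_counts.tsv")
        io.write_table(
            pd.DataFrame(
                {"discarded": [discarded], "whole_brain_density_mm3": [density]}
            ),
            out / "aggregate_summary.tsv",
            index=False,
        )
    if "counts" in enabled:
        _require(out / "count_matrix.tsv", "counts", "simulate")
        # round-trip check: the matrix must re-read identically
        cm = io.read_count_matrix(out / "count_matrix.tsv", out / "animal_meta.tsv")
        io.write_count_matrix(cm, out / "count_matrix.tsv", out / "animal_meta.tsv")
    if "connectome" in enabled:
        cm = io.read_count_matrix(
            _require(out / "count_matrix.tsv", "connectome", "counts"),
            _require(out / "animal_meta.tsv", "connectome", "counts"),
        )
        corr = connectome.correlation_matrix(cm, group=config.group)
        io.write_correlation(corr, out / "correlation.tsv")
        eco = connectome.eco_optimize(corr, grid=config.eco_grid)
        io.write_table(eco.curve, out / "eco_curve.tsv", index=False)
        net = connectome.threshold_at_density(corr, eco.selected_density)
        io.write_edge_list(net, out / "network_edges.tsv")
        io.write_graphml(net, out / "network.graphml")
    if "metrics" in enabled:
        net = io.read_graphml(_require(out / "network.graphml", "metrics", "connectome"))
        lseed = (
            config.louvain_seed
            if config.louvain_seed is not None
            else config.stage_seed("louvain")
        )
        part = netmetrics.louvain(net, seed=lseed)
        metrics = netmetrics.node_metrics_table(
            net,
            part,
            z_hub=config.z_hub,
            p_connector_nonhub=config.p_connector_nonhub,
            p_connector_hub=config.p_connector_hub,
        )
        io.write_table(metrics, out / "node_metrics.tsv")
        io.write_table(
            pd.Series(part.assignment, name="community").rename_axis("region").to_frame(),
            out / "partition.tsv",
        )
        sw = netmetrics.small_world_analysis(
            net,
            n_rand=config.er_n_rep,
            seed=config.stage_seed("er"),
            low_degree=config.clustering_low_degree,
        )
        io.write_table(
            pd.DataFrame([dataclasses.asdict(sw)]), out / "small_world.tsv", index=False
        )
    if "stats" in enabled:
        tc = io.read_table(
            _require(out / "timecourse.tsv", "stats", "simulate"), index_col=None
        )
        report = stats.timecourse_report(
            tc,
            control=config.control_group,
            n_mc=config.dunnett_n_mc,
            seed=config.stage_seed("dunnett"),
            ss_type=config.ss_type,
        )
        io.write_table(report["anova"].rename_axis("effect"), out / "anova.tsv")
        io.write_table(report["dunnett"], out / "dunnett.tsv")

    _write_manifest(config, out, enabled)
    return out


def _stage_simulate(config: PipelineConfig, out: Path) -> None:
    cands, truth = synth.gen_candidate_cloud(
        n_cells=config.n_cells,
        n_duplicates=config.n_duplicates,
        dup_radius=config.dup_radius,
        min_true_sep=config.min_true_sep,
        extent=tuple(s * config.voxel_size for s in config.volume_shape),
        seed=config.stage_seed("candidates"),
    )
    io.write_candidates(cands, out / "candidates.csv")
    pd.Series(truth.duplicate_map, name="parent").rename_axis("duplicate").to_frame().to_csv(
        out / "ground_truth_duplicates.tsv", sep="\t"
    )
    vol, table = synth.gen_label_volume(
        shape=config.volume_shape,
        n_regions=config.n_regions,
        n_white=config.n_white,
        voxel_size=config.voxel_size,
        seed=config.stage_seed("volume"),
    )
    io.write_label_volume(vol, out / "labels.nii.gz")
    io.write_region_table(table, out / "regions.tsv")
    spec = synth.SyntheticSpec(
        n_regions=config.n_regions,
        n_animals=config.n_animals,
        community_sizes=synth._default_sizes(config.n_regions, min(10, config.n_regions)),
        within_corr=config.within_corr,
        between_corr=config.between_corr,
        seed=config.stage_seed("counts"),
    )
    cm, truth_counts = synth.gen_counts(spec)
    io.write_count_matrix(cm, out / "count_matrix.tsv", out / "animal_meta.tsv")
    pd.Series(truth_counts.true_partition, name="community").rename_axis(
        "region"
    ).to_frame().to_csv(out / "ground_truth_partition.tsv", sep="\t")
    tc = synth.gen_timecourse(seed=config.stage_seed("timecourse"))
    io.write_table(tc, out / "timecourse.tsv", index=False)


def _write_manifest(config: PipelineConfig, out: Path, enabled: list[str]) -> None:
    artifacts = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "cfosnet_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stages_run": enabled,
        "config": dataclasses.asdict(config),
        "artifact_sha256": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
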