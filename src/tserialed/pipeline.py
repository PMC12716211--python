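"""End-to-end orchestration: simulate → preprocess → index → integrate →
merge → phase analysis, reproducible from (config, seed) alone.

A run directory receives:

* ``frames.h5`` / ``truth.json`` — the simulated acquisition + sidecar
* ``offsets.csv`` — drift-correction offsets per frame
* ``cells.csv`` — one row per indexed lattice (and per failed dataset)
* ``phase_<k>.hkl`` / ``stats_<k>.json`` — merged intensities per cluster
* ``report.json`` — indexing rate, clusters, fractions, merge statistics,
  and the full parameter echo for provenance
* ``log.jsonl`` — structured stage log
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import phase_analysis
from .exceptions import IndexingFailureError, InsufficientDataError
from .frame_io import write_frames
from .geometry import BeamModel, DetectorGeometry, UnitCell, niggli_comparison_cell, tilt_axis_from_azimuth
from .indexing import IndexingParams, build_cloud, find_spots, multi_lattice_index, refine_cell
from .integration import integrate_series
from .merging import merge, resolve_indexing_ambiguity, scale_frames, write_hkl
from .preprocessing import correct_center_drift, regroup
from .symmetry import ambiguity_operators
from .synthetic_data import (
    NoiseModel,
    PhaseDefinition,
    make_schedule,
    simulate_experiment,
    six_phase_mixture,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "default_run_config"]


@dataclass
class GeometryConfig:
    voltage_kv: float = 200.0
    distance_mm: float = 650.0
    pixel_size_mm: float = 0.1
    image_shape: tuple[int, int] = (256, 256)
    beam_center_px: tuple[float, float] = (128.0, 128.0)
    tilt_axis_azimuth_deg: float = 0.0

    def detector(self) -> DetectorGeometry:
        return DetectorGeometry(
            distance_mm=self.distance_mm,
            pixel_size_mm=self.pixel_size_mm,
            n_fast=self.image_shape[1],
            n_slow=self.image_shape[0],
            beam_center=tuple(self.beam_center_px),
        )

    def beam(self) -> BeamModel:
        return BeamModel(voltage_kv=self.voltage_kv)


@dataclass
class SimulationConfig:
    phases: list[PhaseDefinition] = field(default_factory=six_phase_mixture)
    mixture_fractions: list[float] | None = None  # None = equal
    n_positions: int = 60
    tilt_angles: tuple[float, ...] = tuple(float(x) for x in range(-30, 31, 10))
    aggregate_fraction: float = 0.15
    failure_fraction: float = 0.1
    noise: NoiseModel = field(default_factory=NoiseModel)


@dataclass
class ProcessingConfig:
    k_sigma: float = 6.0
    min_pixels: int = 3
    beam_mask_radius: float = 12.0
    drift_crop: int = 128
    indexing: IndexingParams = field(default_factory=IndexingParams)
    integration_d_min: float = 1.3
    cluster_threshold: float = 1.5
    cluster_linkage: str = "average"
    cluster_min_members: int = 2
    laue_group: str = "-1"


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, UnitCell):
                return list(obj.parameters)
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return convert(self)


def default_run_config() -> RunConfig:
    return RunConfig()


def config_from_dict(payload: dict) -> RunConfig:
    """Build a RunConfig from a plain (YAML/JSON) dictionary."""
    cfg = RunConfig()
    geo = payload.get("geometry", {})
    for key, val in geo.items():
        if hasattr(cfg.geometry, key):
            setattr(cfg.geometry, key, tuple(val) if isinstance(val, list) else val)
    sim = payload.get("simulation", {})
    if "phases" in sim:
        cfg.simulation.phases = [
            PhaseDefinition(
                name=p["name"],
                cell=UnitCell(*p["cell"]),
                density=p["density"],
                laue_group=p.get("laue_group", "-1"),
            )
            for p in sim["phases"]
        ]
    for key in ("mixture_fractions", "n_positions", "aggregate_fraction", "failure_fraction"):
        if key in sim:
            cfg.simulation = dataclasses.replace(cfg.simulation, **{key: sim[key]})
    if "tilt_angles" in sim:
        cfg.simulation.tilt_angles = tuple(float(a) for a in sim["tilt_angles"])
    if "noise" in sim:
        cfg.simulation.noise = NoiseModel(**sim["noise"])
    proc = payload.get("processing", {})
    for key, val in proc.items():
        if key == "indexing":
            cfg.processing.indexing = IndexingParams(**val)
        elif hasattr(cfg.processing, key):
            setattr(cfg.processing, key, val)
    return cfg


@dataclass
class PipelineResult:
    report: dict
    out_dir: Path
    cells: pd.DataFrame


class _StageLog:
    def __init__(self, path: Path):
        self._fh = open(path, "w")

    def emit(self, stage: str, **fields) -> None:
        rec = {"stage": stage, "time": round(time.time(), 3), **fields}
        self._fh.write(json.dumps(rec) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def run_pipeline(config: RunConfig, seed: int, out_dir: str | Path) -> PipelineResult:
    """Execute all stages; deterministic given (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "log.jsonl")
    geom = config.geometry.detector()
    beam = config.geometry.beam()
    axis = tilt_axis_from_azimuth(config.geometry.tilt_axis_azimuth_deg)
    sim = config.simulation
    proc = config.processing
    fractions = sim.mixture_fractions or [1.0 / len(sim.phases)] * len(sim.phases)

    try:
        # --- simulate -----------------------------------------------------
        schedule = make_schedule(sim.n_positions, list(sim.tilt_angles))
        stack, truth = simulate_experiment(
            sim.phases, fractions, schedule,
            noise=sim.noise,
            aggregate_fraction=sim.aggregate_fraction,
            failure_fraction=sim.failure_fraction,
            seed=seed,
            geom=geom, beam=beam,
            tilt_axis_azimuth_deg=config.geometry.tilt_axis_azimuth_deg,
        )
        write_frames(stack, out / "frames.h5", "hdf5")
        truth.to_json(out / "truth.json")
        log.emit("simulate", n_frames=len(stack), n_positions=sim.n_positions)

        # --- preprocess ---------------------------------------------------
        corrected, offsets = correct_center_drift(
            stack, crop=proc.drift_crop, beam_center=config.geometry.beam_center_px
        )
        offsets.to_csv(out / "offsets.csv", index=False)
        series_list = regroup(corrected)
        log.emit("preprocess", n_series=len(series_list))

        # --- spot finding + indexing ---------------------------------------
        bc = config.geometry.beam_center_px
        spots = {}
        for idx in range(len(corrected)):
            row = corrected.metadata.iloc[idx]
            fid = int(row["frame_id"])
            spots[fid] = find_spots(
                corrected.frames[idx],
                k_sigma=proc.k_sigma,
                min_pixels=proc.min_pixels,
                beam_mask_radius=proc.beam_mask_radius,
                beam_center=bc,
                frame_id=fid,
            )

        cell_rows = []
        solutions = {}
        for series in series_list:
            cloud = build_cloud(series, spots, geom, beam, axis=axis)
            try:
                solution = multi_lattice_index(cloud, params=proc.indexing)
            except (IndexingFailureError, InsufficientDataError) as exc:
                log.emit("index", position_id=series.position_id, event="failed", reason=str(exc))
                cell_rows.append(
                    {"position_id": series.position_id, "lattice_id": -1, "status": "unindexed",
                     "a": np.nan, "b": np.nan, "c": np.nan,
                     "alpha": np.nan, "beta": np.nan, "gamma": np.nan,
                     "n_points": len(cloud), "fraction_indexed": 0.0}
                )
                continue
            refined_models = []
            for lat_id, model in enumerate(solution.lattices):
                ref = refine_cell(model, cloud, assignment=solution.assignment == lat_id,
                                  index_tolerance=proc.indexing.index_tolerance)
                final = (ref.model if ref.success else model).niggli_reduced()
                refined_models.append(final)
                report_cell = niggli_comparison_cell(final.cell)
                cell_rows.append(
                    {"position_id": series.position_id, "lattice_id": lat_id, "status": "indexed",
                     **dict(zip(("a", "b", "c", "alpha", "beta", "gamma"), report_cell.parameters)),
                     "n_points": int(np.sum(solution.assignment == lat_id)),
                     "fraction_indexed": solution.fraction_indexed[lat_id]}
                )
            solution.lattices = refined_models
            solutions[series.position_id] = (series, cloud, solution)
        cells_df = pd.DataFrame(cell_rows)
        cells_df.to_csv(out / "cells.csv", index=False)
        n_indexed_positions = len(solutions)
        log.emit("index", n_indexed=n_indexed_positions, n_collected=len(series_list))

        # --- clustering -----------------------------------------------------
        indexed = cells_df[cells_df["status"] == "indexed"]
        report: dict = {
            "parameters": config.to_dict(),
            "seed": seed,
            "positions": {
                "collected": len(series_list),
                "indexed": n_indexed_positions,
                "failed": len(series_list) - n_indexed_positions,
            },
            "indexing_rate_percent": phase_analysis.indexing_rate(
                n_indexed_positions, len(series_list)
            ) if len(series_list) else None,
        }
        if len(indexed) == 0:
            report.update({"clusters": [], "outlier_ids": [], "n_lattices": 0})
            (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
            log.emit("phase", event="no indexed lattices")
            return PipelineResult(report=report, out_dir=out, cells=cells_df)

        cells = [UnitCell(*row) for row in indexed[["a", "b", "c", "alpha", "beta", "gamma"]].to_numpy()]
        lattice_keys = [
            (int(r.position_id), int(r.lattice_id)) for r in indexed.itertuples()
        ]
        clusters, outliers = phase_analysis.cluster_cells(
            cells, ids=lattice_keys,
            threshold=proc.cluster_threshold,
            linkage=proc.cluster_linkage,
            min_members=proc.cluster_min_members,
            check_reduced=False,  # produced by niggli_reduced() above
        )
        densities = _match_densities(clusters, sim.phases)
        phase_report = phase_analysis.quantify(
            clusters, densities=densities, outlier_ids=outliers, n_collected=len(series_list)
        )
        report["phase_report"] = phase_report.to_dict()
        report["n_lattices"] = int(len(indexed))
        log.emit("phase", n_clusters=len(clusters), n_outliers=len(outliers))

        # --- integration + merging per cluster ------------------------------
        merge_stats = {}
        twin_ops = ambiguity_operators(proc.laue_group)
        for cluster in clusters:
            per_dataset = []
            for (pid, lat_id) in cluster.member_ids:
                series, cloud, solution = solutions[pid]
                obs = integrate_series(
                    series, solution, corrected, geom, beam,
                    d_min=proc.integration_d_min,
                    eps_max=sim.noise.eps_max,
                    sigma_e=sim.noise.sigma_e,
                    axis=axis,
                )
                obs = obs[obs["lattice_id"] == lat_id]
                if len(obs):
                    per_dataset.append(obs)
            if not per_dataset:
                continue
            resolved, _, _ = resolve_indexing_ambiguity(
                per_dataset, twin_ops, proc.laue_group, intensity_col="I_corr"
            )
            all_obs = pd.concat(resolved, ignore_index=True)
            # globally unique frame keys so per-still scales stay per-still
            all_obs["frame_id"] = all_obs["position_id"] * 10_000 + all_obs["frame_id"]
            try:
                scales = scale_frames(all_obs, proc.laue_group)
                all_obs["I_corr"] = all_obs["I_corr"] / scales.loc[all_obs["frame_id"]].to_numpy()
                all_obs["sigma_corr"] = (
                    all_obs["sigma_corr"] / scales.loc[all_obs["frame_id"]].to_numpy()
                )
                merged, stats = merge(
                    all_obs, proc.laue_group,
                    cell=cluster.centroid_cell, d_min=proc.integration_d_min,
                )
            except InsufficientDataError as exc:
                log.emit("merge", cluster_id=cluster.cluster_id, event="skipped", reason=str(exc))
                continue
            write_hkl(merged, out / f"phase_{cluster.cluster_id}.hkl")
            (out / f"stats_{cluster.cluster_id}.json").write_text(
                json.dumps(stats.to_dict(), indent=1)
            )
            merge_stats[str(cluster.cluster_id)] = stats.to_dict()
            log.emit("merge", cluster_id=cluster.cluster_id, n_unique=stats.n_unique)
        report["merge_stats"] = merge_stats

        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        return PipelineResult(report=report, out_dir=out, cells=cells_df)
    finally:
        log.close()


def _match_densities(clusters, phases: list[PhaseDefinition]) -> dict[int, float] | None:
    """Assign each cluster the density of the nearest phase reference cell."""
    refs = [(p.density, np.array(niggli_comparison_cell(p.cell).parameters)) for p in phases]
    out = {}
    for cluster in clusters:
        centroid = np.array(cluster.centroid_cell.parameters)
        dists = [np.linalg.norm(centroid - ref) for _, ref in refs]
        best = int(np.argmin(dists))
        if dists[best] > 3.0:
            return None  # cannot attribute densities confidently
        out[cluster.cluster_id] = refs[best][0]
    return out
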