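"""End-to-end orchestration: simulate or load → decompose → cluster → tree → evaluate.

One global seed deterministically derives every module's seed (CRC32 of the
module name XORed into the global seed), so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .clustering import ClusterConfig, cluster_cells
from .metrics import clustering_scores, recovery_report
from .rda import AutoencoderSpec, DecompositionResult, RDAConfig, decompose
from .simulate import SimulatedDataset, SimulationConfig, simulate_dataset
from .tree import SubcloneTree, build_tree

logger = logging.getLogger(__name__)

SWEEP_AXES = ("sites", "fpr", "fnr", "mr", "subclones", "cells")
_AXIS_FIELD = {
    "sites": "n_sites",
    "fpr": "fpr",
    "fnr": "fnr",
    "mr": "mr",
    "subclones": "n_subclones",
    "cells": "n_cells",
}


def derive_seed(global_seed: int, module: str) -> int:
    """Stable per-module seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(module.encode())) % (2**31)


@dataclass
class PipelineConfig:
    input_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    rda: RDAConfig = field(default_factory=RDAConfig)
    autoencoder: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    outdir: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"
    order_sites_on_write: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_path or simulation must be given"
            )


@dataclass
class RunManifest:
    """What a run did: config snapshot, artifacts, timings, summaries."""

    config: dict
    artifacts: list[str]
    stage_seconds: dict[str, float]
    convergence: dict
    n_subclones_found: int
    metrics: dict | None
    package_version: str

    # in-memory handles for programmatic use (not serialised)
    genotype: gio.ObservedGenotypeMatrix | None = None
    decomposition: DecompositionResult | None = None
    labels: np.ndarray | None = None
    tree: SubcloneTree | None = None
    dataset: SimulatedDataset | None = None


def _config_snapshot(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {
        "input_path": str(cfg.input_path) if cfg.input_path else None,
        "simulation": enc(cfg.simulation) if cfg.simulation else None,
        "rda": enc(cfg.rda),
        "autoencoder": enc(cfg.autoencoder),
        "cluster": enc(cfg.cluster),
        "outdir": str(cfg.outdir) if cfg.outdir else None,
        "seed": cfg.seed,
    }


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the full analysis and (optionally) write the artifact set.

    In simulation mode the ground truth travels with the run and the
    manifest embeds the recovery and clustering metrics.
    """
    from . import __version__

    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stage_seconds: dict[str, float] = {}
    dataset: SimulatedDataset | None = None

    t0 = time.perf_counter()
    if cfg.input_path is not None:
        path = Path(cfg.input_path)
        if not path.exists():
            raise FileNotFoundError(f"input matrix not found: {path}")
        genotype = gio.read_genotype_matrix(path)
    else:
        sim_cfg = dataclasses.replace(
            cfg.simulation, seed=derive_seed(cfg.seed, "simulate")
            if cfg.simulation.seed == 0 else cfg.simulation.seed
        )
        dataset = simulate_dataset(sim_cfg)
        genotype = dataset.observed
    stage_seconds["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    X, omega = gio.encode_for_rda(genotype)
    ae = dataclasses.replace(
        cfg.autoencoder,
        seed=cfg.autoencoder.seed or derive_seed(cfg.seed, "autoencoder"),
    )
    result = decompose(X, omega, cfg.rda, ae)
    stage_seconds["decompose"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    ccfg = dataclasses.replace(
        cfg.cluster, seed=cfg.cluster.seed or derive_seed(cfg.seed, "cluster")
    )
    assignment = cluster_cells(result.genotype_calls, ccfg)
    stage_seconds["cluster"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tree = build_tree(result.genotype_calls, assignment)
    stage_seconds["tree"] = time.perf_counter() - t0

    metrics: dict | None = None
    if dataset is not None:
        t0 = time.perf_counter()
        rep = recovery_report(
            result.genotype_calls,
            dataset.truth_matrix,
            np.where(genotype.values == gio.MISSING, 0, genotype.values),
            genotype.omega_mask,
        )
        crep = clustering_scores(assignment.labels, dataset.true_labels)
        metrics = {**rep.to_dict(), **crep.to_dict()}
        stage_seconds["evaluate"] = time.perf_counter() - t0

    artifacts: list[str] = []
    if cfg.outdir is not None:
        t0 = time.perf_counter()
        site_labels = None
        if cfg.order_sites_on_write and genotype.m >= 4:
            # presentation-only: block-order sites with the same machinery
            site_cfg = ClusterConfig(
                k_neighbors=min(ccfg.k_neighbors, genotype.m - 1),
                resolution=ccfg.resolution,
                seed=derive_seed(cfg.seed, "site_order"),
            )
            site_labels = cluster_cells(result.genotype_calls.T, site_cfg).labels
        written = gio.write_outputs(
            cfg.outdir,
            genotype=genotype,
            decomposition=result,
            assignment=assignment,
            tree=tree,
            metrics=metrics,
            site_labels=site_labels,
        )
        artifacts = [str(p) for p in written]
        stage_seconds["write"] = time.perf_counter() - t0

    last_c1, last_c2 = result.trace[-1]
    manifest = RunManifest(
        config=_config_snapshot(cfg),
        artifacts=artifacts,
        stage_seconds=stage_seconds,
        convergence={
            "converged": result.converged,
            "iterations": result.iterations_run,
            "c1": last_c1,
            "c2": last_c2,
        },
        n_subclones_found=assignment.K,
        metrics=metrics,
        package_version=__version__,
        genotype=genotype,
        decomposition=result,
        labels=assignment.labels,
        tree=tree,
        dataset=dataset,
    )
    return manifest


def run_benchmark_sweep(
    base: SimulationConfig,
    axis: str,
    values: list,
    replicates: int = 3,
    rda: RDAConfig | None = None,
    autoencoder: AutoencoderSpec | None = None,
    cluster: ClusterConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """One pipeline run per (axis value, replicate); long-format metric table.

    A failing cell is recorded with its error message and the sweep
    continues.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    rows = []
    for value in values:
        for rep in range(replicates):
            seed = derive_seed(base_seed, f"{axis}={value}/rep={rep}")
            row = {"axis": axis, "value": value, "replicate": rep, "seed": seed}
            try:
                sim = dataclasses.replace(
                    base, **{_AXIS_FIELD[axis]: value}, seed=seed
                )
                cfg = PipelineConfig(
                    simulation=sim,
                    rda=rda or RDAConfig(),
                    autoencoder=autoencoder or AutoencoderSpec(),
                    cluster=cluster or ClusterConfig(),
                    seed=seed,
                )
                manifest = run_pipeline(cfg)
                row.update(manifest.metrics or {})
                row["n_subclones_found"] = manifest.n_subclones_found
                row["status"] = "ok"
            except Exception as exc:  # noqa: BLE001 - sweep isolation
                logger.exception("sweep cell %s=%s rep %d failed", axis, value, rep)
                row["status"] = f"error: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)
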