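"""End-to-end orchestration: simulate/load -> marker QC -> optional
recombination-hotspot filter -> optional marker spacing or RSM
restriction -> optional call-rate degradation grid -> distances ->
MDS/PCA/NJ/Fst/drift, with a JSON manifest recording parameters, seeds,
hashes and marker/sample bookkeeping at every stage.

Stage order is fixed: hotspot filtering always precedes distance
computation, and the degradation grid fans out after marker selection so
every dataset variant shares the same marker panel.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import callrate, distances, genotype_io, ld_hotspots, njtree, popstats, projection, rsm
from .matrix import GenotypeMatrix
from .synthetic_data import SimulationConfig, simulate

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    outdir: str = "popflow_run"
    seed: int = 0
    ped: str | None = None
    map: str | None = None
    simulation: dict[str, Any] | None = None
    marker_call_rate_cutoff: float = 0.95
    degraded_call_rate_cutoff: float = 0.80
    rh_filter: bool = False
    rh_flank: int = 25
    rh_threshold: float = 0.7
    rsm_only: bool = False
    rsm_z_threshold: float = 4.0
    thin_bp: int = 500_000
    spacing_only: bool = False
    gcr_grid: list[float] = field(default_factory=list)
    k_components: int = 5
    population_tree: bool = False

    def __post_init__(self) -> None:
        if (self.ped is None) != (self.map is None):
            raise PipelineError("ped and map must be given together")
        if self.ped is None and self.simulation is None:
            raise PipelineError("either ped/map paths or a simulation block is required")
        if not 0 < self.rh_threshold <= 1:
            raise PipelineError("rh_threshold outside (0, 1]")
        if not 0 <= self.marker_call_rate_cutoff <= 1:
            raise PipelineError("marker_call_rate_cutoff outside [0, 1]")
        if self.rsm_z_threshold <= 0:
            raise PipelineError("rsm_z_threshold must be positive")
        for g in self.gcr_grid:
            if not 0 < g <= 1:
                raise PipelineError(f"gcr target {g} outside (0, 1]")
        if self.rsm_only and self.spacing_only:
            raise PipelineError("rsm_only and spacing_only are mutually exclusive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _digest(matrix: GenotypeMatrix) -> str:
    h = hashlib.sha256()
    h.update(matrix.dosage.tobytes())
    h.update("|".join(map(str, matrix.sample_ids)).encode())
    h.update("|".join(map(str, matrix.marker_ids)).encode())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every configured stage; returns the manifest (also written
    to ``<outdir>/manifest.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": []}

    def record(stage: str, matrix: GenotypeMatrix | None = None, **extra) -> None:
        entry: dict[str, Any] = {"stage": stage, **extra}
        if matrix is not None:
            entry.update(
                n_samples=matrix.n_samples,
                n_markers=matrix.n_markers,
                digest=_digest(matrix),
            )
        manifest["stages"].append(entry)
        logger.info("[%s] %s", stage, {k: v for k, v in entry.items() if k != "stage"})

    try:
        # -- input ------------------------------------------------------
        if config.ped is not None:
            matrix = genotype_io.read_ped_map(config.ped, config.map)
            record("load", matrix, ped=str(config.ped))
        else:
            sim_cfg = SimulationConfig(**{**config.simulation, "seed": config.seed})
            result = simulate(sim_cfg)
            matrix = result.matrix
            result.ground_truth().to_csv(out / "ground_truth.tsv", sep="\t", index=False)
            genotype_io.write_ped_map(matrix, out / "simulated")
            record("simulate", matrix, params={k: str(v) for k, v in config.simulation.items()})

        # -- marker QC --------------------------------------------------
        before = matrix.n_markers
        matrix, dropped = callrate.filter_markers_by_call_rate(
            matrix, config.marker_call_rate_cutoff
        )
        dropped.to_csv(out / "qc_dropped_markers.tsv", sep="\t", index=False)
        record("marker_qc", matrix, cutoff=config.marker_call_rate_cutoff,
               dropped=before - matrix.n_markers)

        # -- recombination-hotspot filter -------------------------------
        if config.rh_filter:
            scan = ld_hotspots.flag_hotspots(
                matrix, flank=config.rh_flank, threshold=config.rh_threshold
            )
            ld_hotspots.hotspot_table(scan, matrix).to_csv(
                out / "hotspots.tsv", sep="\t", index=False
            )
            before = matrix.n_markers
            matrix = ld_hotspots.remove_hotspots(matrix, scan)
            record("rh_filter", matrix, flank=config.rh_flank,
                   threshold=config.rh_threshold, dropped=before - matrix.n_markers)

        # -- marker restriction -----------------------------------------
        if config.rsm_only:
            table = rsm.marker_variance_table(matrix)
            table = rsm.select_rsm(table, config.rsm_z_threshold)
            table = rsm.thin_by_distance(table, config.thin_bp)
            table.to_csv(out / "rsm.tsv", sep="\t", index=False)
            keep_ids = set(rsm.rsm_marker_ids(table))
            keep = np.asarray([m in keep_ids for m in matrix.marker_ids])
            before = matrix.n_markers
            matrix = matrix.subset_markers(np.flatnonzero(keep))
            record("rsm_restrict", matrix, z=config.rsm_z_threshold,
                   dropped=before - matrix.n_markers)
        elif config.spacing_only:
            table = rsm.marker_variance_table(matrix)
            table["selected"] = True  # spacing applies to the whole panel
            table = rsm.thin_by_distance(table, config.thin_bp)
            keep_ids = set(rsm.rsm_marker_ids(table))
            keep = np.asarray([m in keep_ids for m in matrix.marker_ids])
            before = matrix.n_markers
            matrix = matrix.subset_markers(np.flatnonzero(keep))
            record("spacing", matrix, thin_bp=config.thin_bp,
                   dropped=before - matrix.n_markers)

        # -- call-rate degradation grid ---------------------------------
        datasets = {"data0": matrix}
        for k, target in enumerate(config.gcr_grid, start=1):
            degraded = callrate.degrade_call_rate(matrix, target, seed=config.seed + k)
            degraded, _ = callrate.filter_markers_by_call_rate(
                degraded, config.degraded_call_rate_cutoff
            )
            datasets[f"data{k}"] = degraded
            record(f"degrade_data{k}", degraded, target_gcr=target,
                   marker_cutoff=config.degraded_call_rate_cutoff)

        # -- structure analyses per dataset -----------------------------
        summaries = {}
        for name, mat in datasets.items():
            dist = distances.distance_matrix(mat, metric="IBS")
            genotype_io.write_distance_phylip(dist, out / f"{name}_ibs.phylip")
            k = min(config.k_components, mat.n_samples - 1)
            mds = projection.classical_mds(dist, k)
            pca = projection.snp_pca(mat, k)
            genotype_io.write_embedding_tsv(mds, mat.pop_labels, out / f"{name}_mds.tsv")
            genotype_io.write_embedding_tsv(pca, mat.pop_labels, out / f"{name}_pca.tsv")
            tree_dist = (
                distances.population_centroid_distances(dist, mat.pop_labels)
                if config.population_tree
                else dist
            )
            if tree_dist.n >= 3:
                tree = njtree.neighbor_joining(tree_dist)
                (out / f"{name}_nj.nwk").write_text(njtree.to_newick(tree) + "\n")
            fst = popstats.wc_fst(mat)
            drift = popstats.drift_table(popstats.monomorphic_drift(mat))
            drift.to_csv(out / f"{name}_drift.tsv", sep="\t", index=False)
            sep = projection.embedding_separation(mds.coordinates, mat.pop_labels)
            summaries[name] = {
                "mean_fst": fst.mean,
                "mds_separation": sep,
                "n_markers": mat.n_markers,
                "n_samples": mat.n_samples,
            }
            record(f"analyse_{name}", mat, mean_fst=fst.mean, mds_separation=sep)
        manifest["summaries"] = summaries
    except Exception as exc:  # annotate failing stage, keep partial manifest
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "init"
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(
            f"pipeline failed after stage {stage!r}: {exc} "
            f"(partial manifest: {out / 'manifest.partial.json'})"
        ) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
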