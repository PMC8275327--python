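"""End-to-end skinning pipeline.

morphology -> adaptive resample -> skin (soma / arbors / endfeet) ->
blend -> polygonize -> prune interior partition (hybrid soma) ->
visual branch (decimate) / simulation branch (repair to watertight) ->
write meshes + QC reports.

The polygonization resolution follows the fragmentation-avoidance rule:
the minimum effective surface radius over every meta-component (skeleton
sample radii and endfoot half-thicknesses), clamped between a hard floor
and an optional user cap.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from astroskin import meshops
from astroskin.endfeet import SubdivisionSpec, required_levels, skin_endfoot, subdivide_patch
from astroskin.metaballs import ISO_LEVEL, MetaObject, blend, polygonize, skin_arbor
from astroskin.morphology import AstrocyteMorphology, read_endfeet_sidecar, read_swc
from astroskin.resampling import ResamplingPolicy, resample_morphology
from astroskin.soma import (
    SoftBodyParams,
    simulate_soma_surface,
    skin_soma_hybrid,
    skin_soma_marching,
    uniform_remesh,
)

log = logging.getLogger("astroskin")


@dataclass
class PipelineConfig:
    soma_method: str = "marching"  # "marching" | "hybrid"
    resample_factor: float = 1.0
    step_factor: float = 1.0
    iso_level: float = ISO_LEVEL
    resolution_cap: float | None = None  # µm; upper bound on grid spacing
    resolution_floor: float = 0.05  # µm; guard against pathological grids
    endfoot_subdiv: str | int = "auto"
    endfoot_subdiv_mode: str = "simple"
    thickness_is_radius: bool = False
    outputs: tuple[str, ...] = ("visual", "simulation")
    decimate_ratio: float = 0.1
    softbody: SoftBodyParams = field(default_factory=SoftBodyParams)
    n_workers: int = 1
    seed: int = 0
    check_self_intersections: bool = True

    def __post_init__(self):
        if self.soma_method not in ("marching", "hybrid"):
            raise ValueError("soma_method must be 'marching' or 'hybrid'")
        bad = set(self.outputs) - {"visual", "simulation"}
        if bad or not self.outputs:
            raise ValueError("outputs must be a non-empty subset of {visual, simulation}")

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        return json.dumps(doc, indent=2, default=str)


def _pipeline_resolution(m: AstrocyteMorphology, cfg: PipelineConfig) -> float:
    """Grid spacing: min effective surface radius over all meta-components."""
    r = m.min_radius()
    for patch in m.endfeet:
        t = float(patch.thickness.min())
        r = min(r, t if cfg.thickness_is_radius else 0.5 * t)
    if cfg.resolution_cap is not None:
        r = min(r, cfg.resolution_cap)
    return max(r, cfg.resolution_floor)


def build_meta_object(
    m: AstrocyteMorphology, cfg: PipelineConfig | None = None
) -> MetaObject:
    """Skin every component of a (resampled) morphology and blend."""
    cfg = cfg or PipelineConfig()
    resolution = _pipeline_resolution(m, cfg)
    parts: list[MetaObject] = []

    arbor_roots = [a.root_sample for a in m.arbors]
    if cfg.soma_method == "marching":
        parts.append(skin_soma_marching(m.soma, arbor_roots, cfg.step_factor))
    else:
        surf = simulate_soma_surface(
            m.soma, arbor_roots, cfg.softbody, seed=cfg.seed
        )
        spacing = max(0.8 * resolution, 0.08 * m.soma.radius)
        cloud = uniform_remesh(surf, spacing, seed=cfg.seed)
        parts.append(skin_soma_hybrid(cloud))

    for arbor in m.arbors:
        parts.append(skin_arbor(arbor, cfg.step_factor))

    for patch in m.endfeet:
        if cfg.endfoot_subdiv == "auto":
            levels = required_levels(patch)
        else:
            levels = int(cfg.endfoot_subdiv)
        sub = subdivide_patch(
            patch, SubdivisionSpec(levels=levels, mode=cfg.endfoot_subdiv_mode)
        )
        parts.append(skin_endfoot(sub, thickness_is_radius=cfg.thickness_is_radius))

    mo = blend(parts)
    mo.resolution = resolution
    return mo


def mesh_morphology(
    m: AstrocyteMorphology, cfg: PipelineConfig | None = None
) -> tuple[trimesh.Trimesh, dict]:
    """Run the skinning core on one morphology.

    Returns the pruned, single-partition polygonized mesh plus a stage
    log (counts, timings, partition bookkeeping).  Decimation/repair are
    applied by :func:`run_pipeline` per output branch.
    """
    cfg = cfg or PipelineConfig()
    info: dict = {"stages": []}

    def stage(name, fn):
        t0 = time.perf_counter()
        out = fn()
        info["stages"].append({"stage": name, "seconds": time.perf_counter() - t0})
        return out

    resampled = stage(
        "resample",
        lambda: resample_morphology(m, ResamplingPolicy(cfg.resample_factor)),
    )
    mo = stage("skin", lambda: build_meta_object(resampled, cfg))
    info["n_balls"] = len(mo)
    info["resolution"] = mo.resolution
    mesh = stage("polygonize", lambda: polygonize(mo, cfg.iso_level))
    info["n_triangles_raw"] = len(mesh.faces)

    parts = meshops.split_partitions(mesh)
    info["partition_count_raw"] = len(parts)
    if cfg.soma_method == "hybrid" and len(parts) == 2:
        mesh = stage("prune_interior", lambda: meshops.remove_interior_partition(mesh))
    elif len(parts) > 1:
        log.warning(
            "polygonization produced %d partitions; keeping the largest",
            len(parts),
        )
        mesh = parts[0]
    info["n_triangles"] = len(mesh.faces)
    return mesh, info


def run_pipeline(
    cfg: PipelineConfig,
    morphology_paths: list,
    out_dir: str | Path,
) -> dict:
    """Batch driver: per morphology, write branch meshes + QC reports.

    ``morphology_paths`` entries are either SWC paths or (swc, sidecar)
    pairs.  Failures are isolated per morphology; the returned run report
    carries per-file status, and ``ok`` is False when any simulation-branch
    output misses watertightness.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "resolved_config.json").write_text(cfg.to_json())

    jobs = []
    for entry in morphology_paths:
        if isinstance(entry, (tuple, list)):
            jobs.append((Path(entry[0]), Path(entry[1]) if entry[1] else None))
        else:
            jobs.append((Path(entry), None))

    def process(swc_path: Path, sidecar: Path | None) -> dict:
        name = swc_path.stem
        record: dict = {"morphology": name, "ok": True, "outputs": {}}
        try:
            m = read_swc(swc_path)
            if sidecar is not None:
                m.endfeet = read_endfeet_sidecar(sidecar)
            mesh, info = mesh_morphology(m, cfg)
            record["skinning"] = info
            if "visual" in cfg.outputs:
                t0 = time.perf_counter()
                visual = meshops.decimate(mesh, cfg.decimate_ratio)
                path = out_dir / f"{name}_visual.obj"
                meshops.write_mesh(visual, path)
                qc = meshops.mesh_metrics(
                    visual, check_self_intersections=False
                )
                qc.to_json(out_dir / f"{name}_visual_qc.json")
                record["outputs"]["visual"] = {
                    "mesh": str(path),
                    "n_triangles": len(visual.faces),
                    "seconds": time.perf_counter() - t0,
                }
            if "simulation" in cfg.outputs:
                t0 = time.perf_counter()
                sim = meshops.repair_watertight(mesh)
                path = out_dir / f"{name}_simulation.obj"
                meshops.write_mesh(sim, path)
                qc = meshops.mesh_metrics(
                    sim, check_self_intersections=cfg.check_self_intersections
                )
                qc.to_json(out_dir / f"{name}_simulation_qc.json")
                record["outputs"]["simulation"] = {
                    "mesh": str(path),
                    "n_triangles": len(sim.faces),
                    "watertight": qc.watertight,
                    "seconds": time.perf_counter() - t0,
                }
                if not qc.watertight:
                    record["ok"] = False
        except Exception as exc:  # isolate per-morphology failures
            log.exception("pipeline failed for %s", name)
            record["ok"] = False
            record["error"] = str(exc)
        return record

    if cfg.n_workers > 1:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=cfg.n_workers)(
            delayed(process)(swc, sc) for swc, sc in jobs
        )
    else:
        records = [process(swc, sc) for swc, sc in jobs]

    report = {"ok": all(r["ok"] for r in records), "morphologies": records}
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
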