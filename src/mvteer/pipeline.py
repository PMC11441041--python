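"""End-to-end orchestration: synthesize/load -> calibrate -> clip -> metrics.

Mirrors the simulation chain of the planning workflow: build (or read) the
segmented-valve data model, generate chordae, optionally calibrate the
native closed shape against a target systolic surface, simulate the
pre-clip systole/diastole, implant the clip(s), re-simulate, and quantify
ERO / MVA / orifice topology. Every stage persists its artifact, runs are
resumable from persisted stages, and a fixed seed makes the metrics JSON
byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import calibration as cal
from .chordae import ChordalApparatus, apply_prestretch, generate_chordae
from .errors import MVTeerError, ParameterError
from .geometry import (SynthValveConfig, ValveGeometry, generate_synthetic_valve,
                       read_valve, write_valve)
from .material import FungParams
from .metrics import detect_orifices, coaptation_height, total_ero, mva
from .solver import SolverConfig, simulate_closure, simulate_opening
from .teer import ClipPlacement, device_by_name, implant_clips

log = logging.getLogger("mvteer")


@dataclass
class PipelineConfig:
    """Declarative description of one simulation run."""

    out_dir: str = "mvteer_run"
    seed: int = 0
    synthetic: dict = field(default_factory=dict)   # SynthValveConfig overrides
    mesh_path: str | None = None                    # alternative: load a mesh
    landmark_path: str | None = None
    material: dict = field(default_factory=dict)    # FungParams overrides
    solver: dict = field(default_factory=dict)      # SolverConfig overrides
    chordae: dict = field(default_factory=dict)     # generate_chordae kwargs
    calibration: dict = field(default_factory=dict) # {target_mesh, alpha, max_iter, tune_prestretch}
    placements: list = field(default_factory=list)  # [{"device","position","grip_fraction"}]
    annular_reduction: float = 1.0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        elif path.suffix == ".json":
            data = json.loads(path.read_text())
        else:
            raise ParameterError(f"config must be .toml or .json, got {path.suffix}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir, "seed": self.seed,
            "synthetic": dict(self.synthetic), "mesh_path": self.mesh_path,
            "landmark_path": self.landmark_path, "material": dict(self.material),
            "solver": dict(self.solver), "chordae": dict(self.chordae),
            "calibration": dict(self.calibration),
            "placements": [dict(p) for p in self.placements],
            "annular_reduction": self.annular_reduction,
            "log_level": self.log_level,
        }

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    config: dict
    config_hash: str
    stages: dict = field(default_factory=dict)   # name -> {status, seconds, artifact}
    pre_metrics: dict | None = None
    post_metrics: dict | None = None
    calibration_report: dict | None = None
    error: str | None = None

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config, "config_hash": self.config_hash,
            "stages": self.stages, "pre_metrics": self.pre_metrics,
            "post_metrics": self.post_metrics,
            "calibration_report": self.calibration_report,
            "error": self.error,
        }, indent=1, sort_keys=True)


# Default study conditions: a dilated, tethered functional-regurgitation
# valve treated with one wide long-arm clip at the central coaptation line.
DEFAULT_REGURGITANT = {
    "dilation_factor": 1.5,
    "tethering_displacement": (0.0, -3.0, -8.0),
    "mesh_edge_length": 2.5,
}


def default_config(out_dir: str = "mvteer_run", seed: int = 0) -> PipelineConfig:
    return PipelineConfig(
        out_dir=out_dir, seed=seed, synthetic=dict(DEFAULT_REGURGITANT),
        placements=[{"device": "NTW", "position": 0.5, "grip_fraction": 0.70}],
    )


def _save_positions(path: Path, geometry: ValveGeometry, positions: np.ndarray):
    from .geometry import _write_vtk_polydata
    _write_vtk_polydata(path, positions, geometry.triangles)


def _load_positions(path: Path):
    from .geometry import _read_vtk_polydata
    pts, _ = _read_vtk_polydata(path)
    return pts


class _FrozenState:
    """Minimal stand-in for a SimulationState restored from disk."""

    def __init__(self, positions, phase):
        self.positions = positions
        self.phase = phase
        self.converged = True


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """Execute all stages, persisting artifacts under ``config.out_dir``.

    A stage whose artifact already exists for the same configuration hash
    is loaded rather than recomputed, so a completed run is a no-op and a
    failed run resumes at the failed stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(config=config.to_dict(), config_hash=config.content_hash())
    hash_file = out / "config_hash.txt"
    reuse = hash_file.exists() and hash_file.read_text() == record.config_hash
    hash_file.write_text(record.config_hash)

    def stage(name, artifact, compute, load):
        t0 = time.perf_counter()
        path = out / artifact if artifact else None
        try:
            if reuse and path is not None and path.exists():
                result = load(path)
                status = "cached"
            else:
                result = compute(path)
                status = "completed"
        except MVTeerError as e:
            record.stages[name] = {"status": "failed", "seconds": round(
                time.perf_counter() - t0, 3), "error": str(e)}
            record.error = f"{name}: {e}"
            log.error("stage %s failed: %s", name, e)
            raise _StageFailure() from e
        record.stages[name] = {
            "status": status, "seconds": round(time.perf_counter() - t0, 3),
            "artifact": str(path) if path else None}
        log.info("stage %-14s %s (%.2fs)", name, status,
                 record.stages[name]["seconds"])
        return result

    try:
        return _run_stages(config, record, out, stage)
    except _StageFailure:
        (out / "run_record.json").write_text(record.to_json())
        return record


class _StageFailure(Exception):
    pass


def _run_stages(config, record, out, stage):
    # -- geometry ----------------------------------------------------------
    def make_geometry(path):
        if config.mesh_path:
            if not Path(config.mesh_path).exists():
                raise ParameterError(f"mesh path {config.mesh_path} does not exist")
            g = read_valve(config.mesh_path, config.landmark_path)
        else:
            syn = dict(config.synthetic)
            syn.setdefault("seed", config.seed)
            g = generate_synthetic_valve(SynthValveConfig.from_dict(syn))
        write_valve(g, path, out / "valve_landmarks.json")
        return g

    geometry = stage("geometry", "valve.vtk", make_geometry,
                     lambda p: read_valve(p, out / "valve_landmarks.json"))

    params = FungParams.from_dict({**FungParams().to_dict(), **config.material})
    solver_cfg = SolverConfig.from_dict({**SolverConfig().to_dict(),
                                         "seed": config.seed, **config.solver})

    # -- chordae -----------------------------------------------------------
    def make_chordae(path):
        app = generate_chordae(geometry, **config.chordae)
        path.write_text(app.to_json())
        return app

    apparatus = stage("chordae", "chordae.json", make_chordae,
                      lambda p: ChordalApparatus.from_json(p.read_text()))

    # -- optional native-shape calibration --------------------------------
    corrective = None
    if config.calibration.get("target_mesh"):
        def run_calibration(path):
            target = trimesh.load(config.calibration["target_mesh"], process=False)
            app = apparatus
            lam0 = None
            if config.calibration.get("tune_prestretch", True):
                app, lam0, _ = cal.tune_chordal_prestretch(
                    geometry, apparatus, params, target,
                    solver_config=solver_cfg)
            fieldp, st, report = cal.calibrate_to_closed_shape(
                geometry, app, params, target,
                alpha=config.calibration.get("alpha", cal.DEFAULT_ALPHA),
                max_iter=config.calibration.get("max_iter", cal.DEFAULT_MAX_ITER),
                solver_config=solver_cfg)
            doc = {"p": fieldp.p.tolist(), "alpha": fieldp.alpha,
                   "prestretch": lam0,
                   "report": {"iterations": report.iterations,
                              "mean_distance": report.mean_distance,
                              "converged": report.converged,
                              "threshold": report.threshold}}
            path.write_text(json.dumps(doc, indent=1))
            return doc

        doc = stage("calibration", "corrective_field.json", run_calibration,
                    lambda p: json.loads(p.read_text()))
        corrective = np.asarray(doc["p"])
        record.calibration_report = doc["report"]
        if doc.get("prestretch"):
            apparatus = apply_prestretch(apparatus, doc["prestretch"])

    # -- pre-clip simulation ----------------------------------------------
    pre_sys = stage(
        "pre_systole", "pre_systole.vtk",
        lambda p: _persist(simulate_closure(geometry, apparatus, params,
                                            solver_cfg, corrective=corrective),
                           p, geometry),
        lambda p: _FrozenState(_load_positions(p), "systole"))
    pre_dia = stage(
        "pre_diastole", "pre_diastole.vtk",
        lambda p: _persist(simulate_opening(geometry, apparatus, params,
                                            solver_cfg), p, geometry),
        lambda p: _FrozenState(_load_positions(p), "diastole"))

    record.pre_metrics = _metrics_dict(pre_sys, pre_dia, geometry)

    # -- clip implantation -------------------------------------------------
    if config.placements:
        placements = [
            ClipPlacement(device_by_name(p["device"]), p.get("position", 0.5),
                          p.get("grip_fraction", 0.70))
            for p in config.placements]

        def do_implant(path):
            sys_st, dia_st, _ = implant_clips(
                geometry, apparatus, params, placements, solver_cfg,
                annular_reduction_factor=config.annular_reduction,
                corrective=corrective)
            _persist(sys_st, out / "post_systole.vtk", geometry)
            _persist(dia_st, out / "post_diastole.vtk", geometry)
            return sys_st, dia_st

        post_sys, post_dia = stage(
            "clip", "post_systole.vtk", do_implant,
            lambda p: (_FrozenState(_load_positions(p), "systole"),
                       _FrozenState(_load_positions(out / "post_diastole.vtk"),
                                    "diastole")))
        record.post_metrics = _metrics_dict(post_sys, post_dia, geometry)

    metrics_doc = {"pre": record.pre_metrics, "post": record.post_metrics,
                   "seed": config.seed}
    (out / "metrics.json").write_text(json.dumps(metrics_doc, indent=1,
                                                 sort_keys=True))
    (out / "run_record.json").write_text(record.to_json())
    return record


def _persist(state, path, geometry):
    _save_positions(path, geometry, state.positions)
    return state


def _round(x, nd=6):
    return float(np.round(x, nd))


def _metrics_dict(sys_state, dia_state, geometry) -> dict:
    sys_or = detect_orifices(sys_state, geometry)
    dia_or = detect_orifices(dia_state, geometry)
    coapt, _ = coaptation_height(sys_state, geometry)
    return {
        "total_ero_cm2": _round(total_ero(sys_or)),
        "mva_cm2": _round(mva(dia_or)),
        "orifice_count_systole": len(sys_or),
        "orifice_count_diastole": len(dia_or),
        "coaptation_height_mm": _round(coapt),
    }


# ---------------------------------------------------------------------------
# fixture suite
# ---------------------------------------------------------------------------

def make_elliptical_orifice_disc(semi_major: float = 3.0, semi_minor: float = 1.0,
                                 outer_radius: float = 15.0, edge: float = 1.0):
    """Flat disc with a machined elliptical hole, wrapped as a ValveGeometry.

    A synthetic stand-in for a closed valve with a residual orifice of a
    known analytic area (pi * a * b); used to validate orifice detection.
    """
    from scipy.spatial import Delaunay
    from .geometry import (ANTERIOR, POSTERIOR, ValveFrame, ValveGeometry)

    pts = []
    dy = edge * np.sqrt(3) / 2
    ny = int(np.ceil(2 * outer_radius / dy)) + 1
    nx = int(np.ceil(2 * outer_radius / edge)) + 1
    for j in range(-ny, ny + 1):
        y = j * dy
        off = 0.5 * edge if j % 2 else 0.0
        for i in range(-nx, nx + 1):
            x = i * edge + off
            r2 = x * x + y * y
            in_hole = (x / (semi_major + 0.55 * edge)) ** 2 + \
                      (y / (semi_minor + 0.55 * edge)) ** 2 < 1.0
            if r2 < (outer_radius - 0.6 * edge) ** 2 and not in_hole:
                pts.append((x, y))
    n_out = max(16, int(np.ceil(2 * np.pi * outer_radius / edge)))
    th = 2 * np.pi * np.arange(n_out) / n_out
    outer = np.column_stack([outer_radius * np.cos(th), outer_radius * np.sin(th)])
    per_e = np.pi * (3 * (semi_major + semi_minor) -
                     np.sqrt((3 * semi_major + semi_minor) * (semi_major + 3 * semi_minor)))
    n_in = max(16, int(np.ceil(per_e / (0.5 * edge))))
    th = 2 * np.pi * (np.arange(n_in) + 0.5) / n_in
    inner = np.column_stack([semi_major * np.cos(th), semi_minor * np.sin(th)])
    pts = np.vstack([np.asarray(pts), outer, inner])
    tri = Delaunay(pts)
    simplices = tri.simplices
    cen = pts[simplices].mean(axis=1)
    keep = (cen[:, 0] / semi_major) ** 2 + (cen[:, 1] / semi_minor) ** 2 > 1.0
    simplices = simplices[keep]
    p = pts[simplices]
    area2 = np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) -
                   (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    simplices = simplices[area2 > 1e-9]

    vertices = np.column_stack([pts, np.zeros(len(pts))])
    labels = np.where(vertices[simplices].mean(axis=1)[:, 1] > 0,
                      ANTERIOR, POSTERIOR).astype(object)
    # ensure both labels exist
    if (labels == ANTERIOR).sum() == 0 or (labels == POSTERIOR).sum() == 0:
        labels[:] = ANTERIOR
        labels[len(labels) // 2:] = POSTERIOR
    out_start = len(pts) - n_out - n_in
    annulus_ids = np.arange(out_start, out_start + n_out)
    inner_ids = np.arange(out_start + n_out, out_start + n_out + n_in)
    free = {ANTERIOR: inner_ids[vertices[inner_ids, 1] >= 0],
            POSTERIOR: inner_ids[vertices[inner_ids, 1] < 0]}
    frame = ValveFrame(origin=np.zeros(3), axial_axis=np.array([0.0, 0, 1]),
                       commissural_axis=np.array([0.0, 1, 0]),
                       septal_lateral_axis=np.array([1.0, 0, 0]))
    tips = {lab: {ph: np.array([0.0, s, -18.0]) for ph in
                  ("end_diastole", "early_systole")}
            for lab, s in (("anterolateral", 9.0), ("posteromedial", -9.0))}
    return ValveGeometry(
        vertices=vertices, triangles=np.asarray(simplices, dtype=np.int64),
        leaflet_label=labels, annulus_vertex_ids=annulus_ids,
        free_edge_vertex_ids=free, papillary_tips=tips,
        thickness=np.ones(len(vertices)), frame=frame, mesh_edge_length=edge)


def generate_fixture_suite(out_dir, seed: int = 0,
                           mesh_edge_length: float | None = None) -> dict:
    """Write the standard test fixtures and their ground-truth manifest.

    Fixtures: healthy valve, regurgitant valve, flat benchmark membrane,
    machined-ellipse orifice disc, and a forward-run calibration target
    with a hidden corrective field and known chordal pre-stretch.
    """
    from .solver import make_circular_membrane
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "fixtures": {}}
    base = dict(DEFAULT_REGURGITANT)
    if mesh_edge_length is not None:
        base["mesh_edge_length"] = mesh_edge_length

    healthy_cfg = SynthValveConfig.from_dict({**base,
                                              "dilation_factor": 1.0,
                                              "tethering_displacement": (0, 0, 0),
                                              "seed": seed})
    g_h = generate_synthetic_valve(healthy_cfg)
    write_valve(g_h, out / "healthy.vtk", out / "healthy_landmarks.json")
    manifest["fixtures"]["healthy_valve"] = {
        "mesh": "healthy.vtk", "landmarks": "healthy_landmarks.json",
        "config": healthy_cfg.to_dict(), "expected_ero_cm2": 0.0}

    reg_cfg = SynthValveConfig.from_dict({**base, "seed": seed})
    g_r = generate_synthetic_valve(reg_cfg)
    write_valve(g_r, out / "regurgitant.vtk", out / "regurgitant_landmarks.json")

    params, scfg = FungParams(), SolverConfig(seed=seed)
    app_r = generate_chordae(g_r)
    st = simulate_closure(g_r, app_r, params, scfg)
    ors = detect_orifices(st, g_r)
    _save_positions(out / "regurgitant_closed.vtk", g_r, st.positions)
    manifest["fixtures"]["regurgitant_valve"] = {
        "mesh": "regurgitant.vtk", "landmarks": "regurgitant_landmarks.json",
        "closed_state": "regurgitant_closed.vtk", "config": reg_cfg.to_dict(),
        "ero_cm2": _round(total_ero(ors))}

    v, t, rim = make_circular_membrane(radius=10.0, edge=1.0)
    np.savetxt(out / "membrane_vertices.txt", v)
    np.savetxt(out / "membrane_triangles.txt", t, fmt="%d")
    manifest["fixtures"]["benchmark_membrane"] = {
        "vertices": "membrane_vertices.txt", "triangles": "membrane_triangles.txt",
        "radius_mm": 10.0, "n_rim": len(rim)}

    disc = make_elliptical_orifice_disc()
    write_valve(disc, out / "ellipse_disc.vtk", out / "ellipse_disc_landmarks.json")
    manifest["fixtures"]["ellipse_orifice_disc"] = {
        "mesh": "ellipse_disc.vtk", "landmarks": "ellipse_disc_landmarks.json",
        "analytic_area_cm2": _round(np.pi * 3.0 * 1.0 / 100.0)}

    # forward-run calibration truth: closure with a hidden corrective field
    rng = np.random.default_rng(seed)
    lam0 = 1.05
    app_t = apply_prestretch(app_r, lam0)
    centroids = g_r.vertices[g_r.triangles].mean(axis=1)
    yy = g_r.frame.to_local(centroids)[:, 1]
    hidden = 4.0 * np.exp(-(yy / 10.0) ** 2)        # smooth central push, kPa
    st_t = simulate_closure(g_r, app_t, params, scfg, corrective=hidden)
    _save_positions(out / "calibration_target.vtk", g_r, st_t.positions)
    np.savetxt(out / "hidden_corrective.txt", hidden)
    manifest["fixtures"]["calibration_target"] = {
        "target": "calibration_target.vtk", "hidden_corrective": "hidden_corrective.txt",
        "true_prestretch": lam0, "base_mesh": "regurgitant.vtk"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
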