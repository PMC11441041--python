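"""Inverse calibration of the native closed valve.

The simulated closed leaflets are driven onto a target (image-derived)
closed surface by a local corrective pressure field: each element carries
an extra pressure increment updated per iteration by

    p_new = p_old + delta * alpha * ||d||

where d is the shortest vector from the element centroid to the target
surface, alpha (kPa/mm) is a constant correction coefficient, and
delta = d.n / |d.n| in {-1, +1} picks the push direction from the element
normal n. Iteration stops when the area-weighted mean distance between the
simulated and target closed surfaces falls below the average leaflet
thickness — the convergence yardstick of the underlying imaging problem.

Chordal pre-stretch is tuned first (a bounded scalar line search on the
free-margin mismatch), then the corrective field is calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .chordae import ChordalApparatus, apply_prestretch
from .errors import ConvergenceError, ParameterError
from .geometry import ValveGeometry
from .material import FungParams
from .solver import SimulationState, SolverConfig, simulate_closure

DEFAULT_ALPHA = 0.25          # kPa/mm
DEFAULT_MAX_ITER = 50


@dataclass
class DistanceField:
    """Per-element shortest vectors to the target surface."""

    d: np.ndarray           # (m, 3) mm, element centroid -> nearest target point
    normals: np.ndarray     # (m, 3) current element unit normals
    delta: np.ndarray       # (m,) in {-1, +1}

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.d, axis=1)


@dataclass
class CorrectiveField:
    """Per-element corrective pressure increments (kPa)."""

    p: np.ndarray
    alpha: float = DEFAULT_ALPHA
    iteration: int = 0

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ParameterError(f"alpha must be positive, got {self.alpha}")


@dataclass
class CalibrationReport:
    iterations: int
    mean_distance: list          # mm, one entry per iteration
    converged: bool
    threshold: float             # mm (average leaflet thickness)


# ---------------------------------------------------------------------------
# distance field
# ---------------------------------------------------------------------------

def nearest_on_surface(target: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Vertex/edge/face-accurate nearest points on a triangulated surface.

    Exact minimum over all target triangles (vectorised clamped-barycentric
    projection, chunked to bound memory).
    """
    from .solver import _point_triangle_closest
    points = np.asarray(points, dtype=float)
    faces = np.asarray(target.faces)
    if len(faces) == 0:
        raise ParameterError("target surface has no triangles")
    tri_pts = np.asarray(target.vertices, dtype=float)[faces]   # (m, 3, 3)
    m = len(tri_pts)
    best = np.full(len(points), np.inf)
    out = np.zeros_like(points)
    chunk = max(1, int(2e6) // max(m, 1))
    for s in range(0, len(points), chunk):
        pts = points[s:s + chunk]
        n = len(pts)
        rep_p = np.repeat(pts, m, axis=0)
        rep_t = np.tile(tri_pts, (n, 1, 1))
        closest, _ = _point_triangle_closest(rep_p, rep_t)
        d2 = np.sum((rep_p - closest) ** 2, axis=1).reshape(n, m)
        k = np.argmin(d2, axis=1)
        out[s:s + chunk] = closest.reshape(n, m, 3)[np.arange(n), k]
        best[s:s + chunk] = np.sqrt(d2[np.arange(n), k])
    return out


def signed_distance_field(fe_positions: np.ndarray, triangles: np.ndarray,
                          target: trimesh.Trimesh) -> DistanceField:
    """Shortest vectors from FE element centroids to the target surface.

    delta is +1 where d has a positive component along the element normal
    (push forward), -1 where negative, and +1 at the degenerate d.n = 0.
    """
    fe_positions = np.asarray(fe_positions, dtype=float)
    centroids = fe_positions[triangles].mean(axis=1)
    nearest = nearest_on_surface(target, centroids)
    d = nearest - centroids
    n = np.cross(fe_positions[triangles[:, 1]] - fe_positions[triangles[:, 0]],
                 fe_positions[triangles[:, 2]] - fe_positions[triangles[:, 0]])
    n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-30)
    dn = np.sum(d * n, axis=1)
    delta = np.where(dn >= 0.0, 1.0, -1.0)
    return DistanceField(d=d, normals=n, delta=delta)


def update_corrective_pressure(field: CorrectiveField,
                               dist: DistanceField) -> CorrectiveField:
    """One corrective-pressure update: p += delta * alpha * ||d|| per element."""
    if len(field.p) != len(dist.d):
        raise ParameterError(
            f"corrective field has {len(field.p)} elements, "
            f"distance field {len(dist.d)}")
    p_new = field.p + dist.delta * field.alpha * dist.magnitude
    return CorrectiveField(p=p_new, alpha=field.alpha, iteration=field.iteration + 1)


def _area_weighted_mean_distance(positions, triangles, target) -> float:
    dist = signed_distance_field(positions, triangles, target)
    areas = 0.5 * np.linalg.norm(np.cross(
        positions[triangles[:, 1]] - positions[triangles[:, 0]],
        positions[triangles[:, 2]] - positions[triangles[:, 0]]), axis=1)
    return float(np.sum(areas * dist.magnitude) / np.sum(areas))


# ---------------------------------------------------------------------------
# calibration loops
# ---------------------------------------------------------------------------

def calibrate_to_closed_shape(geometry: ValveGeometry, apparatus: ChordalApparatus,
                              params: FungParams, target_surface: trimesh.Trimesh,
                              alpha: float = DEFAULT_ALPHA,
                              max_iter: int = DEFAULT_MAX_ITER,
                              solver_config: SolverConfig | None = None):
    """Iterate closure / distance / pressure-update until the closed shape matches.

    Returns (CorrectiveField, SimulationState, CalibrationReport). The
    convergence threshold is the average leaflet thickness. Raises a
    diagnostic error when the mean distance grows five iterations in a row
    (alpha too large for the geometry).
    """
    cfg = solver_config or SolverConfig()
    threshold = geometry.mean_thickness
    field = CorrectiveField(p=np.zeros(len(geometry.triangles)), alpha=alpha)
    field.validate()

    history = []
    state = None
    grow_streak = 0
    positions = None
    for it in range(max_iter + 1):
        try:
            state = simulate_closure(geometry, apparatus, params, cfg,
                                     corrective=field.p,
                                     initial_positions=positions)
        except ConvergenceError:
            state = simulate_closure(geometry, apparatus, params, cfg,
                                     corrective=field.p)
        positions = state.positions    # warm-start the next iteration
        md = _area_weighted_mean_distance(state.positions, geometry.triangles,
                                          target_surface)
        history.append(md)
        if md < threshold:
            return field, state, CalibrationReport(
                iterations=it, mean_distance=history, converged=True,
                threshold=threshold)
        if len(history) >= 2 and md > history[-2]:
            grow_streak += 1
            if grow_streak >= 5:
                raise ConvergenceError(
                    f"calibration diverging (mean distance grew 5 iterations "
                    f"in a row, now {md:.3f} mm); try a smaller alpha",
                    history=history)
        else:
            grow_streak = 0
        if it == max_iter:
            break
        dist = signed_distance_field(state.positions, geometry.triangles,
                                     target_surface)
        field = update_corrective_pressure(field, dist)
    return field, state, CalibrationReport(
        iterations=max_iter, mean_distance=history, converged=False,
        threshold=threshold)


def tune_chordal_prestretch(geometry: ValveGeometry, apparatus: ChordalApparatus,
                            params: FungParams, target_surface: trimesh.Trimesh,
                            bounds: tuple = (1.0, 1.15),
                            tol: float = 5e-3,
                            solver_config: SolverConfig | None = None):
    """Tune the chordal pre-stretch to match the target free-margin position.

    A bounded golden-section search over a shared pre-stretch factor
    minimises the mean free-edge distance to the target surface; the
    result is applied per chorda. Returns (apparatus, lambda0, warning)
    where warning is True when no improvement over the input was possible.
    """
    cfg = solver_config or SolverConfig()
    free_ids = np.concatenate(list(geometry.free_edge_vertex_ids.values()))
    warm = {"pos": None}

    def objective(lam):
        app = apply_prestretch(apparatus, lam)
        try:
            st = simulate_closure(geometry, app, params, cfg,
                                  initial_positions=warm["pos"])
        except ConvergenceError:
            # a warm start from a different pre-stretch can trap the
            # relaxation in a contact limit cycle; retry cold
            st = simulate_closure(geometry, app, params, cfg)
        warm["pos"] = st.positions
        edge = st.positions[free_ids]
        near = nearest_on_surface(target_surface, edge)
        return float(np.mean(np.linalg.norm(near - edge, axis=1)))

    lo, hi = bounds
    if lo < 1.0:
        raise ParameterError("pre-stretch lower bound must be >= 1")
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = objective(x1), objective(x2)
    evals = {x1: f1, x2: f2}
    while b - a > tol:
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = objective(x1)
            evals[x1] = f1
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = objective(x2)
            evals[x2] = f2
    best = min(evals, key=evals.get)
    f_input = objective(max(1.0, min(apparatus.chordae[0].pre_stretch, hi))) \
        if apparatus.chordae else np.inf
    warning = evals[best] >= f_input - 1e-12
    lam0 = float(best) if not warning else float(apparatus.chordae[0].pre_stretch)
    return apply_prestretch(apparatus, lam0), lam0, warning
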