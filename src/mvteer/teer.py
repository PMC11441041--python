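"""Virtual transcatheter edge-to-edge repair: devices, grasp, implantation.

The clip is modelled as a rigid kinematic constraint rather than a
deformable device mesh: bands of leaflet tissue on both leaflets —
extending 70% of the clip arm length from the free edge by default, and
one device width across — are drawn together, then tied rigidly to a
6-degree-of-freedom clip frame that equilibrates under the tissue forces.
Post-clip systole and diastole are then re-simulated with the constraint
active, producing the residual regurgitant orifice(s) and the double- (or
triple-) orifice diastolic geometry.

Device catalog (arm length x width, mm): NTW 9 x 6, XT 12 x 4, XTW 12 x 6,
plus NT 9 x 4 extrapolated from the same two arm lengths and widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .chordae import ChordalApparatus
from .errors import GeometryError, ParameterError
from .geometry import ANTERIOR, POSTERIOR, ValveGeometry
from .material import FungParams
from .solver import (RigidBody, SimulationState, SolverConfig,
                     simulate_closure, simulate_opening)

DEFAULT_GRIP_FRACTION = 0.70
DEFAULT_CLOSED_GAP = 4.0      # mm: two leaflet thicknesses + clip body


@dataclass(frozen=True)
class ClipDevice:
    name: str
    arm_length: float   # mm
    width: float        # mm
    closed_gap: float = DEFAULT_CLOSED_GAP
    extrapolated: bool = False

    def __post_init__(self):
        if self.arm_length not in (9.0, 12.0):
            raise ParameterError(f"arm_length must be 9 or 12 mm, got {self.arm_length}")
        if self.width not in (4.0, 6.0):
            raise ParameterError(f"width must be 4 or 6 mm, got {self.width}")
        if self.closed_gap <= 0:
            raise ParameterError("closed_gap must be positive")


def device_catalog() -> list:
    """The clip family: NTW (9, 6), XT (12, 4), XTW (12, 6); NT (9, 4) is
    the fourth combination of the same arms and widths, flagged
    extrapolated."""
    return [
        ClipDevice("NT", 9.0, 4.0, extrapolated=True),
        ClipDevice("NTW", 9.0, 6.0),
        ClipDevice("XT", 12.0, 4.0),
        ClipDevice("XTW", 12.0, 6.0),
    ]


def device_by_name(name: str) -> ClipDevice:
    for d in device_catalog():
        if d.name == name.upper():
            return d
    raise ParameterError(f"unknown clip device {name!r} (NT, NTW, XT, XTW)")


@dataclass(frozen=True)
class ClipPlacement:
    """Where and how a clip grasps the coaptation line.

    ``coaptation_coordinate`` runs from 0 at the anterolateral commissure
    to 1 at the posteromedial commissure; ``grip_fraction`` is the fraction
    of the arm length that grips leaflet tissue.
    """

    device: ClipDevice
    coaptation_coordinate: float = 0.5
    grip_fraction: float = DEFAULT_GRIP_FRACTION

    def __post_init__(self):
        if not 0.0 <= self.coaptation_coordinate <= 1.0:
            raise ParameterError(
                f"coaptation_coordinate must be in [0, 1], got {self.coaptation_coordinate}")
        if not 0.0 < self.grip_fraction <= 1.0:
            raise ParameterError(
                f"grip_fraction must be in (0, 1], got {self.grip_fraction}")

    @property
    def grasp_depth(self) -> float:
        """Band depth from the free edge (mm) = grip_fraction x arm length."""
        return self.grip_fraction * self.device.arm_length


@dataclass
class GraspSets:
    anterior_node_ids: np.ndarray
    posterior_node_ids: np.ndarray
    clip_frame_origin: np.ndarray
    clip_frame_axes: np.ndarray     # (3, 3) rows: along-coaptation, across, axial


# ---------------------------------------------------------------------------
# grasp-region selection
# ---------------------------------------------------------------------------

def geodesic_depth_from_free_edge(geometry: ValveGeometry, leaflet: str):
    """Geodesic (edge-graph) distance of every leaflet vertex from the free
    edge, plus the index of the nearest free-edge vertex."""
    tris = geometry.leaflet_triangles(leaflet)
    verts = np.unique(tris)
    remap = -np.ones(len(geometry.vertices), dtype=np.int64)
    remap[verts] = np.arange(len(verts))
    edges = np.sort(np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]],
                                    tris[:, [0, 2]]]), axis=1)
    edges = np.unique(edges, axis=0)
    w = np.linalg.norm(geometry.vertices[edges[:, 0]] -
                       geometry.vertices[edges[:, 1]], axis=1)
    n = len(verts)
    i, j = remap[edges[:, 0]], remap[edges[:, 1]]
    adj = csr_matrix((np.concatenate([w, w]),
                      (np.concatenate([i, j]), np.concatenate([j, i]))),
                     shape=(n, n))
    sources = remap[geometry.free_edge_vertex_ids[leaflet]]
    dist, _, src = dijkstra(adj, indices=sources, min_only=True,
                            return_predecessors=True)
    # src holds, for each vertex, the index of the free-edge source vertex
    return verts, dist, src


def _free_edge_coordinate(geometry: ValveGeometry, leaflet: str) -> np.ndarray:
    """Normalised arc-length coordinate along the free edge, oriented from
    the anterolateral (positive commissural axis) end."""
    chain = geometry.free_edge_vertex_ids[leaflet]
    pts = geometry.vertices[chain]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s /= s[-1]
    y = geometry.frame.to_local(pts)[:, 1]
    if y[0] < y[-1]:
        s = 1.0 - s
    return s


def select_grasp_region(geometry: ValveGeometry, placement: ClipPlacement) -> GraspSets:
    """Vertices grasped by the clip arms on each leaflet.

    The band starts at the free edge, extends ``grip_fraction x arm_length``
    toward the annulus (geodesic depth on the leaflet surface), and spans
    one device width along the coaptation line, centred at the requested
    coaptation coordinate.
    """
    depth_limit = placement.grasp_depth
    half_width = 0.5 * placement.device.width
    bands = {}
    for leaflet in (ANTERIOR, POSTERIOR):
        chain = geometry.free_edge_vertex_ids[leaflet]
        s_chain = _free_edge_coordinate(geometry, leaflet)
        chain_len = float(np.sum(np.linalg.norm(
            np.diff(geometry.vertices[chain], axis=0), axis=1)))
        verts, depth, src_idx = geodesic_depth_from_free_edge(geometry, leaflet)
        # lateral position: arc-length coordinate of the geodesically
        # nearest free-edge vertex (dijkstra reports the winning source)
        remap = -np.ones(len(geometry.vertices), dtype=np.int64)
        remap[verts] = np.arange(len(verts))
        s_by_reduced = np.full(len(verts), np.nan)
        s_by_reduced[remap[chain]] = s_chain
        lateral = s_by_reduced[src_idx]
        s0 = placement.coaptation_coordinate
        in_band = (depth <= depth_limit + 1e-9) & \
                  (np.abs(lateral - s0) * chain_len <= half_width + 1e-9)
        ids = verts[in_band]
        if len(ids) == 0:
            raise GeometryError(
                f"no graspable vertices on the {leaflet} leaflet at "
                f"coordinate {s0:.2f}")
        max_depth = float(np.max(depth[np.isfinite(depth)]))
        if depth_limit > max_depth + 1e-9:
            raise GeometryError(
                f"leaflet too short to grasp: {leaflet} height "
                f"{max_depth:.1f} mm < band depth {depth_limit:.1f} mm")
        bands[leaflet] = ids
    origin = 0.5 * (geometry.vertices[bands[ANTERIOR]].mean(axis=0) +
                    geometry.vertices[bands[POSTERIOR]].mean(axis=0))
    fr = geometry.frame
    axes = np.stack([fr.commissural_axis, fr.septal_lateral_axis, fr.axial_axis])
    return GraspSets(anterior_node_ids=bands[ANTERIOR],
                     posterior_node_ids=bands[POSTERIOR],
                     clip_frame_origin=origin, clip_frame_axes=axes)


# ---------------------------------------------------------------------------
# implantation
# ---------------------------------------------------------------------------

def _check_disjoint(grasps: list) -> None:
    seen = set()
    for gs in grasps:
        ids = set(gs.anterior_node_ids.tolist()) | set(gs.posterior_node_ids.tolist())
        if seen & ids:
            raise ParameterError("overlapping clip placements (grasp bands intersect)")
        seen |= ids


def _grasp_targets(geometry, grasps, placements):
    """Kinematic targets mapping each grasped band onto the closed clip arms.

    The closed clip clamps both leaflet segments flat against two parallel
    near-axial planes one leaflet thickness apart; a band node keeps its
    along-coaptation coordinate, and its geodesic depth from the free edge
    becomes its axial position on the arm. The clamp plane is placed on the
    annulus-to-annulus chord in proportion to the ungrasped leaflet lengths
    so neither leaflet is forced to overstretch (the clip settles toward
    the shorter, restricted leaflet).
    """
    fr = geometry.frame
    t_mean = geometry.mean_thickness
    ids_all, tgt_all = [], []
    for gs, pl in zip(grasps, placements):
        depth_by_leaflet = {}
        height_by_leaflet = {}
        for leaflet in (ANTERIOR, POSTERIOR):
            verts, depth, _ = geodesic_depth_from_free_edge(geometry, leaflet)
            lookup = dict(zip(verts.tolist(), depth.tolist()))
            depth_by_leaflet[leaflet] = lookup
            height_by_leaflet[leaflet] = float(np.max(depth[np.isfinite(depth)]))

        D = pl.grasp_depth
        band_ids = {ANTERIOR: gs.anterior_node_ids, POSTERIOR: gs.posterior_node_ids}
        centre = gs.clip_frame_origin
        # annulus anchor per leaflet: annulus vertex nearest in the
        # commissural coordinate to the clip centre
        ann = geometry.vertices[geometry.annulus_vertex_ids]
        ann_local = fr.to_local(ann)
        c_local = fr.to_local(centre[None])[0]
        anchors = {}
        for leaflet, sign in ((ANTERIOR, -1.0), (POSTERIOR, +1.0)):
            side = ann_local[:, 0] * sign > 0
            cand = ann_local[side]
            k = np.argmin(np.abs(cand[:, 1] - c_local[1]))
            anchors[leaflet] = cand[k]
        La = max(height_by_leaflet[ANTERIOR] - D, 1e-3)
        Lp = max(height_by_leaflet[POSTERIOR] - D, 1e-3)
        # clamp-plane position divides the chord by ungrasped lengths
        w = La / (La + Lp)
        top = anchors[ANTERIOR] + w * (anchors[POSTERIOR] - anchors[ANTERIOR])
        top[2] = min(anchors[ANTERIOR][2], anchors[POSTERIOR][2]) - 0.25 * min(La, Lp)
        for leaflet, sign in ((ANTERIOR, -1.0), (POSTERIOR, +1.0)):
            ids = band_ids[leaflet]
            local = fr.to_local(geometry.vertices[ids])
            d = np.array([depth_by_leaflet[leaflet].get(int(i), 0.0) for i in ids])
            tgt_local = np.column_stack([
                np.full(len(ids), top[0] + sign * 0.5 * t_mean),
                local[:, 1],
                top[2] - (D - np.minimum(d, D)),
            ])
            R = np.column_stack([fr.septal_lateral_axis, fr.commissural_axis,
                                 fr.axial_axis])
            ids_all.append(ids)
            tgt_all.append(tgt_local @ R.T + fr.origin)
    return np.concatenate(ids_all), np.vstack(tgt_all)


def annular_reduction(geometry: ValveGeometry, factor: float) -> ValveGeometry:
    """Scale the annulus ring toward its centroid (post-clip remodeling).

    factor 1.0 leaves the annulus unchanged; the leaflet interior follows
    via the same in-plane scaling to preserve mesh quality.
    """
    if factor <= 0:
        raise ParameterError("annular reduction factor must be positive")
    if factor == 1.0:
        return geometry
    fr = geometry.frame
    local = fr.to_local(geometry.vertices)
    local[:, :2] *= factor
    R = np.column_stack([fr.septal_lateral_axis, fr.commissural_axis, fr.axial_axis])
    return geometry.with_vertices(local @ R.T + fr.origin)


def implant_clips(geometry: ValveGeometry, apparatus: ChordalApparatus,
                  params: FungParams, placements: list,
                  solver_config: SolverConfig | None = None,
                  annular_reduction_factor: float = 1.0,
                  corrective: np.ndarray | None = None):
    """Implant one or more clips and re-simulate systole and diastole.

    Three phases per the kinematic clip model: (1) the grasp bands are
    drawn together by stiff pair springs under light loading; (2) the
    closed bands are tied to a rigid 6-DOF clip frame; (3) systolic
    closure and diastolic opening are re-run with the constraint active.
    Returns (systolic_state, diastolic_state, grasps).
    """
    cfg = solver_config or SolverConfig()
    if not placements:
        raise ParameterError("at least one clip placement is required")
    geometry = annular_reduction(geometry, annular_reduction_factor)
    grasps = [select_grasp_region(geometry, pl) for pl in placements]
    _check_disjoint(grasps)

    # phase 1: kinematic closing of the grasp bands (no transvalvular load)
    ids, targets = _grasp_targets(geometry, grasps, placements)
    # the unloaded staging equilibrium only seeds phase 3; a loose residual
    # suffices and avoids kinetic-damping limit cycles around slack chordae
    grasp_cfg = SolverConfig(**{**cfg.to_dict(), "pressure_systole": 0.0,
                                "residual_tol": max(cfg.residual_tol, 0.05),
                                "max_steps": min(cfg.max_steps, 20000)})
    closed = simulate_closure(geometry, apparatus, params, grasp_cfg,
                              prescribed=(ids, targets, 800))
    # nearest-node separation includes up to one mesh edge of sampling
    # mismatch between the two bands' grids
    worst_allowed = max(pl.device.closed_gap for pl in placements) \
        + geometry.mesh_edge_length
    for gs in grasps:
        from scipy.spatial import cKDTree
        pa = closed.positions[gs.anterior_node_ids]
        pp = closed.positions[gs.posterior_node_ids]
        gap = float(np.max(cKDTree(pp).query(pa)[0]))
        if gap > worst_allowed:
            raise GeometryError(
                f"grasp infeasible: residual arm gap {gap:.1f} mm exceeds "
                f"the device closed gap allowance {worst_allowed:.1f} mm")

    # phase 2: tie each band pair to a rigid clip body
    bodies = [RigidBody.from_nodes(
        np.concatenate([gs.anterior_node_ids, gs.posterior_node_ids]),
        closed.positions) for gs in grasps]

    # phase 3: loaded states with the constraint active
    systolic = simulate_closure(geometry, apparatus, params, cfg,
                                corrective=corrective, bodies=bodies,
                                initial_positions=closed.positions,
                                initial_branch=closed.branch_positions)
    bodies_d = [RigidBody.from_nodes(b.node_ids, closed.positions) for b in bodies]
    diastolic = simulate_opening(geometry, apparatus, params, cfg,
                                 bodies=bodies_d,
                                 initial_positions=closed.positions,
                                 initial_branch=closed.branch_positions)
    return systolic, diastolic, grasps
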