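"""Automated orifice quantification: residual ERO, diastolic MVA, coaptation.

Orifices are delineated on the en-face projection of the valve (looking
down the axial axis, as in multi-planar reconstruction of a 3D-TEE en-face
view): the annulus polygon minus the union of the projected leaflet
surfaces leaves the open channels. Channels narrower than the gap
threshold (numerical contact noise, coapted-but-not-touching seams) are
suppressed with a morphological opening of radius gap_threshold / 2. The
same construction yields the systolic regurgitant orifice(s) and the
diastolic open orifice(s): a clip's tissue bridge splits the diastolic
channel into a double (or triple) orifice.

Areas are reported in cm^2 (1 cm^2 = 100 mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .errors import GeometryError, ParameterError
from .geometry import ANTERIOR, POSTERIOR, ValveGeometry, slice_valve
from .solver import SimulationState, SYSTOLE, DIASTOLE

MM2_TO_CM2 = 1e-2
_MIN_ORIFICE_AREA_MM2 = 2.0   # discard slivers below this area


@dataclass
class OrificePolygon:
    """One delineated orifice: a closed 3-D loop with its measurement plane."""

    boundary: np.ndarray       # (k, 3) ordered loop, mm
    plane_point: np.ndarray    # (3,)
    plane_normal: np.ndarray   # (3,)
    area: float                # cm^2
    phase: str

    def __post_init__(self):
        self.boundary = np.asarray(self.boundary, dtype=float)
        self.plane_point = np.asarray(self.plane_point, dtype=float)
        self.plane_normal = np.asarray(self.plane_normal, dtype=float)


@dataclass
class ValveMetrics:
    orifices: list
    total_ero: float           # cm^2, systole
    mva: float                 # cm^2, diastole
    orifice_count: int
    coaptation_height: float | None = None   # mm

    def to_dict(self) -> dict:
        d = {
            "total_ero_cm2": self.total_ero,
            "mva_cm2": self.mva,
            "orifice_count": self.orifice_count,
        }
        if self.coaptation_height is not None:
            d["coaptation_height_mm"] = self.coaptation_height
        return d


# ---------------------------------------------------------------------------
# polygon area
# ---------------------------------------------------------------------------

def _best_fit_plane(loop: np.ndarray):
    centroid = loop.mean(axis=0)
    # vector area: the projection plane maximising the projected area
    va = 0.5 * np.cross(loop, np.roll(loop, -1, axis=0)).sum(axis=0) \
        - 0.5 * np.cross(centroid, centroid)  # zero; kept for clarity
    rolled = np.roll(loop - centroid, -1, axis=0)
    va = 0.5 * np.cross(loop - centroid, rolled).sum(axis=0)
    n = np.linalg.norm(va)
    if n < 1e-12:
        # degenerate loop: fall back to SVD normal
        _, _, vt = np.linalg.svd(loop - centroid)
        return centroid, vt[2], 0.0
    return centroid, va / n, n


def orifice_area(polygon: OrificePolygon | np.ndarray) -> float:
    """Area (cm^2) of a closed loop projected on its best-fit plane.

    Uses the vector-area formula, equal to the planar polygon (shoelace)
    area for planar loops. Raises if the planar projection self-intersects.
    """
    loop = polygon.boundary if isinstance(polygon, OrificePolygon) else np.asarray(polygon, float)
    if len(loop) < 3:
        return 0.0
    centroid, normal, area_mm2 = _best_fit_plane(loop)
    if area_mm2 > 0:
        # simplicity check in the projection plane
        ref = np.eye(3)[np.argmin(np.abs(normal))]
        u = np.cross(normal, ref)
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        xy = np.column_stack([(loop - centroid) @ u, (loop - centroid) @ v])
        poly = Polygon(xy)
        if not poly.is_valid:
            raise GeometryError("orifice loop projection is self-intersecting")
    return float(area_mm2 * MM2_TO_CM2)


def total_ero(orifices: list) -> float:
    """Sum of systolic orifice areas (cm^2); multiple jets are summed."""
    return _sum_phase(orifices, SYSTOLE)


def mva(orifices: list) -> float:
    """Sum of diastolic orifice areas (cm^2)."""
    return _sum_phase(orifices, DIASTOLE)


def _sum_phase(orifices: list, phase: str) -> float:
    for o in orifices:
        if o.phase != phase:
            raise ParameterError(
                f"orifice list mixes phases: expected {phase}, found {o.phase}")
    return float(sum(o.area for o in orifices))


# ---------------------------------------------------------------------------
# orifice detection
# ---------------------------------------------------------------------------

def _project(frame, points):
    local = frame.to_local(points)
    return local[:, :2], local[:, 2]


def detect_orifices(state: SimulationState, geometry: ValveGeometry,
                    gap_threshold: float | None = None) -> list:
    """Delineate open channels through the valve in the given state.

    Returns orifice polygons in decreasing area order. ``gap_threshold``
    defaults to the mean leaflet thickness: channels narrower than this are
    treated as coapted (numerical contact separation), mirroring the role
    of leaflet thickness as the coaptation yardstick.
    """
    if not state.converged:
        raise ParameterError("orifice detection requires a converged state")
    if gap_threshold is None:
        gap_threshold = geometry.mean_thickness
    if gap_threshold <= 0:
        raise ParameterError("gap_threshold must be positive")

    frame = geometry.frame
    pos = state.positions
    xy, _ = _project(frame, pos)

    ann_xy = xy[geometry.annulus_vertex_ids]
    annulus_poly = Polygon(ann_xy)
    if not annulus_poly.is_valid:
        annulus_poly = annulus_poly.buffer(0)

    tri_polys = []
    for tri in geometry.triangles:
        p = Polygon(xy[tri])
        if p.is_valid and p.area > 1e-12:
            tri_polys.append(p)
    cover = unary_union(tri_polys).buffer(1e-6)
    holes = annulus_poly.difference(cover)

    # two coapted mid-surfaces of thickness-t leaflets sit ~t apart, so the
    # coaptation seam projects to a channel about gap_threshold wide; an
    # opening radius of 0.75 * gap removes channels narrower than 1.5 * gap
    r = 0.75 * gap_threshold
    opened = holes.buffer(-r).buffer(r * 1.001)
    parts = list(opened.geoms) if isinstance(opened, MultiPolygon) else (
        [opened] if not opened.is_empty else [])

    out = []
    for part in parts:
        if part.is_empty:
            continue
        # recover the un-eroded extent of this component
        full = part.buffer(r * 1.05).intersection(holes)
        if isinstance(full, MultiPolygon):
            full = max(full.geoms, key=lambda g: g.area)
        if full.is_empty or full.area < _MIN_ORIFICE_AREA_MM2:
            continue
        loop_xy = np.asarray(full.exterior.coords[:-1])
        loop3 = _lift_loop(loop_xy, geometry, pos, frame)
        centroid, normal, _ = _best_fit_plane(loop3)
        out.append(OrificePolygon(
            boundary=loop3, plane_point=centroid, plane_normal=normal,
            area=float(full.area * MM2_TO_CM2), phase=state.phase))
    out.sort(key=lambda o: -o.area)
    return out


def _lift_loop(loop_xy: np.ndarray, geometry: ValveGeometry, pos: np.ndarray,
               frame) -> np.ndarray:
    """Assign axial coordinates to a projected orifice boundary.

    Each boundary point takes the height of the nearest free-edge (or any
    mesh) vertex in projection, which places the loop on the orifice rim.
    """
    from scipy.spatial import cKDTree
    edge_ids = np.unique(np.concatenate([
        geometry.free_edge_vertex_ids[ANTERIOR],
        geometry.free_edge_vertex_ids[POSTERIOR]]))
    cand = pos[edge_ids]
    local = frame.to_local(cand)
    tree = cKDTree(local[:, :2])
    _, idx = tree.query(loop_xy)
    z = local[idx, 2]
    R = np.column_stack([frame.septal_lateral_axis, frame.commissural_axis,
                         frame.axial_axis])
    local_loop = np.column_stack([loop_xy, z])
    return local_loop @ R.T + frame.origin


# ---------------------------------------------------------------------------
# coaptation height
# ---------------------------------------------------------------------------

def coaptation_height(state: SimulationState, geometry: ValveGeometry,
                      gap_threshold: float | None = None,
                      angular_spacing: float = 10.0):
    """Mean axial overlap length of the apposed leaflets (mm).

    For every radial slice, points of one leaflet trace lying within
    ``gap_threshold`` of the other trace form the coapted set; the axial
    extent of that set is the per-slice coaptation height. Returns
    (mean_height, per_slice_profile); 0 with an empty profile when the
    leaflets do not coapt.
    """
    if state.phase != SYSTOLE:
        raise ParameterError("coaptation height is defined on the systolic state")
    if gap_threshold is None:
        # apposed mid-surfaces of thickness-t leaflets sit ~t apart
        gap_threshold = 1.5 * geometry.mean_thickness
    from scipy.spatial import cKDTree

    sliced = slice_valve(geometry, angular_spacing, positions=state.positions,
                         phase="early_systole")
    heights = []
    axis = geometry.frame.axial_axis
    for s in sliced.slices:
        a, p = s["anterior_trace"], s["posterior_trace"]
        if len(a) < 2 or len(p) < 2:
            continue
        d_ap = cKDTree(p).query(a)[0]
        close = a[d_ap <= gap_threshold]
        if len(close) >= 2:
            ax = close @ axis
            heights.append(float(ax.max() - ax.min()))
        else:
            heights.append(0.0)
    profile = np.asarray(heights)
    coapted = profile[profile > 0]
    mean_h = float(coapted.mean()) if len(coapted) else 0.0
    return mean_h, profile


def write_orifice_loops_vtk(orifices: list, path) -> None:
    """Export orifice boundary loops as legacy-VTK polylines."""
    pts = []
    lines = []
    for o in orifices:
        k = len(o.boundary)
        start = len(pts)
        pts.extend(o.boundary.tolist())
        lines.append([k + 1] + list(range(start, start + k)) + [start])
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\norifice loops\nASCII\n"
                "DATASET POLYDATA\n")
        f.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        total = sum(len(l) for l in lines)
        f.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            f.write(" ".join(str(i) for i in l) + "\n")


def valve_metrics(systolic_state: SimulationState | None,
                  diastolic_state: SimulationState | None,
                  geometry: ValveGeometry,
                  gap_threshold: float | None = None) -> ValveMetrics:
    """Convenience wrapper computing ERO, MVA and coaptation height."""
    orifices = []
    ero_val = 0.0
    mva_val = 0.0
    coapt = None
    if systolic_state is not None:
        sys_or = detect_orifices(systolic_state, geometry, gap_threshold)
        orifices += sys_or
        ero_val = total_ero(sys_or)
        coapt, _ = coaptation_height(systolic_state, geometry, gap_threshold)
    if diastolic_state is not None:
        dia_or = detect_orifices(diastolic_state, geometry, gap_threshold)
        orifices += dia_or
        mva_val = mva(dia_or)
    count = len(orifices)
    return ValveMetrics(orifices=orifices, total_ero=ero_val, mva=mva_val,
                        orifice_count=count, coaptation_height=coapt)
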