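"""Valve geometry: synthetic generation, radial slicing, reconstruction, I/O.

The data model stands in for manual 3D-TEE segmentation of the mitral valve.
All coordinates are millimetres in a local Cartesian frame whose axial axis
is the annulus best-fit-plane normal pointing toward the atrium; the valve
leaflets hang toward negative axial coordinates (the ventricle).

The synthetic generator emulates a functional-regurgitation phenotype:
an elliptical saddle annulus, a continuous two-leaflet funnel surface,
two papillary tips registered in end-diastole and early systole, and
optional annular dilation / papillary tethering that open a central
coaptation gap when the valve is closed under pressure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError, SchemaError

ANTERIOR = "anterior"
POSTERIOR = "posterior"
ANTEROLATERAL = "anterolateral"
POSTEROMEDIAL = "posteromedial"
PHASES = ("end_diastole", "early_systole")

# Funnel tilt of the open (diastolic) leaflets from the axial direction.
# Steep (near-axial) open leaflets keep the papillary-tip-to-free-edge
# distance nearly unchanged between the open and closed configurations,
# as marginal chordae are in vivo.
_FUNNEL_TILT_DEG = 15.0
# Leaflet height retained at the commissures, as a fraction of the smaller
# leaflet height (the leaflet band is continuous around the commissures).
_COMMISSURE_HEIGHT_FRAC = 0.5
# Amplitude of the seeded smooth surface perturbation (mm).
_PERTURB_MM = 0.08


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValveFrame:
    """Local Cartesian frame of the valve.

    ``axial_axis`` points from ventricle to atrium, ``septal_lateral_axis``
    from the anterior toward the posterior annulus, and ``commissural_axis``
    completes a right-handed triad.
    """

    origin: np.ndarray
    axial_axis: np.ndarray
    commissural_axis: np.ndarray
    septal_lateral_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "axial_axis", "commissural_axis", "septal_lateral_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        R = np.column_stack([self.septal_lateral_axis, self.commissural_axis, self.axial_axis])
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("valve frame axes are not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("valve frame is not right-handed")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        R = np.column_stack([self.septal_lateral_axis, self.commissural_axis, self.axial_axis])
        return (np.asarray(points, dtype=float) - self.origin) @ R

    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "axial_axis": self.axial_axis.tolist(),
            "commissural_axis": self.commissural_axis.tolist(),
            "septal_lateral_axis": self.septal_lateral_axis.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValveFrame":
        return cls(d["origin"], d["axial_axis"], d["commissural_axis"], d["septal_lateral_axis"])


@dataclass
class ValveGeometry:
    """Triangulated leaflet mid-surface with landmarks and labels.

    ``leaflet_label`` holds one of {"anterior", "posterior"} per triangle.
    ``papillary_tips[label][phase]`` gives the tip position (mm) for
    label in {"anterolateral", "posteromedial"} and phase in
    {"end_diastole", "early_systole"}.
    """

    vertices: np.ndarray                 # (n, 3) mm
    triangles: np.ndarray                # (m, 3) int
    leaflet_label: np.ndarray            # (m,) str
    annulus_vertex_ids: np.ndarray       # ordered closed loop
    free_edge_vertex_ids: dict           # leaflet -> ordered open chain
    papillary_tips: dict                 # label -> phase -> (3,) mm
    thickness: np.ndarray                # (n,) mm
    frame: ValveFrame
    mesh_edge_length: float = 1.5        # generator target edge length (mm)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.leaflet_label = np.asarray(self.leaflet_label, dtype=object)
        self.annulus_vertex_ids = np.asarray(self.annulus_vertex_ids, dtype=np.int64)
        self.free_edge_vertex_ids = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.free_edge_vertex_ids.items()
        }
        th = np.asarray(self.thickness, dtype=float)
        if th.ndim == 0:
            th = np.full(len(self.vertices), float(th))
        self.thickness = th
        self.papillary_tips = {
            lab: {ph: np.asarray(p, dtype=float) for ph, p in phases.items()}
            for lab, phases in self.papillary_tips.items()
        }

    # -- convenience -------------------------------------------------------

    def as_trimesh(self, vertices: np.ndarray | None = None) -> trimesh.Trimesh:
        v = self.vertices if vertices is None else vertices
        return trimesh.Trimesh(v.copy(), self.triangles.copy(), process=False)

    def leaflet_triangles(self, leaflet: str) -> np.ndarray:
        return self.triangles[self.leaflet_label == leaflet]

    def leaflet_vertex_ids(self, leaflet: str) -> np.ndarray:
        return np.unique(self.leaflet_triangles(leaflet))

    def with_vertices(self, vertices: np.ndarray) -> "ValveGeometry":
        g = replace(self)
        g.vertices = np.asarray(vertices, dtype=float).copy()
        return g

    @property
    def mean_thickness(self) -> float:
        return float(np.mean(self.thickness))

    def tips(self, phase: str) -> dict:
        return {lab: self.papillary_tips[lab][phase] for lab in (ANTEROLATERAL, POSTEROMEDIAL)}

    # -- invariant checks --------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`GeometryError` if any structural invariant fails."""
        v, t = self.vertices, self.triangles
        if not np.isfinite(v).all():
            raise GeometryError("non-finite vertex coordinates")
        if t.min() < 0 or t.max() >= len(v):
            raise GeometryError("triangle index out of range")
        if np.any(self.thickness <= 0):
            raise GeometryError("leaflet thickness must be positive everywhere")
        # edge-manifold: every edge is used by at most two triangles
        edges = np.sort(t[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise GeometryError("mesh is non-manifold (edge shared by >2 triangles)")
        # one boundary loop per leaflet region
        for leaflet in (ANTERIOR, POSTERIOR):
            tri = self.leaflet_triangles(leaflet)
            if len(tri) == 0:
                raise GeometryError(f"no triangles labelled {leaflet!r}")
            if _count_boundary_loops(tri) != 1:
                raise GeometryError(f"{leaflet} leaflet does not have exactly one boundary loop")
        # closed annulus loop: consecutive ids connected by mesh edges
        ring = self.annulus_vertex_ids
        edge_set = {tuple(e) for e in edges}
        for a, b in zip(ring, np.roll(ring, -1)):
            if tuple(sorted((int(a), int(b)))) not in edge_set:
                raise GeometryError("annulus loop is not a closed edge-connected ring")
        # free-edge vertices lie on the mesh boundary
        boundary = _boundary_vertices(t)
        for leaflet, chain in self.free_edge_vertex_ids.items():
            if not np.all(np.isin(chain, boundary)):
                raise GeometryError(f"{leaflet} free-edge chain leaves the mesh boundary")
        # papillary tips on the ventricular side (negative axial coordinate)
        for lab, phases in self.papillary_tips.items():
            for ph, p in phases.items():
                if self.frame.to_local(p[None])[0, 2] >= 0:
                    raise GeometryError(f"papillary tip {lab}/{ph} is not on the ventricular side")


def _count_boundary_loops(triangles: np.ndarray) -> int:
    edges = np.sort(triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bedges = uniq[counts == 1]
    if len(bedges) == 0:
        return 0
    import networkx as nx  # lazy; only for loop counting

    g = nx.Graph()
    g.add_edges_from(map(tuple, bedges))
    return sum(1 for _ in nx.connected_components(g))


def _boundary_vertices(triangles: np.ndarray) -> np.ndarray:
    edges = np.sort(triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


@dataclass(frozen=True)
class SynthValveConfig:
    """Parameters of the synthetic valve generator.

    ``tethering_displacement`` is applied to the posteromedial papillary tip
    in both phases (apical displacement is negative axial); together with
    ``dilation_factor`` > 1 it produces the functional-regurgitation
    morphology (central coaptation gap under systolic load).
    """

    annulus_ap_diameter: float = 30.0       # septal-lateral, mm
    annulus_cc_diameter: float = 36.0       # inter-commissural, mm
    saddle_height: float = 4.0              # peak-to-peak annulus saddle, mm
    anterior_leaflet_height: float = 24.0   # mm
    posterior_leaflet_height: float = 14.0  # mm
    tethering_displacement: tuple = (0.0, 0.0, 0.0)  # mm
    dilation_factor: float = 1.0
    mesh_edge_length: float = 1.5           # mm
    seed: int = 0
    thickness: float = 1.0                  # uniform leaflet thickness, mm

    def validate(self) -> None:
        for name in ("annulus_ap_diameter", "annulus_cc_diameter",
                     "anterior_leaflet_height", "posterior_leaflet_height",
                     "mesh_edge_length", "thickness"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.saddle_height < 0:
            raise ParameterError(f"saddle_height must be >= 0, got {self.saddle_height}")
        if self.dilation_factor < 1.0:
            raise ParameterError(f"dilation_factor must be >= 1, got {self.dilation_factor}")
        if len(tuple(self.tethering_displacement)) != 3:
            raise ParameterError("tethering_displacement must be a 3-vector")

    def to_dict(self) -> dict:
        return {
            "annulus_ap_diameter": self.annulus_ap_diameter,
            "annulus_cc_diameter": self.annulus_cc_diameter,
            "saddle_height": self.saddle_height,
            "anterior_leaflet_height": self.anterior_leaflet_height,
            "posterior_leaflet_height": self.posterior_leaflet_height,
            "tethering_displacement": list(self.tethering_displacement),
            "dilation_factor": self.dilation_factor,
            "mesh_edge_length": self.mesh_edge_length,
            "seed": self.seed,
            "thickness": self.thickness,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthValveConfig":
        d = dict(d)
        if "tethering_displacement" in d:
            d["tethering_displacement"] = tuple(d["tethering_displacement"])
        return cls(**d)


@dataclass
class SliceSet:
    """Radial cross-sections of the valve (planes containing the axial axis)."""

    angular_spacing: float                  # degrees
    slices: list                            # {angle, anterior_trace, posterior_trace, annulus_landmarks}
    phase: str = "end_diastole"


# ---------------------------------------------------------------------------
# synthetic valve generation
# ---------------------------------------------------------------------------

def _leaflet_span(theta: np.ndarray) -> np.ndarray:
    """True where an angle (radians, measured from +x) lies on the posterior leaflet."""
    th = np.mod(theta + np.pi / 2, 2 * np.pi)  # 0 at the posteromedial commissure
    return th < np.pi


def generate_synthetic_valve(config: SynthValveConfig) -> ValveGeometry:
    """Generate an open-configuration (diastolic) synthetic valve.

    The leaflet surface is a continuous band around the annulus: columns of
    vertices descend from the annulus toward the ventricle, tilted inward by
    a fixed funnel angle, with leaflet-specific heights that taper to a
    shared commissural height. Deterministic for a given ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    dil = config.dilation_factor
    a = 0.5 * config.annulus_ap_diameter * dil          # septal-lateral semi-axis
    b = 0.5 * config.annulus_cc_diameter * dil          # commissural semi-axis
    h_saddle = 0.5 * config.saddle_height
    H_a = config.anterior_leaflet_height
    H_p = config.posterior_leaflet_height
    H_c = _COMMISSURE_HEIGHT_FRAC * min(H_a, H_p)
    tilt = np.radians(_FUNNEL_TILT_DEG)

    # ring resolution from annulus circumference, column resolution from height
    circum = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))  # Ramanujan
    n_u = max(24, int(np.ceil(circum / config.mesh_edge_length)))
    n_v = max(5, int(np.ceil(max(H_a, H_p) / config.mesh_edge_length)))

    # columns at theta from -pi/2 (posteromedial commissure) around the ring
    theta = -np.pi / 2 + 2 * np.pi * np.arange(n_u) / n_u
    posterior_col = _leaflet_span(theta)

    ann = np.column_stack([a * np.cos(theta), b * np.sin(theta),
                           h_saddle * np.cos(2 * theta)])
    # unit inward horizontal direction at each annulus point
    u_in = -np.column_stack([a * np.cos(theta), b * np.sin(theta), np.zeros(n_u)])
    u_in /= np.linalg.norm(u_in, axis=1, keepdims=True)

    # leaflet height profile, continuous across the commissures
    xi = np.mod(theta + np.pi / 2, np.pi)  # position within the leaflet span
    H_leaf = np.where(posterior_col, H_p, H_a)
    H = H_c + (H_leaf - H_c) * np.sin(xi)

    # smooth seeded perturbation (low-order Fourier in theta, vanishing at annulus)
    amps = rng.normal(scale=_PERTURB_MM, size=3)
    phs = rng.uniform(0, 2 * np.pi, size=3)
    wob = sum(amps[k] * np.sin((k + 1) * theta + phs[k]) for k in range(3))

    direction = np.column_stack([
        np.sin(tilt) * u_in[:, 0], np.sin(tilt) * u_in[:, 1],
        -np.cos(tilt) * np.ones(n_u)])

    vv = np.arange(n_v + 1) / n_v
    # vertices indexed [iv, iu]
    verts = (ann[None, :, :] + vv[:, None, None] * H[None, :, None] * direction[None, :, :])
    verts = verts + (vv[:, None] * wob[None, :])[:, :, None] * np.column_stack(
        [u_in[:, 0], u_in[:, 1], np.zeros(n_u)])[None, :, :]
    vid = np.arange((n_v + 1) * n_u).reshape(n_v + 1, n_u)

    tris, labels = [], []
    for iv in range(n_v):
        for iu in range(n_u):
            ju = (iu + 1) % n_u
            v00, v01 = vid[iv, iu], vid[iv, ju]
            v10, v11 = vid[iv + 1, iu], vid[iv + 1, ju]
            # alternate the quad diagonal for an unbiased triangulation;
            # winding is chosen so triangle normals face the atrium
            if (iu + iv) % 2 == 0:
                quad = [(v00, v01, v10), (v01, v11, v10)]
            else:
                quad = [(v00, v11, v10), (v00, v01, v11)]
            lab = POSTERIOR if posterior_col[iu] else ANTERIOR
            tris.extend(quad)
            labels.extend([lab, lab])
    tris = np.asarray(tris, dtype=np.int64)
    labels = np.asarray(labels, dtype=object)

    vertices = verts.reshape(-1, 3)

    annulus_ids = vid[0]
    free_edge = {}
    for leaflet, mask in ((POSTERIOR, posterior_col), (ANTERIOR, ~posterior_col)):
        cols = np.where(mask)[0]
        # a column strip is labelled by its left column; the chain therefore
        # ends one column past the strip run (shared commissure vertex)
        cols = np.concatenate([cols, [(cols[-1] + 1) % n_u]])
        free_edge[leaflet] = vid[n_v, cols]

    # papillary tips below the commissures, between annulus and apex;
    # tethering displaces both tips (mirrored laterally) while the chordal
    # rest lengths stay anchored to the untethered reference position —
    # the ventricular-remodeling mechanism of functional regurgitation
    tip_depth = -(0.85 * max(a, b) + 2.0)
    tether = np.asarray(config.tethering_displacement, dtype=float)
    tips = {}
    for lab, sign in ((ANTEROLATERAL, +1.0), (POSTEROMEDIAL, -1.0)):
        base = np.array([0.0, sign * 0.5 * b, tip_depth])
        shift = tether.copy()
        if lab == ANTEROLATERAL:
            shift[1] = -shift[1]     # lateral displacement mirrors across the AP plane
        tips[lab] = {
            "rest_reference": base.copy(),
            "end_diastole": base + shift,
            "early_systole": base + shift,
        }

    frame = ValveFrame(
        origin=vertices[annulus_ids].mean(axis=0),
        axial_axis=np.array([0.0, 0.0, 1.0]),
        commissural_axis=np.array([0.0, 1.0, 0.0]),
        septal_lateral_axis=np.array([1.0, 0.0, 0.0]),
    )

    geom = ValveGeometry(
        vertices=vertices, triangles=tris, leaflet_label=labels,
        annulus_vertex_ids=annulus_ids, free_edge_vertex_ids=free_edge,
        papillary_tips=tips, thickness=np.full(len(vertices), config.thickness),
        frame=frame, mesh_edge_length=config.mesh_edge_length,
    )
    geom.validate()
    return geom


# ---------------------------------------------------------------------------
# radial slicing
# ---------------------------------------------------------------------------

def _chain_segments(segments: np.ndarray, tol: float = 1e-7) -> list:
    """Assemble unordered 2-point segments into maximal polylines."""
    if len(segments) == 0:
        return []
    pts = segments.reshape(-1, 3)
    tree = cKDTree(pts)
    groups = tree.query_ball_point(pts, tol)
    canon = np.array([min(g) for g in groups])
    _, node_of = np.unique(canon, return_inverse=True)
    n_nodes = node_of.max() + 1
    node_pos = np.zeros((n_nodes, 3))
    node_pos[node_of] = pts
    adj = [[] for _ in range(n_nodes)]
    for i in range(len(segments)):
        p, q = node_of[2 * i], node_of[2 * i + 1]
        if p != q:
            adj[p].append(q)
            adj[q].append(p)
    seen = set()
    chains = []
    order = sorted(range(n_nodes), key=lambda n: (len(adj[n]) != 1, n))
    for start in order:
        if start in seen or not adj[start]:
            continue
        chain = [start]
        seen.add(start)
        cur = start
        while True:
            nxt = [n for n in adj[cur] if n not in seen]
            if not nxt:
                break
            cur = nxt[0]
            seen.add(cur)
            chain.append(cur)
        if len(chain) >= 2:
            chains.append(node_pos[chain])
    return chains


def _leaflet_trace(geometry: ValveGeometry, positions: np.ndarray, leaflet: str,
                   normal: np.ndarray, origin: np.ndarray) -> np.ndarray:
    sub = trimesh.Trimesh(positions, geometry.leaflet_triangles(leaflet), process=False)
    segs = trimesh.intersections.mesh_plane(sub, normal, origin)
    chains = _chain_segments(np.asarray(segs))
    if not chains:
        return np.zeros((0, 3))
    lengths = [np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)) for c in chains]
    trace = chains[int(np.argmax(lengths))]
    # orient annulus -> free edge
    ann_pts = positions[geometry.annulus_vertex_ids]
    tree = cKDTree(ann_pts)
    d_first = tree.query(trace[0])[0]
    d_last = tree.query(trace[-1])[0]
    if d_last < d_first:
        trace = trace[::-1]
    return trace


def slice_valve(geometry: ValveGeometry, angular_spacing: float = 10.0,
                positions: np.ndarray | None = None,
                phase: str = "end_diastole") -> SliceSet:
    """Cut the valve with planes containing the axial axis.

    Planes are placed every ``angular_spacing`` degrees over 180 degrees of
    unique orientations (18 slices at the default 10 degrees); each plane
    cuts the valve twice, yielding one anterior and one posterior trace
    ordered from the annulus to the free edge.
    """
    if angular_spacing <= 0 or abs(180.0 / angular_spacing - round(180.0 / angular_spacing)) > 1e-9:
        raise ParameterError(f"angular_spacing must divide 180, got {angular_spacing}")
    pos = geometry.vertices if positions is None else np.asarray(positions, dtype=float)
    n_slices = int(round(180.0 / angular_spacing))
    fr = geometry.frame
    ann_pts = pos[geometry.annulus_vertex_ids]

    slices = []
    for k in range(n_slices):
        # planes are offset by half the spacing so that none is tangent to
        # a leaflet boundary (the commissural plane) for even divisions
        gamma = np.radians((k + 0.5) * angular_spacing)
        g = np.cos(gamma) * fr.septal_lateral_axis + np.sin(gamma) * fr.commissural_axis
        normal = np.cross(fr.axial_axis, g)
        ant = _leaflet_trace(geometry, pos, ANTERIOR, normal, fr.origin)
        post = _leaflet_trace(geometry, pos, POSTERIOR, normal, fr.origin)
        # the two annulus crossings of this plane (ventricular-side registration)
        side = (ann_pts - fr.origin) @ normal
        lm = []
        ring = np.append(np.arange(len(ann_pts)), 0)
        for i, j in zip(ring[:-1], ring[1:]):
            si, sj = side[i], side[j]
            if si == 0.0:
                lm.append(ann_pts[i])
            elif si * sj < 0:
                t = si / (si - sj)
                lm.append(ann_pts[i] + t * (ann_pts[j] - ann_pts[i]))
        slices.append({
            "angle": float((k + 0.5) * angular_spacing),
            "anterior_trace": ant,
            "posterior_trace": post,
            "annulus_landmarks": np.asarray(lm[:2]),
        })
    return SliceSet(angular_spacing=float(angular_spacing), slices=slices, phase=phase)


# ---------------------------------------------------------------------------
# reconstruction from slices
# ---------------------------------------------------------------------------

def _resample_polyline(poly: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(poly[:1], n, axis=0)
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, poly[:, k]) for k in range(3)])


def reconstruct_from_slices(slices: SliceSet, tips: dict,
                            thickness: float = 1.0) -> ValveGeometry:
    """Loft radial slice traces back into a triangulated mid-surface.

    Traces from all slices are ordered by their angular position around the
    annulus and joined into a closed band from the annulus row to the free
    edge. ``tips`` maps papillary labels to per-phase positions.
    """
    traces = []
    for idx, s in enumerate(slices.slices):
        for leaflet in (ANTERIOR, POSTERIOR):
            tr = np.asarray(s[f"{leaflet}_trace"], dtype=float)
            if len(tr) >= 2:
                traces.append((leaflet, idx, tr))
    if len({i for _, i, _ in traces}) < 8:
        raise ParameterError("reconstruction requires at least 8 slices with traces")

    # order traces by the angle of their annulus-end point
    def angle_of(tr):
        return float(np.arctan2(tr[0, 1], tr[0, 0]))

    traces.sort(key=lambda t: angle_of(t[2]))
    # adjacent traces must not cross: their free-edge ends must preserve the
    # cyclic order of their annulus ends
    for (la, ia, ta), (lb, ib, tb) in zip(traces, traces[1:] + traces[:1]):
        if np.linalg.norm(ta[0] - ta[-1]) < 1e-9:
            raise GeometryError(f"degenerate trace in slice {ia}")
        gap_ann = np.mod(angle_of(tb) - angle_of(ta), 2 * np.pi)
        fe = float(np.arctan2(tb[-1, 1], tb[-1, 0]) - np.arctan2(ta[-1, 1], ta[-1, 0]))
        gap_fe = np.mod(fe, 2 * np.pi)
        if gap_ann > 1e-9 and gap_fe > np.pi and gap_ann < np.pi / 4:
            raise GeometryError(f"crossing traces between slices {ia} and {ib}")

    n_v = max(max(len(t) for _, _, t in traces), 4)
    grid = np.stack([_resample_polyline(t, n_v) for _, _, t in traces])  # (n_tr, n_v, 3)
    labs = [l for l, _, _ in traces]
    n_u = len(traces)

    vid = np.arange(n_u * n_v).reshape(n_u, n_v)
    tris, labels = [], []
    for iu in range(n_u):
        ju = (iu + 1) % n_u
        for iv in range(n_v - 1):
            v00, v10 = vid[iu, iv], vid[ju, iv]
            v01, v11 = vid[iu, iv + 1], vid[ju, iv + 1]
            tris.extend([(v00, v10, v01), (v01, v10, v11)])
            labels.extend([labs[iu], labs[iu]])
    vertices = grid.reshape(-1, 3)
    tris = np.asarray(tris, dtype=np.int64)
    labels = np.asarray(labels, dtype=object)

    annulus_ids = vid[:, 0]
    free_edge = {}
    for leaflet in (ANTERIOR, POSTERIOR):
        cols = [iu for iu in range(n_u) if labs[iu] == leaflet]
        free_edge[leaflet] = vid[cols, n_v - 1]

    frame = frame_from_annulus(vertices[annulus_ids], vertices)
    tips_full = {
        lab: {ph: np.asarray(tips[lab][ph], dtype=float) for ph in PHASES}
        for lab in (ANTEROLATERAL, POSTEROMEDIAL)
    }
    edge_len = float(np.median(np.linalg.norm(
        vertices[tris[:, 0]] - vertices[tris[:, 1]], axis=1)))
    return ValveGeometry(
        vertices=vertices, triangles=tris, leaflet_label=labels,
        annulus_vertex_ids=annulus_ids, free_edge_vertex_ids=free_edge,
        papillary_tips=tips_full, thickness=np.full(len(vertices), thickness),
        frame=frame, mesh_edge_length=edge_len,
    )


def frame_from_annulus(annulus_points: np.ndarray, all_vertices: np.ndarray) -> ValveFrame:
    """Best-fit annulus-plane frame with the axial axis pointing atrially."""
    origin = annulus_points.mean(axis=0)
    u, s, vt = np.linalg.svd(annulus_points - origin)
    normal = vt[2]
    # leaflets hang ventricularly: the mesh centroid sits below the annulus
    if (all_vertices.mean(axis=0) - origin) @ normal > 0:
        normal = -normal
    x = vt[0] - (vt[0] @ normal) * normal
    x /= np.linalg.norm(x)
    y = np.cross(normal, x)
    return ValveFrame(origin=origin, axial_axis=normal, commissural_axis=y,
                      septal_lateral_axis=x)


# ---------------------------------------------------------------------------
# landmark morphing
# ---------------------------------------------------------------------------

def morph_to_systolic_reference(geometry: ValveGeometry, systolic_landmarks: dict) -> ValveGeometry:
    """Warp the diastolic surface onto systolic landmarks.

    ``systolic_landmarks`` carries ``"annulus"`` (positions matching the
    annulus loop order) and ``"papillary_tips"`` (label -> position). The
    displacement field interpolates the landmark displacements exactly with
    a thin-plate-spline radial basis, leaving the mesh topology unchanged.
    """
    ann_target = np.asarray(systolic_landmarks["annulus"], dtype=float)
    if len(ann_target) != len(geometry.annulus_vertex_ids):
        raise ParameterError(
            f"annulus landmark count {len(ann_target)} != "
            f"{len(geometry.annulus_vertex_ids)} annulus vertices")
    tip_targets = systolic_landmarks["papillary_tips"]
    for lab in (ANTEROLATERAL, POSTEROMEDIAL):
        if lab not in tip_targets:
            raise ParameterError(f"missing papillary tip landmark {lab!r}")

    src = np.vstack([
        geometry.vertices[geometry.annulus_vertex_ids],
        [geometry.papillary_tips[lab]["end_diastole"] for lab in (ANTEROLATERAL, POSTEROMEDIAL)],
    ])
    dst = np.vstack([ann_target,
                     [np.asarray(tip_targets[lab], dtype=float)
                      for lab in (ANTEROLATERAL, POSTEROMEDIAL)]])
    disp = dst - src
    if np.allclose(disp, 0.0):
        warped = geometry.vertices.copy()
    else:
        interp = RBFInterpolator(src, disp, kernel="thin_plate_spline", degree=1)
        warped = geometry.vertices + interp(geometry.vertices)
        # landmarks are interpolated exactly; enforce to machine precision
        warped[geometry.annulus_vertex_ids] = dst[:len(ann_target)]
    out = geometry.with_vertices(warped)
    out.papillary_tips = {
        lab: {
            **{ph: p.copy() for ph, p in geometry.papillary_tips[lab].items()},
            "early_systole": np.asarray(tip_targets[lab], dtype=float).copy(),
        }
        for lab in (ANTEROLATERAL, POSTEROMEDIAL)
    }
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _write_vtk_polydata(path: Path, vertices: np.ndarray, triangles: np.ndarray) -> None:
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvalve surface\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(vertices)} double\n")
        for p in vertices:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
        for t in triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_vtk_polydata(path: Path):
    tokens = Path(path).read_text().split()
    def find(word):
        for i, t in enumerate(tokens):
            if t.upper() == word:
                return i
        raise SchemaError(f"{path}: VTK keyword {word} not found")
    i = find("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=float).reshape(n, 3)
    j = find("POLYGONS")
    m = int(tokens[j + 1])
    body = np.array(tokens[j + 3:j + 3 + 4 * m], dtype=np.int64).reshape(m, 4)
    if np.any(body[:, 0] != 3):
        raise SchemaError(f"{path}: only triangle polygons are supported")
    return pts, body[:, 1:]


def write_valve(geometry: ValveGeometry, path, landmark_path) -> None:
    """Write the mesh (STL/PLY/VTK by suffix) and the landmark/label JSON."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".vtk":
        _write_vtk_polydata(path, geometry.vertices, geometry.triangles)
    elif suffix == ".ply":
        # ascii PLY with double precision (binary PLY is float32)
        v, t = geometry.vertices, geometry.triangles
        with open(path, "w") as f:
            f.write("ply\nformat ascii 1.0\n")
            f.write(f"element vertex {len(v)}\n")
            f.write("property double x\nproperty double y\nproperty double z\n")
            f.write(f"element face {len(t)}\n")
            f.write("property list uchar int vertex_indices\nend_header\n")
            for p in v:
                f.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
            for tri in t:
                f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
    elif suffix == ".stl":
        mesh = geometry.as_trimesh()
        mesh.export(path)
    else:
        raise ParameterError(f"unsupported mesh format {suffix!r} (use .stl/.ply/.vtk)")
    doc = {
        "units": "mm",
        "frame": geometry.frame.to_dict(),
        "annulus": geometry.vertices[geometry.annulus_vertex_ids].tolist(),
        "papillary_tips": {
            lab: {ph: p.tolist() for ph, p in geometry.papillary_tips[lab].items()}
            for lab in (ANTEROLATERAL, POSTEROMEDIAL)
        },
        "leaflet_labels": geometry.leaflet_label.tolist(),
        "free_edges": {
            leaflet: geometry.vertices[ids].tolist()
            for leaflet, ids in geometry.free_edge_vertex_ids.items()
        },
        "thickness": geometry.thickness.tolist(),
        "mesh_edge_length": geometry.mesh_edge_length,
    }
    Path(landmark_path).write_text(json.dumps(doc, indent=1))


def read_valve(path, landmark_path) -> ValveGeometry:
    """Read a valve mesh plus its landmark JSON back into a ValveGeometry."""
    path = Path(path)
    landmark_path = Path(landmark_path)
    if not landmark_path.exists():
        raise SchemaError(f"landmark file {landmark_path} not found")
    try:
        doc = json.loads(landmark_path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{landmark_path}: invalid JSON ({e})") from e
    for key in ("annulus", "papillary_tips", "units", "frame", "leaflet_labels"):
        if key not in doc:
            raise SchemaError(f"{landmark_path}: missing required key {key!r}")

    suffix = path.suffix.lower()
    if suffix == ".vtk":
        vertices, triangles = _read_vtk_polydata(path)
    elif suffix in (".stl", ".ply"):
        mesh = trimesh.load(str(path), process=False)
        vertices = np.asarray(mesh.vertices, dtype=float)
        triangles = np.asarray(mesh.faces, dtype=np.int64)
        if suffix == ".stl":
            # STL stores a facet soup; weld coincident vertices deterministically
            vertices, inverse = np.unique(vertices.round(6), axis=0, return_inverse=True)
            triangles = inverse[triangles]
    else:
        raise ParameterError(f"unsupported mesh format {suffix!r} (use .stl/.ply/.vtk)")

    tree = cKDTree(vertices)

    def match(points):
        d, idx = tree.query(np.asarray(points, dtype=float))
        if np.any(d > 1e-3):
            raise SchemaError(f"{landmark_path}: landmark points do not lie on the mesh")
        return np.asarray(idx, dtype=np.int64)

    annulus_ids = match(doc["annulus"])
    free_edge = {leaflet: match(pts) for leaflet, pts in doc.get("free_edges", {}).items()}
    thickness = np.asarray(doc.get("thickness", 1.0), dtype=float)
    if thickness.ndim == 1 and len(thickness) != len(vertices):
        thickness = np.full(len(vertices), float(thickness.mean()))
    tips = {
        lab: {ph: np.asarray(p, dtype=float)
              for ph, p in doc["papillary_tips"][lab].items()}
        for lab in (ANTEROLATERAL, POSTEROMEDIAL)
    }
    geom = ValveGeometry(
        vertices=vertices, triangles=triangles,
        leaflet_label=np.asarray(doc["leaflet_labels"], dtype=object),
        annulus_vertex_ids=annulus_ids, free_edge_vertex_ids=free_edge,
        papillary_tips=tips, thickness=thickness,
        frame=ValveFrame.from_dict(doc["frame"]),
        mesh_edge_length=float(doc.get("mesh_edge_length", 1.5)),
    )
    geom.validate()
    return geom


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def surface_area(geometry: ValveGeometry, positions: np.ndarray | None = None) -> float:
    """Total leaflet mid-surface area (mm^2)."""
    pos = geometry.vertices if positions is None else positions
    t = geometry.triangles
    cross = np.cross(pos[t[:, 1]] - pos[t[:, 0]], pos[t[:, 2]] - pos[t[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def mean_surface_distance(mesh_a: trimesh.Trimesh, mesh_b: trimesh.Trimesh) -> float:
    """Symmetric mean vertex-to-surface distance between two meshes (mm)."""
    from .calibration import nearest_on_surface
    d_ab = np.linalg.norm(nearest_on_surface(mesh_b, mesh_a.vertices) - mesh_a.vertices, axis=1)
    d_ba = np.linalg.norm(nearest_on_surface(mesh_a, mesh_b.vertices) - mesh_b.vertices, axis=1)
    return float(0.5 * (d_ab.mean() + d_ba.mean()))
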