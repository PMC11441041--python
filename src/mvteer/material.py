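"""Fung anisotropic hyperelastic membrane law for the mitral leaflets.

The leaflets are thin collagenous membranes modelled with constant-strain
triangles. The strain energy per unit reference volume is

    W = (c/2) (exp(Q) - 1) + (1/D) ((J^2 - 1)/2 - ln J),       Q = eps : b : eps

where ``c`` (kPa) sets the stress scale, ``D`` (1/kPa) penalises volume
change, ``J`` is the volumetric Jacobian and ``eps`` is the in-plane Green
strain with its shear component suppressed (shear stress is taken as
negligible for the leaflet membrane). With shear suppressed the fourth-order
anisotropy tensor ``b`` reduces to the in-plane orthotropic coefficients
{b_ff, b_ss, b_fs} (fiber, cross-fiber, coupling) expressed in a
per-triangle fiber frame.

Incompressibility is enforced kinematically by default: the current
thickness is t0 / areal_stretch so that J = 1 and the volumetric term
vanishes; the penalty form with finite D is available for direct evaluation
of the volumetric term.

Units: stresses kPa = 1e-3 N/mm^2; lengths mm; forces N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ParameterError

KPA_TO_N_PER_MM2 = 1e-3

# Quadratic penalty on the (otherwise unresisted) in-plane shear strain,
# dimensionless multiple of c. Stabilises the zero-energy shearing mode of
# the shear-free constitutive law without measurably stiffening the
# physiological response.
DEFAULT_SHEAR_STABILIZATION = 5.0


@dataclass(frozen=True)
class FungParams:
    """Constitutive parameters of the leaflet membrane.

    Defaults are representative soft-tissue literature values: the strong
    fiber/cross-fiber anisotropy (b_ff > b_ss) reflects the circumferential
    collagen architecture of the leaflets.
    """

    c: float = 0.2          # kPa
    D: float = 1.0          # 1/kPa (penalty form only)
    b_ff: float = 25.0
    b_ss: float = 10.0
    b_fs: float = 5.0
    shear_stabilization: float = DEFAULT_SHEAR_STABILIZATION

    def validate(self) -> None:
        if self.c <= 0:
            raise ParameterError(f"c must be positive, got {self.c}")
        if self.D <= 0:
            raise ParameterError(f"D must be positive, got {self.D}")
        B = self.b_matrix
        ev = np.linalg.eigvalsh(B)
        if ev.min() < -1e-12:
            raise ParameterError("reduced anisotropy matrix must be positive semidefinite")
        if self.shear_stabilization < 0:
            raise ParameterError("shear_stabilization must be >= 0")

    @property
    def b_matrix(self) -> np.ndarray:
        return np.array([[self.b_ff, self.b_fs], [self.b_fs, self.b_ss]])

    def to_dict(self) -> dict:
        return {"c": self.c, "D": self.D, "b_ff": self.b_ff, "b_ss": self.b_ss,
                "b_fs": self.b_fs, "shear_stabilization": self.shear_stabilization}

    @classmethod
    def from_dict(cls, d: dict) -> "FungParams":
        return cls(**d)


@dataclass
class MembraneState:
    """Per-triangle kinematic state of the membrane."""

    F: np.ndarray                # (m, 2, 2) local in-plane deformation gradient
    eps: np.ndarray              # (m, 2, 2) shear-suppressed Green strain
    areal_stretch: np.ndarray    # (m,)
    J: np.ndarray                # (m,) volumetric Jacobian (1 when incompressible)
    thickness_current: np.ndarray  # (m,) mm


# ---------------------------------------------------------------------------
# strain measures
# ---------------------------------------------------------------------------

def green_strain(F: np.ndarray) -> np.ndarray:
    """Shear-suppressed Green strain eps = (F^T F - I)/2 with eps_12 zeroed.

    ``F`` may be (..., 2, 2) (in-plane) or (..., 3, 2) (3-D current
    configuration mapped from a 2-D reference); the product F^T F is 2x2
    either way. Raises on inverted elements (det of the metric <= 0).
    """
    F = np.asarray(F, dtype=float)
    C = np.swapaxes(F, -1, -2) @ F
    det = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    if np.any(det <= 0):
        bad = np.nonzero(np.atleast_1d(det <= 0))[0]
        raise NumericalError(f"inverted membrane element(s) at index {bad[:5].tolist()}")
    eps = 0.5 * (C - np.eye(2))
    eps[..., 0, 1] = 0.0
    eps[..., 1, 0] = 0.0
    return eps


# Beyond this exponent the exponential is continued linearly (C^1): the
# stress slope stays bounded, so the explicit solver's tangent estimate
# remains valid through extreme transients. Physiological states have Q of
# order 1-10 and are unaffected; at Q = 12 the membrane tension already
# exceeds the total transvalvular load by orders of magnitude, so the
# saturated regime behaves as (numerically tame) near-inextensibility.
Q_SATURATION = 12.0


def _q_and_beps(eps: np.ndarray, params: FungParams):
    e1 = eps[..., 0, 0]
    e2 = eps[..., 1, 1]
    q = params.b_ff * e1 ** 2 + 2.0 * params.b_fs * e1 * e2 + params.b_ss * e2 ** 2
    be1 = params.b_ff * e1 + params.b_fs * e2
    be2 = params.b_fs * e1 + params.b_ss * e2
    return q, be1, be2


def _exp_g(q: np.ndarray):
    """Saturated exponential: g(Q) = e^Q below Q_SATURATION, linear above.

    Returns (g, g') with g' = e^min(Q, Q_SATURATION); g is C^1.
    """
    q = np.asarray(q, dtype=float)
    qc = np.minimum(q, Q_SATURATION)
    gp = np.exp(qc)
    g = np.where(q <= Q_SATURATION, gp,
                 np.exp(Q_SATURATION) * (1.0 + (q - Q_SATURATION)))
    return g, gp


def fung_energy(eps: np.ndarray, J, params: FungParams) -> np.ndarray:
    """Strain energy per unit reference volume, W(eps, J), in kPa.

    W >= 0 with equality exactly at the reference state (eps = 0, J = 1).
    """
    eps = np.asarray(eps, dtype=float)
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise NumericalError("volumetric Jacobian must be positive")
    q, _, _ = _q_and_beps(eps, params)
    g, _ = _exp_g(q)
    w_dev = 0.5 * params.c * (g - 1.0)
    w_vol = (1.0 / params.D) * (0.5 * (J ** 2 - 1.0) - np.log(J))
    return w_dev + w_vol


def fung_stress(eps: np.ndarray, J, params: FungParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = dW/d(eps) at fixed J, in kPa.

    S = c exp(Q) (b : eps); the volumetric part of W carries no direct
    strain dependence at fixed J (it enters through the thickness /
    Jacobian coupling), so S is the exact eps-gradient of
    :func:`fung_energy`.
    """
    eps = np.asarray(eps, dtype=float)
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise NumericalError("volumetric Jacobian must be positive")
    q, be1, be2 = _q_and_beps(eps, params)
    _, gp = _exp_g(q)
    scale = params.c * gp
    S = np.zeros(np.broadcast_shapes(eps.shape, (2, 2)))
    S[..., 0, 0] = scale * be1
    S[..., 1, 1] = scale * be2
    return S


def volumetric_pressure(J, params: FungParams) -> np.ndarray:
    """dW_vol/dJ = (1/D)(J - 1/J), in kPa."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise NumericalError("volumetric Jacobian must be positive")
    return (1.0 / params.D) * (J - 1.0 / J)


# ---------------------------------------------------------------------------
# constant-strain membrane elements
# ---------------------------------------------------------------------------

@dataclass
class MembraneElements:
    """Precomputed reference quantities for a batch of membrane triangles.

    The local reference frame of each triangle is aligned with its fiber
    direction, so strain component (0, 0) is the fiber strain.
    """

    triangles: np.ndarray     # (m, 3) vertex ids
    inv_ref: np.ndarray       # (m, 2, 2) inverse reference edge matrix (fiber frame)
    area0: np.ndarray         # (m,) reference areas, mm^2
    t0: np.ndarray            # (m,) reference thickness, mm
    altitude0: np.ndarray = None  # (m,) smallest reference altitude, mm


def build_elements(vertices: np.ndarray, triangles: np.ndarray,
                   thickness: np.ndarray,
                   fiber_direction: np.ndarray | None = None) -> MembraneElements:
    """Precompute reference edge matrices in per-triangle fiber frames.

    ``fiber_direction``: (m, 3) unit vectors (projected onto each triangle
    plane). Default is circumferential: the horizontal direction orthogonal
    to the radial direction of the triangle centroid, matching the
    predominantly annulus-parallel collagen architecture.
    """
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    p0, p1, p2 = (vertices[triangles[:, k]] for k in range(3))
    d1, d2 = p1 - p0, p2 - p0
    n = np.cross(d1, d2)
    a2 = np.linalg.norm(n, axis=1)
    if np.any(a2 <= 1e-12):
        raise NumericalError("degenerate reference triangle")
    nu = n / a2[:, None]

    if fiber_direction is None:
        centroid = (p0 + p1 + p2) / 3.0
        circ = np.column_stack([-centroid[:, 1], centroid[:, 0], np.zeros(len(triangles))])
        nrm = np.linalg.norm(circ, axis=1)
        circ[nrm < 1e-9] = [1.0, 0.0, 0.0]
        fiber_direction = circ
    f = np.asarray(fiber_direction, dtype=float).copy()
    # project onto the triangle plane
    f -= (np.sum(f * nu, axis=1, keepdims=True)) * nu
    nrm = np.linalg.norm(f, axis=1, keepdims=True)
    small = nrm[:, 0] < 1e-9
    if np.any(small):
        # fiber nearly normal to the element: fall back to first edge direction
        f[small] = d1[small]
        nrm = np.linalg.norm(f, axis=1, keepdims=True)
    e1 = f / nrm
    e2 = np.cross(nu, e1)

    ref = np.stack([
        np.stack([np.sum(d1 * e1, axis=1), np.sum(d2 * e1, axis=1)], axis=-1),
        np.stack([np.sum(d1 * e2, axis=1), np.sum(d2 * e2, axis=1)], axis=-1),
    ], axis=-2)  # (m, 2, 2): rows = local axes, cols = edges
    det = ref[:, 0, 0] * ref[:, 1, 1] - ref[:, 0, 1] * ref[:, 1, 0]
    inv_ref = np.empty_like(ref)
    inv_ref[:, 0, 0] = ref[:, 1, 1]
    inv_ref[:, 0, 1] = -ref[:, 0, 1]
    inv_ref[:, 1, 0] = -ref[:, 1, 0]
    inv_ref[:, 1, 1] = ref[:, 0, 0]
    inv_ref /= det[:, None, None]

    t = np.asarray(thickness, dtype=float)
    t0 = t[triangles].mean(axis=1) if t.ndim == 1 and len(t) == len(vertices) \
        else np.full(len(triangles), float(np.mean(t)))
    longest = np.max(np.stack([
        np.linalg.norm(d1, axis=1), np.linalg.norm(d2, axis=1),
        np.linalg.norm(d2 - d1, axis=1)]), axis=0)
    altitude0 = a2 / longest  # 2*A0 / longest edge
    return MembraneElements(triangles=triangles, inv_ref=inv_ref, area0=0.5 * a2,
                            t0=t0, altitude0=altitude0)


def membrane_state(elements: MembraneElements, positions: np.ndarray) -> MembraneState:
    """Current kinematic state of every element (incompressible thickness)."""
    t = elements.triangles
    d1 = positions[t[:, 1]] - positions[t[:, 0]]
    d2 = positions[t[:, 2]] - positions[t[:, 0]]
    D = np.stack([d1, d2], axis=-1)              # (m, 3, 2)
    F = D @ elements.inv_ref                      # (m, 3, 2)
    C = np.swapaxes(F, -1, -2) @ F
    if not np.isfinite(C).all():
        raise NumericalError("non-finite membrane deformation")
    detC = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    tiny = detC < 1e-6
    if np.any(tiny):
        C[tiny] += 1e-3 * np.eye(2)
        detC = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    areal = np.sqrt(detC)
    eps = 0.5 * (C - np.eye(2))
    eps12 = eps[:, 0, 1].copy()
    eps[:, 0, 1] = 0.0
    eps[:, 1, 0] = 0.0
    # report a representative in-plane 2x2 F (polar-free projection)
    F2 = np.stack([
        np.stack([np.sqrt(np.maximum(C[:, 0, 0], 1e-30)),
                  C[:, 0, 1] / np.sqrt(np.maximum(C[:, 0, 0], 1e-30))], axis=-1),
        np.stack([np.zeros(len(t)),
                  areal / np.sqrt(np.maximum(C[:, 0, 0], 1e-30))], axis=-1),
    ], axis=-2)
    state = MembraneState(
        F=F2, eps=eps, areal_stretch=areal, J=np.ones(len(t)),
        thickness_current=elements.t0 / areal,
    )
    state._eps12 = eps12  # kept for the stabilisation term
    state._F3 = F
    return state


def element_energy(elements: MembraneElements, positions: np.ndarray,
                   params: FungParams) -> np.ndarray:
    """Strain energy per element (N mm), incompressible form."""
    st = membrane_state(elements, positions)
    w = fung_energy(st.eps, 1.0, params)
    w = w + 2.0 * params.c * params.shear_stabilization * st._eps12 ** 2
    return w * KPA_TO_N_PER_MM2 * elements.area0 * elements.t0


def membrane_nodal_forces(elements: MembraneElements, positions: np.ndarray,
                          params: FungParams, out: np.ndarray | None = None) -> np.ndarray:
    """Internal nodal forces (N): exact negative gradient of the element energy.

    The three forces of each triangle sum to zero (pure internal stress).
    """
    t = elements.triangles
    d1 = positions[t[:, 1]] - positions[t[:, 0]]
    d2 = positions[t[:, 2]] - positions[t[:, 0]]
    D = np.stack([d1, d2], axis=-1)
    F = D @ elements.inv_ref                      # (m, 3, 2)
    C = np.swapaxes(F, -1, -2) @ F
    if not np.isfinite(C).all():
        raise NumericalError("non-finite membrane deformation")
    # a collapsed element (areal stretch ~ 0) carries clamped strains; the
    # resulting compressive stress pushes it back open
    detC = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    tiny = detC < 1e-6
    if np.any(tiny):
        C[tiny] += 1e-3 * np.eye(2)
    eps = 0.5 * (C - np.eye(2))
    eps12 = eps[:, 0, 1].copy()
    eps[:, 0, 1] = 0.0
    eps[:, 1, 0] = 0.0
    # clamp the compressive strain driving exp(Q) to keep stresses finite
    eps[:, [0, 1], [0, 1]] = np.clip(eps[:, [0, 1], [0, 1]], -0.45, None)
    S = fung_stress(eps, 1.0, params)             # (m, 2, 2), kPa
    sh = 2.0 * params.c * params.shear_stabilization * eps12
    S[:, 0, 1] = sh
    S[:, 1, 0] = sh
    # P = F S ; energy gradient wrt edge vectors is P B^T, scaled by A0 t0
    P = F @ S                                     # (m, 3, 2)
    G = P @ np.swapaxes(elements.inv_ref, -1, -2)  # (m, 3, 2)
    scale = (KPA_TO_N_PER_MM2 * elements.area0 * elements.t0)[:, None]
    f1 = -scale * G[:, :, 0]
    f2 = -scale * G[:, :, 1]
    f0 = -(f1 + f2)
    if out is None:
        out = np.zeros_like(positions)
    np.add.at(out, t[:, 0], f0)
    np.add.at(out, t[:, 1], f1)
    np.add.at(out, t[:, 2], f2)
    return out


def tangent_stiffness_scale(elements: MembraneElements, positions: np.ndarray,
                            params: FungParams) -> np.ndarray:
    """Per-element upper-bound tangent stiffness (N/mm) for explicit mass scaling."""
    st = membrane_state(elements, positions)
    e1 = st.eps[:, 0, 0]
    e2 = st.eps[:, 1, 1]
    q, be1, be2 = _q_and_beps(st.eps, params)
    _, gp = _exp_g(q)
    bmax = max(params.b_ff, params.b_ss) + abs(params.b_fs)
    emod = params.c * gp * (bmax + 2.0 * bmax ** 2 * (e1 ** 2 + e2 ** 2) +
                            2.0 * params.shear_stabilization)
    # stretch the modulus by the squared stretch (geometric stiffening)
    emod = emod * np.maximum(1.0, st.areal_stretch) ** 2
    h2 = elements.altitude0 ** 2               # smallest reference altitude
    return KPA_TO_N_PER_MM2 * emod * elements.t0 * elements.area0 / h2
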