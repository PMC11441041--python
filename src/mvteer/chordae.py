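"""Branched chordae tendineae: generation, pre-stretch, tension-only forces.

Each chorda is a tree of cable segments: a trunk from a papillary tip to a
branch node, splitting into two branches that insert on the leaflet free
margin. Twelve chordae originate from each papillary muscle by default,
each splitting into two branches before insertion; each papillary tip
serves the commissural half of both leaflets on its own side.

Cables are tension-only linear springs on engineering strain: segment
tension T = k max(0, L/L0 - 1). Pre-stretch lambda0 rescales rest lengths
so that the as-generated (diastolic) configuration carries stretch lambda0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, NumericalError, ParameterError
from .geometry import ANTERIOR, ANTEROLATERAL, POSTERIOR, POSTEROMEDIAL, ValveGeometry

DEFAULT_STIFFNESS = 6.0        # N per unit strain, per segment
DEFAULT_BRANCH_FRACTION = 0.8  # branch point at this fraction of tip->margin distance


@dataclass
class Chorda:
    """One branched chorda: trunk from a papillary tip, two margin insertions."""

    origin_tip: str                      # papillary label
    branch_point: np.ndarray             # (3,) mm, as generated
    insertion_vertex_ids: np.ndarray     # (2,) mesh vertex ids on the free margin
    rest_length_trunk: float             # mm
    rest_length_branches: np.ndarray     # (2,) mm
    pre_stretch: float = 1.0
    stiffness: float = DEFAULT_STIFFNESS

    def __post_init__(self):
        self.branch_point = np.asarray(self.branch_point, dtype=float)
        self.insertion_vertex_ids = np.asarray(self.insertion_vertex_ids, dtype=np.int64)
        self.rest_length_branches = np.asarray(self.rest_length_branches, dtype=float)
        if self.rest_length_trunk <= 0 or np.any(self.rest_length_branches <= 0):
            raise ParameterError("chordal rest lengths must be positive")
        if self.pre_stretch < 1.0:
            raise ParameterError(f"pre_stretch must be >= 1, got {self.pre_stretch}")


@dataclass
class ChordalApparatus:
    chordae: list
    n_per_papillary: int = 12

    def to_json(self) -> str:
        return json.dumps([
            {
                "origin_tip": c.origin_tip,
                "branch_point": c.branch_point.tolist(),
                "insertion_vertex_ids": c.insertion_vertex_ids.tolist(),
                "rest_length_trunk": c.rest_length_trunk,
                "rest_length_branches": c.rest_length_branches.tolist(),
                "pre_stretch": c.pre_stretch,
                "stiffness": c.stiffness,
            }
            for c in self.chordae
        ], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ChordalApparatus":
        items = json.loads(text)
        chordae = [Chorda(**it) for it in items]
        per = {}
        for c in chordae:
            per[c.origin_tip] = per.get(c.origin_tip, 0) + 1
        return cls(chordae=chordae, n_per_papillary=max(per.values()) if per else 0)


def _chain_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def generate_chordae(geometry: ValveGeometry, n_per_pm: int = 12, branches: int = 2,
                     branch_fraction: float = DEFAULT_BRANCH_FRACTION,
                     stiffness: float = DEFAULT_STIFFNESS,
                     pre_stretch: float = 1.0) -> ChordalApparatus:
    """Distribute branched chordae evenly along the free margins.

    Each papillary tip serves its ipsilateral commissural half of both
    leaflets: insertion sites are spaced evenly by arc length along each
    half-chain, consecutive pairs feeding one chorda. Rest lengths are the
    generated geometric lengths divided by ``pre_stretch``.
    """
    if n_per_pm < 1:
        raise ParameterError(f"n_per_pm must be >= 1, got {n_per_pm}")
    if branches != 2:
        raise ParameterError("exactly 2 branches per chorda are supported")
    if not 0.0 < branch_fraction < 1.0:
        raise ParameterError(f"branch_fraction must be in (0, 1), got {branch_fraction}")

    fr = geometry.frame
    # rest lengths anchor to the untethered reference tip position when one
    # exists: papillary displacement (ventricular remodeling) then loads
    # the chordae instead of being absorbed into their rest lengths
    tips = {lab: geometry.papillary_tips[lab].get(
        "rest_reference", geometry.papillary_tips[lab]["end_diastole"])
        for lab in (ANTEROLATERAL, POSTEROMEDIAL)}
    chordae = []
    for leaflet in (ANTERIOR, POSTERIOR):
        chain = geometry.free_edge_vertex_ids[leaflet]
        pts = geometry.vertices[chain]
        # commissural coordinate: sign of the commissural-axis component
        y = fr.to_local(pts)[:, 1]
        for tip_label, side in ((ANTEROLATERAL, +1.0), (POSTEROMEDIAL, -1.0)):
            mask = side * y >= 0.0
            ids = chain[mask]
            if len(ids) < 2:
                raise GeometryError(
                    f"free margin of {leaflet} leaflet too short on the "
                    f"{tip_label} side for chordal insertions")
            half = geometry.vertices[ids]
            s = _chain_arclength(half)
            # n_per_pm chordae per tip are split between the two leaflets
            n_here = n_per_pm // 2 + (1 if (n_per_pm % 2 and leaflet == ANTERIOR) else 0)
            if n_here == 0:
                continue
            n_ins = 2 * n_here
            targets = (np.arange(n_ins) + 0.5) / n_ins * s[-1]
            pick = np.array([int(np.argmin(np.abs(s - t))) for t in targets])
            # on coarse chains different chordae may share a vertex, but the
            # two branches of one chorda must insert at distinct vertices
            for k in range(n_here):
                if pick[2 * k] == pick[2 * k + 1]:
                    if pick[2 * k + 1] < len(ids) - 1:
                        pick[2 * k + 1] += 1
                    else:
                        pick[2 * k] -= 1
            tip = tips[tip_label]
            for k in range(n_here):
                ia, ib = ids[pick[2 * k]], ids[pick[2 * k + 1]]
                pa, pb = geometry.vertices[ia], geometry.vertices[ib]
                mid = 0.5 * (pa + pb)
                bp = tip + branch_fraction * (mid - tip)
                lt = float(np.linalg.norm(bp - tip))
                lb = np.array([np.linalg.norm(pa - bp), np.linalg.norm(pb - bp)])
                chordae.append(Chorda(
                    origin_tip=tip_label, branch_point=bp,
                    insertion_vertex_ids=np.array([ia, ib]),
                    rest_length_trunk=lt / pre_stretch,
                    rest_length_branches=lb / pre_stretch,
                    pre_stretch=pre_stretch, stiffness=stiffness,
                ))
    return ChordalApparatus(chordae=chordae, n_per_papillary=n_per_pm)


def apply_prestretch(apparatus: ChordalApparatus, lam0) -> ChordalApparatus:
    """Rescale rest lengths so the as-generated configuration carries stretch lam0.

    ``lam0`` is a scalar or one value per chorda; values must be >= 1.
    Rest lengths are re-derived from the generated lengths (rest * old
    pre-stretch), so the operation is idempotent in the generated state.
    """
    lam = np.asarray(lam0, dtype=float)
    if lam.ndim == 0:
        lam = np.full(len(apparatus.chordae), float(lam))
    if len(lam) != len(apparatus.chordae):
        raise ParameterError("one pre-stretch per chorda required")
    if np.any(lam < 1.0):
        raise ParameterError("pre-stretch must be >= 1")
    out = []
    for c, l0 in zip(apparatus.chordae, lam):
        gen_trunk = c.rest_length_trunk * c.pre_stretch
        gen_branches = c.rest_length_branches * c.pre_stretch
        out.append(replace(
            c,
            branch_point=c.branch_point.copy(),
            insertion_vertex_ids=c.insertion_vertex_ids.copy(),
            rest_length_trunk=gen_trunk / l0,
            rest_length_branches=gen_branches / l0,
            pre_stretch=float(l0),
        ))
    return ChordalApparatus(chordae=out, n_per_papillary=apparatus.n_per_papillary)


def _segment_force(p: np.ndarray, q: np.ndarray, rest: float, k: float):
    """Tension-only spring force on endpoint p (equal-and-opposite on q)."""
    d = q - p
    length = np.linalg.norm(d)
    if length < 1e-12:
        raise NumericalError("zero-length chordal segment")
    strain = length / rest - 1.0
    T = k * max(0.0, strain)
    return (T / length) * d, T


def chordal_force(chorda: Chorda, tip_position: np.ndarray,
                  branch_position: np.ndarray,
                  insertion_positions: np.ndarray) -> dict:
    """Nodal forces (N) of one chorda at the given node positions.

    Returns {"tip", "branch", "insertions"} force vectors. Every segment
    contributes an equal-and-opposite pair, so the global sum is exactly
    zero; the branch node balances only at equilibrium (it is a massless
    junction resolved by the solver).
    """
    tip_position = np.asarray(tip_position, dtype=float)
    branch_position = np.asarray(branch_position, dtype=float)
    insertion_positions = np.asarray(insertion_positions, dtype=float)
    f_tip = np.zeros(3)
    f_branch = np.zeros(3)
    f_ins = np.zeros((2, 3))
    f, _ = _segment_force(tip_position, branch_position,
                          chorda.rest_length_trunk, chorda.stiffness)
    f_tip += f
    f_branch -= f
    for j in range(2):
        f, _ = _segment_force(branch_position, insertion_positions[j],
                              chorda.rest_length_branches[j], chorda.stiffness)
        f_branch += f
        f_ins[j] -= f
    return {"tip": f_tip, "branch": f_branch, "insertions": f_ins}


def chordal_energy(chorda: Chorda, tip_position, branch_position,
                   insertion_positions) -> float:
    """Elastic energy (N mm): sum of (k/2) max(0, lam-1)^2 L0 per segment."""
    def seg(p, q, rest):
        lam = np.linalg.norm(np.asarray(q, float) - np.asarray(p, float)) / rest
        return 0.5 * chorda.stiffness * max(0.0, lam - 1.0) ** 2 * rest

    e = seg(tip_position, branch_position, chorda.rest_length_trunk)
    for j in range(2):
        e += seg(branch_position, insertion_positions[j], chorda.rest_length_branches[j])
    return float(e)


def apparatus_arrays(apparatus: ChordalApparatus, geometry: ValveGeometry,
                     phase: str = "early_systole"):
    """Flatten the apparatus into solver-ready arrays.

    Returns (tip_positions (n_ch, 3), branch_rest (n_ch,), insertion ids
    (n_ch, 2), branch rest lengths (n_ch, 2), stiffness (n_ch,), initial
    branch positions (n_ch, 3)).
    """
    tips = geometry.tips(phase)
    tip_pos = np.array([tips[c.origin_tip] for c in apparatus.chordae])
    trunk_rest = np.array([c.rest_length_trunk for c in apparatus.chordae])
    ins_ids = np.array([c.insertion_vertex_ids for c in apparatus.chordae])
    br_rest = np.array([c.rest_length_branches for c in apparatus.chordae])
    stiff = np.array([c.stiffness for c in apparatus.chordae])
    br_pos = np.array([c.branch_point for c in apparatus.chordae])
    return tip_pos, trunk_rest, ins_ids, br_rest, stiff, br_pos
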