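"""Solver: pressure loads, contact, equilibrium, inflation benchmark."""

import numpy as np
import pytest
import trimesh

from mvteer.errors import ParameterError
from mvteer.geometry import ANTERIOR, POSTERIOR
from mvteer.material import FungParams
from mvteer.solver import (SolverConfig, contact_forces, inflate_membrane,
                           make_circular_membrane, pressure_forces,
                           simulate_closure, _point_triangle_closest)


class TestPressureForces:
    def test_zero_pressure_zero_forces(self, healthy_valve):
        f = pressure_forces(healthy_valve.vertices, healthy_valve.triangles, 0.0)
        assert np.abs(f).max() == 0.0

    def test_closed_sphere_net_force_vanishes(self):
        # divergence theorem: uniform pressure on a closed surface
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
        f = pressure_forces(np.asarray(sphere.vertices),
                            np.asarray(sphere.faces), 1.0)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_flat_unit_square_closed_form(self):
        # 10 x 10 mm square at 1 kPa -> 0.1 N normal to the plane
        v = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], float)
        t = np.array([[0, 1, 2], [0, 2, 3]])
        f = pressure_forces(v, t, 1.0)
        assert f.sum(axis=0) == pytest.approx([0, 0, 0.1], abs=1e-12)

    def test_total_force_equals_area_weighted_normals(self, healthy_valve, rng):
        p = 2.5
        corr = rng.uniform(-1, 1, len(healthy_valve.triangles))
        f = pressure_forces(healthy_valve.vertices, healthy_valve.triangles,
                            p, corr)
        v, t = healthy_valve.vertices, healthy_valve.triangles
        an = 0.5 * np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        expected = 1e-3 * ((p + corr)[:, None] * an).sum(axis=0)
        assert np.allclose(f.sum(axis=0), expected, atol=1e-12)

    def test_mismatched_corrective_field_rejected(self, healthy_valve):
        with pytest.raises(ParameterError):
            pressure_forces(healthy_valve.vertices, healthy_valve.triangles,
                            1.0, np.zeros(3))


class TestPointTriangleProjection:
    def test_matches_slow_reference(self, rng):
        # oracle: scalar reference implementation per pair
        def slow(p, a, b, c):
            best, bp = None, None
            for u in np.linspace(0, 1, 201):
                for v in np.linspace(0, 1 - u, max(2, int(201 * (1 - u)) + 1)):
                    q = a + u * (b - a) + v * (c - a)
                    d = np.linalg.norm(p - q)
                    if best is None or d < best:
                        best, bp = d, q
            return best

        pts = rng.normal(size=(40, 3)) * 3
        tris = rng.normal(size=(40, 3, 3)) * 3
        closest, bary = _point_triangle_closest(pts, tris)
        d_fast = np.linalg.norm(pts - closest, axis=1)
        for k in range(len(pts)):
            d_ref = slow(pts[k], *tris[k])
            assert d_fast[k] <= d_ref + 1e-3
            assert abs(bary[k].sum() - 1) < 1e-9
            assert (bary[k] > -1e-9).all()


class TestContact:
    def test_separated_leaflets_no_contact(self, healthy_valve, solver_config):
        f = contact_forces(healthy_valve, healthy_valve.vertices, solver_config)
        assert np.abs(f).max() == 0.0

    def _patch_pair(self, separation):
        # small anterior triangle hovering over a large posterior triangle:
        # every anterior node projects inside the posterior interior, and
        # the posterior vertices are too far out to see the anterior patch
        from mvteer.geometry import ValveFrame, ValveGeometry
        big = 60.0
        verts = np.array([
            [-big, -big, 0.0], [big, -big, 0.0], [0.0, big, 0.0],   # posterior
            [-1.0, -1.0, separation], [1.0, -1.0, separation],
            [0.0, 1.0, separation],                                  # anterior
        ])
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        frame = ValveFrame(origin=np.zeros(3), axial_axis=[0, 0, 1.0],
                           commissural_axis=[0, 1.0, 0],
                           septal_lateral_axis=[1.0, 0, 0])
        tips = {lab: {"end_diastole": np.array([0.0, s, -9.0]),
                      "early_systole": np.array([0.0, s, -9.0])}
                for lab, s in (("anterolateral", 5.0), ("posteromedial", -5.0))}
        return ValveGeometry(
            vertices=verts, triangles=tris,
            leaflet_label=np.array([POSTERIOR, ANTERIOR], dtype=object),
            annulus_vertex_ids=np.array([0, 1, 2]),
            free_edge_vertex_ids={ANTERIOR: np.array([3, 4, 5]),
                                  POSTERIOR: np.array([0, 1, 2])},
            papillary_tips=tips, thickness=np.ones(6), frame=frame)

    def test_penalty_matches_hand_computation_on_parallel_patches(
            self, solver_config):
        gap = solver_config.contact_gap
        d = 0.5 * gap
        g = self._patch_pair(d)
        f = contact_forces(g, g.vertices, solver_config)
        # action-reaction: exact zero total
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)
        # each anterior node: single pair at distance d, force k*(gap-d) up
        expected = solver_config.contact_penalty * (gap - d)
        for n in (3, 4, 5):
            assert f[n] == pytest.approx([0.0, 0.0, expected], abs=1e-9)

    def test_no_force_beyond_the_gap_on_patches(self, solver_config):
        g = self._patch_pair(1.5 * solver_config.contact_gap)
        f = contact_forces(g, g.vertices, solver_config)
        assert np.abs(f).max() == 0.0

    def test_valve_contact_bounded_and_balanced(self, healthy_valve,
                                                solver_config):
        # push one anterior free-edge node to gap/2 from the posterior edge
        pos = healthy_valve.vertices.copy()
        ids_a = healthy_valve.free_edge_vertex_ids[ANTERIOR]
        ids_p = healthy_valve.free_edge_vertex_ids[POSTERIOR]
        target = pos[ids_p[len(ids_p) // 2]]
        node = ids_a[len(ids_a) // 2]
        gap = solver_config.contact_gap
        pos[node] = target + np.array([0.5 * gap, 0.0, 0.0])
        f = contact_forces(healthy_valve, pos, solver_config)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)
        # own pass bounded by k*gap; the reaction pass can add up to as much
        mag = np.linalg.norm(f[node])
        assert mag <= 2.0 * solver_config.contact_penalty * gap + 1e-9


class TestEquilibrium:
    def test_unloaded_valve_stays_undeformed(self, healthy_valve,
                                             healthy_chordae, fung_params):
        cfg = SolverConfig(pressure_systole=0.0)
        st = simulate_closure(healthy_valve, healthy_chordae, fung_params, cfg)
        disp = np.abs(st.positions - healthy_valve.vertices).max()
        assert disp < 1e-6

    def test_rerun_from_converged_state_is_stationary(self, healthy_closed,
                                                      healthy_valve,
                                                      healthy_chordae,
                                                      fung_params,
                                                      solver_config):
        st2 = simulate_closure(healthy_valve, healthy_chordae, fung_params,
                               solver_config,
                               initial_positions=healthy_closed.positions,
                               initial_branch=healthy_closed.branch_positions)
        moved = np.abs(st2.positions - healthy_closed.positions).max()
        assert moved < 1e-8

    def test_residual_below_tolerance_at_convergence(self, healthy_closed,
                                                     solver_config):
        assert healthy_closed.converged
        assert healthy_closed.residual_history[-1] < solver_config.residual_tol

    def test_pressure_work_bounds_strain_energy(self, healthy_closed):
        # kinetic damping dissipates the difference
        assert healthy_closed.external_work >= healthy_closed.strain_energy > 0

    def test_healthy_valve_coapts_under_systolic_load(self, healthy_closed,
                                                      healthy_valve,
                                                      solver_config):
        # inter-leaflet gap below contact_gap over most of the free margin
        from scipy.spatial import cKDTree
        pos = healthy_closed.positions
        ids_p = healthy_valve.free_edge_vertex_ids[POSTERIOR]
        tris_a = healthy_valve.leaflet_triangles(ANTERIOR)
        tp = pos[tris_a]
        dmin = np.full(len(ids_p), np.inf)
        for i, p in enumerate(pos[ids_p]):
            c, _ = _point_triangle_closest(np.repeat(p[None], len(tp), 0), tp)
            dmin[i] = np.linalg.norm(c - p, axis=1).min()
        frac = (dmin < 1.05 * solver_config.contact_gap).mean()
        assert frac > 0.5


class TestInflationBenchmark:
    def test_center_deflection_matches_hencky_closed_form(self):
        # linear isotropic limit of the constitutive law
        b, nu, c = 1.0, 0.3, 100.0
        E = c * b * (1 - nu ** 2)
        params = FungParams(c=c, b_ff=b, b_ss=b, b_fs=nu * b,
                            shear_stabilization=E / (2 * (1 + nu)) / c)
        a, t, p = 10.0, 0.5, 2.0
        w0, _ = inflate_membrane(a, p, params, thickness=t, edge=1.0)
        w_ref = 0.662 * a * (p * a / (E * t)) ** (1 / 3)
        assert w0 == pytest.approx(w_ref, rel=0.10)

    def test_mesh_generation_is_clean(self):
        v, t, rim = make_circular_membrane(radius=10.0, edge=1.0)
        assert len(rim) >= 12
        r = np.linalg.norm(v[rim, :2], axis=1)
        assert np.allclose(r, 10.0, atol=1e-9)
        areas = 0.5 * np.linalg.norm(np.cross(
            v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1)
        assert areas.min() > 1e-6
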