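"""Synthetic valve generation, slicing, reconstruction, morphing, I/O."""

import numpy as np
import pytest

from mvteer.errors import GeometryError, ParameterError, SchemaError
from mvteer.geometry import (ANTERIOR, ANTEROLATERAL, POSTERIOR, POSTEROMEDIAL,
                             SliceSet, SynthValveConfig, generate_synthetic_valve,
                             mean_surface_distance, morph_to_systolic_reference,
                             read_valve, reconstruct_from_slices, slice_valve,
                             surface_area, write_valve)


class TestGeneration:
    def test_default_valve_satisfies_invariants(self, healthy_valve):
        healthy_valve.validate()   # raises on any violation
        assert len(healthy_valve.papillary_tips) == 2
        assert set(healthy_valve.free_edge_vertex_ids) == {ANTERIOR, POSTERIOR}

    def test_requested_ap_diameter_is_realised(self):
        g = generate_synthetic_valve(SynthValveConfig(
            annulus_ap_diameter=30.0, mesh_edge_length=2.0))
        x = g.frame.to_local(g.vertices[g.annulus_vertex_ids])[:, 0]
        assert x.max() - x.min() == pytest.approx(30.0, abs=g.mesh_edge_length)

    def test_surface_area_matches_per_triangle_summation(self, healthy_valve):
        # independent oracle: python loop over triangles
        total = 0.0
        for t in healthy_valve.triangles:
            a, b, c = healthy_valve.vertices[t]
            total += 0.5 * np.linalg.norm(np.cross(b - a, c - a))
        assert surface_area(healthy_valve) == pytest.approx(total, rel=1e-12)

    def test_determinism_is_bitwise(self, healthy_config):
        g1 = generate_synthetic_valve(healthy_config)
        g2 = generate_synthetic_valve(healthy_config)
        assert np.array_equal(g1.vertices, g2.vertices)
        assert np.array_equal(g1.triangles, g2.triangles)

    def test_different_seed_changes_surface(self, healthy_config):
        g1 = generate_synthetic_valve(healthy_config)
        g2 = generate_synthetic_valve(SynthValveConfig(
            **{**healthy_config.to_dict(), "seed": 7}))
        assert not np.array_equal(g1.vertices, g2.vertices)

    @pytest.mark.parametrize("field,value", [
        ("annulus_ap_diameter", -1.0), ("dilation_factor", 0.9),
        ("mesh_edge_length", 0.0), ("thickness", -0.5)])
    def test_invalid_config_names_the_field(self, field, value):
        cfg = SynthValveConfig(**{field: value})
        with pytest.raises(ParameterError, match=field):
            generate_synthetic_valve(cfg)

    def test_tips_are_ventricular_both_phases(self, regurgitant_valve):
        for lab in (ANTEROLATERAL, POSTEROMEDIAL):
            for ph in ("end_diastole", "early_systole"):
                p = regurgitant_valve.papillary_tips[lab][ph]
                assert regurgitant_valve.frame.to_local(p[None])[0, 2] < 0


class TestSlicing:
    @pytest.mark.parametrize("spacing,expected", [(10.0, 18), (90.0, 2), (30.0, 6)])
    def test_slice_count(self, healthy_valve, spacing, expected):
        ss = slice_valve(healthy_valve, spacing)
        assert len(ss.slices) == expected

    def test_non_divisor_spacing_rejected(self, healthy_valve):
        with pytest.raises(ParameterError):
            slice_valve(healthy_valve, 7.0)

    def test_trace_points_lie_on_mesh_surface(self, healthy_valve):
        # oracle: exact point-to-surface distance must vanish
        from mvteer.calibration import nearest_on_surface
        mesh = healthy_valve.as_trimesh()
        ss = slice_valve(healthy_valve)
        pts = np.vstack([np.vstack([s["anterior_trace"], s["posterior_trace"]])
                         for s in ss.slices])
        near = nearest_on_surface(mesh, pts)
        assert np.abs(near - pts).max() < 1e-6

    def test_traces_ordered_annulus_to_free_edge(self, healthy_valve):
        ss = slice_valve(healthy_valve)
        ann = healthy_valve.vertices[healthy_valve.annulus_vertex_ids]
        from scipy.spatial import cKDTree
        tree = cKDTree(ann)
        for s in ss.slices:
            for key in ("anterior_trace", "posterior_trace"):
                tr = s[key]
                assert tree.query(tr[0])[0] < tree.query(tr[-1])[0]


class TestReconstruction:
    def test_roundtrip_surface_distance_below_edge_length(self, healthy_valve):
        ss = slice_valve(healthy_valve)
        rec = reconstruct_from_slices(ss, healthy_valve.papillary_tips)
        rec.validate()
        d = mean_surface_distance(healthy_valve.as_trimesh(), rec.as_trimesh())
        assert d < healthy_valve.mesh_edge_length

    def test_single_slice_rejected(self, healthy_valve):
        ss = slice_valve(healthy_valve, 90.0)
        ss.slices = ss.slices[:1]
        with pytest.raises(ParameterError):
            reconstruct_from_slices(ss, healthy_valve.papillary_tips)

    def test_flat_annular_disc_reconstructs_planar(self):
        # hand-built slices of a flat annular disc (z = 0 everywhere)
        tips = {lab: {"end_diastole": np.array([0.0, s, -10.0]),
                      "early_systole": np.array([0.0, s, -10.0])}
                for lab, s in ((ANTEROLATERAL, 5.0), (POSTEROMEDIAL, -5.0))}
        slices = []
        for k in range(18):
            th = np.radians(k * 10.0)
            r = np.linspace(10.0, 4.0, 8)
            fwd = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(8)])
            bwd = np.column_stack([-r * np.cos(th), -r * np.sin(th), np.zeros(8)])
            ant = fwd if np.cos(th) < 0 else bwd
            post = bwd if np.cos(th) < 0 else fwd
            slices.append({"angle": k * 10.0, "anterior_trace": ant,
                           "posterior_trace": post,
                           "annulus_landmarks": np.array([ant[0], post[0]])})
        ss = SliceSet(angular_spacing=10.0, slices=slices)
        rec = reconstruct_from_slices(ss, tips)
        assert np.abs(rec.vertices[:, 2]).max() < 1e-3


class TestMorphing:
    def _landmarks(self, g, tip_shift=(0.0, 0.0, 0.0), ann_shift=None):
        ann = g.vertices[g.annulus_vertex_ids].copy()
        if ann_shift is not None:
            ann = ann + ann_shift
        return {"annulus": ann,
                "papillary_tips": {
                    lab: g.papillary_tips[lab]["end_diastole"] + tip_shift
                    for lab in (ANTEROLATERAL, POSTEROMEDIAL)}}

    def test_identity_landmarks_leave_geometry_unchanged(self, healthy_valve):
        out = morph_to_systolic_reference(healthy_valve,
                                          self._landmarks(healthy_valve))
        assert np.abs(out.vertices - healthy_valve.vertices).max() < 1e-9

    def test_apical_tip_shift_preserves_annulus_and_matches_tips(self, healthy_valve):
        shift = (0.0, 0.0, -5.0)
        out = morph_to_systolic_reference(healthy_valve,
                                          self._landmarks(healthy_valve, shift))
        ann_ids = healthy_valve.annulus_vertex_ids
        assert np.abs(out.vertices[ann_ids] -
                      healthy_valve.vertices[ann_ids]).max() < 1e-9
        for lab in (ANTEROLATERAL, POSTEROMEDIAL):
            expected = healthy_valve.papillary_tips[lab]["end_diastole"] + shift
            assert np.abs(out.papillary_tips[lab]["early_systole"] -
                          expected).max() < 1e-9

    def test_topology_is_never_modified(self, healthy_valve):
        out = morph_to_systolic_reference(
            healthy_valve, self._landmarks(healthy_valve, (1.0, -2.0, -4.0)))
        assert np.array_equal(out.triangles, healthy_valve.triangles)

    def test_landmark_count_mismatch_rejected(self, healthy_valve):
        lm = self._landmarks(healthy_valve)
        lm["annulus"] = lm["annulus"][:-3]
        with pytest.raises(ParameterError):
            morph_to_systolic_reference(healthy_valve, lm)


class TestIO:
    @pytest.mark.parametrize("fmt", ["vtk", "ply"])
    def test_roundtrip_preserves_vertices_and_labels(self, healthy_valve,
                                                     tmp_path, fmt):
        mesh = tmp_path / f"v.{fmt}"
        lm = tmp_path / "v.json"
        write_valve(healthy_valve, mesh, lm)
        back = read_valve(mesh, lm)
        assert np.abs(back.vertices - healthy_valve.vertices).max() < 1e-6
        assert np.array_equal(back.leaflet_label, healthy_valve.leaflet_label)
        assert np.array_equal(back.annulus_vertex_ids,
                              healthy_valve.annulus_vertex_ids)
        assert np.allclose(back.thickness, healthy_valve.thickness)

    def test_vtk_and_ply_roundtrips_agree(self, healthy_valve, tmp_path):
        a = {}
        for fmt in ("vtk", "ply"):
            write_valve(healthy_valve, tmp_path / f"v.{fmt}", tmp_path / f"{fmt}.json")
            a[fmt] = read_valve(tmp_path / f"v.{fmt}", tmp_path / f"{fmt}.json")
        assert np.abs(a["vtk"].vertices - a["ply"].vertices).max() < 1e-6

    def test_stl_roundtrip_preserves_geometry(self, healthy_valve, tmp_path):
        # STL stores a facet soup: vertex order is not preserved, the
        # surface and labels are
        write_valve(healthy_valve, tmp_path / "v.stl", tmp_path / "v.json")
        back = read_valve(tmp_path / "v.stl", tmp_path / "v.json")
        d = mean_surface_distance(healthy_valve.as_trimesh(), back.as_trimesh())
        assert d < 1e-5
        assert np.array_equal(back.leaflet_label, healthy_valve.leaflet_label)

    def test_missing_landmark_file_is_schema_error(self, healthy_valve, tmp_path):
        write_valve(healthy_valve, tmp_path / "v.vtk", tmp_path / "v.json")
        with pytest.raises(SchemaError):
            read_valve(tmp_path / "v.vtk", tmp_path / "missing.json")

    def test_incomplete_landmark_schema_rejected(self, healthy_valve, tmp_path):
        import json
        write_valve(healthy_valve, tmp_path / "v.vtk", tmp_path / "v.json")
        doc = json.loads((tmp_path / "v.json").read_text())
        del doc["annulus"]
        (tmp_path / "v.json").write_text(json.dumps(doc))
        with pytest.raises(SchemaError):
            read_valve(tmp_path / "v.vtk", tmp_path / "v.json")
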