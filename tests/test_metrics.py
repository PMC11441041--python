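"""Orifice quantification: areas, summation, detection, coaptation height."""

import numpy as np
import pytest

from mvteer.errors import ParameterError
from mvteer.metrics import (OrificePolygon, coaptation_height, detect_orifices,
                            mva, orifice_area, total_ero, valve_metrics)
from mvteer.pipeline import make_elliptical_orifice_disc
from mvteer.solver import DIASTOLE, SYSTOLE


def _loop(points, phase=SYSTOLE):
    pts = np.asarray(points, dtype=float)
    return OrificePolygon(boundary=pts, plane_point=pts.mean(axis=0),
                          plane_normal=np.array([0.0, 0, 1]),
                          area=orifice_area(pts), phase=phase)


class _State:
    def __init__(self, positions, phase):
        self.positions = positions
        self.phase = phase
        self.converged = True


class TestOrificeArea:
    def test_square_loop_closed_form(self):
        sq = [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]]
        assert orifice_area(np.array(sq, dtype=float)) == pytest.approx(1.0)

    def test_degenerate_collinear_loop_has_zero_area(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 0, 0]], dtype=float)
        assert orifice_area(line) == pytest.approx(0.0, abs=1e-12)

    def test_tilted_planar_loop_equals_true_area(self, rng):
        # square rotated out of plane: vector area is rotation invariant
        from scipy.spatial.transform import Rotation
        sq = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], dtype=float)
        for _ in range(10):
            R = Rotation.random(rng=rng).as_matrix()
            assert orifice_area(sq @ R.T) == pytest.approx(1.0, rel=1e-12)

    def test_random_convex_loops_match_monte_carlo(self, rng):
        # oracle: rejection-sampled point-in-polygon area
        from shapely.geometry import Point, Polygon
        for _ in range(10):
            n = rng.integers(5, 12)
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(4, 9)
            xy = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
            loop = np.column_stack([xy, np.zeros(n)])
            poly = Polygon(xy)
            lo, hi = xy.min(axis=0), xy.max(axis=0)
            samples = rng.uniform(lo, hi, size=(20000, 2))
            inside = np.fromiter((poly.contains(Point(p)) for p in samples),
                                 bool, len(samples))
            box = np.prod(hi - lo)
            mc_area = inside.mean() * box / 100.0    # cm^2
            assert orifice_area(loop) == pytest.approx(mc_area, rel=0.05)


class TestSummation:
    def test_empty_list_is_zero(self):
        assert total_ero([]) == 0.0
        assert mva([]) == 0.0

    def test_two_orifice_sum(self):
        a = _loop([[0, 0, 0], [np.sqrt(5), 0, 0], [np.sqrt(5), np.sqrt(5), 0],
                   [0, np.sqrt(5), 0]])
        b = _loop([[0, 0, 0], [np.sqrt(3), 0, 0], [np.sqrt(3), np.sqrt(3), 0],
                   [0, np.sqrt(3), 0]])
        assert total_ero([a, b]) == pytest.approx(0.08, abs=1e-9)
        assert total_ero([b, a]) == pytest.approx(total_ero([a, b]))

    def test_mixed_phases_rejected(self):
        a = _loop(np.eye(3) * 3, SYSTOLE)
        b = _loop(np.eye(3) * 3, DIASTOLE)
        with pytest.raises(ParameterError):
            total_ero([a, b])
        with pytest.raises(ParameterError):
            mva([a, b])


class TestDetection:
    def test_machined_ellipse_area_within_five_percent(self):
        disc = make_elliptical_orifice_disc(semi_major=3.0, semi_minor=1.0,
                                            edge=0.5)
        state = _State(disc.vertices, SYSTOLE)
        orifices = detect_orifices(state, disc, gap_threshold=0.4)
        assert len(orifices) == 1
        analytic = np.pi * 3.0 * 1.0 / 100.0
        assert orifices[0].area == pytest.approx(analytic, rel=0.05)

    def test_open_valve_has_single_orifice(self, regurgitant_open,
                                           regurgitant_valve):
        orifices = detect_orifices(regurgitant_open, regurgitant_valve)
        assert len(orifices) == 1

    def test_nonconverged_state_rejected(self, regurgitant_valve):
        bad = _State(regurgitant_valve.vertices, SYSTOLE)
        bad.converged = False
        with pytest.raises(ParameterError):
            detect_orifices(bad, regurgitant_valve)

    def test_healthy_closed_valve_has_no_orifice(self, healthy_closed,
                                                 healthy_valve):
        orifices = detect_orifices(healthy_closed, healthy_valve)
        assert total_ero(orifices) == 0.0

    def test_ero_insensitive_to_gap_threshold(self, regurgitant_closed,
                                              regurgitant_valve):
        # ERO varies < 10% over thresholds of 0.5-1.5 leaflet thicknesses
        t = regurgitant_valve.mean_thickness
        eros = [total_ero(detect_orifices(regurgitant_closed,
                                          regurgitant_valve,
                                          gap_threshold=f * t))
                for f in (0.5, 1.0, 1.5)]
        assert min(eros) > 0
        assert (max(eros) - min(eros)) / max(eros) < 0.10


class TestLoopExport:
    def test_orifice_loops_roundtrip_through_vtk_polylines(self, tmp_path):
        from mvteer.metrics import write_orifice_loops_vtk
        from mvteer.pipeline import make_elliptical_orifice_disc
        disc = make_elliptical_orifice_disc(edge=0.5)
        state = _State(disc.vertices, SYSTOLE)
        orifices = detect_orifices(state, disc, gap_threshold=0.4)
        out = tmp_path / "loops.vtk"
        write_orifice_loops_vtk(orifices, out)
        text = out.read_text()
        assert "DATASET POLYDATA" in text
        assert f"LINES {len(orifices)}" in text
        n_pts = sum(len(o.boundary) for o in orifices)
        assert f"POINTS {n_pts} double" in text


class TestCoaptationHeight:
    def test_parallel_vertical_strips_overlap(self):
        # two vertical strips 0.5 mm apart overlapping 5 mm axially,
        # wrapped in a minimal valve-like geometry
        from mvteer.pipeline import make_elliptical_orifice_disc
        disc = make_elliptical_orifice_disc()
        state = _State(disc.vertices, SYSTOLE)
        # flat disc: traces coincide at z=0 -> per-slice height 0
        h, profile = coaptation_height(state, disc)
        assert h == pytest.approx(0.0)

    def test_healthy_valve_coapts_with_positive_height(self, healthy_closed,
                                                       healthy_valve):
        h, profile = coaptation_height(healthy_closed, healthy_valve)
        assert h > 1.0
        assert (profile > 0).mean() > 0.5

    def test_tethering_reduces_coaptation_height(self, healthy_closed,
                                                 healthy_valve,
                                                 regurgitant_closed,
                                                 regurgitant_valve):
        h_healthy, _ = coaptation_height(healthy_closed, healthy_valve)
        h_reg, _ = coaptation_height(regurgitant_closed, regurgitant_valve)
        assert h_reg < h_healthy

    def test_wrong_phase_rejected(self, regurgitant_open, regurgitant_valve):
        with pytest.raises(ParameterError):
            coaptation_height(regurgitant_open, regurgitant_valve)
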