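"""Constitutive law: strain measures, energy/stress consistency, elements."""

import numpy as np
import pytest

from mvteer.errors import NumericalError, ParameterError
from mvteer.material import (FungParams, build_elements, element_energy,
                             fung_energy, fung_stress, green_strain,
                             membrane_nodal_forces, membrane_state,
                             volumetric_pressure)


@pytest.fixture(scope="module")
def params():
    return FungParams()


class TestGreenStrain:
    def test_identity_gives_zero_strain(self):
        assert np.allclose(green_strain(np.eye(2)), 0.0)

    @pytest.mark.parametrize("lam", [1.1, 1.5, 0.8])
    def test_uniaxial_fiber_stretch_closed_form(self, lam):
        F = np.diag([lam, 1.0])
        eps = green_strain(F)
        assert eps[0, 0] == pytest.approx((lam ** 2 - 1) / 2, abs=1e-14)
        assert eps[1, 1] == pytest.approx(0.0, abs=1e-14)

    def test_shear_component_suppressed(self):
        F = np.array([[1.0, 0.3], [0.0, 1.0]])
        eps = green_strain(F)
        assert eps[0, 1] == 0.0 and eps[1, 0] == 0.0

    def test_matches_direct_recomputation_on_random_gradients(self, rng):
        # independent oracle: plain (F^T F - I)/2 with the shear zeroed
        for _ in range(50):
            F = np.eye(2) + 0.3 * rng.normal(size=(2, 2))
            if np.linalg.det(F) <= 0.05:
                continue
            expected = 0.5 * (F.T @ F - np.eye(2))
            expected[0, 1] = expected[1, 0] = 0.0
            assert np.allclose(green_strain(F), expected, atol=1e-12)

    def test_inverted_element_rejected(self):
        with pytest.raises(NumericalError):
            green_strain(np.diag([0.0, 1.0]))


class TestFungEnergy:
    def test_reference_state_has_zero_energy(self, params):
        assert fung_energy(np.zeros((2, 2)), 1.0, params) == pytest.approx(0.0)

    def test_fiber_only_strain_closed_form(self, params):
        e = 0.08
        eps = np.diag([e, 0.0])
        w = fung_energy(eps, 1.0, params)
        expected = 0.5 * params.c * (np.exp(params.b_ff * e ** 2) - 1.0)
        assert w == pytest.approx(expected, rel=1e-12)

    def test_volumetric_term_matches_direct_formula(self, params, rng):
        # independent oracle: (1/D)((J^2-1)/2 - ln J) evaluated separately
        for _ in range(30):
            J = rng.uniform(0.6, 1.6)
            w_vol = fung_energy(np.zeros((2, 2)), J, params)
            expected = (1.0 / params.D) * (0.5 * (J ** 2 - 1.0) - np.log(J))
            assert w_vol == pytest.approx(expected, abs=1e-12)

    def test_energy_nonnegative_and_zero_only_at_reference(self, params, rng):
        for _ in range(100):
            eps = np.diag(rng.uniform(-0.2, 0.4, size=2))
            J = rng.uniform(0.7, 1.4)
            w = fung_energy(eps, J, params)
            assert w >= -1e-14
            if abs(eps).max() > 1e-3 or abs(J - 1) > 1e-3:
                assert w > 0

    def test_nonpositive_jacobian_rejected(self, params):
        with pytest.raises(NumericalError):
            fung_energy(np.zeros((2, 2)), -0.5, params)


class TestFungStress:
    def test_stress_free_reference(self, params):
        assert np.allclose(fung_stress(np.zeros((2, 2)), 1.0, params), 0.0)

    def test_matches_finite_difference_gradient(self, params, rng):
        h = 1e-6
        for _ in range(100):
            eps = np.zeros((2, 2))
            eps[0, 0], eps[1, 1] = rng.uniform(-0.15, 0.3, size=2)
            S = fung_stress(eps, 1.0, params)
            for k in range(2):
                ep, em = eps.copy(), eps.copy()
                ep[k, k] += h
                em[k, k] -= h
                num = (fung_energy(ep, 1.0, params) -
                       fung_energy(em, 1.0, params)) / (2 * h)
                assert S[k, k] == pytest.approx(num, rel=1e-5, abs=1e-9)

    def test_small_strain_linearization(self, params):
        eps = np.diag([1e-3, -0.5e-3])
        S = fung_stress(eps, 1.0, params)
        lin = params.c * params.b_matrix @ np.array([eps[0, 0], eps[1, 1]])
        assert np.allclose(np.diag(S), lin, rtol=1e-2)

    def test_volumetric_pressure_is_dW_dJ(self, params):
        h = 1e-7
        for J in (0.8, 1.0, 1.3):
            num = (fung_energy(np.zeros((2, 2)), J + h, params) -
                   fung_energy(np.zeros((2, 2)), J - h, params)) / (2 * h)
            assert volumetric_pressure(J, params) == pytest.approx(num, rel=1e-6, abs=1e-8)

    def test_convexity_near_reference(self, params):
        # Hessian of W at eps=0 is c * b (plus shear term): positive definite
        ev = np.linalg.eigvalsh(params.c * params.b_matrix)
        assert ev.min() > 0


class TestParams:
    def test_indefinite_anisotropy_rejected(self):
        with pytest.raises(ParameterError):
            FungParams(b_ff=1.0, b_ss=1.0, b_fs=5.0).validate()

    @pytest.mark.parametrize("field,value", [("c", -1.0), ("D", 0.0)])
    def test_nonpositive_scalars_rejected(self, field, value):
        with pytest.raises(ParameterError):
            FungParams(**{field: value}).validate()


class TestMembraneElements:
    @pytest.fixture
    def patch(self, rng):
        verts = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.5, 1.8, 0],
                          [2.4, 1.9, 0.3]])
        tris = np.array([[0, 1, 2], [1, 3, 2]])
        return verts, tris

    def test_undeformed_patch_has_zero_forces(self, patch, params):
        verts, tris = patch
        els = build_elements(verts, tris, np.ones(len(verts)))
        f = membrane_nodal_forces(els, verts, params)
        assert np.abs(f).max() < 1e-12

    def test_forces_match_energy_finite_difference(self, patch, params, rng):
        verts, tris = patch
        els = build_elements(verts, tris, np.ones(len(verts)))
        pos = verts + 0.15 * rng.normal(size=verts.shape)
        f = membrane_nodal_forces(els, pos, params)
        h = 1e-6
        for i in range(len(verts)):
            for j in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, j] += h
                pm[i, j] -= h
                num = -(element_energy(els, pp, params).sum() -
                        element_energy(els, pm, params).sum()) / (2 * h)
                assert f[i, j] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_element_forces_sum_to_zero(self, patch, params, rng):
        verts, tris = patch
        els = build_elements(verts, tris, np.ones(len(verts)))
        pos = verts + 0.2 * rng.normal(size=verts.shape)
        f = membrane_nodal_forces(els, pos, params)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_frame_indifference_of_force_magnitudes(self, patch, params, rng):
        from scipy.spatial.transform import Rotation
        verts, tris = patch
        els = build_elements(verts, tris, np.ones(len(verts)))
        pos = verts + 0.2 * rng.normal(size=verts.shape)
        f = membrane_nodal_forces(els, pos, params)
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            fR = membrane_nodal_forces(els, pos @ R.T, params)
            assert np.allclose(np.linalg.norm(fR, axis=1),
                               np.linalg.norm(f, axis=1), atol=1e-9)
            assert np.allclose(fR, f @ R.T, atol=1e-9)

    def test_incompressible_thickness_update(self, patch, params):
        verts, tris = patch
        els = build_elements(verts, tris, np.ones(len(verts)))
        pos = verts.copy()
        pos[:, :2] *= 1.2   # biaxial in-plane stretch
        st = membrane_state(els, pos)
        assert np.allclose(st.J, 1.0)
        assert np.allclose(st.thickness_current, 1.0 / st.areal_stretch)
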