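"""Material-point law: kinematics, passive/volumetric/active stress."""

import numpy as np
import pytest

from conftest import random_deformation
from ventmech import material as M


def rot_about(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    th = np.deg2rad(deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K


class TestDecompose:
    def test_identity(self):
        J, Fd, Ed = M.decompose_deformation(np.eye(3))
        assert J == pytest.approx(1.0)
        assert np.allclose(Fd, np.eye(3))
        assert np.allclose(Ed, 0.0)

    def test_incompressible_fiber_shortening(self):
        # shortening to 80% with 1/sqrt(0.8) lateral stretch is isochoric
        lat = 1.0 / np.sqrt(0.8)
        J, _, _ = M.decompose_deformation(np.diag([0.8, lat, lat]))
        assert J == pytest.approx(1.0, abs=1e-10)

    def test_uniform_double(self):
        J, Fd, Ed = M.decompose_deformation(2.0 * np.eye(3))
        assert J == pytest.approx(8.0)
        assert np.allclose(Fd, np.eye(3), atol=1e-12)
        assert np.allclose(Ed, 0.0, atol=1e-12)

    def test_det_fdev_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            F = random_deformation(rng)
            _, Fd, _ = M.decompose_deformation(F)
            assert abs(np.linalg.det(Fd) - 1.0) < 1e-10

    def test_inverted_raises(self):
        with pytest.raises(M.InvalidDeformationError):
            M.decompose_deformation(np.diag([-1.0, 1.0, 1.0]))


class TestFungQ:
    def test_zero_strain(self, fiber_x_frame, params):
        assert M.fung_Q(np.zeros((3, 3)), fiber_x_frame, params) == 0.0

    def test_fiber_only_component(self, fiber_x_frame, params):
        E = np.zeros((3, 3))
        E[0, 0] = 0.1
        # A1 * E11^2 = 12 * 0.01
        assert M.fung_Q(E, fiber_x_frame, params) == pytest.approx(0.12)

    def test_transverse_isotropy(self, params):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((3, 3))
        E = 0.05 * (A + A.T)
        m = np.array([1.0, 0.0, 0.0])
        f1 = M.FiberFrame.from_fiber(m)
        R = rot_about(m, 30.0)
        f2 = M.FiberFrame(m=m, s=R @ f1.s, n=R @ f1.n)
        assert M.fung_Q(E, f1, params) == pytest.approx(
            M.fung_Q(E, f2, params), abs=1e-12)

    def test_asymmetric_raises(self, fiber_x_frame, params):
        E = np.zeros((3, 3))
        E[0, 1] = 0.1
        with pytest.raises(M.InvalidStrainError):
            M.fung_Q(E, fiber_x_frame, params)


def fd_passive_oracle(F, frame, params, h=1e-7):
    """Finite-difference oracle: d(W_dev)/d(F_dev) pushed forward, plus
    the volumetric pressure from dW_vol/dJ."""
    J, Fd, _ = M.decompose_deformation(F)

    def wdev(G):
        E = 0.5 * (G.T @ G - np.eye(3))
        Q = M.fung_Q(E, frame, params)
        return 0.5 * params.c * (np.exp(params.alpha * Q) - 1.0)

    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Gp = Fd.copy(); Gp[i, j] += h
            Gm = Fd.copy(); Gm[i, j] -= h
            P[i, j] = (wdev(Gp) - wdev(Gm)) / (2 * h)
    sig_dev = P @ Fd.T / J
    K = params.K_inc
    p_vol = ((K / 2) * ((J + h)**2 - 1) / 2 - (K / 2) * np.log(J + h)
             - ((K / 2) * ((J - h)**2 - 1) / 2 - (K / 2) * np.log(J - h))
             ) / (2 * h)
    return sig_dev + p_vol * np.eye(3)


class TestPassiveStress:
    def test_zero_at_identity(self, fiber_x_frame, params):
        sig = M.passive_deviatoric_cauchy(np.eye(3), fiber_x_frame, params)
        assert np.allclose(sig, 0.0, atol=1e-14)

    @pytest.mark.parametrize("case", ["equibiaxial", "shear"])
    def test_matches_fd_energy_oracle(self, fiber_x_frame, params, case):
        if case == "equibiaxial":
            s = 1.05
            F = np.diag([1.0 / s**2, s, s])
        else:
            F = np.eye(3)
            F[0, 1] = 0.1  # simple shear in the fiber plane
        sig = M.passive_deviatoric_cauchy(F, fiber_x_frame, params)
        J = np.linalg.det(F)
        oracle = fd_passive_oracle(F, fiber_x_frame, params)
        full = sig + M.volumetric_cauchy(J, params.K_inc)
        assert np.allclose(full, oracle, rtol=1e-6, atol=1e-8)
        if case == "shear":
            assert abs(sig[0, 1]) > 1e-3  # nonzero shear stress

    def test_energy_consistency_random_states(self, params):
        rng = np.random.default_rng(7)
        frame = M.FiberFrame.from_fiber(rng.standard_normal(3))
        for _ in range(50):
            F = random_deformation(rng, 0.08)
            J = np.linalg.det(F)
            full = (M.passive_deviatoric_cauchy(F, frame, params)
                    + M.volumetric_cauchy(J, params.K_inc))
            oracle = fd_passive_oracle(F, frame, params)
            scale = max(np.abs(oracle).max(), 1e-6)
            assert np.abs(full - oracle).max() / scale < 1e-5

    def test_overflow_flagged(self, fiber_x_frame, params):
        with pytest.raises(M.StrainDivergenceError):
            M.passive_deviatoric_cauchy(
                np.diag([8.0, 1.0, 1.0]), fiber_x_frame,
                params.with_(alpha=50.0))


class TestBulkModulus:
    def test_passive_is_K_inc(self, params):
        assert M.bulk_modulus(0.0, params) == params.K_inc

    def test_linear_softening(self):
        p = M.MaterialParameters(mode="compressible", gamma=5.0,
                                 K_inc=1000.0, K_floor=10.0)
        assert M.bulk_modulus(100.0, p) == pytest.approx(500.0)

    def test_floor_clamp(self):
        p = M.MaterialParameters(mode="compressible", gamma=5.0,
                                 K_inc=1000.0, K_floor=10.0)
        assert M.bulk_modulus(300.0, p) == pytest.approx(10.0)

    def test_incompressible_mode_constant(self, params):
        for T in [0.0, 50.0, 500.0]:
            assert M.bulk_modulus(T, params) == params.K_inc


class TestVolumetric:
    def test_zero_at_unit_jacobian(self):
        assert np.allclose(M.volumetric_cauchy(1.0, 123.0), 0.0)

    def test_compressive_value(self):
        sig = M.volumetric_cauchy(0.9, 100.0)
        assert sig[0, 0] == pytest.approx(50 * (0.9 - 1 / 0.9))
        assert sig[0, 0] < 0

    def test_sign_antisymmetry_series(self):
        eps = 1e-3
        p1 = M.volumetric_pressure(1 + eps, 100.0)
        p2 = M.volumetric_pressure(1 / (1 + eps), 100.0)
        assert p1 > 0
        assert p1 + p2 == pytest.approx(0.0, abs=100 * 5 * eps**2)


class TestFiberStretch:
    def test_identity(self):
        assert M.fiber_stretch(np.eye(3), [1, 0, 0]) == pytest.approx(1.0)

    def test_shortening(self):
        F = np.diag([0.8, 1.118, 1.118])
        assert M.fiber_stretch(F, [1, 0, 0]) == pytest.approx(0.8)

    def test_equals_norm(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            F = random_deformation(rng)
            m = rng.standard_normal(3)
            m /= np.linalg.norm(m)
            assert M.fiber_stretch(F, m) == pytest.approx(
                np.linalg.norm(F @ m), abs=1e-12)


class TestActiveStress:
    def test_zero_without_tension(self, fiber_x_frame, params):
        st = M.MaterialState(np.eye(3), T_Ca=0.0)
        assert np.allclose(M.active_cauchy(st, fiber_x_frame, params), 0.0)

    def test_reference_magnitude(self, fiber_x_frame, params):
        st = M.MaterialState(np.eye(3), T_Ca=100.0, f=1.0)
        sig = M.active_cauchy(st, fiber_x_frame, params)
        assert sig[0, 0] == pytest.approx(100.0)
        assert abs(sig[1, 1]) < 1e-12

    def test_pushforward_identity(self, fiber_x_frame):
        # lambda^2 cancels: magnitude is T f [1+beta(lam-1)] / J exactly
        params = M.MaterialParameters(beta=0.0)
        lat = 1.0 / np.sqrt(0.8)
        F = np.diag([0.8, lat, lat])  # J = 1, lam = 0.8
        st = M.MaterialState(F, T_Ca=50.0)
        sig = M.active_cauchy(st, fiber_x_frame, params)
        Fm = F @ fiber_x_frame.m
        lam = np.linalg.norm(Fm)
        S = 50.0 / lam**2 * np.outer(fiber_x_frame.m, fiber_x_frame.m)
        explicit = F @ S @ F.T / np.linalg.det(F)
        assert np.allclose(sig, explicit, atol=1e-12)
        assert sig[0, 0] == pytest.approx(50.0, abs=1e-10)

    def test_length_modulation_floor(self, fiber_x_frame, params):
        # beta=1.45: modulation hits zero at lam < 1 - 1/beta
        lam = 0.2
        F = np.diag([lam, 1.0, 1.0])
        st = M.MaterialState(F, T_Ca=100.0)
        sig = M.active_cauchy(st, fiber_x_frame, params)
        assert np.allclose(sig, 0.0)


class TestTotalStress:
    def test_zero_reference(self, fiber_x_frame, params):
        st = M.MaterialState(np.eye(3), T_Ca=0.0)
        assert np.allclose(M.total_cauchy(st, fiber_x_frame, params), 0.0,
                           atol=1e-12)

    def test_additivity(self, fiber_x_frame):
        params = M.MaterialParameters(mode="compressible", gamma=30.0,
                                      K_inc=1000.0)
        rng = np.random.default_rng(5)
        F = random_deformation(rng, 0.05)
        st = M.MaterialState(F, T_Ca=40.0, f=0.7)
        J = np.linalg.det(F)
        K = M.bulk_modulus(st.T_Ca * st.f, params)
        total = (M.volumetric_cauchy(J, K)
                 + M.passive_deviatoric_cauchy(F, fiber_x_frame, params)
                 + M.active_cauchy(st, fiber_x_frame, params))
        assert np.allclose(M.total_cauchy(st, fiber_x_frame, params), total,
                           atol=1e-12)

    def test_objectivity(self, params):
        rng = np.random.default_rng(11)
        frame = M.FiberFrame.from_fiber([0.3, 0.5, 0.81])
        F = random_deformation(rng, 0.06)
        st = M.MaterialState(F, T_Ca=20.0)
        sig = M.total_cauchy(st, frame, params)
        for _ in range(100):
            ax = rng.standard_normal(3)
            Q = rot_about(ax, rng.uniform(0, 360))
            stQ = M.MaterialState(Q @ F, T_Ca=20.0)
            sigQ = M.total_cauchy(stQ, frame, params)
            assert np.abs(sigQ - Q @ sig @ Q.T).max() < 1e-9 * max(
                1.0, np.abs(sig).max())

    def test_transverse_isotropy_of_stress(self, params):
        rng = np.random.default_rng(13)
        m = np.array([0.0, 0.0, 1.0])
        f1 = M.FiberFrame.from_fiber(m, hint=(1, 0, 0))
        R = rot_about(m, 47.0)
        f2 = M.FiberFrame(m=m, s=R @ f1.s, n=R @ f1.n)
        F = random_deformation(rng, 0.05)
        st = M.MaterialState(F, T_Ca=30.0)
        s1 = M.total_cauchy(st, f1, params)
        s2 = M.total_cauchy(st, f2, params)
        assert np.abs(s1 - s2).max() < 1e-9 * max(1.0, np.abs(s1).max())


class TestNumericalTangent:
    def test_h_range_enforced(self, fiber_x_frame, params):
        st = M.MaterialState(np.eye(3))
        with pytest.raises(ValueError):
            M.numerical_tangent(st, fiber_x_frame, params, h=1e-2)

    def test_positive_definite_at_identity(self, fiber_x_frame, params):
        st = M.MaterialState(np.eye(3), T_Ca=0.0)
        A = M.numerical_tangent(st, fiber_x_frame, params)
        # restrict to symmetric perturbations
        sym_basis = []
        for i in range(3):
            for j in range(i, 3):
                B = np.zeros((3, 3))
                B[i, j] = B[j, i] = 1.0
                sym_basis.append(B)
        Amat = np.array([[np.einsum("ij,ijkl,kl->", B1, A, B2)
                          for B2 in sym_basis] for B1 in sym_basis])
        eig = np.linalg.eigvalsh(0.5 * (Amat + Amat.T))
        assert eig.min() > 0

    def test_small_strain_limit_constant(self, fiber_x_frame, params):
        # with alpha*Q -> 0 the tangent approaches a constant tensor
        st1 = M.MaterialState(np.eye(3))
        F2 = np.eye(3) + 1e-4 * np.array([[0.0, 1.0, 0], [0, 0, 0],
                                          [0, 0, 0.0]])
        st2 = M.MaterialState(F2)
        A1 = M.numerical_tangent(st1, fiber_x_frame, params)
        A2 = M.numerical_tangent(st2, fiber_x_frame, params)
        assert np.abs(A1 - A2).max() < 1e-2 * np.abs(A1).max()


class TestLateralResponse:
    def test_incompressible_kinematics(self, params):
        lat = M.lateral_response(0.8, 100.0, params)
        assert lat == pytest.approx(1.0 / np.sqrt(0.8), abs=1e-12)

    def test_compressible_thickens_less(self):
        inc = M.MaterialParameters()
        lat_inc = M.lateral_response(0.8, 30.0, inc)
        comp = M.MaterialParameters(mode="compressible", gamma=30.0,
                                    K_inc=900.0)
        lat_c = M.lateral_response(0.8, 30.0, comp)
        assert lat_c < lat_inc


try:
    from hypothesis import given, settings, strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


@pytest.mark.skipif(not HAVE_HYPOTHESIS, reason="hypothesis not installed")
class TestKinematicProperties:
    """Randomized invariants of the deformation decomposition."""

    @staticmethod
    def _make_F(entries):
        F = np.eye(3) + 0.25 * np.array(entries).reshape(3, 3)
        if np.linalg.det(F) <= 0.05:
            F = np.eye(3) + 0.05 * np.array(entries).reshape(3, 3)
        return F

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=9,
                    max_size=9))
    def test_decomposition_reassembles(self, entries):
        F = self._make_F(entries)
        J, Fd, Ed = M.decompose_deformation(F)
        assert np.allclose(J ** (1 / 3) * Fd, F, atol=1e-12)
        assert abs(np.linalg.det(Fd) - 1) < 1e-10
        assert np.allclose(Ed, Ed.T, atol=1e-14)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=9,
                    max_size=9),
           st.lists(st.floats(-1, 1, allow_nan=False), min_size=3,
                    max_size=3))
    def test_fiber_stretch_norm_identity(self, entries, mvec):
        F = self._make_F(entries)
        m = np.array(mvec)
        n = np.linalg.norm(m)
        if n < 1e-3:
            m = np.array([1.0, 0.0, 0.0])
            n = 1.0
        m = m / n
        assert M.fiber_stretch(F, m) == pytest.approx(
            np.linalg.norm(F @ m), abs=1e-12)


class TestParameterValidation:
    def test_incompressible_requires_zero_gamma(self):
        with pytest.raises(ValueError):
            M.MaterialParameters(mode="incompressible", gamma=1.0)

    def test_negative_constants_rejected(self):
        with pytest.raises(ValueError):
            M.MaterialParameters(c=-1.0)

    def test_frame_validation(self):
        with pytest.raises(ValueError):
            M.FiberFrame(m=np.array([1.0, 0, 0]), s=np.array([1.0, 0, 0]),
                         n=np.array([0.0, 0, 1]))
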