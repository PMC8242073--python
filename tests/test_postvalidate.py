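"""Validation metrics: marker J, wall thickness, PV metrics, active work."""

import numpy as np
import pytest

from ventmech import postvalidate as P
from ventmech import synthdata as S
from ventmech.mechsolver import CycleSolution


# ---------------------------------------------------------------------------
# sonocrystal volume ratio


@pytest.fixture(scope="module")
def crystal_layout(coarse_lv):
    return S.default_crystal_layout(coarse_lv, "volume27")


class TestSonoVolumeJ:
    def test_static_markers_unity(self, crystal_layout):
        pts, layout = crystal_layout
        arr = S.gen_sonocrystal_array(lambda X, t: X, pts,
                                      times=np.linspace(0, 1, 4),
                                      layout=layout)
        J = P.sono_volume_J(arr)
        for series in J.values():
            assert np.allclose(series, 1.0, atol=1e-12)

    def test_linearly_varying_volumetric_field(self, crystal_layout):
        pts, layout = crystal_layout
        z0, z1 = pts[:, 2].min(), pts[:, 2].max()

        def g(z):  # local volume ratio, linear in z
            return 0.8 + 0.3 * (z - z0) / (z1 - z0)

        def deform(X, t):
            if t == 0:
                return X
            out = X.copy()
            out[:, 0] = X[:, 0] * g(X[:, 2])
            return out

        arr = S.gen_sonocrystal_array(deform, pts,
                                      times=np.array([0.0, 1.0]),
                                      layout=layout)
        J = P.sono_volume_J(arr)
        # regional means of det F = mean of g over each region's z-span;
        # the marker grid's longitudinal axis is not exactly z, so compare
        # against the g-average over the region's own markers
        grid = pts.reshape(3, 3, 3, 3)
        for region, sl in [("basal", slice(0, 2)), ("mid", slice(1, 3)),
                           ("apical", slice(1, 3))]:
            pass
        overall = J["overall"][1]
        expect = np.mean([g(z) for z in np.linspace(z0, z1, 200)])
        assert overall == pytest.approx(expect, rel=0.02)

    def test_degenerate_cell_raises(self, crystal_layout):
        pts, layout = crystal_layout
        flat = pts.copy()
        flat[:, 2] = 0.0  # coplanar markers
        arr = S.gen_sonocrystal_array(lambda X, t: X, flat,
                                      times=np.array([0.0]), layout=layout)
        with pytest.raises(ValueError):
            P.sono_volume_J(arr)


# ---------------------------------------------------------------------------
# wall thickness (marker version)


def flat_slab_markers():
    """Epi markers on z=10 plane (3x4 grid), endo markers on z=0 (3x3)."""
    xs4 = np.linspace(0, 30, 4)
    xs3 = np.linspace(2, 28, 3)
    ys = np.linspace(0, 20, 3)
    epi = np.array([[x, y, 10.0] for y in ys for x in xs4])
    endo = np.array([[x, y, 0.0] for y in ys for x in xs3])
    return epi, endo


class TestWallThicknessSono:
    def test_rigid_translation_unity(self):
        epi, endo = flat_slab_markers()
        d = np.array([3.0, -2.0, 5.0])
        ratio = P.wall_thickness_sono(np.stack([epi, epi + d]),
                                      np.stack([endo, endo + d]),
                                      es_index=1)
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_planted_uniform_thickening(self):
        epi, endo = flat_slab_markers()
        epi2 = epi.copy()
        epi2[:, 2] = 11.0  # 10% thicker
        ratio = P.wall_thickness_sono(np.stack([epi, epi2]),
                                      np.stack([endo, endo]), es_index=1)
        assert ratio == pytest.approx(1.10, rel=0.01)

    def test_apical_markers_excluded(self):
        epi, endo = flat_slab_markers()
        endo2 = endo.copy()
        endo2[:3] += np.array([50.0, 50.0, 50.0])  # ids 1-3 garbage
        r1 = P.wall_thickness_sono(np.stack([epi, epi]),
                                   np.stack([endo, endo]), es_index=1)
        r2 = P.wall_thickness_sono(np.stack([epi, epi]),
                                   np.stack([endo2, endo2]), es_index=1)
        assert r1 == pytest.approx(r2, abs=1e-12)


# ---------------------------------------------------------------------------
# FE-based metrics on synthetic displacement histories


def make_solution(mesh, displacements, times=None):
    S_ = len(displacements)
    E = mesh.n_elements
    times = np.linspace(0, 1, S_) if times is None else times
    from ventmech.heartgeom import cavity_volume

    vols = np.array([cavity_volume(mesh, d) for d in displacements])
    return CycleSolution(
        mesh=mesh, times=times,
        displacements=np.asarray(displacements),
        pressures=np.zeros(S_), cavity_volumes=vols,
        J=np.ones((S_, E)), lam=np.ones((S_, E, 8)),
        s_act_pk2=np.zeros((S_, E, 8)),
        sigma_act_fiber=np.zeros((S_, E, 8)),
        T_Ca=np.zeros(S_),
        gp_weights=np.full((E, 8), mesh.element_volumes()[:, None] / 8),
        elem_volumes=mesh.element_volumes(),
    )


class TestWallThicknessFem:
    def test_identity_unity(self, tiny_lv):
        sol = make_solution(tiny_lv, np.zeros((2,) + tiny_lv.nodes.shape))
        assert P.wall_thickness_fem(sol, es_index=1) == pytest.approx(1.0)

    def test_radial_scaling_known_thickening(self):
        from conftest import make_tiny_lv
        from ventmech import heartgeom as G

        # hemispherical shell: pure radial scaling thickens by the factor
        mesh = G.build_ideal_lv(base_radius_endo=25.0, wall_thickness=8.0,
                                long_axis=25.0, truncation_fraction=0.0,
                                target_edge_len=5.0)
        s = 1.08
        u = (s - 1.0) * mesh.nodes
        sol = make_solution(mesh, [np.zeros_like(u), u])
        ratio = P.wall_thickness_fem(sol, es_index=1)
        assert ratio == pytest.approx(s, rel=0.01)


class TestLVHeight:
    def test_identity(self, tiny_lv):
        sol = make_solution(tiny_lv, np.zeros((2,) + tiny_lv.nodes.shape))
        assert P.lv_height(sol, es_index=1) == pytest.approx(1.0)

    def test_pure_radial_deformation(self, tiny_lv):
        u = np.zeros_like(tiny_lv.nodes)
        u[:, :2] = -0.1 * tiny_lv.nodes[:, :2]
        sol = make_solution(tiny_lv, [np.zeros_like(u), u])
        assert P.lv_height(sol, es_index=1) == pytest.approx(1.0, abs=1e-9)

    def test_planted_longitudinal_shortening(self, tiny_lv):
        u = np.zeros_like(tiny_lv.nodes)
        u[:, 2] = -0.08 * tiny_lv.nodes[:, 2]
        sol = make_solution(tiny_lv, [np.zeros_like(u), u])
        assert P.lv_height(sol, es_index=1) == pytest.approx(0.92, abs=1e-6)


class TestPVMetrics:
    def test_printed_formulas(self):
        pv = S.gen_pv_loop(EDV=60.0, EF=0.30, HR=90.0)
        m = P.pv_metrics(pv)
        assert m["SV_mL"] == pytest.approx(18.0, abs=1e-9)
        assert m["EF"] == pytest.approx(0.30, abs=1e-9)
        assert m["CO_mL_per_min"] == pytest.approx(1620.0, abs=1e-6)
        assert m["dPdt_max_mmHg_per_s"] > 0 > m["dPdt_min_mmHg_per_s"]

    def test_rectangle_loop_area(self):
        # clockwise-in-time rectangle: P in [10, 100], V in [40, 60]
        t = np.linspace(0, 1, 401)
        V = np.empty_like(t)
        Pr = np.empty_like(t)
        for i, ti in enumerate(t):
            if ti < 0.25:
                V[i], Pr[i] = 60.0, 10 + 90 * (ti / 0.25)
            elif ti < 0.5:
                V[i], Pr[i] = 60 - 20 * (ti - 0.25) / 0.25, 100.0
            elif ti < 0.75:
                V[i], Pr[i] = 40.0, 100 - 90 * (ti - 0.5) / 0.25
            else:
                V[i], Pr[i] = 40 + 20 * (ti - 0.75) / 0.25, 10.0
        pv = S.PVTrace(t=t, P=Pr, V=V)
        m = P.pv_metrics(pv)
        assert m["stroke_work_mmHg_mL"] == pytest.approx(1800.0, rel=1e-9)
        assert m["orientation_valid"]

    def test_reversed_loop_flags_orientation(self):
        pv = S.gen_pv_loop()
        rev = S.PVTrace(t=pv.t, P=pv.P[::-1].copy(), V=pv.V[::-1].copy())
        m_fwd = P.pv_metrics(pv)
        m_rev = P.pv_metrics(rev)
        assert m_fwd["stroke_work_mmHg_mL"] == pytest.approx(
            -m_rev["stroke_work_mmHg_mL"], rel=1e-9)
        assert not m_rev["orientation_valid"]


class TestActiveWork:
    def test_zero_tension_zero_work(self, tiny_lv):
        sol = make_solution(tiny_lv, np.zeros((5,) + tiny_lv.nodes.shape))
        _, W, _ = P.active_work(sol)
        assert np.allclose(W, 0.0)

    def test_single_point_closed_form(self, tiny_lv):
        # one fictitious element, homogeneous lam(t), s(t):
        # W(t) = -int s d(lam^2/2), with linear histories -> closed form
        E = 1
        Sn = 51
        t = np.linspace(0, 1, Sn)
        lam = 1.0 - 0.2 * t
        s = 30.0 * t
        sol = CycleSolution(
            mesh=tiny_lv, times=t,
            displacements=np.zeros((Sn, 1, 3)), pressures=np.zeros(Sn),
            cavity_volumes=np.linspace(1, 0.5, Sn),
            J=np.ones((Sn, E)),
            lam=np.tile(lam[:, None, None], (1, E, 8)),
            s_act_pk2=np.tile(s[:, None, None], (1, E, 8)),
            sigma_act_fiber=np.zeros((Sn, E, 8)),
            T_Ca=s, gp_weights=np.full((E, 8), 1000.0 / 8),
            elem_volumes=np.array([1000.0]),
        )
        _, W, _ = P.active_work(sol)
        tt = np.linspace(0, 1, 20001)
        integrand = (30.0 * tt) * (1.0 - 0.2 * tt) * 0.2  # -s lam dlam/dt
        expect = 1000.0 * np.trapezoid(integrand, tt) * 1e-6  # J
        assert W[-1] == pytest.approx(expect, rel=0.01)


class TestStressSummary:
    def test_volume_conservation_and_infarct_zero(self, tiny_lv):
        from ventmech.heartgeom import aha_segment

        E = tiny_lv.n_elements
        Sn = 3
        sol = make_solution(tiny_lv,
                            np.zeros((Sn,) + tiny_lv.nodes.shape))
        sol.sigma_act_fiber = np.full((Sn, E, 8), 40.0)
        aha = aha_segment(tiny_lv)
        mask = aha == 17
        sol.sigma_act_fiber[:, mask, :] = 0.0  # infarcted cap
        summ = P.active_stress_summary(sol, aha)
        wall_vol = tiny_lv.element_volumes().sum()
        assert summ.hist_counts[0].sum() == pytest.approx(wall_vol,
                                                          rel=1e-9)
        assert summ.segment_means[16].max() < 1.0
        assert summ.segment_means[0].max() == pytest.approx(40.0)

    def test_segment_volumes_sum(self, tiny_lv):
        from ventmech.heartgeom import aha_segment

        sol = make_solution(tiny_lv,
                            np.zeros((2,) + tiny_lv.nodes.shape))
        summ = P.active_stress_summary(sol, aha_segment(tiny_lv))
        assert summ.segment_volumes.sum() == pytest.approx(
            tiny_lv.element_volumes().sum(), rel=1e-9)


class TestJFieldSummary:
    def test_planted_homogeneous_field(self, tiny_lv):
        sol = make_solution(tiny_lv, np.zeros((3,) + tiny_lv.nodes.shape))
        sol.J[:] = 0.93
        js = P.j_field_summary(sol)
        assert js["mean_J_es"] == pytest.approx(0.93)
        assert js["min_J_es"] == pytest.approx(0.93)
        for v in js["thirds_J_es"].values():
            assert v == pytest.approx(0.93)
        assert np.allclose(js["transmural_profile"][:, 1], 0.93)

    def test_metrics_rigid_motion_invariant(self, tiny_lv):
        # thickness/height under a rigid rotation + translation
        th = np.deg2rad(12.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        u = tiny_lv.nodes @ R.T + np.array([5.0, -3.0, 2.0]) - tiny_lv.nodes
        sol = make_solution(tiny_lv, [np.zeros_like(u), u])
        assert P.wall_thickness_fem(sol, es_index=1) == pytest.approx(
            1.0, abs=1e-9)
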