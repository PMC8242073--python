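"""Quasi-static implicit finite-element mechanics on a HeartMesh.

Total-Lagrangian trilinear hexahedra with selective reduced integration:
the deviatoric and active stresses are integrated at the full 2x2x2 Gauss
rule while the volumetric penalty acts on the element-mean dilatation
(evaluated at the element centroid), the standard locking control for
near-incompressible Q1 elements. Cavity pressure is a follower load on the
deformed endocardial surface. Newton's method uses a consistent tangent
obtained by per-element forward differencing of the discrete residual, and
load steps are bisected automatically on divergence.

Force units are kPa*mm^2 (= mN); pressures are supplied in mmHg and
converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import material as mat
from .heartgeom import (
    HeartMesh,
    cavity_volume,
    gauss_points_hex,
    hex_shape_grad,
)

__all__ = [
    "MMHG_TO_KPA",
    "BoundaryConditions",
    "CycleSolution",
    "NonConvergenceError",
    "FESystem",
    "lv_base_constraints",
    "basal_symmetry_constraints",
    "solve_static",
    "solve_cycle",
]

MMHG_TO_KPA = 0.133322

_2D_CORNERS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)


def _quad_shape(xi):
    g = _2D_CORNERS
    return 0.25 * (1 + xi[..., None, 0] * g[:, 0]) * (1 + xi[..., None, 1] * g[:, 1])


def _quad_shape_grad(xi):
    g = _2D_CORNERS
    out = np.empty(xi.shape[:-1] + (4, 2))
    out[..., 0] = 0.25 * g[:, 0] * (1 + xi[..., None, 1] * g[:, 1])
    out[..., 1] = 0.25 * g[:, 1] * (1 + xi[..., None, 0] * g[:, 0])
    return out


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


@dataclass
class BoundaryConditions:
    """Endocardial pressure trace plus rigid-mode-eliminating constraints.

    times/pressures define p_endo(t) in mmHg on the surface named by
    `surface`; constrained_dofs are global displacement DOF indices held at
    zero (the basal constraint set).
    """

    times: np.ndarray
    pressures: np.ndarray
    constrained_dofs: np.ndarray
    surface: str = "endo_lv"

    def pressure_at(self, t):
        return float(np.interp(t, self.times, self.pressures))


def lv_base_constraints(mesh: HeartMesh):
    """Base plane fixed long-axis; one basal node pinned, one de-rotated.

    Mirrors constraining the ventricle through a stiff basal attachment:
    every base-surface node is fixed in z, the basal node nearest the -x
    direction is fully fixed, and the basal node nearest +x is fixed in y
    (its circumferential direction), removing rotation about the long axis.
    """
    base_nodes = np.unique(mesh.surfaces["base"])
    dofs = [3 * n + 2 for n in base_nodes]
    xy = mesh.nodes[base_nodes, :2]
    theta = np.arctan2(xy[:, 1], xy[:, 0])
    n_pin = base_nodes[np.argmin(np.cos(theta))]       # nearest -x
    n_rot = base_nodes[np.argmax(np.cos(theta))]       # nearest +x
    dofs += [3 * n_pin, 3 * n_pin + 1, 3 * n_rot + 1]
    return np.unique(dofs)


def basal_symmetry_constraints(mesh: HeartMesh):
    """Equatorial symmetry set for benchmark shells (free radial motion)."""
    base_nodes = np.unique(mesh.surfaces["base"])
    dofs = [3 * n + 2 for n in base_nodes]
    xy = mesh.nodes[base_nodes, :2]
    theta = np.arctan2(xy[:, 1], xy[:, 0])
    n_x = base_nodes[np.argmax(np.cos(theta))]
    n_y = base_nodes[np.argmax(np.sin(theta))]
    dofs += [3 * n_x + 1, 3 * n_y]
    return np.unique(dofs)


class FESystem:
    """Assembled FE problem for one mesh + material parameter set."""

    def __init__(self, mesh: HeartMesh, params: mat.MaterialParameters,
                 constrained_dofs=None, pressure_surface="endo_lv",
                 tol_rel=1e-6, tol_abs=1e-7, max_newton=25):
        self.mesh = mesh
        self.params = params
        self.tol_rel = tol_rel
        self.tol_abs = tol_abs
        self.max_newton = max_newton
        self.surface = pressure_surface
        if mesh.frames is None:
            raise ValueError("mesh must carry fiber frames")

        X = mesh.nodes[mesh.elems]  # (E, 8, 3)
        pts, wts = gauss_points_hex(2)
        grad = hex_shape_grad(pts)  # (8gp, 8, 3)
        Jx = np.einsum("eai,gaj->egij", X, grad)
        detJ = np.linalg.det(Jx)
        if np.any(detJ <= 0):
            raise ValueError("mesh contains non-positive Jacobians")
        Jinv = np.linalg.inv(Jx)
        # dN_a/dX_J at each gp: grad_xi . d(xi)/dX
        self.gradN = np.einsum("gak,egkJ->egaJ", grad, Jinv)
        self.w0 = detJ * wts  # (E, 8) reference quadrature volumes
        self.elem_vol = self.w0.sum(axis=1)
        # mean-dilatation gradients: exact volume-averaged dN/dX (classical
        # B-bar); a centroid-sampled gradient would fail the patch test on
        # distorted elements
        self.gradNc = np.einsum("eg,egaJ->eaJ", self.w0,
                                self.gradN) / self.elem_vol[:, None, None]
        self.w0c = self.elem_vol

        self.frames = mesh.frames  # (E, 3, 3) columns m, s, n
        self.fib = mesh.frames[:, :, 0]
        self.edof = (3 * mesh.elems[:, :, None]
                     + np.arange(3)[None, None, :]).reshape(len(mesh.elems), 24)

        self.facets = mesh.surfaces[pressure_surface]
        self.fdof = (3 * self.facets[:, :, None]
                     + np.arange(3)[None, None, :]).reshape(len(self.facets), 12)
        q1d = 1.0 / np.sqrt(3.0)
        qp = np.array([[-q1d, -q1d], [q1d, -q1d], [q1d, q1d], [-q1d, q1d]])
        self.qN = _quad_shape(qp)        # (4gp, 4)
        self.qdN = _quad_shape_grad(qp)  # (4gp, 4, 2)

        ndof = 3 * mesh.n_nodes
        self.ndof = ndof
        if constrained_dofs is None:
            constrained_dofs = lv_base_constraints(mesh)
        self.fixed = np.asarray(constrained_dofs, int)
        self.free = np.setdiff1d(np.arange(ndof), self.fixed)
        rows = np.repeat(self.edof[:, :, None], 24, axis=2)
        self.Krows = rows.ravel()
        self.Kcols = np.swapaxes(rows, 1, 2).ravel()
        frows = np.repeat(self.fdof[:, :, None], 12, axis=2)
        self.Frows = frows.ravel()
        self.Fcols = np.swapaxes(frows, 1, 2).ravel()
        self._tiled = None  # 24x-tiled element arrays for the FD tangent

    # -- kinematics and stress ------------------------------------------

    def _def_grad(self, ue):
        """F at the 8 Gauss points and the centroid; ue is (E, 8, 3)."""
        F = np.eye(3) + np.einsum("eai,egaJ->egiJ", ue, self.gradN)
        Fc = np.eye(3) + np.einsum("eai,eaJ->eiJ", ue, self.gradNc)
        return F, Fc

    def _elem_internal(self, ue, T_Ca, f_elem):
        """Element internal force vectors (E, 24); raises on inversion."""
        T_eff = np.broadcast_to(T_Ca * np.asarray(f_elem, float), (len(ue),))
        return self._elem_internal_core(ue, T_eff, self.gradN, self.gradNc,
                                        self.w0, self.w0c, self.frames,
                                        self.fib)

    def _elem_internal_core(self, ue, T_eff, gradN, gradNc, w0, w0c,
                            frames, fib):
        F = np.eye(3) + np.einsum("eai,egaJ->egiJ", ue, gradN)
        Fc = np.eye(3) + np.einsum("eai,eaJ->eiJ", ue, gradNc)
        J = np.linalg.det(F)
        Jc = np.linalg.det(Fc)
        if np.any(J <= 0) or np.any(Jc <= 0):
            raise mat.InvalidDeformationError("element inversion")
        R = frames[:, None]  # broadcast over gps

        # deviatoric Fung stress; the first Piola form
        # F_dev S F_dev^T F^{-T} collapses to J^(-2/3) F S
        Jm23 = J ** (-2.0 / 3.0)
        C = np.swapaxes(F, -1, -2) @ F
        E_dev = 0.5 * (Jm23[..., None, None] * C - np.eye(3))
        S = mat._passive_pk2_dev(E_dev, R, self.params)
        P = Jm23[..., None, None] * (F @ S)

        # active stress: P_act = s(lambda) (F m) (x) m
        if np.any(T_eff > 0):
            m = fib[:, None]  # (E,1,3)
            Fm = np.einsum("egiJ,egJ->egi", F,
                           np.broadcast_to(m, F.shape[:2] + (3,)))
            lam = np.linalg.norm(Fm, axis=-1)
            s = mat._active_scalar(lam, T_eff[:, None], 1.0, self.params)
            P = P + s[..., None, None] * Fm[..., :, None] * np.broadcast_to(
                m, Fm.shape)[..., None, :]

        fe = np.einsum("eg,egiJ,egaJ->eai", w0, P, gradN)

        # volumetric penalty on the element-mean dilatation (centroid)
        K = mat.bulk_modulus(T_eff, self.params)
        p_vol = 0.5 * np.asarray(K) * (Jc - 1.0 / Jc)
        Pvol = (Jc * p_vol)[:, None, None] * np.swapaxes(
            np.linalg.inv(Fc), -1, -2)
        fe = fe + w0c[:, None, None] * np.einsum(
            "eiJ,eaJ->eai", Pvol, gradNc)
        return fe.reshape(-1, 24)

    def _facet_load(self, xf, p_kpa):
        """Follower pressure nodal forces (Fc, 12) on deformed facets xf."""
        a1 = np.einsum("fgac,fai->fgci", self.qdN[None], xf)  # (F,4gp,2,3)
        nvec = np.cross(a1[:, :, 0], a1[:, :, 1])  # (F, 4gp, 3)
        fl = p_kpa * np.einsum("ga,fgi->fai", self.qN, nvec)
        return fl.reshape(-1, 12)

    # -- assembly --------------------------------------------------------

    def residual(self, u, p_mmhg, T_Ca, f_elem):
        ue = u.reshape(-1, 3)[self.mesh.elems]
        fe = self._elem_internal(ue, T_Ca, f_elem)
        r = np.zeros(self.ndof)
        np.add.at(r, self.edof.ravel(), fe.ravel())
        if p_mmhg != 0.0:
            xf = (self.mesh.nodes + u.reshape(-1, 3))[self.facets]
            fl = self._facet_load(xf, p_mmhg * MMHG_TO_KPA)
            np.add.at(r, self.fdof.ravel(), -fl.ravel())
        return r

    def external_force(self, u, p_mmhg):
        f = np.zeros(self.ndof)
        if p_mmhg != 0.0:
            xf = (self.mesh.nodes + u.reshape(-1, 3))[self.facets]
            fl = self._facet_load(xf, p_mmhg * MMHG_TO_KPA)
            np.add.at(f, self.fdof.ravel(), fl.ravel())
        return f

    def tangent(self, u, p_mmhg, T_Ca, f_elem, h=1e-6):
        """Forward-difference consistent tangent, assembled sparse.

        All 24 DOF perturbations of every element are evaluated in one
        batched call (the element arrays are tiled 24x).
        """
        ue = u.reshape(-1, 3)[self.mesh.elems]
        fe0 = self._elem_internal(ue, T_Ca, f_elem)
        E = len(fe0)
        flat = ue.reshape(-1, 24)
        pert = np.tile(flat[None], (24, 1, 1))  # (24, E, 24)
        pert[np.arange(24), :, np.arange(24)] += h
        if self._tiled is None:
            self._tiled = tuple(
                np.tile(a, (24,) + (1,) * (a.ndim - 1))
                for a in (self.gradN, self.gradNc, self.w0, self.w0c,
                          self.frames, self.fib))
        T_eff = np.tile(np.broadcast_to(
            T_Ca * np.asarray(f_elem, float), (E,)), 24)
        fp = self._elem_internal_core(
            pert.reshape(-1, 8, 3), T_eff, *self._tiled)
        Ke = np.transpose((fp.reshape(24, E, 24) - fe0[None]) / h, (1, 2, 0))
        Kmat = sp.coo_matrix(
            (Ke.ravel(), (self.Krows, self.Kcols)),
            shape=(self.ndof, self.ndof)).tocsr()
        if p_mmhg != 0.0:
            xf = (self.mesh.nodes + u.reshape(-1, 3))[self.facets]
            fl0 = self._facet_load(xf, p_mmhg * MMHG_TO_KPA)
            Kf = np.empty((len(fl0), 12, 12))
            xflat = xf.reshape(-1, 12)
            for d in range(12):
                xp = xflat.copy()
                xp[:, d] += h
                Kf[:, :, d] = -(self._facet_load(
                    xp.reshape(-1, 4, 3), p_mmhg * MMHG_TO_KPA) - fl0) / h
            Kmat = Kmat + sp.coo_matrix(
                (Kf.ravel(), (self.Frows, self.Fcols)),
                shape=(self.ndof, self.ndof)).tocsr()
        return Kmat

    # -- solves ----------------------------------------------------------

    def newton(self, p_mmhg, T_Ca, f_elem, u0=None):
        """Newton solve at fixed load with backtracking line search."""
        u = np.zeros(self.ndof) if u0 is None else u0.copy()
        u[self.fixed] = 0.0
        f_ext = self.external_force(u, p_mmhg)
        ref = max(np.linalg.norm(f_ext[self.free]), self.tol_abs)
        hist = []

        def res_norm(uv):
            r = self.residual(uv, p_mmhg, T_Ca, f_elem)
            return r, np.linalg.norm(r[self.free])

        try:
            r, rn = res_norm(u)
        except (mat.InvalidDeformationError, mat.StrainDivergenceError) as exc:
            raise NonConvergenceError(str(exc), {"residuals": hist})
        hist.append(rn)
        lu = None
        stale = 0
        for it in range(self.max_newton):
            if rn <= self.tol_rel * ref + self.tol_abs:
                return u, {"iterations": it, "residuals": hist,
                           "converged": True}
            if lu is None or stale >= 1:
                try:
                    K = self.tangent(u, p_mmhg, T_Ca, f_elem)
                except (mat.InvalidDeformationError,
                        mat.StrainDivergenceError) as exc:
                    raise NonConvergenceError(str(exc), {"residuals": hist})
                try:
                    lu = spla.splu(K[self.free][:, self.free].tocsc())
                except RuntimeError as exc:
                    raise NonConvergenceError(f"singular tangent: {exc}",
                                              {"residuals": hist})
                stale = 0
            du = lu.solve(-r[self.free])
            if not np.all(np.isfinite(du)):
                raise NonConvergenceError("singular tangent",
                                          {"residuals": hist})
            # near-full Newton steps (the penalty residual is non-monotone
            # but convergent); cap the displacement increment, and backtrack
            # on inversion, overflow, or catastrophic residual growth
            alpha = min(1.0, 5.0 / max(np.abs(du).max(), 1e-12))
            accepted = False
            for _ in range(8):
                u_try = u.copy()
                u_try[self.free] += alpha * du
                try:
                    r_try, rn_try = res_norm(u_try)
                except (mat.InvalidDeformationError,
                        mat.StrainDivergenceError):
                    alpha *= 0.5
                    continue
                if not np.isfinite(rn_try) or (rn_try > 10.0 * rn
                                                and alpha > 1 / 64):
                    alpha *= 0.5
                    continue
                u, r, rn = u_try, r_try, rn_try
                accepted = True
                break
            if not accepted:
                raise NonConvergenceError(
                    f"line search failed at |r|={rn:.3e}",
                    {"residuals": hist})
            hist.append(rn)
            if rn > max(1e3 * min(hist), 1e8):
                raise NonConvergenceError(
                    f"Newton diverged (|r|={rn:.3e})", {"residuals": hist})
            if it >= 14 and rn > 0.5 * hist[0]:
                raise NonConvergenceError(
                    f"Newton stagnated (|r|={rn:.3e})", {"residuals": hist})
            # reuse the factorization only in the fast-converging tail
            if rn > 0.1 * hist[-2] or stale >= 3:
                lu = None
            else:
                stale += 1
            f_ext = self.external_force(u, p_mmhg)
            ref = max(np.linalg.norm(f_ext[self.free]), ref, self.tol_abs)
        if rn <= self.tol_rel * ref + self.tol_abs:
            return u, {"iterations": self.max_newton, "residuals": hist,
                       "converged": True}
        raise NonConvergenceError(
            f"Newton stalled at |r|={rn:.3e} after {self.max_newton} "
            "iterations", {"residuals": hist})

    def solve(self, p_mmhg, T_Ca, f_elem=1.0, u0=None,
              from_load=(0.0, 0.0), max_bisect=5, f_from=None):
        """Adaptive load-stepped solve from a known state to (p, T_Ca).

        u0 must correspond to the converged state at from_load; on Newton
        divergence the load increment is bisected (at most max_bisect
        levels). If the activation pattern also changed since the start
        state, pass it as f_from and it is ramped along with the loads.
        """
        f_elem = np.broadcast_to(np.asarray(f_elem, float),
                                 (self.mesh.n_elements,))
        if f_from is not None:
            f_from = np.broadcast_to(np.asarray(f_from, float),
                                     (self.mesh.n_elements,))
        p0, T0 = from_load
        u = np.zeros(self.ndof) if u0 is None else u0.copy()
        # size the first increment by the load change to avoid wasted
        # diverging Newton runs on large steps
        n0 = max(1.0, np.ceil(abs(p_mmhg - p0) / 25.0),
                 np.ceil(abs(T_Ca - T0) / 10.0))
        lam, step = 0.0, 1.0 / n0
        info = {"solves": 0}
        bisects = 0
        while lam < 1.0 - 1e-12:
            target = min(1.0, lam + step)
            p = p0 + (p_mmhg - p0) * target
            T = T0 + (T_Ca - T0) * target
            f_t = (f_elem if f_from is None
                   else f_from + (f_elem - f_from) * target)
            try:
                u_new, ninfo = self.newton(p, T, f_t, u0=u)
            except NonConvergenceError as exc:
                bisects += 1
                step *= 0.5
                if bisects > max_bisect:
                    raise NonConvergenceError(
                        f"load stepping failed at fraction {lam:.3f}: {exc}",
                        exc.diagnostics)
                continue
            u = u_new
            lam = target
            info["solves"] += 1
            info["iterations"] = ninfo["iterations"]
            info["residuals"] = ninfo["residuals"]
            if ninfo["iterations"] <= 6 and step < 1.0:
                step *= 2.0
        info["converged"] = True
        info["bisections"] = bisects
        return u, info

    # -- state extraction -------------------------------------------------

    def state_fields(self, u, T_Ca, f_elem):
        """Per-element J (mean dilatation) and per-gp lambda, active stress."""
        ue = u.reshape(-1, 3)[self.mesh.elems]
        F, Fc = self._def_grad(ue)
        Jc = np.linalg.det(Fc)
        m = self.fib[:, None]
        Fm = np.einsum("egiJ,egJ->egi", F, np.broadcast_to(m, F.shape[:2] + (3,)))
        lam = np.linalg.norm(Fm, axis=-1)
        T_eff = (T_Ca * np.broadcast_to(np.asarray(f_elem, float),
                                        (self.mesh.n_elements,)))[:, None]
        s_pk2 = mat._active_scalar(lam, T_eff, 1.0, self.params)
        sig_fiber = s_pk2 * lam**2 / Jc[:, None]
        return {"J": Jc, "lam": lam, "s_act_pk2": s_pk2,
                "sigma_act_fiber": sig_fiber}


@dataclass
class CycleSolution:
    """Converged kinematic history of one simulated cardiac cycle."""

    mesh: HeartMesh
    times: np.ndarray
    displacements: np.ndarray     # (S, N, 3) mm
    pressures: np.ndarray         # (S,) mmHg
    cavity_volumes: np.ndarray    # (S,) mL
    J: np.ndarray                 # (S, E) element mean dilatation
    lam: np.ndarray               # (S, E, 8) fiber stretch at gps
    s_act_pk2: np.ndarray         # (S, E, 8) second-Piola active magnitude
    sigma_act_fiber: np.ndarray   # (S, E, 8) Cauchy active fiber stress kPa
    T_Ca: np.ndarray              # (S,) kPa
    gp_weights: np.ndarray        # (E, 8) reference quadrature volumes mm^3
    elem_volumes: np.ndarray      # (E,) reference element volumes mm^3
    es_index_hint: int | None = None  # ES step of the driving PV data
    diagnostics: list = field(default_factory=list)

    @property
    def es_index(self):
        """End-systole step: the PV data's minimum-volume time when known
        (isovolumic segments make the model's own argmin ambiguous)."""
        if self.es_index_hint is not None:
            return int(self.es_index_hint)
        return int(np.argmin(self.cavity_volumes))

    def export_csv(self, path):
        import pandas as pd

        pd.DataFrame({
            "t": self.times, "P_mmHg": self.pressures,
            "V_mL": self.cavity_volumes, "T_Ca_kPa": self.T_Ca,
        }).to_csv(path, index=False)

    def export_vtk_series(self, directory, prefix="cycle"):
        import os

        from .heartgeom import write_vtk

        os.makedirs(directory, exist_ok=True)
        for k in range(len(self.times)):
            write_vtk(
                os.path.join(directory, f"{prefix}_{k:03d}.vtk"),
                self.mesh,
                point_data={"displacement": self.displacements[k]},
                cell_data={
                    "J": self.J[k],
                    "lam_mean": self.lam[k].mean(axis=1),
                    "sigma_act": self.sigma_act_fiber[k].mean(axis=1),
                },
            )


def solve_static(mesh, params, bc, T_Ca, f_field=1.0, initial_guess=None,
                 pressure=None, system=None):
    """One quasi-static equilibrium solve (module-level convenience wrapper).

    pressure defaults to bc.pressures[-1]; returns the nodal displacement.
    """
    sys_ = system or FESystem(mesh, params, bc.constrained_dofs, bc.surface)
    p = bc.pressures[-1] if pressure is None else pressure
    u, _ = sys_.solve(p, T_Ca, f_field, u0=initial_guess)
    return u


def solve_cycle(mesh, params, bc, T_Ca_trace, activation=None, system=None,
                store_vtk=None):
    """Sequential quasi-static solves over the cardiac-cycle time grid.

    T_Ca_trace is the global active tension (kPa) on bc.times; activation
    supplies the local drive f(x, t) (defaults to synchronous f = 1).
    """
    T_Ca_trace = np.asarray(T_Ca_trace, float)
    if abs(T_Ca_trace[0]) > 1e-12:
        raise ValueError("T_Ca must vanish at end-diastole (t = 0)")
    sys_ = system or FESystem(mesh, params, bc.constrained_dofs, bc.surface)
    E = mesh.n_elements
    S = len(bc.times)
    sol = CycleSolution(
        mesh=mesh, times=np.asarray(bc.times, float),
        displacements=np.zeros((S, mesh.n_nodes, 3)),
        pressures=np.asarray(bc.pressures, float),
        cavity_volumes=np.zeros(S),
        J=np.zeros((S, E)), lam=np.zeros((S, E, 8)),
        s_act_pk2=np.zeros((S, E, 8)), sigma_act_fiber=np.zeros((S, E, 8)),
        T_Ca=T_Ca_trace.copy(),
        gp_weights=sys_.w0, elem_volumes=sys_.elem_vol,
    )
    u = np.zeros(sys_.ndof)
    prev = (0.0, 0.0)
    for k, t in enumerate(bc.times):
        f_elem = 1.0 if activation is None else activation.f_at(t)
        p = bc.pressures[k]
        T = T_Ca_trace[k]
        try:
            u, info = sys_.solve(p, T, f_elem, u0=u, from_load=prev)
        except NonConvergenceError as exc:
            raise NonConvergenceError(
                f"cycle step {k} (t={t:.3f}) failed: {exc}", exc.diagnostics)
        prev = (p, T)
        fields = sys_.state_fields(u, T, f_elem)
        sol.displacements[k] = u.reshape(-1, 3)
        sol.cavity_volumes[k] = cavity_volume(mesh, sol.displacements[k])
        sol.J[k] = fields["J"]
        sol.lam[k] = fields["lam"]
        sol.s_act_pk2[k] = fields["s_act_pk2"]
        sol.sigma_act_fiber[k] = fields["sigma_act_fiber"]
        sol.diagnostics.append({"step": k, "iterations": info.get("iterations"),
                                "solves": info["solves"]})
    if store_vtk:
        sol.export_vtk_series(store_vtk)
    return sol
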