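"""Output analyses: kinematic validation metrics and stress summaries.

Mirrors the measurement side of the study: sonomicrometry-style local
volume ratios (J) from marker arrays, wall thickness by projecting
endocardial points onto a triangulated epicardial surface (both for marker
arrays and for the FE solution), LV height shortening, PV-loop function
metrics (SV, EF, CO, stroke work, dP/dt extrema), cumulative active work,
and regional active-stress summaries (histograms, 17-segment bullseyes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heartgeom import HeartMesh, _facet_triangles, region_thirds

__all__ = [
    "MetricReport",
    "sono_volume_J",
    "wall_thickness_sono",
    "wall_thickness_fem",
    "lv_height",
    "pv_metrics",
    "active_work",
    "active_stress_summary",
    "j_field_summary",
    "closest_point_distance",
]

UJ_TO_J = 1e-6  # kPa*mm^3 is a microjoule


# ---------------------------------------------------------------------------
# geometric helper: point-to-triangulated-surface distance


def _closest_on_triangles(p, tri_pts):
    """Distance from point p to each triangle (T, 3, 3); returns min."""
    a, b, c = tri_pts[:, 0], tri_pts[:, 1], tri_pts[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    # region tests (Ericson); degenerate triangles fall back to vertices
    closest = np.where((d1 <= 0) & (d2 <= 0), 0, -1)  # vertex a
    out = np.empty(len(a))
    pts = np.empty_like(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)
    cond_a = (d1 <= 0) & (d2 <= 0)
    cond_b = (d3 >= 0) & (d4 <= d3)
    cond_c = (d6 >= 0) & (d5 <= d6)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    pts[:] = a + v_in[:, None] * ab + w_in[:, None] * ac  # interior default
    m = cond_bc
    pts[m] = b[m] + w_bc[m, None] * (c[m] - b[m])
    m = cond_ac
    pts[m] = a[m] + w_ac[m, None] * ac[m]
    m = cond_ab
    pts[m] = a[m] + v_ab[m, None] * ab[m]
    m = cond_c
    pts[m] = c[m]
    m = cond_b
    pts[m] = b[m]
    m = cond_a
    pts[m] = a[m]
    out = np.linalg.norm(pts - p, axis=1)
    return out.min()


def closest_point_distance(points, tri_vertices):
    """Min distance of each point to a triangulated surface (T, 3, 3)."""
    return np.array([_closest_on_triangles(p, tri_vertices)
                     for p in np.asarray(points, float)])


# ---------------------------------------------------------------------------
# sonocrystal volume ratio


def _lagrange_quad(x):
    """Quadratic Lagrange basis on nodes {0, 0.5, 1} and derivatives."""
    L = np.array([2 * (x - 0.5) * (x - 1.0), -4 * x * (x - 1.0),
                  2 * x * (x - 0.5)])
    dL = np.array([4 * x - 3.0, -8 * x + 4.0, 4 * x - 1.0])
    return L, dL


def _triquad_jacobian(grid_pts, xi):
    """det of the triquadratic map jacobian at parametric point xi.

    grid_pts is (3, 3, 3, 3) indexed (trans, long, circ, xyz); xi is
    (circ, long, trans) in [0, 1]^3.
    """
    Lc, dLc = _lagrange_quad(xi[0])
    Ll, dLl = _lagrange_quad(xi[1])
    Lt, dLt = _lagrange_quad(xi[2])
    Jc = np.einsum("tlcx,c,l,t->x", grid_pts, dLc, Ll, Lt)
    Jl = np.einsum("tlcx,c,l,t->x", grid_pts, Lc, dLl, Lt)
    Jt = np.einsum("tlcx,c,l,t->x", grid_pts, Lc, Ll, dLt)
    return float(np.linalg.det(np.column_stack([Jc, Jl, Jt])))


def _region_volume(grid_pts, long_range, n_gauss=3):
    x, w = np.polynomial.legendre.leggauss(n_gauss)
    x01 = 0.5 * (x + 1.0)
    w01 = 0.5 * w
    lo, hi = long_range
    xl = lo + (hi - lo) * x01
    wl = (hi - lo) * w01
    vol = 0.0
    for ic, wc in zip(x01, w01):
        for il, wll in zip(xl, wl):
            for it, wt in zip(x01, w01):
                vol += wc * wll * wt * _triquad_jacobian(
                    grid_pts, (ic, il, it))
    return vol


def sono_volume_J(array, ref_frame=0):
    """Regional tissue volume ratio J(t) from a 27-marker array.

    The 3x3x3 marker grid is interpolated as a single triquadratic
    curvilinear cell; local volume is the Gauss-quadrature integral of the
    interpolant's Jacobian determinant, and J is the current-to-reference
    volume ratio, reported for the basal/mid/apical longitudinal thirds
    and overall.
    """
    shape = array.layout.get("shape", (3, 3, 3))
    if shape != (3, 3, 3):
        raise ValueError("volume analysis expects the 27-marker layout")
    nF = len(array.times)
    regions = {"basal": (0.0, 1 / 3), "mid": (1 / 3, 2 / 3),
               "apical": (2 / 3, 1.0), "overall": (0.0, 1.0)}
    grids = array.positions.reshape(nF, 3, 3, 3, 3)  # (F, trans, long, circ, xyz)
    ref = {name: _region_volume(grids[ref_frame], rng)
           for name, rng in regions.items()}
    for name, v in ref.items():
        if abs(v) < 1e-9:
            raise ValueError(f"degenerate marker cell in region {name}")
    out = {name: np.array([_region_volume(grids[k], rng) / ref[name]
                           for k in range(nF)])
           for name, rng in regions.items()}
    return out


# ---------------------------------------------------------------------------
# wall thickness


def _grid_triangles(shape):
    """Triangulation of an (nr, nc) structured grid of point indices."""
    nr, nc = shape
    tris = []
    for r in range(nr - 1):
        for c in range(nc - 1):
            a = r * nc + c
            b = r * nc + c + 1
            cc = (r + 1) * nc + c + 1
            d = (r + 1) * nc + c
            tris.append((a, b, cc))
            tris.append((a, cc, d))
    return np.array(tris, int)


def wall_thickness_sono(epi_positions, endo_positions, es_index,
                        ed_index=0, epi_shape=(3, 4), excluded_ids=(1, 2, 3)):
    """ES/ED wall-thickness ratio from the 12-epi / 9-endo marker scheme.

    Per frame the epicardial markers are triangulated on their grid and
    each endocardial marker is projected to the nearest surface point;
    thickness is the projection distance. Endocardial ids 1-3 (apical row)
    are excluded; the ratio is mean thickness at ES over ED.
    """
    tris = _grid_triangles(epi_shape)
    keep = np.array([i for i in range(endo_positions.shape[1])
                     if (i + 1) not in excluded_ids])

    def mean_thickness(k):
        tv = epi_positions[k][tris]
        d = closest_point_distance(endo_positions[k][keep], tv)
        return d.mean()

    return float(mean_thickness(es_index) / mean_thickness(ed_index))


def wall_thickness_fem(solution, mesh=None, es_index=None, ed_index=0,
                       max_nodes=845, seed=0, lc_max=0.75,
                       return_distribution=False):
    """Mean endocardial ES/ED thickness ratio of an FE cycle solution.

    Every (optionally subsampled) endocardial node on the free wall is
    projected onto the deformed triangulated epicardial surface at the ED
    and ES steps; thickness is the projection distance. The apical cap
    (longitudinal coordinate beyond lc_max) is excluded, mirroring the
    exclusion of the apex-adjacent markers in the sonomicrometry protocol.
    """
    mesh = mesh or solution.mesh
    if es_index is None:
        es_index = solution.es_index
    endo_nodes = np.unique(mesh.surfaces["endo_lv"])
    if lc_max is not None and mesh.longitudinal_coord is not None:
        endo_nodes = endo_nodes[
            mesh.longitudinal_coord[endo_nodes] <= lc_max]
    if max_nodes and len(endo_nodes) > max_nodes:
        rng = np.random.default_rng(seed)
        endo_nodes = np.sort(rng.choice(endo_nodes, max_nodes, replace=False))
    tris = _facet_triangles(mesh.surfaces["epi"])

    def thicknesses(k):
        x = mesh.nodes + solution.displacements[k]
        return closest_point_distance(x[endo_nodes], x[tris])

    t_ed = thicknesses(ed_index)
    t_es = thicknesses(es_index)
    ratio = float(t_es.mean() / t_ed.mean())
    if return_distribution:
        return ratio, t_es / t_ed
    return ratio


def lv_height(solution, mesh=None, es_index=None, ed_index=0):
    """ES/ED ratio of base-plane-to-epicardial-apex long-axis distance."""
    mesh = mesh or solution.mesh
    if es_index is None:
        es_index = solution.es_index
    base_nodes = np.unique(mesh.surfaces["base"])
    epi_nodes = np.unique(mesh.surfaces["epi"])
    apex_node = epi_nodes[np.argmax(mesh.nodes[epi_nodes, 2])]

    def height(k):
        x = mesh.nodes + solution.displacements[k]
        return abs(x[apex_node, 2] - x[base_nodes, 2].mean())

    return float(height(es_index) / height(ed_index))


# ---------------------------------------------------------------------------
# PV-loop metrics


def pv_metrics(pv):
    """Standard cardiac function metrics of a closed PV loop.

    SV = EDV - ESV, EF = SV/EDV, CO = SV * HR; stroke work is the loop
    area (mmHg*mL, work done by the ventricle, positive for the normal
    loop orientation); dP/dt extrema use centered differences on the
    dimensional time grid t * 60/HR seconds.
    """
    edv, esv = pv.edv, pv.esv
    sv = edv - esv
    ef = sv / edv
    co = sv * pv.HR
    V = np.append(pv.V, pv.V[0])
    P = np.append(pv.P, pv.P[0])
    loop_integral = float(np.sum(0.5 * (P[1:] + P[:-1]) * np.diff(V)))
    stroke_work = -loop_integral  # mmHg*mL; positive for a normal loop
    t_sec = pv.t * 60.0 / pv.HR
    dPdt = np.gradient(pv.P, t_sec)
    return {
        "EDV_mL": float(edv), "ESV_mL": float(esv), "SV_mL": float(sv),
        "EF": float(ef), "CO_mL_per_min": float(co),
        "stroke_work_mmHg_mL": stroke_work,
        "orientation_valid": bool(stroke_work > 0),
        "dPdt_max_mmHg_per_s": float(dPdt.max()),
        "dPdt_min_mmHg_per_s": float(dPdt.min()),
    }


# ---------------------------------------------------------------------------
# active work and stress summaries


def active_work(solution):
    """Cumulative work delivered by the active stress, in joules.

    W(t) = -int_0^t int_Omega0 S_act : dE/dt' dV dt', accumulated with the
    trapezoidal rule in time and Gauss quadrature in space (fiber-aligned
    rank-one S_act makes S:Edot = s * d(lambda^2/2)/dt). Positive during
    shortening against tension. Returns (times, W, power).
    """
    s = solution.s_act_pk2          # (S, E, 8)
    lam2 = solution.lam**2
    w0 = solution.gp_weights        # (E, 8) mm^3
    S = len(solution.times)
    W = np.zeros(S)
    power = np.zeros(S)
    t = solution.times
    for k in range(1, S):
        s_mid = 0.5 * (s[k] + s[k - 1])
        dE = 0.5 * (lam2[k] - lam2[k - 1])
        dW = -np.sum(w0 * s_mid * dE)  # microjoules
        W[k] = W[k - 1] + dW * UJ_TO_J
        dt = t[k] - t[k - 1]
        power[k] = dW * UJ_TO_J / dt if dt > 0 else 0.0
    return t, W, power


@dataclass
class ActiveStressSummary:
    times: np.ndarray
    hist_edges: np.ndarray
    hist_counts: np.ndarray      # (S, nbins) volume-weighted, mm^3
    segment_means: np.ndarray    # (17, S) kPa, volume-weighted
    segment_volumes: np.ndarray  # (17,) mm^3


def active_stress_summary(solution, aha, nbins=30):
    """Histograms and 17-segment bullseye means of active fiber stress."""
    sig = solution.sigma_act_fiber  # (S, E, 8)
    w0 = solution.gp_weights
    S = sig.shape[0]
    smax = max(float(sig.max()), 1e-9)
    edges = np.linspace(0.0, smax, nbins + 1)
    counts = np.empty((S, nbins))
    wflat = np.broadcast_to(w0, sig.shape[1:]).ravel()
    for k in range(S):
        counts[k], _ = np.histogram(sig[k].ravel(), bins=edges,
                                    weights=wflat)
    seg_means = np.zeros((17, S))
    seg_vols = np.zeros(17)
    ew = w0.sum(axis=1)  # element volumes
    sig_elem = np.einsum("seg,eg->se", sig, w0) / ew  # volume-weighted mean
    for s_id in range(1, 18):
        m = aha == s_id
        seg_vols[s_id - 1] = ew[m].sum()
        if np.any(m):
            seg_means[s_id - 1] = (sig_elem[:, m] * ew[m]).sum(axis=1) \
                / ew[m].sum()
    return ActiveStressSummary(times=solution.times, hist_edges=edges,
                               hist_counts=counts, segment_means=seg_means,
                               segment_volumes=seg_vols)


def j_field_summary(solution, mesh=None):
    """Mean/min dilatation history, transmural profile and thirds table."""
    mesh = mesh or solution.mesh
    w = solution.elem_volumes
    mean_J = (solution.J * w).sum(axis=1) / w.sum()
    k_es = solution.es_index
    J_es = solution.J[k_es]
    thirds = region_thirds(mesh)
    thirds_table = {
        name: float((J_es[thirds == name] * w[thirds == name]).sum()
                    / w[thirds == name].sum())
        for name in ("basal", "mid", "apical")
    }
    tc = mesh.transmural_coord
    layers = np.unique(np.round(tc, 6))
    profile = []
    for lay in layers:
        m = np.isclose(tc, lay)
        profile.append([lay, (J_es[m] * w[m]).sum() / w[m].sum()])
    profile = np.array(profile)
    lc_e = mesh.longitudinal_coord[mesh.elems].mean(axis=1)
    freewall = lc_e <= 0.75
    return {
        "mean_J": mean_J,
        "mean_J_es": float(mean_J[k_es]),
        "min_J_es": float(J_es.min()),
        # context: extreme away from the idealized apex-pole closure
        "min_J_es_freewall": float(J_es[freewall].min()),
        "transmural_profile": profile,  # (layer coordinate, mean J at ES)
        "thirds_J_es": thirds_table,
        "es_index": int(k_es),
    }


# ---------------------------------------------------------------------------
# aggregate report


@dataclass
class MetricReport:
    """Named scalar metrics with units, JSON/CSV serializable."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def update(self, **kw):
        self.values.update(kw)

    def to_json(self, path):
        import json

        def clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            return v

        with open(path, "w") as fh:
            json.dump({k: clean(v) for k, v in self.values.items()}, fh,
                      indent=2)

    def to_csv(self, path):
        import pandas as pd

        rows = [(k, v) for k, v in self.values.items()
                if np.isscalar(v) or isinstance(v, (int, float, bool))]
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path,
                                                               index=False)
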