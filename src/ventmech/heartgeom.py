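"""Idealized left-ventricular geometry, fibers and regional maps.

The default geometry is a truncated prolate-ellipsoid shell meshed with a
structured grid of trilinear hexahedra (the apex is closed by a ring of
collapsed-hex wedges), standing in for an image-derived ventricular mesh.
Rule-based helical fibers (+60 deg endo to -60 deg epi by default) stand in
for diffusion-tensor measured myofiber directions.

Coordinate convention: the long axis is +z from the base plane (z = 0)
toward the apex; all lengths in mm, volumes reported in mL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HeartMesh",
    "ResolutionError",
    "build_ideal_lv",
    "build_box",
    "rule_based_fibers",
    "cavity_volume",
    "half_ellipsoid_volume",
    "aha_segment",
    "region_thirds",
    "scale_to_cavity",
    "min_scaled_jacobian",
    "interpolate_displacement",
    "read_fiber_table",
    "write_vtk",
    "save_mesh_json",
    "load_mesh_json",
]

MM3_TO_ML = 1e-3

# hex8 local corner coordinates, standard ordering (bottom face then top)
_XI_CORNERS = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    float,
)


class ResolutionError(ValueError):
    """Target edge length too coarse to resolve the wall."""


def hex_shape(xi):
    """Trilinear shape functions (…, 8) at local coordinates xi (…, 3)."""
    xi = np.asarray(xi, float)
    g = _XI_CORNERS
    return 0.125 * (
        (1 + xi[..., None, 0] * g[:, 0])
        * (1 + xi[..., None, 1] * g[:, 1])
        * (1 + xi[..., None, 2] * g[:, 2])
    )


def hex_shape_grad(xi):
    """Gradients dN/dxi, shape (…, 8, 3)."""
    xi = np.asarray(xi, float)
    g = _XI_CORNERS
    out = np.empty(xi.shape[:-1] + (8, 3))
    a = 1 + xi[..., None, 0] * g[:, 0]
    b = 1 + xi[..., None, 1] * g[:, 1]
    c = 1 + xi[..., None, 2] * g[:, 2]
    out[..., 0] = 0.125 * g[:, 0] * b * c
    out[..., 1] = 0.125 * g[:, 1] * a * c
    out[..., 2] = 0.125 * g[:, 2] * a * b
    return out


def gauss_points_hex(n=2):
    """Tensor Gauss rule on [-1,1]^3: (points (n^3,3), weights (n^3,))."""
    x, w = np.polynomial.legendre.leggauss(n)
    pts = np.array([[a, b, c] for a in x for b in x for c in x])
    wts = np.array([wa * wb * wc for wa in w for wb in w for wc in w])
    return pts, wts


@dataclass
class HeartMesh:
    """Hexahedral ventricular mesh with labeled surfaces and fiber data.

    surfaces maps {'endo_lv', 'epi', 'base'} to (F, 4) facet connectivity
    (degenerate quads with a repeated node encode triangles at the apex).
    fibers/frames are per element; longitudinal_coord is per node in [0, 1]
    (0 = base, 1 = apex); transmural_coord is per element in [0, 1]
    (0 = endo, 1 = epi).
    """

    nodes: np.ndarray
    elems: np.ndarray
    surfaces: dict
    fibers: np.ndarray | None = None
    frames: np.ndarray | None = None
    longitudinal_coord: np.ndarray | None = None
    transmural_coord: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.elems)

    def element_centroids(self):
        return self.nodes[self.elems].mean(axis=1)

    def element_volumes(self):
        pts, wts = gauss_points_hex(2)
        grad = hex_shape_grad(pts)  # (8gp, 8, 3)
        X = self.nodes[self.elems]  # (E, 8, 3)
        Jm = np.einsum("eai,gaj->egij", X, grad)  # dx/dxi
        return np.einsum("g,eg->e", wts, np.linalg.det(Jm))

    def copy(self):
        return replace(
            self,
            nodes=self.nodes.copy(),
            elems=self.elems.copy(),
            surfaces={k: v.copy() for k, v in self.surfaces.items()},
            fibers=None if self.fibers is None else self.fibers.copy(),
            frames=None if self.frames is None else self.frames.copy(),
            longitudinal_coord=None
            if self.longitudinal_coord is None
            else self.longitudinal_coord.copy(),
            transmural_coord=None
            if self.transmural_coord is None
            else self.transmural_coord.copy(),
            meta=dict(self.meta),
        )

    def with_nodes(self, nodes):
        m = self.copy()
        m.nodes = np.asarray(nodes, float)
        return m


# ---------------------------------------------------------------------------
# mesh builders


def build_ideal_lv(
    base_radius_endo=20.0,
    wall_thickness=11.0,
    long_axis=48.0,
    truncation_fraction=0.5,
    target_edge_len=6.0,
):
    """Structured truncated-ellipsoid LV shell.

    base_radius_endo: endocardial radius at the base plane (mm);
    long_axis: base-plane-to-endocardial-apex distance (mm);
    truncation_fraction u in [0, 1): the base plane cuts the endocardial
    ellipsoid at height u*a above its equator.
    """
    if min(base_radius_endo, wall_thickness, long_axis) <= 0:
        raise ValueError("all dimensions must be positive")
    if not (0 <= truncation_fraction < 1):
        raise ValueError("truncation_fraction must be in [0, 1)")
    if wall_thickness >= base_radius_endo:
        raise ValueError("wall_thickness must be < base_radius_endo")
    if target_edge_len > wall_thickness:
        raise ResolutionError(
            "target_edge_len coarser than the wall: fewer than 2 "
            "transmural element layers would result"
        )
    u = truncation_fraction
    a_endo = long_axis / (1.0 + u)
    b_endo = base_radius_endo / np.sqrt(1.0 - u * u)
    z_c = u * a_endo  # ellipsoid center height above the base plane
    w = wall_thickness
    a_epi, b_epi = a_endo + w, b_endo + w

    h = target_edge_len
    b_mid = b_endo + 0.5 * w
    nc = max(8, int(round(2 * np.pi * b_mid / h)))
    # meridian arc length of the mid-wall ellipse, numeric
    nu_mid = np.arccos(np.clip(-z_c / (a_endo + 0.5 * w), -1, 1))
    tt = np.linspace(0, nu_mid, 200)
    am, bm = a_endo + 0.5 * w, b_mid
    arc = np.trapezoid(np.hypot(am * np.sin(tt), bm * np.cos(tt)), tt)
    nl = max(3, int(round(arc / h)))
    nt = max(2, int(round(w / h)))

    return _structured_lv(a_endo, b_endo, a_epi, b_epi, z_c, nc, nl, nt,
                          dict(
                              base_radius_endo=base_radius_endo,
                              wall_thickness=wall_thickness,
                              long_axis=long_axis,
                              truncation_fraction=truncation_fraction,
                              target_edge_len=target_edge_len,
                          ))


def _structured_lv(a_endo, b_endo, a_epi, b_epi, z_c, nc, nl, nt, params):
    layers_a = np.linspace(a_endo, a_epi, nt + 1)
    layers_b = np.linspace(b_endo, b_epi, nt + 1)
    theta = 2 * np.pi * np.arange(nc) / nc

    def ring_nodes(k, j):
        a, b = layers_a[k], layers_b[k]
        nu_max = np.arccos(np.clip(-z_c / a, -1, 1))
        nu = nu_max * (1.0 - j / nl)  # j=0 base ... j=nl pole
        r = b * np.sin(nu)
        z = z_c + a * np.cos(nu)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                np.full(nc, z)])

    n_reg = nc * nl * (nt + 1)

    def nid(i, j, k):
        return k * (nc * nl) + j * nc + (i % nc)

    def pole(k):
        return n_reg + k

    nodes = np.empty((n_reg + nt + 1, 3))
    lc = np.empty(len(nodes))
    for k in range(nt + 1):
        for j in range(nl):
            idx = slice(k * nc * nl + j * nc, k * nc * nl + (j + 1) * nc)
            nodes[idx] = ring_nodes(k, j)
            lc[idx] = j / nl
        nodes[pole(k)] = [0.0, 0.0, z_c + layers_a[k]]
        lc[pole(k)] = 1.0

    elems, tcoord = [], []
    for k in range(nt):
        for j in range(nl):
            for i in range(nc):
                if j < nl - 1:
                    bot = [nid(i, j, k), nid(i + 1, j, k),
                           nid(i + 1, j + 1, k), nid(i, j + 1, k)]
                    top = [nid(i, j, k + 1), nid(i + 1, j, k + 1),
                           nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)]
                else:  # apex wedge, collapsed edge at the pole
                    bot = [nid(i, j, k), nid(i + 1, j, k), pole(k), pole(k)]
                    top = [nid(i, j, k + 1), nid(i + 1, j, k + 1),
                           pole(k + 1), pole(k + 1)]
                elems.append(bot + top)
                tcoord.append((k + 0.5) / nt)
    elems = np.array(elems, int)

    endo, epi, base = [], [], []
    for j in range(nl):
        for i in range(nc):
            if j < nl - 1:
                endo.append([nid(i, j, 0), nid(i + 1, j, 0),
                             nid(i + 1, j + 1, 0), nid(i, j + 1, 0)])
                epi.append([nid(i, j, nt), nid(i + 1, j, nt),
                            nid(i + 1, j + 1, nt), nid(i, j + 1, nt)])
            else:
                endo.append([nid(i, j, 0), nid(i + 1, j, 0), pole(0), pole(0)])
                epi.append([nid(i, j, nt), nid(i + 1, j, nt),
                            pole(nt), pole(nt)])
    for k in range(nt):
        for i in range(nc):
            base.append([nid(i, 0, k), nid(i + 1, 0, k),
                         nid(i + 1, 0, k + 1), nid(i, 0, k + 1)])

    mesh = HeartMesh(
        nodes=nodes,
        elems=elems,
        surfaces={
            "endo_lv": np.array(endo, int),
            "epi": np.array(epi, int),
            "base": np.array(base, int),
        },
        longitudinal_coord=lc,
        transmural_coord=np.array(tcoord),
        meta=dict(
            kind="ideal_lv", nc=nc, nl=nl, nt=nt,
            a_endo=a_endo, b_endo=b_endo, a_epi=a_epi, b_epi=b_epi,
            z_c=z_c, **params,
        ),
    )
    if np.any(mesh.element_volumes() <= 0):
        raise RuntimeError("ideal LV construction produced inverted elements")
    rule_based_fibers(mesh)
    return mesh


def build_box(lx=1.0, ly=1.0, lz=1.0, nx=1, ny=1, nz=1, origin=(0.0, 0.0, 0.0)):
    """Structured box of hex8 elements; surfaces xmin/xmax/.../zmax.

    Used by material-point drivers, patch tests and the unit-cube worked
    example; fibers default to +x.
    """
    xs = np.linspace(0, lx, nx + 1) + origin[0]
    ys = np.linspace(0, ly, ny + 1) + origin[1]
    zs = np.linspace(0, lz, nz + 1) + origin[2]
    nodes = np.array([[x, y, z] for z in zs for y in ys for x in xs])

    def nid(i, j, k):
        return k * (nx + 1) * (ny + 1) + j * (nx + 1) + i

    elems = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elems.append([
                    nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k),
                    nid(i, j + 1, k), nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ])
    elems = np.array(elems, int)
    surf = {}
    surf["xmin"] = np.array([[nid(0, j, k), nid(0, j + 1, k),
                              nid(0, j + 1, k + 1), nid(0, j, k + 1)]
                             for k in range(nz) for j in range(ny)], int)
    surf["xmax"] = np.array([[nid(nx, j, k), nid(nx, j, k + 1),
                              nid(nx, j + 1, k + 1), nid(nx, j + 1, k)]
                             for k in range(nz) for j in range(ny)], int)
    surf["ymin"] = np.array([[nid(i, 0, k), nid(i, 0, k + 1),
                              nid(i + 1, 0, k + 1), nid(i + 1, 0, k)]
                             for k in range(nz) for i in range(nx)], int)
    surf["ymax"] = np.array([[nid(i, ny, k), nid(i + 1, ny, k),
                              nid(i + 1, ny, k + 1), nid(i, ny, k + 1)]
                             for k in range(nz) for i in range(nx)], int)
    surf["zmin"] = np.array([[nid(i, j, 0), nid(i, j + 1, 0),
                              nid(i + 1, j + 1, 0), nid(i + 1, j, 0)]
                             for j in range(ny) for i in range(nx)], int)
    surf["zmax"] = np.array([[nid(i, j, nz), nid(i + 1, j, nz),
                              nid(i + 1, j + 1, nz), nid(i, j + 1, nz)]
                             for j in range(ny) for i in range(nx)], int)
    E = len(elems)
    fibers = np.tile([1.0, 0.0, 0.0], (E, 1))
    frames = np.tile(np.eye(3), (E, 1, 1))
    return HeartMesh(
        nodes=nodes, elems=elems, surfaces=surf,
        fibers=fibers, frames=frames,
        longitudinal_coord=np.zeros(len(nodes)),
        transmural_coord=np.full(E, 0.5),
        meta=dict(kind="box", nx=nx, ny=ny, nz=nz, lx=lx, ly=ly, lz=lz),
    )


# ---------------------------------------------------------------------------
# fibers


def rule_based_fibers(mesh, helix_endo=60.0, helix_epi=-60.0):
    """Helical fiber rule: helix angle linear in the transmural coordinate.

    Fibers are tangent to the local wall surface; angle is measured from the
    circumferential direction toward the apex-directed meridional direction.
    Also populates mesh.frames with the (m, s, n) triads the material needs.
    Returns the (E, 3) fiber array and stores it on the mesh.
    """
    if mesh.transmural_coord is None:
        raise ValueError("transmural_coord must be populated")
    meta = mesh.meta
    cent = mesh.element_centroids()
    t = mesh.transmural_coord
    if meta.get("kind") == "ideal_lv":
        a_t = meta["a_endo"] + t * (meta["a_epi"] - meta["a_endo"])
        b_t = meta["b_endo"] + t * (meta["b_epi"] - meta["b_endo"])
        zc = meta["z_c"]
        n_hat = np.column_stack([
            cent[:, 0] / b_t**2, cent[:, 1] / b_t**2, (cent[:, 2] - zc) / a_t**2,
        ])
    else:
        # generic fallback: radial from the long axis
        n_hat = np.column_stack([cent[:, 0], cent[:, 1], np.zeros(len(cent))])
    n_hat /= np.linalg.norm(n_hat, axis=1, keepdims=True)
    r = np.hypot(cent[:, 0], cent[:, 1])
    e_c = np.column_stack([-cent[:, 1] / r, cent[:, 0] / r, np.zeros(len(r))])
    e_l = np.cross(n_hat, e_c)
    e_l /= np.linalg.norm(e_l, axis=1, keepdims=True)

    alpha = np.deg2rad(helix_endo + (helix_epi - helix_endo) * t)
    m = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    m /= np.linalg.norm(m, axis=1, keepdims=True)
    s = np.cross(n_hat, m)
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    n2 = np.cross(m, s)
    frames = np.stack([m, s, n2], axis=-1)  # columns m, s, n
    mesh.fibers = m
    mesh.frames = frames
    return m


def read_fiber_table(mesh, path):
    """Import per-element fibers from a whitespace table (eid mx my mz)."""
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    eid = data[:, 0].astype(int)
    m = np.zeros((mesh.n_elements, 3))
    m[eid] = data[:, 1:4]
    nrm = np.linalg.norm(m, axis=1)
    if np.any(nrm == 0):
        raise ValueError("fiber table does not cover every element")
    m /= nrm[:, None]
    mesh.fibers = m
    # complete frames with the previous transverse rule if available
    cent = mesh.element_centroids()
    hint = np.column_stack([cent[:, 0], cent[:, 1], np.zeros(len(cent))])
    bad = np.linalg.norm(hint, axis=1) < 1e-9
    hint[bad] = [1.0, 0.0, 0.0]
    hint /= np.linalg.norm(hint, axis=1, keepdims=True)
    s = np.cross(hint, m)
    nrm = np.linalg.norm(s, axis=1, keepdims=True)
    small = nrm[:, 0] < 1e-8
    if np.any(small):
        s[small] = np.cross(np.tile([0.0, 0.0, 1.0], (small.sum(), 1)), m[small])
        nrm = np.linalg.norm(s, axis=1, keepdims=True)
    s /= nrm
    n2 = np.cross(m, s)
    mesh.frames = np.stack([m, s, n2], axis=-1)
    return m


# ---------------------------------------------------------------------------
# volumes


def _facet_triangles(facets):
    tris = []
    for q in facets:
        a, b, c, d = q
        if c == d:
            tris.append((a, b, c))
        else:
            tris.append((a, b, c))
            tris.append((a, c, d))
    return np.array(tris, int)


def _boundary_loop(facets):
    """Ordered node loop of the open boundary of a facet patch."""
    from collections import defaultdict

    count = defaultdict(int)
    succ = {}
    for q in facets:
        corners = [q[0], q[1], q[2], q[3]]
        uniq = []
        for c in corners:
            if not uniq or uniq[-1] != c:
                uniq.append(c)
        if uniq[0] == uniq[-1]:
            uniq.pop()
        for i in range(len(uniq)):
            e = (uniq[i], uniq[(i + 1) % len(uniq)])
            count[frozenset(e)] += 1
            succ.setdefault(e, None)
    boundary = {}
    for e in succ:
        if count[frozenset(e)] == 1:
            boundary[e[1]] = e[0]  # reversed: boundary traversed opposite
    start = next(iter(boundary))
    loop = [start]
    while True:
        nxt = boundary[loop[-1]]
        if nxt == start:
            break
        loop.append(nxt)
    return np.array(loop, int)


_QUAD_CORNERS_2D = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)
_q1 = 1.0 / np.sqrt(3.0)
_QUAD_GP_2D = np.array([[-_q1, -_q1], [_q1, -_q1], [_q1, _q1], [-_q1, _q1]])


def _bilinear_shape_2d(xi):
    g = _QUAD_CORNERS_2D
    return 0.25 * (1 + xi[..., None, 0] * g[:, 0])         * (1 + xi[..., None, 1] * g[:, 1])


def _bilinear_grad_2d(xi):
    g = _QUAD_CORNERS_2D
    out = np.empty(xi.shape[:-1] + (4, 2))
    out[..., 0] = 0.25 * g[:, 0] * (1 + xi[..., None, 1] * g[:, 1])
    out[..., 1] = 0.25 * g[:, 1] * (1 + xi[..., None, 0] * g[:, 0])
    return out


def cavity_volume(mesh, displacements=None, surface="endo_lv"):
    """LV cavity volume (mL) by the divergence theorem.

    The facet integral uses the bilinear surface parametrization with a
    2x2 Gauss rule (exact for bilinear patches, so exactly work-conjugate
    with the follower pressure load); the open base ring is closed with a
    cap fanned from its centroid. Exact for affine deformations.
    """
    x = mesh.nodes if displacements is None else mesh.nodes + displacements
    facets = mesh.surfaces[surface]
    loop = mesh.meta.get("_cached_endo_loop")
    if loop is None:
        loop = _boundary_loop(facets)
        mesh.meta["_cached_endo_loop"] = loop
    xq = x[facets]  # (F, 4, 3)
    N = _bilinear_shape_2d(_QUAD_GP_2D)       # (4gp, 4)
    dN = _bilinear_grad_2d(_QUAD_GP_2D)       # (4gp, 4, 2)
    xg = np.einsum("ga,fai->fgi", N, xq)
    a = np.einsum("gac,fai->fgci", dN, xq)    # (F, 4gp, 2, 3)
    nvec = np.cross(a[:, :, 0], a[:, :, 1])
    v = np.einsum("fgi,fgi->", xg, nvec)      # sum over unit gp weights
    ring = x[loop]
    centroid = ring.mean(axis=0)
    nxt = np.roll(loop, -1)
    v += np.einsum("ij,ij->", np.cross(x[loop], x[nxt]),
                   np.broadcast_to(centroid, (len(loop), 3))) / 2.0
    return abs(v) / 3.0 * MM3_TO_ML


def analytic_truncated_lv_cavity(mesh):
    """Closed-form cavity volume of the ideal geometry (mL)."""
    m = mesh.meta
    a, b, u = m["a_endo"], m["b_endo"], m["truncation_fraction"]
    # integrate pi r(z)^2 from z=-u*a (base) to z=a (apex), z about center
    vol = np.pi * b**2 * a * ((1 + u) - (1 + u**3) / 3.0)
    return vol * MM3_TO_ML


def half_ellipsoid_volume(a, b):
    """Half-ellipsoid cavity approximation V = pi a b^2 / 6, in mL.

    a: long axis (apex-to-base distance, mm); b: short-axis diameter (mm).
    """
    if a <= 0 or b <= 0:
        raise ValueError("axes must be positive")
    return np.pi * a * b * b / 6.0 * MM3_TO_ML


def scale_to_cavity(mesh, target_ml):
    """Uniformly scale the mesh so the discrete cavity volume matches."""
    v = cavity_volume(mesh)
    s = (target_ml / v) ** (1.0 / 3.0)
    out = mesh.with_nodes(mesh.nodes * s)
    for key in ("a_endo", "b_endo", "a_epi", "b_epi", "z_c",
                "base_radius_endo", "wall_thickness", "long_axis"):
        if key in out.meta:
            out.meta[key] = out.meta[key] * s
    out.meta.pop("_cached_endo_loop", None)
    return out


# ---------------------------------------------------------------------------
# regional maps


def aha_segment(mesh, septal_angle=0.0, cap_fraction=0.9):
    """Standard 17-segment map: basal/mid sextants, apical quadrants, cap."""
    if mesh.longitudinal_coord is None:
        raise ValueError("longitudinal_coord must be populated")
    cent = mesh.element_centroids()
    lc = mesh.longitudinal_coord[mesh.elems].mean(axis=1)
    theta = np.mod(np.arctan2(cent[:, 1], cent[:, 0]) - septal_angle, 2 * np.pi)
    seg = np.empty(mesh.n_elements, int)
    sext = np.minimum((theta / (2 * np.pi / 6)).astype(int), 5)
    quad = np.minimum((theta / (2 * np.pi / 4)).astype(int), 3)
    basal = lc < 1.0 / 3.0
    mid = (lc >= 1.0 / 3.0) & (lc < 2.0 / 3.0)
    apical = (lc >= 2.0 / 3.0) & (lc < cap_fraction)
    cap = lc >= cap_fraction
    seg[basal] = 1 + sext[basal]
    seg[mid] = 7 + sext[mid]
    seg[apical] = 13 + quad[apical]
    seg[cap] = 17
    return seg


def region_thirds(mesh):
    """Per-element basal/mid/apical label by longitudinal thirds."""
    lc = mesh.longitudinal_coord[mesh.elems].mean(axis=1)
    labels = np.where(lc < 1.0 / 3.0, "basal",
                      np.where(lc < 2.0 / 3.0, "mid", "apical"))
    return labels


# ---------------------------------------------------------------------------
# quality / interpolation


def min_scaled_jacobian(mesh):
    """Minimum (over elements and Gauss points) scaled Jacobian."""
    pts, _ = gauss_points_hex(2)
    grad = hex_shape_grad(pts)
    X = mesh.nodes[mesh.elems]
    Jm = np.einsum("eai,gaj->egij", X, grad)
    det = np.linalg.det(Jm)
    norms = np.linalg.norm(Jm, axis=-2)  # column norms of dx/dxi
    scaled = det / (norms[..., 0] * norms[..., 1] * norms[..., 2])
    return float(scaled.min())


def _invert_trilinear(Xe, p, xi0=None, tol=1e-10, max_iter=30):
    xi = np.zeros(3) if xi0 is None else xi0.copy()
    for _ in range(max_iter):
        N = hex_shape(xi)
        r = N @ Xe - p
        if np.linalg.norm(r) < tol:
            break
        Jm = Xe.T @ hex_shape_grad(xi)  # dx_i/dxi_j
        try:
            xi = xi - np.linalg.solve(Jm, r)
        except np.linalg.LinAlgError:
            return None
        if np.max(np.abs(xi)) > 3.0:
            return None
    return xi


def locate_points(mesh, points, tol=1e-6):
    """Containing element and local coordinates for each query point."""
    cents = mesh.element_centroids()
    X = mesh.nodes[mesh.elems]
    eids = np.empty(len(points), int)
    xis = np.empty((len(points), 3))
    for q, p in enumerate(np.asarray(points, float)):
        order = np.argsort(np.linalg.norm(cents - p, axis=1))
        found = False
        for e in order[: min(len(order), 40)]:
            xi = _invert_trilinear(X[e], p)
            if xi is not None and np.max(np.abs(xi)) <= 1.0 + tol:
                eids[q], xis[q] = e, xi
                found = True
                break
        if not found:
            # fall back to the best (clamped) candidate
            e = order[0]
            xi = _invert_trilinear(X[e], p)
            if xi is None:
                xi = np.zeros(3)
            eids[q], xis[q] = e, np.clip(xi, -1, 1)
    return eids, xis


def interpolate_displacement(mesh, u, points, location=None):
    """FE interpolation of a nodal field u at arbitrary physical points."""
    if location is None:
        location = locate_points(mesh, points)
    eids, xis = location
    N = hex_shape(xis)  # (P, 8)
    return np.einsum("pa,pai->pi", N, np.asarray(u)[mesh.elems[eids]])


# ---------------------------------------------------------------------------
# I/O


def write_vtk(path, mesh, point_data=None, cell_data=None):
    """Legacy-ASCII VTK unstructured grid with optional data arrays."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nventmech mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        E = mesh.n_elements
        fh.write(f"CELLS {E} {E * 9}\n")
        for e in mesh.elems:
            fh.write("8 " + " ".join(map(str, e)) + "\n")
        fh.write(f"CELL_TYPES {E}\n")
        fh.write("\n".join(["12"] * E) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            _write_vtk_arrays(fh, point_data)
        data = dict(cell_data or {})
        if mesh.fibers is not None:
            data.setdefault("fibers", mesh.fibers)
        if data:
            fh.write(f"CELL_DATA {E}\n")
            _write_vtk_arrays(fh, data)


def _write_vtk_arrays(fh, arrays):
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        if arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} double\n")
            for v in arr:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        else:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in arr.ravel():
                fh.write(f"{v:.9g}\n")


def save_mesh_json(path, mesh):
    """Plain-text JSON mesh interchange (nodes, elements, labels, fibers)."""
    meta = {k: v for k, v in mesh.meta.items() if not k.startswith("_")}
    obj = dict(
        nodes=mesh.nodes.tolist(),
        elems=mesh.elems.tolist(),
        surfaces={k: v.tolist() for k, v in mesh.surfaces.items()},
        fibers=None if mesh.fibers is None else mesh.fibers.tolist(),
        frames=None if mesh.frames is None else mesh.frames.tolist(),
        longitudinal_coord=None
        if mesh.longitudinal_coord is None
        else mesh.longitudinal_coord.tolist(),
        transmural_coord=None
        if mesh.transmural_coord is None
        else mesh.transmural_coord.tolist(),
        meta=meta,
    )
    with open(path, "w") as fh:
        json.dump(obj, fh)


def load_mesh_json(path):
    with open(path) as fh:
        obj = json.load(fh)
    return HeartMesh(
        nodes=np.array(obj["nodes"], float),
        elems=np.array(obj["elems"], int),
        surfaces={k: np.array(v, int) for k, v in obj["surfaces"].items()},
        fibers=None if obj["fibers"] is None else np.array(obj["fibers"]),
        frames=None if obj["frames"] is None else np.array(obj["frames"]),
        longitudinal_coord=None
        if obj["longitudinal_coord"] is None
        else np.array(obj["longitudinal_coord"]),
        transmural_coord=None
        if obj["transmural_coord"] is None
        else np.array(obj["transmural_coord"]),
        meta=obj.get("meta", {}),
    )
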