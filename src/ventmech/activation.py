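"""Spatiotemporal activation drive f(x, t) from epicardial MAP recordings.

Monophasic action potential (MAP) waveforms recorded at scattered epicardial
sites are reduced to three timing features (upstroke, peak-contraction time
at 60% repolarization, 90% repolarization), interpolated over the epicardial
surface by barycentric triangulation in an unrolled angle-longitude chart,
and converted per element into a beta-distribution approximation of the
local calcium transient. The synchronous alternative is simply f = 1
everywhere inside the systolic window.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import beta as beta_dist

__all__ = [
    "MAPRecording",
    "ActivationField",
    "MalformedWaveformError",
    "map_features",
    "beta_transient",
    "interpolate_field",
    "synchronous_field",
    "read_map_set",
    "write_map_set",
]


class MalformedWaveformError(ValueError):
    """MAP trace without a usable depolarization."""


@dataclass
class MAPRecording:
    """One epicardial MAP site: position (mm) and normalized waveform."""

    position: np.ndarray
    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        if len(self.t) < 20:
            raise ValueError("MAP recording needs at least 20 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass
class ActivationField:
    """Per-element contraction drive f(x, t) on a shared time grid."""

    times: np.ndarray
    f: np.ndarray  # (E, T) in [0, 1]

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.f = np.asarray(self.f, float)
        if self.f.min() < -1e-12 or self.f.max() > 1 + 1e-12:
            raise ValueError("activation drive must lie in [0, 1]")

    def f_at(self, t):
        """Drive of every element at time t (linear interpolation)."""
        idx = np.searchsorted(self.times, t)
        if idx == 0:
            return self.f[:, 0].copy()
        if idx >= len(self.times):
            return self.f[:, -1].copy()
        t0, t1 = self.times[idx - 1], self.times[idx]
        w = (t - t0) / (t1 - t0)
        return (1 - w) * self.f[:, idx - 1] + w * self.f[:, idx]


def _cross_time(t, v, level, rising, start=0):
    """First crossing time of `level` (linear interp) from index `start`."""
    v = v[start:]
    tt = t[start:]
    if rising:
        hit = np.nonzero((v[:-1] < level) & (v[1:] >= level))[0]
    else:
        hit = np.nonzero((v[:-1] > level) & (v[1:] <= level))[0]
    if len(hit) == 0:
        return None
    i = hit[0]
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return tt[i] + frac * (tt[i + 1] - tt[i])


def map_features(rec: MAPRecording):
    """Timing features (t_act, t_peak, t_repol) of a MAP waveform.

    t_act: rising crossing of 50% of peak; t_peak: 60% decay of the peak
    after the plateau (time of maximum contraction); t_repol: 90% decay.
    """
    v = rec.v
    vmax = v.max()
    if vmax <= 0:
        raise MalformedWaveformError("waveform has no depolarization")
    imax = int(np.argmax(v))
    t_act = _cross_time(rec.t, v, 0.5 * vmax, rising=True)
    t_peak = _cross_time(rec.t, v, 0.4 * vmax, rising=False, start=imax)
    t_repol = _cross_time(rec.t, v, 0.1 * vmax, rising=False, start=imax)
    if t_act is None or t_peak is None or t_repol is None:
        raise MalformedWaveformError("missing upstroke or repolarization")
    if not (t_act < t_peak < t_repol):
        raise MalformedWaveformError("features out of order")
    return float(t_act), float(t_peak), float(t_repol)


def beta_transient(t_act, t_peak, t_repol, shape_a=3.0, width_scale=1.2,
                   times=None):
    """Beta-density calcium-transient surrogate, normalized to peak 1.

    The transient is supported on [t_act, t_act + w] with
    w = width_scale * (t_repol - t_act); the second shape parameter is
    solved from the mode condition so the density peaks at t_peak.
    """
    if not (t_act < t_peak < t_repol):
        raise ValueError("need t_act < t_peak < t_repol")
    if shape_a <= 1:
        raise ValueError("shape_a must exceed 1")
    w = width_scale * (t_repol - t_act)
    mode = (t_peak - t_act) / w
    if not (0 < mode < 1):
        raise ValueError("t_peak outside the transient support")
    # mode of Beta(a, b) on [0,1] is (a-1)/(a+b-2)
    shape_b = (shape_a - 1.0) / mode - shape_a + 2.0
    if shape_b <= 1:
        raise ValueError("t_peak too late in the support for this shape_a")
    if times is None:
        times = np.linspace(0.0, 1.0, 201)
    times = np.asarray(times, float)
    x = (times - t_act) / w
    f = np.zeros_like(times)
    inside = (x > 0) & (x < 1)
    f[inside] = beta_dist.pdf(x[inside], shape_a, shape_b)
    peak = beta_dist.pdf(mode, shape_a, shape_b)
    return times, f / peak


def _epi_chart(mesh, points):
    """Unrolled (arc-scaled angle, longitudinal) chart of epicardial points."""
    theta = np.arctan2(points[:, 1], points[:, 0])
    r_scale = mesh.meta.get("b_epi", np.hypot(points[:, 0], points[:, 1]).mean())
    zmax = mesh.nodes[:, 2].max()
    lc = np.clip(points[:, 2] / max(zmax, 1e-9), 0.0, 1.0)
    return theta, r_scale * 1.0, lc


def interpolate_field(recordings, mesh, shape_a=3.0, width_scale=1.2,
                      times=None):
    """Barycentric interpolation of MAP features onto mesh elements.

    Site features are triangulated in the unrolled epicardial chart
    (angle x longitudinal coordinate, with periodic images in angle);
    each element takes the interpolated features at its epicardial
    projection (constant transmurally) and a beta transient is built from
    them. Elements outside the convex hull use the nearest site.
    """
    if len(recordings) < 3:
        raise ValueError("need at least 3 epicardial sites")
    if times is None:
        times = np.linspace(0.0, 1.0, 201)
    feats = np.array([map_features(r) for r in recordings])  # (S, 3)
    pos = np.array([r.position for r in recordings])
    theta_s, r_scale, lc_s = _epi_chart(mesh, pos)
    # periodic images in the angular direction
    pts, vals = [], []
    for shift in (-2 * np.pi, 0.0, 2 * np.pi):
        pts.append(np.column_stack([(theta_s + shift) * r_scale,
                                    lc_s * mesh.nodes[:, 2].max()]))
        vals.append(feats)
    pts = np.vstack(pts)
    vals = np.vstack(vals)

    cent = mesh.element_centroids()
    theta_e = np.arctan2(cent[:, 1], cent[:, 0])
    lc_e = mesh.longitudinal_coord[mesh.elems].mean(axis=1)
    q = np.column_stack([theta_e * r_scale,
                         lc_e * mesh.nodes[:, 2].max()])

    try:
        tri = Delaunay(pts)
    except Exception as exc:  # degenerate (collinear) site sets
        raise ValueError(f"site triangulation failed: {exc}")
    simp = tri.find_simplex(q)
    feat_e = np.empty((len(q), 3))
    inside = simp >= 0
    if np.any(inside):
        X = tri.transform[simp[inside]]
        bary2 = np.einsum("pij,pj->pi", X[:, :2],
                          q[inside] - X[:, 2])
        bary = np.column_stack([bary2, 1 - bary2.sum(axis=1)])
        feat_e[inside] = np.einsum(
            "pi,pik->pk", bary, vals[tri.simplices[simp[inside]]])
    if np.any(~inside):
        tree = cKDTree(pts)
        _, nearest = tree.query(q[~inside])
        feat_e[~inside] = vals[nearest]

    f = np.zeros((mesh.n_elements, len(times)))
    for e in range(mesh.n_elements):
        ta, tp, tr = feat_e[e]
        _, f[e] = beta_transient(ta, tp, tr, shape_a, width_scale, times)
    return ActivationField(times=times, f=f)


def synchronous_field(mesh, systole_window=(0.0, 1.0), times=None):
    """Uniform drive: f = 1 for every element inside the systolic window."""
    if times is None:
        times = np.linspace(0.0, 1.0, 201)
    times = np.asarray(times, float)
    inside = (times >= systole_window[0]) & (times <= systole_window[1])
    f = np.tile(inside.astype(float), (mesh.n_elements, 1))
    return ActivationField(times=times, f=f)


# ---------------------------------------------------------------------------
# table I/O: one file per site, manifest lists them


def write_map_set(directory, recordings):
    os.makedirs(directory, exist_ok=True)
    names = []
    for i, rec in enumerate(recordings):
        name = f"map_site_{i:03d}.txt"
        names.append(name)
        with open(os.path.join(directory, name), "w") as fh:
            fh.write("# position_mm %.9g %.9g %.9g\n" % tuple(rec.position))
            for t, v in zip(rec.t, rec.v):
                fh.write(f"{t:.9g} {v:.9g}\n")
    with open(os.path.join(directory, "map_manifest.txt"), "w") as fh:
        fh.write("\n".join(names) + "\n")


def read_map_set(directory):
    with open(os.path.join(directory, "map_manifest.txt")) as fh:
        names = [ln.strip() for ln in fh if ln.strip()]
    recs = []
    for name in names:
        path = os.path.join(directory, name)
        with open(path) as fh:
            header = fh.readline().split()
            pos = np.array(header[-3:], float)
        data = np.loadtxt(path, skiprows=1)
        recs.append(MAPRecording(position=pos, t=data[:, 0], v=data[:, 1]))
    return recs
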