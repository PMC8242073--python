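"""Synthetic stand-ins for the in vivo ovine measurements.

Every input the animal experiment supplied is generated here with the
temporal and spatial structure the downstream analysis assumes: a one-cycle
LV pressure-volume loop (end-diastole at normalized time t = 0, ED pressure
around 15 mmHg, filling along a Klotz-type EDPVR), epicardial MAP-like
waveforms with an activation delay along the long axis, sonomicrometry
crystal trajectories carried by a prescribed deformation, and an apical
infarct element mask. Default loop constants (EDV 60 mL, EF 0.30, peak
pressure 95 mmHg, HR 90 bpm, infarct fraction 0.20) are declared synthetic
stand-ins — only the ED pressure of ~15 mmHg is a measured anchor.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activation import MAPRecording
from .heartgeom import HeartMesh, interpolate_displacement, locate_points

__all__ = [
    "PVTrace",
    "SonocrystalArray",
    "InfarctMask",
    "gen_pv_loop",
    "gen_map_set",
    "gen_sonocrystal_array",
    "gen_infarct",
    "average_cycles",
    "resample_pv",
]


@dataclass
class PVTrace:
    """One cardiac cycle of paired pressure/volume samples.

    t is normalized to [0, 1] with end-diastole (maximum volume) at t = 0.
    """

    t: np.ndarray
    P: np.ndarray  # mmHg
    V: np.ndarray  # mL
    HR: float = 90.0  # bpm

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.P = np.asarray(self.P, float)
        self.V = np.asarray(self.V, float)

    @property
    def edv(self):
        return float(self.V[0])

    @property
    def esv(self):
        return float(self.V.min())

    @property
    def es_index(self):
        return int(np.argmin(self.V))

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame({"t": self.t, "P_mmHg": self.P,
                      "V_mL": self.V}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, HR=90.0):
        import pandas as pd

        df = pd.read_csv(path)
        return cls(t=df["t"].to_numpy(), P=df["P_mmHg"].to_numpy(),
                   V=df["V_mL"].to_numpy(), HR=HR)


@dataclass
class SonocrystalArray:
    """Marker trajectories: positions (frames, markers, 3) in mm."""

    times: np.ndarray
    positions: np.ndarray
    layout: dict

    @property
    def n_markers(self):
        return self.positions.shape[1]

    def to_csv(self, path):
        import pandas as pd

        rows = []
        for k, t in enumerate(self.times):
            for m in range(self.n_markers):
                rows.append((k, t, m, *self.positions[k, m]))
        pd.DataFrame(rows, columns=["frame", "t", "marker_id",
                                    "x", "y", "z"]).to_csv(path, index=False)


@dataclass
class InfarctMask:
    """Per-element infarct indicator plus the realized volume fraction."""

    mask: np.ndarray
    volume_fraction: float


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def gen_pv_loop(EDV=60.0, EF=0.30, P_ed=15.0, P_peak=95.0, HR=90.0,
                n=120, seed=None, noise=0.0,
                t_ivc=0.06, t_ej_end=0.32, t_ivr_end=0.40,
                ejection_onset_frac=0.75):
    """Smooth four-phase synthetic PV loop.

    Filling follows the Klotz-type EDPVR anchored at (EDV, P_ed); the two
    isovolumic segments hold volume at EDV / ESV while pressure swings;
    ejection takes the volume to ESV = EDV (1 - EF) with pressure peaking
    at P_peak. Optional seeded Gaussian measurement noise for robustness
    tests.
    """
    from .calibrate import klotz_curve

    if not (0.1 < EF < 0.7):
        raise ValueError("EF must lie in (0.1, 0.7)")
    if n < 40:
        raise ValueError("need at least 40 samples")
    if P_ed >= P_peak:
        raise ValueError("P_ed must be below P_peak")
    ESV = EDV * (1.0 - EF)
    curve = klotz_curve(EDV, P_ed)
    P_onset = ejection_onset_frac * P_peak
    P_es = curve.pressure_at(ESV)  # isovolumic relaxation endpoint

    t = np.linspace(0.0, 1.0, n, endpoint=False)
    P = np.empty(n)
    V = np.empty(n)
    for i, ti in enumerate(t):
        if ti < t_ivc:  # isovolumic contraction
            s = _smoothstep(ti / t_ivc)
            V[i] = EDV
            P[i] = P_ed + (P_onset - P_ed) * s
        elif ti < t_ej_end:  # ejection; pressure stays near-systolic to
            # the dicrotic notch (~88% of peak) at end-ejection
            tau = (ti - t_ivc) / (t_ej_end - t_ivc)
            V[i] = EDV + (ESV - EDV) * _smoothstep(tau)
            if tau < 0.45:
                s = _smoothstep(tau / 0.45)
            else:
                s = 1.0 - 0.15 * _smoothstep((tau - 0.45) / 0.55)
            P[i] = P_onset + (P_peak - P_onset) * s
        elif ti < t_ivr_end:  # isovolumic relaxation
            s = _smoothstep((ti - t_ej_end) / (t_ivr_end - t_ej_end))
            V[i] = ESV
            P_start = P_onset + 0.85 * (P_peak - P_onset)
            P[i] = P_start + (P_es - P_start) * s
        else:  # filling along the EDPVR
            tau = (ti - t_ivr_end) / (1.0 - t_ivr_end)
            V[i] = ESV + (EDV - ESV) * _smoothstep(tau)
            P[i] = curve.pressure_at(V[i])
    # continuity of ejection pressure at its end with relaxation start
    if noise > 0:
        rng = np.random.default_rng(seed)
        P = P + rng.normal(0.0, noise, n)
        V = V + rng.normal(0.0, noise * 0.2, n)
        V[0] = EDV
        P[0] = P_ed
    return PVTrace(t=t, P=P, V=V, HR=HR)


def resample_pv(pv: PVTrace, n_steps: int) -> PVTrace:
    """Subsample a trace to n_steps points, keeping ED (t=0) and ES exact."""
    idx = np.unique(np.round(np.linspace(0, len(pv.t) - 1,
                                         n_steps)).astype(int))
    idx = np.unique(np.concatenate([idx, [0, pv.es_index]]))
    return PVTrace(t=pv.t[idx], P=pv.P[idx], V=pv.V[idx], HR=pv.HR)


def average_cycles(traces):
    """Pointwise average of repeated noisy cycles on a common grid."""
    t = traces[0].t
    P = np.mean([np.interp(t, tr.t, tr.P) for tr in traces], axis=0)
    V = np.mean([np.interp(t, tr.t, tr.V) for tr in traces], axis=0)
    return PVTrace(t=t, P=P, V=V, HR=traces[0].HR)


# ---------------------------------------------------------------------------
# MAP-like recordings


def _ap_template(t, t_act, apd=0.30, upstroke=0.01, repol_width=0.05):
    """Normalized action-potential shape: fast upstroke, plateau, decay."""
    up = 0.5 * (1 + np.tanh((t - t_act) / (upstroke / 2.355)))
    down = 0.5 * (1 - np.tanh((t - (t_act + apd)) / (repol_width / 1.5)))
    v = up * down
    vmax = v.max()
    return v / vmax if vmax > 0 else v


def gen_map_set(mesh: HeartMesh, n_sites=71, apex_base_delay=0.06,
                seed=0, t_act_base=0.02, apd=0.30, jitter=0.003,
                n_samples=400):
    """Epicardial MAP-like waveforms with a long-axis activation delay.

    Sites are sampled area-weighted on the epicardial surface; each
    waveform is the template action potential shifted by
    t_act_base + apex_base_delay * longitudinal_coord plus seeded jitter.
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    rng = np.random.default_rng(seed)
    facets = mesh.surfaces["epi"]
    x = mesh.nodes
    # facet areas (two triangles per quad; collapsed corners handled)
    a = x[facets[:, 0]]
    areas = 0.5 * (
        np.linalg.norm(np.cross(x[facets[:, 1]] - a, x[facets[:, 2]] - a),
                       axis=1)
        + np.linalg.norm(np.cross(x[facets[:, 2]] - a, x[facets[:, 3]] - a),
                         axis=1))
    probs = areas / areas.sum()
    chosen = rng.choice(len(facets), size=n_sites, p=probs)
    w = rng.dirichlet(np.ones(4), size=n_sites)
    pos = np.einsum("sa,sai->si", w, x[facets[chosen]])
    lc = np.einsum("sa,sa->s", w, mesh.longitudinal_coord[facets[chosen]])

    t = np.linspace(0.0, 1.0, n_samples)
    recs = []
    for s in range(n_sites):
        t_act = t_act_base + apex_base_delay * lc[s]
        if jitter > 0:
            t_act += rng.normal(0.0, jitter)
        v = _ap_template(t, t_act, apd=apd)
        recs.append(MAPRecording(position=pos[s], t=t, v=v))
    return recs


# ---------------------------------------------------------------------------
# sonocrystal arrays


def default_crystal_layout(mesh: HeartMesh, kind="volume27",
                           theta_span=(np.pi / 4, 3 * np.pi / 4),
                           lc_span=(0.25, 0.75)):
    """Reference marker positions embedded in the LV free wall.

    volume27: 3 circumferential x 3 longitudinal x 3 transmural markers.
    thickness: 12 epicardial markers (4x3 grid) + 9 endocardial (3x3),
    endocardial ids 1..9 with 1-3 the apical row.
    """
    meta = mesh.meta
    if meta.get("kind") != "ideal_lv":
        raise ValueError("default layout requires the ideal LV geometry")

    def surf_point(theta, lc, depth):
        # depth: 0 endo .. 1 epi; lc in [0,1] base->apex
        a = meta["a_endo"] + depth * (meta["a_epi"] - meta["a_endo"])
        b = meta["b_endo"] + depth * (meta["b_epi"] - meta["b_endo"])
        nu_max = np.arccos(np.clip(-meta["z_c"] / a, -1, 1))
        nu = nu_max * (1 - lc)
        r = b * np.sin(nu)
        return np.array([r * np.cos(theta), r * np.sin(theta),
                         meta["z_c"] + a * np.cos(nu)])

    if kind == "volume27":
        thetas = np.linspace(*theta_span, 3)
        lcs = np.linspace(*lc_span, 3)
        depths = np.array([0.15, 0.5, 0.85])
        pts = np.array([
            surf_point(th, lc, d)
            for d in depths for lc in lcs for th in thetas
        ])  # index = (trans, long, circ), trans slowest
        return pts, dict(kind=kind, shape=(3, 3, 3),
                         order="trans_long_circ", lc_values=lcs)
    if kind == "thickness":
        thetas4 = np.linspace(theta_span[0], theta_span[1], 4)
        thetas3 = np.linspace(theta_span[0], theta_span[1], 3)
        lcs = np.linspace(*lc_span, 3)
        epi = np.array([surf_point(th, lc, 0.97)
                        for lc in lcs for th in thetas4])
        # endocardial ids 1..9: rows from apex (1-3) to base (7-9)
        endo = np.array([surf_point(th, lc, 0.08)
                         for lc in lcs[::-1] for th in thetas3])
        return (epi, endo), dict(kind=kind, epi_shape=(3, 4),
                                 endo_shape=(3, 3), apical_ids=(1, 2, 3))
    raise ValueError(f"unknown layout kind {kind!r}")


def gen_sonocrystal_array(deformation, reference_points, times=None,
                          layout=None, mesh=None):
    """Trajectories of markers carried by a deformation history.

    deformation: either a callable x = phi(X, t) applied to reference
    marker positions, or a CycleSolution whose displacement field is
    FE-interpolated at the markers.
    """
    ref = np.asarray(reference_points, float)
    if hasattr(deformation, "displacements"):  # CycleSolution
        sol = deformation
        times = sol.times if times is None else times
        msh = mesh or sol.mesh
        loc = locate_points(msh, ref)
        pos = np.empty((len(times), len(ref), 3))
        for k, t in enumerate(times):
            idx = int(np.argmin(np.abs(sol.times - t)))
            u = interpolate_displacement(msh, sol.displacements[idx], ref,
                                         location=loc)
            pos[k] = ref + u
    else:
        if times is None:
            times = np.linspace(0.0, 1.0, 21)
        pos = np.array([deformation(ref, t) for t in times])
    return SonocrystalArray(times=np.asarray(times, float), positions=pos,
                            layout=layout or {})


# ---------------------------------------------------------------------------
# infarct mask


def gen_infarct(mesh: HeartMesh, volume_fraction=0.20, tol=0.02):
    """Contiguous apical infarct mask of the requested tissue fraction.

    The longitudinal-coordinate threshold is found by bisection on the
    element-volume-weighted fraction.
    """
    if not (0.0 < volume_fraction < 0.5):
        raise ValueError("volume_fraction must lie in (0, 0.5)")
    vol = mesh.element_volumes()
    lc = mesh.longitudinal_coord[mesh.elems].mean(axis=1)
    cent = mesh.element_centroids()
    theta = np.arctan2(cent[:, 1], cent[:, 0])
    total = vol.sum()
    target = volume_fraction * total

    # whole apical bands first, then a partial ring (in angular order,
    # attached to the cap) so coarse meshes still hit the fraction
    mask = np.zeros(mesh.n_elements, bool)
    acc = 0.0
    bands = np.sort(np.unique(np.round(lc, 9)))[::-1]
    for band in bands:
        members = np.nonzero(np.isclose(lc, band))[0]
        band_vol = vol[members].sum()
        if acc + band_vol <= target:
            mask[members] = True
            acc += band_vol
            continue
        order = members[np.argsort(theta[members])]
        for e in order:
            if acc >= target:
                break
            if abs(acc + vol[e] - target) < abs(acc - target):
                mask[e] = True
                acc += vol[e]
            else:
                break
        break
    achieved = acc / total
    if abs(achieved - volume_fraction) > tol:
        raise ValueError(
            f"mesh too coarse to hit infarct fraction {volume_fraction:.2f} "
            f"(closest achievable {achieved:.3f})")
    return InfarctMask(mask=mask, volume_fraction=float(achieved))
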