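"""Model/results interface tying geometry, data and calibration together.

`HeartModel` holds the end-diastolic geometry, the pressure-volume data and
the material template; `fit()` runs the calibration chain (inverse
unloading, passive EDPVR fit, active-tension trace, and — in compressible
mode — the bulk-modulus softening rate) and returns a `HeartCycleResults`
carrying the fitted constants, the simulated cycle, validation metrics and
a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import activation as act
from . import calibrate as cal
from . import material as mat
from . import postvalidate as post
from . import synthdata as synth
from .config import config_hash, default_config, merge_config
from .heartgeom import (aha_segment, build_ideal_lv, cavity_volume,
                        rule_based_fibers, scale_to_cavity)
from .mechsolver import CycleSolution

__all__ = ["HeartModel", "HeartCycleResults"]


def _material_from_config(mc):
    c = mc["c"]
    return mat.MaterialParameters(
        c=c, alpha=mc["alpha"], A1=mc["A1"], A2=mc["A2"], A3=mc["A3"],
        K_inc=mc["K_inc_factor"] * c, gamma=mc["gamma"],
        K_floor=mc["K_floor_factor"] * c, beta=mc["beta"], mode=mc["mode"])


class HeartModel:
    """Calibratable organ-level LV mechanics model.

    Parameters
    ----------
    mesh_ed : HeartMesh
        End-diastolic (imaged) geometry with fibers.
    pv : PVTrace
        Measured or synthetic pressure-volume loop, ED at t = 0, with the
        volume at t = 0 consistent with the mesh cavity volume.
    params : MaterialParameters
        Material template; c is refitted, mode/gamma set per fit call.
    config : dict
        Full run configuration (calibration tolerances etc.).
    """

    def __init__(self, mesh_ed, pv, params=None, config=None,
                 activation_field=None, map_recordings=None):
        self.mesh_ed = mesh_ed
        self.pv = pv
        self.config = merge_config(default_config(), config)
        self.params = params or _material_from_config(
            self.config["material"])
        self.activation_field = activation_field
        self.map_recordings = map_recordings
        self._passive = None
        self._gamma = None  # cached calibrated softening rate
        self._t_ref_hint = None  # peak tension of a previous fit

    # -- construction -----------------------------------------------------

    @classmethod
    def from_synthetic(cls, seed=1, coarse=False, config=None,
                       activation="sync"):
        """Build the default idealized LV plus its synthetic dataset.

        The mesh is scaled so its discrete cavity volume equals the
        configured EDV exactly, and the PV loop is generated anchored at
        that volume. activation: 'sync' (f = 1) or 'async' (MAP-driven).
        """
        cfg = merge_config(default_config(), config)
        cfg["synth"]["seed"] = seed
        cfg["activation"]["kind"] = activation
        g = cfg["geometry"]
        edge = g["coarse_edge_len_mm"] if coarse else g["target_edge_len_mm"]
        mesh = build_ideal_lv(
            base_radius_endo=g["base_radius_endo_mm"],
            wall_thickness=g["wall_thickness_mm"],
            long_axis=g["long_axis_mm"],
            truncation_fraction=g["truncation_fraction"],
            target_edge_len=edge)
        rule_based_fibers(mesh, g["helix_endo_deg"], g["helix_epi_deg"])
        s = cfg["synth"]
        mesh = scale_to_cavity(mesh, s["EDV_mL"])
        pv = synth.gen_pv_loop(
            EDV=s["EDV_mL"], EF=s["EF"], P_ed=s["P_ed_mmHg"],
            P_peak=s["P_peak_mmHg"], HR=s["HR_bpm"], n=s["n_pv_samples"],
            seed=seed)
        model = cls(mesh, pv, config=cfg)
        if activation == "async":
            recs = synth.gen_map_set(
                mesh, n_sites=s["n_map_sites"],
                apex_base_delay=s["apex_base_delay"],
                jitter=s["map_jitter"], seed=seed)
            a = cfg["activation"]
            model.activation_field = act.interpolate_field(
                recs, mesh, shape_a=a["shape_a"],
                width_scale=a["width_scale"])
            model.map_recordings = recs
        return model

    # -- calibration stages ----------------------------------------------

    def fit_passive(self, verbose=False):
        """Passive EDPVR calibration (cached; shared by both modes)."""
        if self._passive is None:
            ccfg = self.config["calibration"]
            P_ed = float(self.pv.P[0])
            curve = cal.klotz_curve(self.pv.edv, P_ed,
                                    An=ccfg["klotz_An"], Bn=ccfg["klotz_Bn"])
            self._passive = cal.fit_passive(
                self.mesh_ed, self.params.with_(mode="incompressible",
                                                gamma=0.0),
                curve, P_ed=P_ed, tol_V=ccfg["tol_V_passive_mL"],
                verbose=verbose)
        return self._passive

    def _cycle_pv(self):
        n = self.config["calibration"]["n_cycle_steps"]
        return synth.resample_pv(self.pv, n)

    def _activation_for(self, infarct_mask=None):
        base = self.activation_field
        if base is None and infarct_mask is None:
            return None
        if base is None:
            base = act.synchronous_field(self.mesh_ed)
        if infarct_mask is None:
            return base
        f = base.f * (~infarct_mask.mask)[:, None]
        return act.ActivationField(times=base.times, f=f)

    def fit(self, mode="incompressible", infarct=None, T_ref=None,
            gamma=None, verbose=False):
        """Calibrate and simulate one full cycle in the requested mode.

        mode: 'incompressible' or 'compressible'. infarct: optional
        InfarctMask; the active drive is zeroed there (passive properties
        unchanged) and T_Ca is refitted against the same PV loop. In
        compressible mode gamma is calibrated to the configured mean
        end-systolic dilatation unless a pre-fitted value is supplied.
        """
        ccfg = self.config["calibration"]
        passive = self.fit_passive(verbose=verbose)
        c = passive.c_fit
        base = self.params.with_(c=c, K_inc=None, K_floor=None)
        if mode == "compressible":
            kf = self.config["material"].get("K_inc_factor_compressible")
            if kf:
                base = base.with_(K_inc=kf * c)
        pv_c = self._cycle_pv()
        activation = self._activation_for(infarct)
        unmesh = passive.unloaded.mesh
        gamma_fit = 0.0
        mean_J_es = np.nan
        if mode == "incompressible":
            params = base.with_(mode="incompressible", gamma=0.0)
            trace = cal.fit_active_trace(
                unmesh, params, pv_c, activation,
                tol_V=ccfg["tol_V_active_mL"], T_max=ccfg["T_max_kPa"],
                verbose=verbose)
        elif mode == "compressible":
            if gamma is None and self._gamma is not None:
                gamma = self._gamma
            if gamma is None:
                if infarct is not None:
                    raise ValueError(
                        "calibrate gamma on the healthy heart first "
                        "(fit compressible without infarct)")
                gfit = cal.fit_gamma(
                    unmesh, base, pv_c, activation,
                    J_target_mean=ccfg["J_target_mean"],
                    tol_J=ccfg["tol_J"], T_ref=T_ref or self._t_ref_hint,
                    tol_V=ccfg["tol_V_active_mL"], verbose=verbose)
                self._gamma = gfit.gamma_fit
                gamma = gfit.gamma_fit
                trace = gfit.trace
                mean_J_es = gfit.mean_J_es
                params = base.with_(mode="compressible", gamma=gamma)
            else:
                params = base.with_(mode="compressible", gamma=gamma)
                trace = cal.fit_active_trace(
                    unmesh, params, pv_c, activation,
                    tol_V=ccfg["tol_V_active_mL"], T_max=ccfg["T_max_kPa"],
                    verbose=verbose)
                mean_J_es = cal.mean_dilatation_at_es(trace)
            gamma_fit = gamma
        else:
            raise ValueError(f"unknown mode {mode!r}")

        self._t_ref_hint = float(np.max(trace.T_Ca)) or self._t_ref_hint
        calres = cal.CalibrationResult(
            c_fit=c, unloaded_mesh=unmesh, T_Ca_times=trace.times,
            T_Ca_trace=trace.T_Ca, gamma_fit=gamma_fit,
            edv_mismatch=passive.edv_mismatch,
            rms_volume_error=passive.rms_volume_error,
            mean_J_es=mean_J_es,
            diagnostics={
                "passive_trials": passive.n_trials,
                "active_solves": trace.n_solves,
                "max_abs_volume_residual_mL":
                    float(np.max(np.abs(trace.volume_residuals))),
                "config_hash": config_hash(self.config),
            })
        return HeartCycleResults(
            model=self, mode=mode, params=params, calibration=calres,
            solution=trace.solution, infarct=infarct,
            activation=activation)


@dataclass
class HeartCycleResults:
    """Calibrated-cycle results: estimates, diagnostics and metrics."""

    model: HeartModel
    mode: str
    params: mat.MaterialParameters
    calibration: cal.CalibrationResult
    solution: CycleSolution
    infarct: object = None
    activation: object = None
    _metrics: dict = field(default=None, repr=False)

    # -- headline quantities ---------------------------------------------

    @property
    def peak_T_Ca(self):
        return float(np.max(self.calibration.T_Ca_trace))

    @property
    def c_fit(self):
        return self.calibration.c_fit

    @property
    def gamma_fit(self):
        return self.calibration.gamma_fit

    def thickness_ratio(self, **kw):
        return post.wall_thickness_fem(self.solution, **kw)

    def height_ratio(self):
        return post.lv_height(self.solution)

    def j_summary(self):
        return post.j_field_summary(self.solution)

    def active_work(self):
        return post.active_work(self.solution)

    def stress_summary(self):
        aha = aha_segment(self.solution.mesh)
        return post.active_stress_summary(self.solution, aha)

    def pv_metrics(self):
        sim = synth.PVTrace(t=self.solution.times,
                            P=self.solution.pressures,
                            V=self.solution.cavity_volumes,
                            HR=self.model.pv.HR)
        return post.pv_metrics(sim)

    def metrics(self):
        """Full validation metric report (cached)."""
        if self._metrics is None:
            js = self.j_summary()
            _, W, _ = self.active_work()
            rep = post.MetricReport()
            rep.update(
                mode=self.mode,
                c_fit_kPa=self.c_fit,
                gamma_fit=self.gamma_fit,
                peak_T_Ca_kPa=self.peak_T_Ca,
                thickness_ratio_es_ed=self.thickness_ratio(),
                lv_height_ratio_es_ed=self.height_ratio(),
                mean_J_es=js["mean_J_es"],
                min_J_es=js["min_J_es"],
                thirds_J_es=js["thirds_J_es"],
                peak_active_work_J=float(W.max()),
                **self.pv_metrics(),
            )
            self._metrics = rep
        return self._metrics

    def simulate_mi(self, fraction=None, verbose=False):
        """Post-infarct counterpart: same material, S_act = 0 apically."""
        frac = fraction or self.model.config["synth"]["infarct_fraction"]
        mask = synth.gen_infarct(self.model.mesh_ed, frac)
        return self.model.fit(mode=self.mode, infarct=mask,
                              gamma=self.gamma_fit or None, verbose=verbose)

    # -- presentation ------------------------------------------------------

    def summary(self):
        m = self.metrics().values
        lines = [
            "Calibrated cardiac-cycle model",
            "=" * 46,
            f"mode:                    {self.mode}"
            + ("  (apical infarct)" if self.infarct is not None else ""),
            f"passive scale c:         {m['c_fit_kPa']:.3f} kPa",
            f"bulk softening gamma:    {m['gamma_fit']:.1f}",
            f"peak active tension:     {m['peak_T_Ca_kPa']:.1f} kPa",
            f"mean J at end-systole:   {m['mean_J_es']:.3f}",
            f"min  J at end-systole:   {m['min_J_es']:.3f}",
            f"wall thickness ES/ED:    {m['thickness_ratio_es_ed']:.3f}",
            f"LV height ES/ED:         {m['lv_height_ratio_es_ed']:.3f}",
            f"peak active work:        {m['peak_active_work_J']:.4f} J",
            f"EF (simulated loop):     {m['EF']:.3f}",
            f"stroke work:             {m['stroke_work_mmHg_mL']:.0f} mmHg*mL",
        ]
        return "\n".join(lines)

    def plot_pv(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.pv.V, self.model.pv.P, "k-", label="data")
        ax.plot(self.solution.cavity_volumes, self.solution.pressures,
                "ro--", label="model")
        ax.set_xlabel("volume (mL)")
        ax.set_ylabel("pressure (mmHg)")
        ax.legend()
        return ax
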