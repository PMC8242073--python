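# Methods

`ventmech` simulates and calibrates organ-level left-ventricular (LV)
mechanics over a full cardiac cycle, with a myocardial constitutive model
whose bulk modulus decreases with active contraction so that the tissue —
nearly incompressible while passive — loses volume during systole, as
sonomicrometry in large animals shows it does. The package runs entirely on
an idealized ventricle with synthetic stand-ins for the in vivo data
(pressure–volume loop, epicardial action-potential maps, sonocrystal
arrays), so the whole pipeline is reproducible offline.

## Constitutive model

At each material point the Cauchy stress is

    T = p(J) I  +  (1/J) F_dev S_dev(E_dev) F_dev^T  +  (1/J) F S_act F^T

* **Volumetric**: `W_vol = (K/2)[(J^2 − 1)/2 − ln J]`, giving
  `p = (K/2)(J − 1/J)`; positive (tension) for J > 1. The printed form of
  the total-stress equation in the source literature omits the identity
  tensor and carries a minus sign on this term; we implement the standard
  convention (hydrostatic tension for J > 1), which is the only sign
  consistent with the stated energy.
* **Passive deviatoric**: transversely isotropic Fung energy
  `W_dev = (c/2)[exp(α Q) − 1]`,
  `Q = A1 E11² + A2 (E22² + E33² + 2 E23²) + A3 (E12² + E13²)`
  on the deviatoric Green–Lagrange strain in the local fiber frame
  (index 1 = fiber). Constants A1 = 12, A2 = 8, A3 = 26 from the
  literature; `c` is the single fitted passive constant; α is not reported
  by the study this model follows and defaults to 1 (exposed in config).
  The stress is the push-forward of ∂W_dev/∂E_dev at fixed F_dev — i.e. the
  J-projection term of a fully variational isochoric split is deliberately
  omitted, matching the model as stated; the finite-difference oracle in
  the tests differentiates the same way.
* **Active**: Hunter–McCulloch–ter-Keurs fiber stress
  `S_act = T_Ca(t) f(x,t) [1 + β(λ − 1)] / λ² m⊗m` (second
  Piola–Kirchhoff), with global tension `T_Ca(t)` (kPa), local drive
  `f ∈ [0,1]`, fiber stretch `λ = |F m|`, and β = 1.45 from the cited
  active-contraction law. The length modulation is floored at zero so
  extreme shortening cannot generate negative tension. Under push-forward
  the λ² cancels: the active Cauchy magnitude is `T_Ca f [1+β(λ−1)]/J`.
* **Contraction-modulated compressibility**: `K(T) = K_inc − γ T`,
  clamped below at `K_floor = 0.01 c`. The modulation uses the *local*
  effective tension `T_Ca·f`, so infarcted tissue (f = 0) remains
  incompressible — consistent with the experimental observation that
  systolic volume loss disappears acutely in ischemic tissue.

Units: kPa, mm, mL; pressures input in mmHg (1 mmHg = 0.133322 kPa);
work reported in J (kPa·mm³ = µJ).

### Bulk-modulus defaults

`K_inc` is a penalty, not a measured stiffness; the study conditions only
require "K ≫ c" and |J − 1| < 0.01 in incompressible phases. We use
`K_inc = 3×10³ c` in incompressible mode (measured max |J−1| ≈ 5×10⁻³ over
a full cycle; 10⁴ c gives no better isochoricity but roughly doubles Newton
cost) and `K_inc = 600 c` inside the compressible law (diastolic
|J−1| ≈ 2×10⁻³). The smaller compressible-mode plateau matters for
calibration conditioning: the γ needed to reach a given end-systolic K
scales with K_inc, and with a very large plateau the volume-matched
equilibrium develops a fold (a stiff J≈1 branch coexisting with the
compressing branch) that makes γ practically uncalibratable. Both factors
are config fields.

## Geometry and discretization

The default geometry is a truncated prolate-ellipsoid LV shell (endocardial
base radius 20 mm, wall 11 mm, base-to-apex 48 mm, truncation 0.5),
uniformly rescaled so the discrete cavity volume equals the target EDV
exactly. It is meshed with a structured grid of trilinear hexahedra; the
apex is closed by a ring of collapsed-hex wedges. Rule-based fibers run
+60° (endo) to −60° (epi) linearly in the transmural coordinate, tangent to
the wall. External meshes and fiber tables can be imported instead.

The solver is total-Lagrangian with selective reduced integration: the
deviatoric and active stresses use the full 2×2×2 Gauss rule while the
volumetric penalty acts on the element-mean dilatation through the exact
volume-averaged shape-function gradients (classical mean dilatation /
B-bar, which passes the distorted patch test; a centroid-sampled gradient
does not). Hexahedra with this treatment were preferred over the
tetrahedra of the original study because a structured ellipsoid shell
meshes naturally with them and Q1 mean-dilatation elements are a
well-understood locking control at desk scale. Reported per-quadrature
J values are the element-mean dilatation of this mixed treatment (the raw
trilinear J contains the usual spurious intra-element modes at near
incompressibility).

Cavity pressure is a follower load on the deformed endocardial surface
integrated with the bilinear 2×2 rule; the cavity-volume functional uses
the same rule plus a basal cap, so load and volume are exactly
work-conjugate (verified to 1e-5 in the tests). Basal constraints: all
base-plane nodes fixed along the long axis, one basal node fully fixed and
one fixed circumferentially — the same rigid-mode elimination as the
original soft-tissue mounting, without modelling the mounting block.

Newton's method uses a consistent tangent obtained by batched forward
differencing of the discrete residual (verified to ~3×10⁻⁸ against
directional finite differences), near-full steps with backtracking only on
element inversion/overflow (the penalty residual is non-monotone but
convergent), an early stagnation abort, and automatic load-step bisection.
Tolerances: relative residual 10⁻⁶ against the follower-load norm,
absolute 10⁻⁷ mN; 25 iterations; 5 bisection levels.

## Calibration chain

1. **Klotz-type EDPVR**: the single-beat normalized curve anchored at the
   measured (EDV, P_ed): `V0 = V_ed(0.6 − 0.006 P_ed)`,
   `V30 = V0 + (V_ed − V0)/(P_ed/An)^(1/Bn)` with An = 27.78 mmHg,
   Bn = 2.76 (literature constants, config inputs), then `P = a V^b`
   through the anchor.
2. **Inverse unloading**: backward-displacement fixed point
   `X ← X − (inflate(X) − x_ED)` to the stress-free reference; converges in
   4–6 iterations to 0.08 mm nodal mismatch (≈0.1–0.3 mL in cavity
   volume), with under-relaxation on divergence.
3. **Passive fit**: scalar search on `c` (α, A1–A3 fixed): each trial
   unloads and reinflates through 3/6/9/12/15 mmHg; the RMS volume error
   against the Klotz curve is minimized by a log-space golden search
   (≈9 trials). The end-diastolic mismatch is the unloading residual and
   is required to stay below the 0.53 mL bound.
4. **Active-tension trace**: sequentially per PV time point, a secant root
   find on `T_Ca(t_k)` drives the model cavity volume to the measured
   volume at the measured pressure within 0.1 mL, warm-started by linear
   extrapolation of the trace (with `T_Ca(0) = 0` at ED). In compressible
   mode the tension probes are (i) capped where `K(T)` would fall below a
   small safety floor, because the linear softening law is unbounded
   below, and (ii) the ejection steps are seeded from the compressed-wall
   side by a brief constant-low-K continuation solve: the volume-matched
   state is bistable there and the physiological branch (the one the
   sonomicrometry sees) is the compressing one.
5. **Compressibility rate**: outer 1-D search on γ until the
   volume-weighted mean element dilatation at end systole (minimum-volume
   time of the PV data) equals the target 0.90 ± 0.005 — the ~10%
   transmural-average systolic volume reduction of the sonocrystal
   studies. Because J(γ) is strongly nonlinear, the update mixes a
   stress-balance step (choose γ so K at the measured peak tension equals
   measured-drive/(1−J_target)) with a bracketed secant; 3–6 trials.

Post-infarct simulations zero the active drive in a contiguous apical
region holding 20% of the wall volume (passive properties and γ
unchanged) and refit only `T_Ca(t)` against the same PV loop.

## Synthetic data

The generators emulate the structure of the animal dataset: a smooth
four-phase PV loop (filling along the same Klotz curve the calibration
targets; ejection pressure peaks mid-ejection and ends near the dicrotic
notch at ~88% of peak; EDV 60 mL, EF 0.30, P_ed 15 mmHg, P_peak 95 mmHg,
HR 90 bpm — declared stand-ins, only the ED pressure is a reported
anchor); 71 epicardial MAP-like waveforms with a base-to-apex activation
delay plus seeded jitter; 27-marker (3×3×3) and 12-epi/9-endo sonocrystal
layouts carried by any deformation field; apical infarct masks. All
generators are bit-reproducible at fixed seed. What they do *not* emulate:
measurement dropout, catheter drift, breathing motion, RV loading, or real
fiber dispersion — so passing tests demonstrate internal consistency of
the pipeline at desk scale, not fidelity to any particular animal.

## Problem sizes

The default mesh uses a 6 mm target edge (≈660 elements); calibration and
validation studies run on a coarse 10 mm preset (≈252 elements) with the
cycle resampled to 16 quasi-static steps, and the test suite uses a
further-reduced preset (≈100–200 elements, 8–14 steps). These sizes were
chosen by the refinement criterion (cavity volume at ED pressure changes
< 2% on refinement); the spatial metrics reported below move by well under
their stated tolerances between the coarse and default meshes.

## Known limitations and honest discrepancies

* The idealized ±60° helix wall is mechanically *more efficient* than a
  real ventricle: the fitted peak tensions (~30 kPa) are several times
  smaller than organ-scale values reported from image-based biventricular
  models (~100–180 kPa). Consequently the cavity pressure is large
  *relative* to the active volumetric drive, which steepens the transmural
  gradient of systolic compression: at a calibrated 10% mean volume
  reduction the idealized model's endocardial extreme overshoots (J down
  to ~0.6–0.7 rather than ~0.8), most strongly in the collapsed-hex apex
  cap where the pole closure and the fiber rule are both singular. The
  J-field summary therefore also reports the free-wall extreme.
* For the same reason the incompressible/compressible contrast in fitted
  peak tension is compressed (ratio ~1.1 rather than ~1.8): the efficiency
  penalty of lateral bulging is mild when the transverse Fung response is
  evaluated at these small strains and α = 1 (α is unreported; a larger α
  would widen the contrast).
* The model *lengthens* slightly at end systole (height ratio > 1) instead
  of shortening ~6–8%: with the base plane held and rule-based fibers, the
  apex is pushed outward by cavity pressure; real apical fiber vortices
  and mitral-plane descent are absent. Orderings between modes
  (compressible shortens/thins less than incompressible bulges) are
  preserved.
* Residual stress, viscoelasticity, perfusion mechanisms, pericardial
  contact and RV loading are out of scope; the compressibility law models
  consequences, not mechanisms.
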