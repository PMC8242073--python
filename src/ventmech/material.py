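"""Myocardial constitutive law at a material point.

Total Cauchy stress is the sum of three parts:

* a volumetric penalty ``p(J) I`` with ``p = dW_vol/dJ = (K/2)(J - 1/J)`` from
  ``W_vol = (K/2)((J^2 - 1)/2 - ln J)``;
* the push-forward of a transversely isotropic Fung deviatoric energy
  ``W_dev = (c/2)(exp(alpha Q) - 1)`` with
  ``Q = A1 E11^2 + A2 (E22^2 + E33^2 + 2 E23^2) + A3 (E12^2 + E13^2)``
  evaluated on the deviatoric Green-Lagrange strain in the local fiber frame
  (index 1 = fiber direction);
* an additive Hunter-McCulloch-ter-Keurs active stress along the fiber,
  ``S_act = T_Ca f [1 + beta (lambda - 1)] / lambda^2  m (x) m`` (second
  Piola-Kirchhoff), pushed forward as ``(1/J) F S_act F^T``.

The distinguishing feature is contraction-modulated compressibility: the bulk
modulus is not a constant but decreases linearly with the current active
tension, ``K(T_Ca) = K_inc - gamma T_Ca`` (floored at ``K_floor``), so the
tissue is nearly incompressible whenever it is passive (T_Ca = 0) and can lose
volume while actively contracting.

Units: stress in kPa, lengths in mm throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

__all__ = [
    "FiberFrame",
    "MaterialParameters",
    "MaterialState",
    "InvalidDeformationError",
    "InvalidStrainError",
    "StrainDivergenceError",
    "decompose_deformation",
    "fung_Q",
    "passive_deviatoric_cauchy",
    "bulk_modulus",
    "volumetric_cauchy",
    "fiber_stretch",
    "active_cauchy",
    "total_cauchy",
    "numerical_tangent",
    "lateral_response",
]

# Q-exponent ceiling beyond which exp(alpha*Q) is treated as a divergence
# (strain far outside the model's calibrated range).
_EXP_CAP = 250.0


class InvalidDeformationError(ValueError):
    """Deformation gradient with non-positive determinant."""


class InvalidStrainError(ValueError):
    """Strain tensor that is not symmetric to tolerance."""


class StrainDivergenceError(FloatingPointError):
    """exp(alpha*Q) overflow: strain outside the model's range."""


@dataclass(frozen=True)
class FiberFrame:
    """Right-handed orthonormal triad (m, s, n); m is the fiber direction."""

    m: np.ndarray
    s: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        for v in (self.m, self.s, self.n):
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise ValueError("frame vectors must be unit length")
        if (
            abs(self.m @ self.s) > 1e-12
            or abs(self.m @ self.n) > 1e-12
            or abs(self.s @ self.n) > 1e-12
        ):
            raise ValueError("frame vectors must be mutually orthogonal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("frame must be right handed")

    @property
    def rotation(self) -> np.ndarray:
        """Columns (m, s, n): maps fiber-frame components to global."""
        return np.column_stack([self.m, self.s, self.n])

    @classmethod
    def from_fiber(cls, m, hint=(0.0, 0.0, 1.0)) -> "FiberFrame":
        """Complete a triad from a fiber vector and a transverse hint."""
        m = np.asarray(m, float)
        m = m / np.linalg.norm(m)
        hint = np.asarray(hint, float)
        s = np.cross(hint, m)
        if np.linalg.norm(s) < 1e-8:  # hint parallel to fiber
            hint = np.array([1.0, 0.0, 0.0])
            s = np.cross(hint, m)
        s /= np.linalg.norm(s)
        n = np.cross(m, s)
        return cls(m=m, s=s, n=n)


@dataclass(frozen=True)
class MaterialParameters:
    """Passive, volumetric and active constants of the myocardial law.

    c, alpha, A1..A3 parameterize the Fung deviatoric energy; K_inc is the
    passive (incompressible-regime) bulk modulus, gamma the rate at which
    active tension softens it, K_floor the clamp that keeps K positive;
    beta the length dependence of active tension.
    """

    c: float = 1.522          # kPa, fitted organ-level value
    alpha: float = 1.0        # dimensionless Fung exponent scale
    A1: float = 12.0
    A2: float = 8.0
    A3: float = 26.0
    K_inc: float = field(default=None)  # kPa; default 3e3*c
    gamma: float = 0.0        # dimensionless; 0 in incompressible mode
    K_floor: float = field(default=None)  # kPa; default 1e-2*c
    beta: float = 1.45        # HMT fiber-length modulation
    mode: str = "incompressible"

    def __post_init__(self):
        if self.K_inc is None:
            object.__setattr__(self, "K_inc", 3.0e3 * self.c)
        if self.K_floor is None:
            object.__setattr__(self, "K_floor", 1.0e-2 * self.c)
        if self.mode not in ("incompressible", "compressible"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "incompressible" and self.gamma != 0.0:
            raise ValueError("incompressible mode requires gamma = 0")
        if min(self.c, self.alpha, self.A1, self.A2, self.A3) <= 0:
            raise ValueError("c, alpha, A1..A3 must be positive")
        if self.K_inc <= 0 or self.K_floor <= 0 or self.gamma < 0:
            raise ValueError("K_inc, K_floor must be > 0 and gamma >= 0")

    def with_(self, **kw) -> "MaterialParameters":
        return replace(self, **kw)


@dataclass
class MaterialState:
    """Point state: deformation gradient, global tension, local drive."""

    F: np.ndarray
    T_Ca: float = 0.0  # kPa
    f: float = 1.0     # local activation drive in [0, 1]

    def __post_init__(self):
        self.F = np.asarray(self.F, float)
        if np.linalg.det(self.F) <= 0:
            raise InvalidDeformationError("det F must be positive")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("activation drive f must lie in [0, 1]")
        if self.T_Ca < 0:
            raise ValueError("T_Ca must be non-negative")


# ---------------------------------------------------------------------------
# kinematics


def decompose_deformation(F):
    """Split F into volume ratio J, deviatoric F_dev and strain E_dev.

    Returns ``(J, F_dev, E_dev)`` with ``F_dev = J^(-1/3) F`` (det = 1) and
    ``E_dev = (F_dev^T F_dev - I)/2``. Batched over leading axes.
    """
    F = np.asarray(F, float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvalidDeformationError("det F must be positive")
    Jm13 = np.asarray(J) ** (-1.0 / 3.0)
    F_dev = Jm13[..., None, None] * F
    I = np.eye(3)
    E_dev = 0.5 * (np.swapaxes(F_dev, -1, -2) @ F_dev - I)
    return J, F_dev, E_dev


def fiber_stretch(F, m):
    """Fiber stretch lambda = sqrt(m . F^T F m) = |F m|."""
    F = np.asarray(F, float)
    m = np.asarray(m, float)
    v = np.einsum("...ij,...j->...i", F, m)
    return np.sqrt(np.einsum("...i,...i->...", v, v))


# ---------------------------------------------------------------------------
# passive deviatoric response


def _check_symmetric(E):
    if np.max(np.abs(E - np.swapaxes(E, -1, -2))) > 1e-10:
        raise InvalidStrainError("strain tensor must be symmetric")


def fung_Q(E_dev, frame, params):
    """Fung quadratic form Q of the strain, in the (m, s, n) fiber basis."""
    E_dev = np.asarray(E_dev, float)
    _check_symmetric(E_dev)
    R = frame.rotation if isinstance(frame, FiberFrame) else np.asarray(frame)
    El = np.swapaxes(R, -1, -2) @ E_dev @ R  # local components, 1 = fiber
    p = params
    return (
        p.A1 * El[..., 0, 0] ** 2
        + p.A2 * (El[..., 1, 1] ** 2 + El[..., 2, 2] ** 2 + 2.0 * El[..., 1, 2] ** 2)
        + p.A3 * (El[..., 0, 1] ** 2 + El[..., 0, 2] ** 2)
    )


def _dQ_dE_local(El, p):
    """dQ/dE in the fiber frame, treating E as a full symmetric tensor."""
    D = np.zeros_like(El)
    D[..., 0, 0] = 2.0 * p.A1 * El[..., 0, 0]
    D[..., 1, 1] = 2.0 * p.A2 * El[..., 1, 1]
    D[..., 2, 2] = 2.0 * p.A2 * El[..., 2, 2]
    D[..., 1, 2] = D[..., 2, 1] = 2.0 * p.A2 * El[..., 1, 2]
    D[..., 0, 1] = D[..., 1, 0] = p.A3 * El[..., 0, 1]
    D[..., 0, 2] = D[..., 2, 0] = p.A3 * El[..., 0, 2]
    return D


def _passive_pk2_dev(E_dev, R, params):
    """S = dW_dev/dE_dev in global components (second Piola w.r.t. F_dev)."""
    El = np.swapaxes(R, -1, -2) @ E_dev @ R
    p = params
    Q = (
        p.A1 * El[..., 0, 0] ** 2
        + p.A2 * (El[..., 1, 1] ** 2 + El[..., 2, 2] ** 2 + 2.0 * El[..., 1, 2] ** 2)
        + p.A3 * (El[..., 0, 1] ** 2 + El[..., 0, 2] ** 2)
    )
    aQ = p.alpha * Q
    if np.any(aQ > _EXP_CAP):
        raise StrainDivergenceError(
            "exp(alpha*Q) overflow: strain outside the model's range "
            f"(max alpha*Q = {float(np.max(aQ)):.3g})"
        )
    scale = 0.5 * p.c * p.alpha * np.exp(aQ)
    Sl = scale[..., None, None] * _dQ_dE_local(El, p)
    return R @ Sl @ np.swapaxes(R, -1, -2)


def passive_deviatoric_cauchy(F, frame, params):
    """Push-forward of the Fung deviatoric stress: (1/J) F_dev S F_dev^T."""
    J, F_dev, E_dev = decompose_deformation(F)
    R = frame.rotation if isinstance(frame, FiberFrame) else np.asarray(frame)
    S = _passive_pk2_dev(E_dev, R, params)
    sig = F_dev @ S @ np.swapaxes(F_dev, -1, -2)
    return sig / np.asarray(J)[..., None, None]


# ---------------------------------------------------------------------------
# volumetric response


def bulk_modulus(T_Ca, params):
    """Contraction-modulated bulk modulus K(T_Ca) = K_inc - gamma*T_Ca.

    Clamped below at K_floor. In incompressible mode K is constant K_inc.
    T_Ca may be an array (e.g. the local effective tension T_Ca * f).
    """
    T_Ca = np.asarray(T_Ca, float)
    if np.any(T_Ca < 0):
        raise ValueError("T_Ca must be non-negative")
    if params.mode == "incompressible":
        return np.broadcast_to(np.float64(params.K_inc), T_Ca.shape).copy() \
            if T_Ca.ndim else float(params.K_inc)
    K = params.K_inc - params.gamma * T_Ca
    K = np.maximum(K, params.K_floor)
    return float(K) if K.ndim == 0 else K


def volumetric_pressure(J, K):
    """p = dW_vol/dJ = (K/2)(J - 1/J); tension for J>1, compression for J<1."""
    J = np.asarray(J, float)
    return 0.5 * np.asarray(K, float) * (J - 1.0 / J)


def volumetric_cauchy(J, K):
    """Hydrostatic stress p(J) I from the volumetric penalty energy."""
    p = volumetric_pressure(J, K)
    return np.asarray(p)[..., None, None] * np.eye(3)


# ---------------------------------------------------------------------------
# active response


def _active_scalar(lam, T_Ca, f, params):
    """HMT second-Piola magnitude T_Ca f [1 + beta(lam-1)]_+ / lam^2."""
    mod = np.maximum(1.0 + params.beta * (np.asarray(lam) - 1.0), 0.0)
    return np.asarray(T_Ca) * np.asarray(f) * mod / np.asarray(lam) ** 2


def active_cauchy(state, frame, params):
    """Active Cauchy stress (1/J) F S_act F^T.

    Rank-one along the deformed fiber direction; the lambda^2 in the HMT law
    cancels under push-forward so the magnitude is T_Ca f [1+beta(lam-1)]/J.
    """
    F = np.asarray(state.F, float)
    m = frame.m if isinstance(frame, FiberFrame) else np.asarray(frame)
    J = np.linalg.det(F)
    lam = fiber_stretch(F, m)
    s = _active_scalar(lam, state.T_Ca, state.f, params)
    Fm = np.einsum("...ij,...j->...i", F, m)
    return (np.asarray(s) / np.asarray(J))[..., None, None] * (
        Fm[..., :, None] * Fm[..., None, :]
    )


def total_cauchy(state, frame, params):
    """Total Cauchy stress: volumetric + passive deviatoric + active."""
    F = np.asarray(state.F, float)
    J = np.linalg.det(F)
    T_eff = state.T_Ca * state.f
    K = bulk_modulus(T_eff, params)
    sig = volumetric_cauchy(J, K)
    sig = sig + passive_deviatoric_cauchy(F, frame, params)
    sig = sig + active_cauchy(state, frame, params)
    return sig


# ---------------------------------------------------------------------------
# tangent and material-point drivers


def numerical_tangent(state, frame, params, h=1e-6):
    """Central-difference tangent dT/dF (3x3x3x3), A[i,j,k,l] = dT_ij/dF_kl."""
    if not (1e-8 <= h <= 1e-4):
        raise ValueError("perturbation h must lie in [1e-8, 1e-4]")
    F0 = np.asarray(state.F, float)
    A = np.zeros((3, 3, 3, 3))
    for k in range(3):
        for l in range(3):
            Fp = F0.copy(); Fp[k, l] += h
            Fm = F0.copy(); Fm[k, l] -= h
            Tp = total_cauchy(MaterialState(Fp, state.T_Ca, state.f), frame, params)
            Tm = total_cauchy(MaterialState(Fm, state.T_Ca, state.f), frame, params)
            A[:, :, k, l] = (Tp - Tm) / (2.0 * h)
    return A


def lateral_response(axial_stretch, T_Ca, params, frame=None):
    """Free lateral stretch of a fiber-aligned block contracted axially.

    The block has its fiber along x and is shortened to ``axial_stretch``
    with traction-free lateral faces and transversely symmetric response
    F = diag(axial, s, s). In incompressible mode s follows from J = 1
    (s = 1/sqrt(axial)); in compressible mode s solves the lateral
    equilibrium ``sigma_yy(F) = 0`` with K evaluated at T_Ca.
    """
    from scipy.optimize import brentq

    if axial_stretch <= 0:
        raise ValueError("axial stretch must be positive")
    if params.mode == "incompressible":
        return 1.0 / np.sqrt(axial_stretch)
    if frame is None:
        frame = FiberFrame(
            m=np.array([1.0, 0.0, 0.0]),
            s=np.array([0.0, 1.0, 0.0]),
            n=np.array([0.0, 0.0, 1.0]),
        )

    def sig_yy(s):
        F = np.diag([axial_stretch, s, s])
        st = MaterialState(F, T_Ca=T_Ca, f=1.0)
        return total_cauchy(st, frame, params)[1, 1]

    lo, hi = 0.4, 1.0 / np.sqrt(axial_stretch) + 0.3
    return brentq(sig_yy, lo, hi, xtol=1e-12)
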