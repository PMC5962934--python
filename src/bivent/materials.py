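"""Constitutive laws for passive and active myocardium.

Passive response: orthotropic Holzapfel-Ogden strain energy built on the
isochoric invariants I1, I4f, I4s, I8fs, plus a volumetric penalty that
enforces near-incompressibility.  Active response: time-varying-elastance
fiber tension with length-dependent calcium sensitivity (Frank-Starling),
a fraction ``n_s`` of which acts in the sheet direction.

Units: stresses and energies in kPa, lengths dimensionless (stretches),
sarcomere lengths in micrometres, time in seconds.

All functions are vectorized over leading array dimensions: ``F`` may be
``(..., 3, 3)`` and the direction vectors ``(..., 3)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

#: cap on exponential arguments; beyond this the energy is astronomically
#: large anyway and raw exp() would overflow to inf and poison the solver
EXP_CAP = 50.0


def _safe_exp(x):
    x = np.asarray(x, dtype=float)
    if np.any(x > EXP_CAP):
        warnings.warn(
            "constitutive exponential argument exceeded cap "
            f"({EXP_CAP}); clipping", RuntimeWarning, stacklevel=3)
        x = np.minimum(x, EXP_CAP)
    return np.exp(x)


@dataclass(frozen=True)
class PassiveParams:
    """Holzapfel-Ogden moduli (kPa), exponents (-) and penalty D (1/kPa).

    ``D = 2/K`` with K the bulk modulus.  ``fiber_tension_only`` activates
    the I4 exponential terms only in fiber/sheet extension (I4 > 1), the
    usual convention for collagen-like fibers that cannot support
    compression.
    """

    a: float = 8.41
    b: float = 30.32
    a_f: float = 27.72
    b_f: float = 58.18
    a_s: float = 3.85
    b_s: float = 50.44
    a_fs: float = 2.26
    b_fs: float = 12.42
    D: float | None = None
    fiber_tension_only: bool = True

    def __post_init__(self):
        for name in ("a", "a_f", "a_s", "a_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"modulus {name} must be >= 0")
        for name in ("b", "b_f", "b_s", "b_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"exponent {name} must be > 0")
        if self.D is None:
            # default bulk modulus K = 1000 a; with the selective-reduced
            # volumetric integration this pins the element-mean J near 1
            object.__setattr__(self, "D", 2.0 / (1000.0 * max(self.a, 1e-12)))
        if self.D <= 0:
            raise ValueError("penalty D must be > 0")

    def scaled(self, A: float, B: float) -> "PassiveParams":
        """Uniformly scale moduli by A and exponents by B (stage-2 action).

        The bulk modulus scales with A as well (D -> D/A), so the degree
        of incompressibility relative to the shear response is preserved
        and the passive pressure-volume curve obeys the exact identity
        V(P; A-scaled) = V(P/A; unscaled).
        """
        if A <= 0 or B <= 0:
            raise ValueError("scaling factors A, B must be > 0")
        return replace(
            self, a=self.a * A, a_f=self.a_f * A, a_s=self.a_s * A,
            a_fs=self.a_fs * A, b=self.b * B, b_f=self.b_f * B,
            b_s=self.b_s * B, b_fs=self.b_fs * B, D=self.D / A)


#: calibrated chronic-heart-failure myocardium preset
CHF_REFERENCE = PassiveParams()


@dataclass(frozen=True)
class ActiveParams:
    """Time-varying-elastance active-tension constants.

    tmax   peak allowable tension (kPa)
    ca0    peak intracellular calcium (umol/l)
    ca0max calcium constant entering ECa50 (umol/l)
    b_len  length-sensitivity exponent (1/um)
    l0     sarcomere length below which no tension develops (um)
    lr     unloaded (reference) sarcomere length (um)
    t0     time to peak tension (s)
    m_relax, b_relax  linear relaxation-duration law t_r = m*l + b (s/um, s)
    n_s    fraction of active tension transferred to the sheet direction
    """

    tmax: float = 170.0
    ca0: float = 4.35
    ca0max: float = 4.35
    b_len: float = 4.75
    l0: float = 1.58
    lr: float = 1.85
    t0: float = 0.17
    m_relax: float = 1.0489
    b_relax: float = -1.429
    n_s: float = 0.25

    def __post_init__(self):
        if self.tmax < 0:
            raise ValueError("tmax must be >= 0")
        if not (0.0 <= self.n_s < 1.0):
            raise ValueError("n_s must lie in [0, 1)")
        if self.l0 >= self.lr:
            raise ValueError("l0 must be below the reference length lr")


@dataclass
class DeformationState:
    """Kinematic quantities at one or many material points."""

    F: np.ndarray
    J: np.ndarray
    Fbar: np.ndarray
    Cbar: np.ndarray
    I1: np.ndarray
    I4f: np.ndarray
    I4s: np.ndarray
    I8fs: np.ndarray
    lambda_f: np.ndarray  # fiber stretch from the FULL C (physical length)


def kinematics(F, f0, s0) -> DeformationState:
    """Invariants of the isochoric right Cauchy-Green tensor.

    The fiber stretch ``lambda_f`` is taken from the full C so that the
    sarcomere length entering the active law is physical, while the
    passive invariants use the isochoric split.
    """
    F = np.asarray(F, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("element inversion: det(F) <= 0")
    Fbar = J[..., None, None] ** (-1.0 / 3.0) * F
    C = np.einsum("...ji,...jk->...ik", F, F)
    Cbar = J[..., None, None] ** (-2.0 / 3.0) * C
    I1 = np.trace(Cbar, axis1=-2, axis2=-1)
    I4f = np.einsum("...i,...ij,...j->...", f0, Cbar, f0)
    I4s = np.einsum("...i,...ij,...j->...", s0, Cbar, s0)
    I8fs = np.einsum("...i,...ij,...j->...", f0, Cbar, s0)
    lambda_f = np.sqrt(np.einsum("...i,...ij,...j->...", f0, C, f0))
    return DeformationState(F=F, J=J, Fbar=Fbar, Cbar=Cbar, I1=I1,
                            I4f=I4f, I4s=I4s, I8fs=I8fs, lambda_f=lambda_f)


def psi_iso(state: DeformationState, p: PassiveParams):
    """Isochoric strain-energy density (kPa).

    Note the isotropic term is a/(2b)*exp(...) which is nonzero at the
    identity; energies reported relative to the reference state should
    subtract ``psi_iso(identity)`` = a/(2b).
    """
    e1 = _safe_exp(p.b * (state.I1 - 3.0))
    w = p.a / (2.0 * p.b) * e1
    for (ai, bi, I4) in ((p.a_f, p.b_f, state.I4f), (p.a_s, p.b_s, state.I4s)):
        if ai == 0.0:
            continue
        d = I4 - 1.0
        if p.fiber_tension_only:
            d = np.maximum(d, 0.0)
        w = w + ai / (2.0 * bi) * (_safe_exp(bi * d * d) - 1.0)
    if p.a_fs != 0.0:
        w = w + p.a_fs / (2.0 * p.b_fs) * (
            _safe_exp(p.b_fs * state.I8fs ** 2) - 1.0)
    return w


def psi_vol(J, D):
    """Volumetric penalty (kPa): ((J^2-1)/2 - ln J)/D, convex, min at J=1."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0):
        raise ValueError("element inversion: J <= 0")
    return ((J * J - 1.0) / 2.0 - np.log(J)) / D


def _pk2_parts(F, f0, s0, p: PassiveParams):
    """Second Piola-Kirchhoff stress, split into (isochoric, volumetric)."""
    st = kinematics(F, f0, s0)
    J = st.J
    C = np.einsum("...ji,...jk->...ik", F, F)
    Cinv = np.linalg.inv(C)
    I = np.broadcast_to(np.eye(3), C.shape)

    psi1 = p.a / 2.0 * _safe_exp(p.b * (st.I1 - 3.0))
    Sbar = 2.0 * psi1[..., None, None] * I
    for (ai, bi, I4, v) in ((p.a_f, p.b_f, st.I4f, f0),
                            (p.a_s, p.b_s, st.I4s, s0)):
        if ai == 0.0:
            continue
        d = I4 - 1.0
        if p.fiber_tension_only:
            d = np.maximum(d, 0.0)
        psi4 = ai * d * _safe_exp(bi * d * d)
        Sbar = Sbar + 2.0 * psi4[..., None, None] * np.einsum(
            "...i,...j->...ij", v, v)
    if p.a_fs != 0.0:
        psi8 = p.a_fs * st.I8fs * _safe_exp(p.b_fs * st.I8fs ** 2)
        sym_fs = 0.5 * (np.einsum("...i,...j->...ij", f0, s0)
                        + np.einsum("...i,...j->...ij", s0, f0))
        Sbar = Sbar + 2.0 * psi8[..., None, None] * sym_fs

    # deviatoric projection in the reference configuration
    SbarC = np.einsum("...ij,...ij->...", Sbar, C)
    S_iso = (J ** (-2.0 / 3.0))[..., None, None] * (
        Sbar - (SbarC / 3.0)[..., None, None] * Cinv)

    p_vol = (J - 1.0 / J) / p.D  # d(psi_vol)/dJ
    S_vol = (J * p_vol)[..., None, None] * Cinv
    return S_iso, S_vol


def pk2_passive(F, f0, s0, p: PassiveParams):
    S_iso, S_vol = _pk2_parts(F, f0, s0, p)
    return S_iso + S_vol


def passive_cauchy(F, f0, s0, p: PassiveParams):
    """Passive Cauchy stress sigma = J^-1 F S F^T (kPa); zero at F = I."""
    F = np.asarray(F, dtype=float)
    S = pk2_passive(F, f0, s0, p)
    J = np.linalg.det(F)
    return np.einsum("...ij,...jk,...lk->...il", F, S, F) / J[..., None, None]


def active_tension(t, lambda_f, ap: ActiveParams):
    """Active fiber tension Ta(t, lambda_f) in kPa.

    Sarcomere length l = lr * lambda_f.  The calcium-sensitivity term uses
    ECa50(l) = ca0max / sqrt(exp(b_len (l - l0)) - 1) for l > l0 and shuts
    tension off entirely for l <= l0.  The timing envelope (1 - cos w)/2
    rises over [0, t0] and relaxes over a length-dependent duration
    t_r = m_relax*l + b_relax, after which tension is zero.  ``t`` is
    reduced modulo the envelope support internally by the caller's cycle.
    """
    lam = np.asarray(lambda_f, dtype=float)
    t = np.asarray(t, dtype=float)
    if ap.tmax == 0.0:
        return np.zeros(np.broadcast_shapes(t.shape, lam.shape))
    l = ap.lr * lam
    active_len = l > ap.l0
    eca50_sq = np.where(
        active_len,
        ap.ca0max ** 2 / np.maximum(_safe_exp(ap.b_len * (l - ap.l0)) - 1.0,
                                    1e-30),
        np.inf)
    ca_term = ap.ca0 ** 2 / (ap.ca0 ** 2 + eca50_sq)

    t_r = np.maximum(ap.m_relax * l + ap.b_relax, 1e-6)
    w = np.where(t < ap.t0, np.pi * t / ap.t0,
                 np.where(t <= ap.t0 + t_r,
                          np.pi * (t - ap.t0 + t_r) / t_r, 0.0))
    # rising phase maps w in [0, pi); relaxation maps w in [pi, 2pi]
    envelope = (1.0 - np.cos(w)) / 2.0
    ta = ap.tmax * ca_term * envelope
    return np.where(active_len, ta, 0.0)


def total_cauchy(sigma_p, Ta, n_s, f, s):
    """Total Cauchy stress: passive + Ta f(x)f + n_s Ta s(x)s (kPa).

    ``f`` and ``s`` are the *deformed*, normalized fiber and sheet
    directions (push-forward of f0, s0).
    """
    if not (0.0 <= n_s < 1.0):
        raise ValueError("n_s must lie in [0, 1)")
    Ta = np.asarray(Ta, dtype=float)
    ff = np.einsum("...i,...j->...ij", f, f)
    ss = np.einsum("...i,...j->...ij", s, s)
    return sigma_p + Ta[..., None, None] * ff \
        + (n_s * Ta)[..., None, None] * ss


def deformed_directions(F, f0, s0):
    """Normalized push-forward of the fiber and sheet directions."""
    f = np.einsum("...ij,...j->...i", F, f0)
    s = np.einsum("...ij,...j->...i", F, s0)
    f = f / np.linalg.norm(f, axis=-1, keepdims=True)
    s = s / np.linalg.norm(s, axis=-1, keepdims=True)
    return f, s


def first_piola(F, f0, s0, p: PassiveParams, Ta=None, n_s=0.0,
                include_vol=True, include_iso=True):
    """First Piola-Kirchhoff stress P = J sigma F^-T for FE assembly.

    ``Ta`` (kPa) adds the active contribution along the deformed fiber
    (and sheet, via ``n_s``).  The iso/vol split supports selective
    reduced integration of the volumetric penalty.
    """
    F = np.asarray(F, dtype=float)
    S_iso, S_vol = _pk2_parts(F, f0, s0, p)
    S = 0.0
    if include_iso:
        S = S + S_iso
    if include_vol:
        S = S + S_vol
    P = np.einsum("...ij,...jk->...ik", F, S)
    if Ta is not None and include_iso:
        J = np.linalg.det(F)
        f, s = deformed_directions(F, f0, s0)
        sig_a = np.einsum("...,...i,...j->...ij", np.asarray(Ta, float), f, f)
        if n_s:
            sig_a = sig_a + n_s * np.einsum(
                "...,...i,...j->...ij", np.asarray(Ta, float), s, s)
        FinvT = np.linalg.inv(F).swapaxes(-1, -2)
        P = P + J[..., None, None] * np.einsum(
            "...ij,...jk->...ik", sig_a, FinvT)
    return P


#: 1 mmHg in kPa — used at every pressure interface
MMHG_TO_KPA = 0.133322

KPA_TO_MMHG = 1.0 / MMHG_TO_KPA
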