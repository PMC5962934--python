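"""Two-stage passive calibration and active-tension calibration.

Stage 1 fits the eight Holzapfel-Ogden constants to tri-axial simple-shear
stress-strain data (six modes).  Stage 2 scales the fitted moduli by A and
exponents by B so the FE passive inflation of the LV tracks the analytic
single-beat end-diastolic pressure-volume relation (Klotz curve) anchored
at the measured (volume, pressure) point, and reaches the target EDV at
the target EDP.  Finally the peak active tension is found by matching the
stroke volume of the coupled beat.

Synthetic data generators are provided so each calibration is
parameter-recovery-testable without external measurements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from . import fem
from .circulation import CircuitParams
from .materials import ActiveParams, PassiveParams
from .simulator import CoupledModel, run_simulation

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Klotz single-beat EDPVR


@dataclass(frozen=True)
class KlotzCurve:
    """Analytic EDPVR anchored at one measured point (Vm ml, Pm mmHg).

    V0 = Vm (0.6 - 0.006 Pm) is the volume at zero pressure, V30 the
    volume at 30 mmHg; P(V) = An * Vn^Bn on the normalized volume
    Vn = (V - V0)/(V30 - V0).  The normalized-curve constants (An, Bn)
    come from the population-averaged human EDPVR.
    """

    Vm: float
    Pm: float
    An: float = 27.78     # mmHg
    Bn: float = 2.76

    def __post_init__(self):
        if self.Vm <= 0:
            raise ValueError("Vm must be positive")
        if not (0.0 < self.Pm <= 30.0):
            raise ValueError("Pm must lie in (0, 30] mmHg")

    @property
    def V0(self) -> float:
        return self.Vm * (0.6 - 0.006 * self.Pm)

    @property
    def V30(self) -> float:
        return self.V0 + (self.Vm - self.V0) / (self.Pm / self.An) \
            ** (1.0 / self.Bn)

    def pressure(self, V) -> np.ndarray:
        """P(V) in mmHg; zero at and below V0, monotone increasing."""
        V = np.asarray(V, dtype=float)
        vn = np.clip((V - self.V0) / (self.V30 - self.V0), 0.0, None)
        return self.An * vn ** self.Bn

    __call__ = pressure


def klotz_edpvr(Vm: float, Pm: float, **kw) -> KlotzCurve:
    return KlotzCurve(Vm=Vm, Pm=Pm, **kw)


# ---------------------------------------------------------------------------
# stage 1: shear-mode fit


@dataclass
class ShearDataset:
    """Six-mode simple-shear stress data: mode -> (amounts, stress kPa)."""

    data: dict
    specimen_mm: float = 4.0

    def __post_init__(self):
        for mode, (g, s) in self.data.items():
            if mode not in fem.SHEAR_MODES:
                raise ValueError(f"unknown shear mode {mode!r}")
            g, s = np.asarray(g, float), np.asarray(s, float)
            if len(g) < 3:
                raise ValueError(f"mode {mode}: need >= 3 points")
            if np.any(g < 0) or np.any(np.diff(g) <= 0):
                raise ValueError(f"mode {mode}: amounts must increase")
            self.data[mode] = (g, s)

    @property
    def modes(self):
        return tuple(self.data)

    def to_csv(self, path):
        rows = [(m, a, s) for m, (g, st) in self.data.items()
                for a, s in zip(g, st)]
        pd.DataFrame(rows, columns=["mode", "amount", "stress_kPa"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ShearDataset":
        df = pd.read_csv(path)
        data = {m: (g["amount"].to_numpy(), g["stress_kPa"].to_numpy())
                for m, g in df.groupby("mode", sort=False)}
        return cls(data)


def synthetic_shear_dataset(params: PassiveParams,
                            amounts=(0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
                            noise: float = 0.0,
                            rng=None) -> ShearDataset:
    """Simple-shear data generated from known parameters (all six modes),
    optionally with multiplicative Gaussian noise of relative size
    ``noise`` (seeded via ``rng``)."""
    rng = np.random.default_rng(rng)
    amounts = np.asarray(amounts, dtype=float)
    data = {}
    for mode in fem.SHEAR_MODES:
        s = np.array([fem.analytic_shear_stress(mode, g, params)
                      for g in amounts])
        if noise > 0:
            s = s * (1.0 + noise * rng.standard_normal(len(s)))
        data[mode] = (amounts, s)
    return ShearDataset(data)


def fit_shear_params(data: ShearDataset, init: PassiveParams,
                     forward: str = "analytic",
                     cube_elements_per_side: int = 3) -> tuple:
    """Least-squares fit of the eight HO constants to shear data.

    ``forward``: "analytic" evaluates the homogeneous closed form (fast,
    default for testing); "fe" runs the hex-cube FE experiment (the
    27-element cube by default).  Returns (PassiveParams, diagnostics
    dict).  Under-determined designs (fewer than 3 modes) still fit but
    carry an identifiability warning in the diagnostics.
    """
    modes = data.modes
    under_determined = len(modes) < 3
    if under_determined:
        warnings.warn("shear fit with < 3 modes is under-determined; "
                      "returned parameters may not be unique", UserWarning)
    # relative residuals, weighted per mode so stiff modes do not dominate
    weights = {m: 1.0 / max(np.abs(data.data[m][1]).max(), 1e-6)
               for m in modes}

    def model_stresses(p: PassiveParams):
        out = []
        for m in modes:
            g, _ = data.data[m]
            if forward == "analytic":
                s = np.array([fem.analytic_shear_stress(m, gg, p)
                              for gg in g])
            else:
                _, s = fem.simulate_shear_cube(m, g, p,
                                               n=cube_elements_per_side)
            out.append(s * weights[m])
        return np.concatenate(out)

    target = np.concatenate([data.data[m][1] * weights[m] for m in modes])
    names = ("a", "b", "a_f", "b_f", "a_s", "b_s", "a_fs", "b_fs")
    x0 = np.log([getattr(init, n) for n in names])

    def resid(x):
        vals = dict(zip(names, np.exp(x)))
        p = replace(init, **vals)
        return model_stresses(p) - target

    method = "lm" if len(target) >= len(x0) else "trf"
    sol = optimize.least_squares(resid, x0, method=method, xtol=1e-12,
                                 ftol=1e-12, max_nfev=4000)
    fitted = replace(init, **dict(zip(names, np.exp(sol.x))))
    diagnostics = {
        "residual": float(np.sum(sol.fun ** 2)),
        "n_points": len(target),
        "n_modes": len(modes),
        "under_determined": under_determined,
        "success": bool(sol.success),
        "nfev": int(sol.nfev),
    }
    if not sol.success:
        raise RuntimeError(
            f"shear fit failed: {sol.message}; last residual "
            f"{diagnostics['residual']:.3g}")
    return fitted, diagnostics


# ---------------------------------------------------------------------------
# stage 2: A/B scaling against the Klotz curve


@dataclass(frozen=True)
class ScalingParams:
    A: float
    B: float

    def __post_init__(self):
        if self.A <= 0 or self.B <= 0:
            raise ValueError("A and B must be positive")


def inflation_curve(model: CoupledModel, p_levels, rv_ratio=0.4):
    """Passive LV inflation course: [(P_LV mmHg, V_LV ml), ...].

    The RV is co-inflated at ``rv_ratio`` times the LV pressure so the
    septum carries a physiologic transmural load during the fit.
    """
    from .geometry import cavity_volume
    out = []
    u = None
    prev = None
    for p in p_levels:
        st = fem.solve_static(model.fe, p, rv_ratio * p, u0=u, prev=prev)
        u = st.displacement.ravel()
        prev = fem.heart_loads(p, rv_ratio * p)
        out.append((p, st.volumes["LV"]))
    return out


def _adaptive_course(model: CoupledModel, B: float, V_stop: float,
                     rv_ratio: float, p_start=3.0, growth=1.7,
                     p_cap=600.0):
    """Unscaled-A (A = 1) inflation course for exponent scaling B, run
    until the LV volume passes ``V_stop``.  Returns (P, V) arrays."""
    m2 = model.with_materials(passive=model.passive.scaled(1.0, B))
    P, V = [0.0], [None]
    u = None
    prev = None
    p = p_start
    from .geometry import cavity_volume
    V[0] = cavity_volume(model.mesh, None, "LV")
    while True:
        st = fem.solve_static(m2.fe, p, rv_ratio * p, u0=u, prev=prev)
        u = st.displacement.ravel()
        prev = fem.heart_loads(p, rv_ratio * p)
        P.append(p)
        V.append(st.volumes["LV"])
        if V[-1] >= V_stop or p >= p_cap:
            break
        p *= growth
    return np.asarray(P), np.asarray(V)


def fit_passive_scaling(model: CoupledModel, EDP: float = 23.0,
                        EDV: float = 254.0, rv_ratio: float = 0.4,
                        B_bounds=(0.12, 2.0), target_curve=None,
                        target_V0: float | None = None,
                        target_volumes=None) -> tuple:
    """Stage-2 calibration: find (A, B) so the passive inflation course
    tracks the Klotz EDPVR and reaches EDV at EDP (within 2%).

    Because a uniform scaling of every modulus (including the bulk
    penalty) by A rescales the pressure axis of the passive P-V curve
    exactly, the EDV-at-EDP anchor determines A in closed form from one
    unscaled inflation course per exponent factor B; the fit is therefore
    a 1-D bounded minimization over B of the squared pressure mismatch
    against the Klotz curve at matched volumes.  Returns (ScalingParams,
    diagnostics).

    ``target_curve`` replaces the Klotz pressure function P(V) (used by
    the parameter-recovery tests, where the target is a forward-simulated
    course from known scalings); ``target_V0`` bounds its validity range
    from below.
    """
    klotz = klotz_edpvr(EDV, EDP)
    target = target_curve if target_curve is not None else klotz.pressure
    v_lo = target_V0 if target_V0 is not None else klotz.V0
    cache = {}

    def eval_B(B):
        key = round(float(B), 8)
        if key in cache:
            return cache[key]
        P1, V1 = _adaptive_course(model, B, EDV * 1.001, rv_ratio)
        if V1[-1] < EDV:
            cache[key] = (np.inf, np.nan, (P1, V1))
            return cache[key]
        # closed-form scalar multiplier from the anchor
        # interpolate the exponential-like course in log-pressure, which
        # is near-linear in volume, to avoid chord bias
        logP = np.log(P1[1:])
        p_at_edv = float(np.exp(np.interp(EDV, V1[1:], logP)))
        A = EDP / p_at_edv
        if target_volumes is not None:
            # evaluate at the target's own sample volumes (exact there)
            vt = np.asarray(target_volumes, dtype=float)
            vt = vt[(vt > v_lo) & (vt >= V1[1]) & (vt <= EDV * 1.001)]
            pc = np.exp(np.interp(vt, V1[1:], logP))
            tgt = np.asarray(target(vt), dtype=float)
        else:
            mask = (V1 > v_lo) & (V1 <= EDV * 1.001) & (P1 > 0)
            pc = P1[mask]
            tgt = np.asarray(target(V1[mask]), dtype=float)
        ok = tgt > 1e-9
        # relative pressure error at matched volumes: balances the toe
        # (where the exponent B is identified) against the high-pressure
        # limb (which the anchor already pins through A)
        err = (A * pc[ok] - tgt[ok]) / tgt[ok]
        obj = float(np.mean(err ** 2))
        cache[key] = (obj, A, (A * P1, V1))
        return cache[key]

    sol = optimize.minimize_scalar(
        lambda B: eval_B(B)[0], bounds=B_bounds, method="bounded",
        options={"xatol": 8e-3, "maxiter": 18})
    B = float(sol.x)
    obj, A, course = eval_B(B)
    if not np.isfinite(obj):
        raise RuntimeError(
            f"stage-2 calibration infeasible: inflation at B={B:.3f} "
            f"never reached EDV={EDV} ml")
    # verification solve at the anchored pressure with the scaled params
    m2 = model.with_materials(passive=model.passive.scaled(A, B))
    pv = inflation_curve(m2, EDP * np.linspace(0.25, 1.0, 4), rv_ratio)
    v_edp = pv[-1][1]
    diagnostics = {
        "objective": obj, "V_at_EDP": float(v_edp), "EDV_target": EDV,
        "rel_error": float(abs(v_edp - EDV) / EDV),
        "n_course_evals": len(cache), "course": course,
    }
    if abs(v_edp - EDV) / EDV > 0.02:
        raise RuntimeError(
            f"stage-2 calibration missed the EDV target: V(EDP)={v_edp:.1f}"
            f" vs {EDV} ml; diagnostics: {diagnostics}")
    return ScalingParams(A=A, B=B), diagnostics


# ---------------------------------------------------------------------------
# active calibration: TMAX to stroke volume


def _beat_metrics(model: CoupledModel, n_cycles=2, dt=0.01):
    res = run_simulation(model, rpm="off", n_cycles=n_cycles, dt=dt)
    cyc = res.last_cycle()
    v = cyc["V_LV"].to_numpy()
    return {"EDV": float(v.max()), "ESV": float(v.min()),
            "SV": float(v.max() - v.min()), "result": res}


def fit_tmax(model: CoupledModel, target_SV: float,
             bounds=(0.0, 400.0), tol_ml: float | None = None,
             n_cycles: int = 2, dt: float = 0.01,
             max_evals: int = 8) -> tuple:
    """Find TMAX (kPa) so the unsupported coupled beat's stroke volume
    matches ``target_SV`` (within 2% by default).  Secant iteration on
    the monotone SV(TMAX) relation.  Returns (tmax, diagnostics)."""
    if target_SV <= 0:
        return 0.0, {"evals": 0, "SV": 0.0, "note": "no ejection requested"}
    tol_ml = tol_ml if tol_ml is not None else 0.015 * target_SV

    evals = []

    def sv_of(tmax):
        m2 = model.with_materials(active=replace(model.active, tmax=tmax))
        met = _beat_metrics(m2, n_cycles=n_cycles, dt=dt)
        evals.append((tmax, met["SV"], met["EDV"], met["ESV"]))
        log.info("TMAX=%.1f kPa -> SV=%.2f ml (EDV %.1f, ESV %.1f)",
                 tmax, met["SV"], met["EDV"], met["ESV"])
        return met["SV"]

    t0 = model.active.tmax if model.active.tmax > 0 else 170.0
    t0 = min(max(t0, bounds[0] + 1.0), bounds[1])
    s0 = sv_of(t0)
    if abs(s0 - target_SV) <= tol_ml:
        return t0, {"evals": evals, "SV": s0}
    t1 = t0 * (1.25 if s0 < target_SV else 0.8)
    s1 = sv_of(t1)
    for _ in range(max_evals - 2):
        if abs(s1 - target_SV) <= tol_ml:
            return t1, {"evals": evals, "SV": s1}
        if s1 == s0:
            break
        t2 = t1 + (target_SV - s1) * (t1 - t0) / (s1 - s0)
        t2 = min(max(t2, bounds[0]), bounds[1])
        t0, s0, t1 = t1, s1, t2
        s1 = sv_of(t1)
    if abs(s1 - target_SV) <= tol_ml:
        return t1, {"evals": evals, "SV": s1}
    raise RuntimeError(
        f"TMAX fit did not reach SV={target_SV} ml within bounds {bounds}; "
        f"trace: {evals}")


# ---------------------------------------------------------------------------
# study setup: preload anchoring


def calibrate_study(model: CoupledModel, EDP: float = 23.0,
                    EDV: float = 254.0, ESV: float = 224.0,
                    n_cycles: int = 2, dt: float = 0.02,
                    max_evals: int = 8, rv_ratio: float = 0.4) -> dict:
    """Full study setup: stage-2 passive scaling, then a joint fit of the
    preload factor (initial compartment pressures) and TMAX so the
    unsupported beat reaches the target EDV and stroke volume EDV - ESV.

    The joint loop shares one coupled simulation per iterate between both
    scalar secant updates (diagonal quasi-Newton), which roughly halves
    the number of beat simulations compared to nesting the two fits.
    Returns a dict with the calibrated model and diagnostics.
    """
    scaling, d2 = fit_passive_scaling(model, EDP=EDP, EDV=EDV,
                                      rv_ratio=rv_ratio)
    mcal = model.with_materials(passive=model.passive.scaled(scaling.A,
                                                             scaling.B))
    target_SV = EDV - ESV
    tol_edv, tol_sv = 0.01 * EDV, 0.015 * target_SV

    f, tmax = 1.0, mcal.active.tmax
    # slope priors, refined by secant updates as evaluations accumulate
    dedv_df, dsv_dtmax = 180.0, 0.30
    hist = []

    def run(f_, tmax_):
        par = replace(mcal.circuit,
                      P_SA_init=mcal.circuit.P_SA_init * f_,
                      P_SV_init=mcal.circuit.P_SV_init * f_,
                      P_PA_init=mcal.circuit.P_PA_init * f_,
                      P_PV_init=mcal.circuit.P_PV_init * f_)
        m2 = mcal.with_materials(active=replace(mcal.active, tmax=tmax_))
        m2.circuit = par
        met = _beat_metrics(m2, n_cycles=n_cycles, dt=dt)
        hist.append((f_, tmax_, met["EDV"], met["SV"]))
        log.info("joint fit: f=%.3f TMAX=%.1f -> EDV=%.1f SV=%.2f",
                 f_, tmax_, met["EDV"], met["SV"])
        return m2, met

    def converged(met):
        return abs(met["EDV"] - EDV) <= tol_edv \
            and abs(met["SV"] - target_SV) <= tol_sv

    m2, met = run(f, tmax)
    for _ in range(max_evals - 1):
        if converged(met):
            break
        e_edv = met["EDV"] - EDV
        e_sv = met["SV"] - target_SV
        if len(hist) >= 2:
            (f0, t0, edv0, sv0), (f1, t1, edv1, sv1) = hist[-2], hist[-1]
            if abs(f1 - f0) > 1e-4 and abs(edv1 - edv0) > 1e-3:
                dedv_df = np.clip((edv1 - edv0) / (f1 - f0), 40.0, 900.0)
            if abs(t1 - t0) > 1e-3 and abs(sv1 - sv0) > 1e-4:
                dsv_dtmax = np.clip((sv1 - sv0) / (t1 - t0), 0.03, 3.0)
        f = float(np.clip(f - e_edv / dedv_df, 0.4, 2.5))
        tmax = float(np.clip(tmax - e_sv / dsv_dtmax, 20.0, 400.0))
        m2, met = run(f, tmax)
    if not converged(met):
        raise RuntimeError(
            f"study calibration did not converge; history: {hist}")

    return {"model": m2, "scaling": scaling, "stage2": d2,
            "preload_factor": f, "tmax": tmax, "metrics": met,
            "history": hist, "result": met.pop("result")}


def tune_preload(model: CoupledModel, target_EDV: float = 254.0,
                 tol_ml: float = 2.5, max_evals: int = 5,
                 n_cycles: int = 2, dt: float = 0.01) -> tuple:
    """Scale the circulation's initial compartment pressures so the
    unsupported periodic beat reaches the target LV EDV.

    Returns (CircuitParams, diagnostics).  This anchors the model at the
    study's stated end-diastolic state; it substitutes for an explicit
    total-blood-volume prescription.
    """
    evals = []

    def edv_of(f):
        par = replace(model.circuit,
                      P_SA_init=model.circuit.P_SA_init * f,
                      P_SV_init=model.circuit.P_SV_init * f,
                      P_PA_init=model.circuit.P_PA_init * f,
                      P_PV_init=model.circuit.P_PV_init * f)
        m2 = CoupledModel(mesh=model.mesh, fibers=model.fibers, fe=model.fe,
                          passive=model.passive, active=model.active,
                          circuit=par, curves=model.curves)
        met = _beat_metrics(m2, n_cycles=n_cycles, dt=dt)
        evals.append((f, met["EDV"]))
        log.info("preload factor %.3f -> EDV %.1f ml", f, met["EDV"])
        return met["EDV"], par

    f0, f1 = 1.0, None
    e0, par0 = edv_of(f0)
    if abs(e0 - target_EDV) <= tol_ml:
        return par0, {"evals": evals}
    f1 = f0 * (1.15 if e0 < target_EDV else 0.87)
    e1, par1 = edv_of(f1)
    for _ in range(max_evals - 2):
        if abs(e1 - target_EDV) <= tol_ml:
            return par1, {"evals": evals}
        if e1 == e0:
            break
        f2 = f1 + (target_EDV - e1) * (f1 - f0) / (e1 - e0)
        f2 = min(max(f2, 0.3), 3.0)
        f0, e0, f1 = f1, e1, f2
        e1, par1 = edv_of(f1)
    if abs(e1 - target_EDV) <= tol_ml:
        return par1, {"evals": evals}
    raise RuntimeError(f"preload tuning failed; trace {evals}")
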