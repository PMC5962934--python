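"""Closed-loop lumped-parameter circulation with an LVAD.

Topology: two FE ventricular cavities exchange blood with four Windkessel
compliances (systemic arterial/venous, pulmonary arterial/venous) through
ideal-diode valve resistances (mitral, aortic, tricuspid, pulmonary) and
two vascular resistances; an optional continuous-flow pump draws blood
from the LV cavity into the systemic arterial compliance according to a
per-speed tabulated pressure-head/flow characteristic.

Units at this interface: pressures mmHg, volumes ml, flows ml/s,
resistances mmHg.s/ml, compliances ml/mmHg.  Pump tables are stored in
L/min (the unit the device literature uses) and converted at the flow
evaluation.

The time integrator is backward Euler on the four compliance volumes with
the chamber pressures held at their (outer-loop) iterates, which makes
the update unconditionally stable at multi-millisecond steps and conserves
total blood volume to round-off by construction.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

L_MIN_TO_ML_S = 1000.0 / 60.0

RPM_LABELS = ("8k", "9k", "10k", "11k", "12k")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CircuitParams:
    """Lumped circulation constants.

    Defaults are representative of end-stage dilated heart failure
    (low output, high filling pressures, raised systemic resistance);
    they are not taken from any published table.
    """

    R_M: float = 0.06       # mitral valve
    R_A: float = 0.05       # aortic valve
    R_T: float = 0.05       # tricuspid valve
    R_P: float = 0.04       # pulmonary valve
    R_SYS: float = 1.65     # systemic vascular
    R_PUL: float = 0.17     # pulmonary vascular
    C_SA: float = 1.0
    C_SV: float = 50.0
    C_PA: float = 2.5
    C_PV: float = 6.0
    V0_SA: float = 0.0      # unstressed volumes
    V0_SV: float = 0.0
    V0_PA: float = 0.0
    V0_PV: float = 0.0
    T_cycle: float = 1.0    # heart period, s (60 bpm)
    # start-of-simulation compliance pressures (mmHg)
    P_SA_init: float = 72.0
    P_SV_init: float = 21.0
    P_PA_init: float = 46.0
    P_PV_init: float = 40.0

    def __post_init__(self):
        for nm in ("R_M", "R_A", "R_T", "R_P", "R_SYS", "R_PUL",
                   "C_SA", "C_SV", "C_PA", "C_PV", "T_cycle"):
            if getattr(self, nm) <= 0:
                raise ConfigError(f"{nm} must be positive")


@dataclass
class CircuitState:
    """Volumes of the four compliances and the two ventricular cavities,
    with derived pressures and the flows of the step that produced it."""

    V_SA: float
    V_SV: float
    V_PA: float
    V_PV: float
    V_LV: float
    V_RV: float
    flows: dict = field(default_factory=dict)

    def pressures(self, par: CircuitParams):
        return {
            "P_SA": (self.V_SA - par.V0_SA) / par.C_SA,
            "P_SV": (self.V_SV - par.V0_SV) / par.C_SV,
            "P_PA": (self.V_PA - par.V0_PA) / par.C_PA,
            "P_PV": (self.V_PV - par.V0_PV) / par.C_PV,
        }

    @property
    def total_volume(self):
        return self.V_SA + self.V_SV + self.V_PA + self.V_PV \
            + self.V_LV + self.V_RV

    @classmethod
    def from_pressures(cls, par: CircuitParams, V_LV, V_RV):
        return cls(V_SA=par.V0_SA + par.P_SA_init * par.C_SA,
                   V_SV=par.V0_SV + par.P_SV_init * par.C_SV,
                   V_PA=par.V0_PA + par.P_PA_init * par.C_PA,
                   V_PV=par.V0_PV + par.P_PV_init * par.C_PV,
                   V_LV=V_LV, V_RV=V_RV)


# ---------------------------------------------------------------------------
# valves and pump


def valve_flow(dP, R):
    """Ideal diode: Q = max(dP, 0)/R (ml/s)."""
    if R <= 0:
        raise ConfigError("valve resistance must be positive")
    return np.maximum(np.asarray(dP, dtype=float), 0.0) / R


@dataclass
class LVADCurveSet:
    """Per-speed pump characteristics: flow (L/min) vs pressure head
    dP = P_out - P_in (mmHg) on a uniform grid, 0..200 by 2."""

    tables: dict  # label -> (dp_grid mmHg, flow L/min)

    def __post_init__(self):
        for label, (dp, q) in self.tables.items():
            dp, q = np.asarray(dp, float), np.asarray(q, float)
            if len(dp) != len(q) or len(dp) < 2:
                raise ConfigError(f"curve {label}: malformed table")
            step = np.diff(dp)
            if not np.allclose(step, step[0]):
                raise ConfigError(f"curve {label}: dP grid not uniform")
            if np.any(np.diff(q) > 1e-12):
                raise ConfigError(f"curve {label}: flow must be "
                                  "non-increasing in dP")
            self.tables[label] = (dp, q)

    @property
    def rpms(self):
        return tuple(self.tables)

    def flow(self, dP, rpm) -> float:
        """Pump flow in ml/s with linear interpolation and linear
        extrapolation using the terminal segment slopes."""
        if rpm not in self.tables:
            raise ConfigError(
                f"unknown pump speed {rpm!r}; available: {self.rpms}")
        dp_grid, q = self.tables[rpm]
        dP = float(dP)
        if dP < dp_grid[0]:
            s = (q[1] - q[0]) / (dp_grid[1] - dp_grid[0])
            q_lmin = q[0] + s * (dP - dp_grid[0])
        elif dP > dp_grid[-1]:
            s = (q[-1] - q[-2]) / (dp_grid[-1] - dp_grid[-2])
            q_lmin = q[-1] + s * (dP - dp_grid[-1])
        else:
            q_lmin = float(np.interp(dP, dp_grid, q))
        return q_lmin * L_MIN_TO_ML_S

    def to_csv(self, path):
        rows = [(rpm, d, f) for rpm, (dp, q) in self.tables.items()
                for d, f in zip(dp, q)]
        pd.DataFrame(rows, columns=["rpm", "dP_mmHg", "flow_L_min"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "LVADCurveSet":
        df = pd.read_csv(path_or_buf)
        need = {"rpm", "dP_mmHg", "flow_L_min"}
        if not need.issubset(df.columns):
            raise ConfigError(
                f"pump curve CSV must have columns {sorted(need)}")
        tables = {}
        for rpm, grp in df.groupby("rpm", sort=False):
            grp = grp.sort_values("dP_mmHg")
            tables[str(rpm)] = (grp["dP_mmHg"].to_numpy(float),
                                grp["flow_L_min"].to_numpy(float))
        return cls(tables)


def synthetic_lvad_curves(rpm_labels=RPM_LABELS, dp_max=200.0,
                          dp_step=2.0) -> LVADCurveSet:
    """Synthetic continuous-flow pump map with the familiar axial-pump
    shape: monotone-decreasing flow vs head, uniformly higher curves at
    higher speed, shut-off head growing with speed squared."""
    tables = {}
    for label in rpm_labels:
        rpm_k = float(str(label).rstrip("k"))
        q0 = 0.65 * rpm_k                # zero-head flow, L/min
        h0 = 2.0 * rpm_k ** 2            # shut-off head, mmHg
        dp = np.arange(0.0, dp_max + dp_step / 2, dp_step)
        q = np.maximum(q0 * (1.0 - (dp / h0) ** 1.2), 0.0)
        tables[label] = (dp, q)
    return LVADCurveSet(tables)


def lvad_flow(dP, rpm, curves: LVADCurveSet):
    """Module-level convenience wrapper (ml/s)."""
    return curves.flow(dP, rpm)


# ---------------------------------------------------------------------------
# circuit time step


def circuit_flows(state_vols, P_LV, P_RV, par: CircuitParams,
                  rpm=None, curves: LVADCurveSet | None = None):
    V_SA, V_SV, V_PA, V_PV = state_vols
    P_SA = (V_SA - par.V0_SA) / par.C_SA
    P_SV = (V_SV - par.V0_SV) / par.C_SV
    P_PA = (V_PA - par.V0_PA) / par.C_PA
    P_PV = (V_PV - par.V0_PV) / par.C_PV
    Q = {
        "Q_M": float(valve_flow(P_PV - P_LV, par.R_M)),
        "Q_A": float(valve_flow(P_LV - P_SA, par.R_A)),
        "Q_SYS": (P_SA - P_SV) / par.R_SYS,
        "Q_T": float(valve_flow(P_SV - P_RV, par.R_T)),
        "Q_P": float(valve_flow(P_RV - P_PA, par.R_P)),
        "Q_PUL": (P_PA - P_PV) / par.R_PUL,
        "Q_LVAD": curves.flow(P_SA - P_LV, rpm)
        if (rpm is not None and rpm != "off") else 0.0,
    }
    return Q


def circuit_step(state: CircuitState, P_LV, P_RV, par: CircuitParams,
                 dt, rpm=None, curves: LVADCurveSet | None = None,
                 _floor_eps=1e-9) -> CircuitState:
    """Backward-Euler update of the circulation over one step.

    Chamber pressures are inputs (the FE side owns the chamber volumes);
    the four compliance volumes are solved implicitly.  Total volume is
    conserved exactly.  A compliance drained below its unstressed volume
    floors at a tiny positive margin with a warning (physiologic
    collapse).
    """
    if dt <= 0:
        raise ConfigError("dt must be positive")
    x0 = np.array([state.V_SA, state.V_SV, state.V_PA, state.V_PV])

    def residual(x):
        Q = circuit_flows(x, P_LV, P_RV, par, rpm, curves)
        return np.array([
            x[0] - x0[0] - dt * (Q["Q_A"] + Q["Q_LVAD"] - Q["Q_SYS"]),
            x[1] - x0[1] - dt * (Q["Q_SYS"] - Q["Q_T"]),
            x[2] - x0[2] - dt * (Q["Q_P"] - Q["Q_PUL"]),
            x[3] - x0[3] - dt * (Q["Q_PUL"] - Q["Q_M"]),
        ]), Q

    x = x0.copy()
    for _ in range(30):
        r, Q = residual(x)
        if np.max(np.abs(r)) < 1e-11 * max(1.0, np.abs(x0).max()):
            break
        J = np.empty((4, 4))
        h = 1e-6 * max(1.0, np.abs(x).max())
        for k in range(4):
            xp = x.copy()
            xp[k] += h
            J[:, k] = (residual(xp)[0] - r) / h
        x = x - np.linalg.solve(J, r)
    r, Q = residual(x)

    floors = np.array([par.V0_SA, par.V0_SV, par.V0_PA, par.V0_PV])
    if np.any(x < floors + _floor_eps):
        warnings.warn("compliance volume at collapse floor", RuntimeWarning)
        x = np.maximum(x, floors + _floor_eps)

    dV_LV = dt * (Q["Q_M"] - Q["Q_A"] - Q["Q_LVAD"])
    dV_RV = dt * (Q["Q_T"] - Q["Q_P"])
    return CircuitState(V_SA=x[0], V_SV=x[1], V_PA=x[2], V_PV=x[3],
                        V_LV=state.V_LV + dV_LV, V_RV=state.V_RV + dV_RV,
                        flows=Q)
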