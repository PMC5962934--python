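"""Output metrics: PV loops, ED/ES detection, functional table, septal
shift, regional myofiber stress statistics and stress histograms.

Sign convention for septal shift: positive when the basal septal midpoint
bulges toward the LV cavity relative to the line through the anterior and
posterior ventricular junction points, zero when the septum is straight,
negative toward the RV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Mesh, REGION_IDS
from .simulator import SimulationResult

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ED / ES detection


def detect_ed_es(volume, pressure, dvdt_frac=0.04):
    """Indices of end diastole and end systole on one cycle of (V, P).

    ED is the last sample before the isovolumic-contraction segment (the
    |dV/dt| plateau at rising pressure); ES the last sample before
    isovolumic relaxation.  With a continuous-flow pump the isovolumic
    phases vanish; the detector then falls back to the volume extrema
    (maximum -> ED, minimum -> ES) and logs that it did so.

    Returns (i_ed, i_es).
    """
    V = np.asarray(volume, dtype=float)
    P = np.asarray(pressure, dtype=float)
    if len(V) < 8 or len(V) != len(P):
        raise ValueError("need at least one full cycle of matched V, P")
    dV = np.gradient(V)
    thresh = dvdt_frac * np.max(np.abs(dV))
    iso = np.abs(dV) < thresh

    # contiguous flat-volume runs of meaningful duration; an isolated
    # near-zero dV sample (a volume extremum of a smooth trace) does not
    # constitute an isovolumic phase
    min_run = 3
    runs = []
    k = 0
    n = len(V)
    while k < n:
        if iso[k]:
            j = k
            while j < n and iso[j]:
                j += 1
            if j - k >= min_run:
                runs.append((k, j))
            k = j
        else:
            k += 1

    i_ed = i_es = None
    rising = [(a, b) for a, b in runs if P[b - 1] > P[a]]
    falling = [(a, b) for a, b in runs if P[b - 1] < P[a]]
    if rising:
        # IVC: the flat run with the largest pressure rise
        a, b = max(rising, key=lambda r: P[r[1] - 1] - P[r[0]])
        i_ed = max(a - 1, 0)
    if falling:
        a, b = max(falling, key=lambda r: P[r[0]] - P[r[1] - 1])
        i_es = max(a - 1, 0)
    if i_ed is None or i_es is None:
        log.info("no isovolumic phase found (continuous pump flow?); "
                 "falling back to volume extrema for ED/ES")
        i_ed = int(np.argmax(V))
        i_es = int(np.argmin(V))
    return i_ed, i_es


# ---------------------------------------------------------------------------
# functional metrics (Table-2 style)


@dataclass
class FunctionalMetrics:
    rpm: str
    LV_EDV: float
    LV_ESV: float
    RV_EDV: float
    RV_ESV: float
    LV_EF: float          # percent
    RV_EF: float
    CO: float             # L/min, mean systemic flow
    PCWP_proxy: float     # cycle-mean pulmonary venous pressure, mmHg
    CVP_proxy: float      # cycle-mean systemic venous pressure, mmHg

    def __post_init__(self):
        for name in ("LV_EF", "RV_EF"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 100 + 1e-9):
                raise ValueError(f"{name} out of [0, 100]: {v}")

    def as_dict(self):
        return dict(self.__dict__)


def ejection_fraction(edv, esv) -> float:
    """EF = (1 - ESV/EDV) * 100, in percent."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    return (1.0 - esv / edv) * 100.0


def functional_metrics(result: SimulationResult) -> FunctionalMetrics:
    """Table-2-style metrics from the last cycle of a simulation."""
    cyc = result.last_cycle()
    if result.periodicity is not np.nan and \
            result.periodicity > 0.01 * cyc["V_LV"].max():
        log.warning("last beat not periodic (EDV drift %.2f ml)",
                    result.periodicity)
    out = {}
    for ch in ("LV", "RV"):
        i_ed, i_es = detect_ed_es(cyc[f"V_{ch}"].to_numpy(),
                                  cyc[f"P_{ch}"].to_numpy())
        out[f"{ch}_EDV"] = float(cyc[f"V_{ch}"].iloc[i_ed])
        out[f"{ch}_ESV"] = float(cyc[f"V_{ch}"].iloc[i_es])
        out[f"{ch}_EF"] = ejection_fraction(out[f"{ch}_EDV"],
                                            out[f"{ch}_ESV"])
    co = cyc["Q_SYS"].mean() * 60.0 / 1000.0  # ml/s -> L/min
    return FunctionalMetrics(
        rpm=result.rpm, CO=float(co),
        PCWP_proxy=float(cyc["P_PV"].mean()),
        CVP_proxy=float(cyc["P_SV"].mean()), **out)


def metrics_table(results: dict) -> pd.DataFrame:
    """Functional metrics for a {rpm: SimulationResult} sweep."""
    return pd.DataFrame([functional_metrics(r).as_dict()
                         for r in results.values()])


def isovolumic_duration(cycle: pd.DataFrame, chamber: str = "LV",
                        thresh_ml_s: float = 10.0,
                        min_dpdt_mmhg_s: float = 100.0) -> float:
    """Longest contiguous interval (s) of near-constant chamber volume
    during the rapid systolic pressure rise — the isovolumic-contraction
    duration.

    With a continuous-flow pump the LV drains throughout pressure rise,
    so this collapses toward zero as pump speed increases.  The flow
    threshold (default 10 ml/s) sits above the coupling-tolerance noise
    floor of the volume traces; the pressure-rate floor (default
    100 mmHg/s) distinguishes the isovolumic upstroke (~1000 mmHg/s)
    from slow diastolic pressure creep.
    """
    t = cycle["t"].to_numpy()
    V = cycle[f"V_{chamber}"].to_numpy()
    P = cycle[f"P_{chamber}"].to_numpy()
    if len(t) < 3:
        raise ValueError("need at least one cycle")
    dt = np.diff(t)
    dvdt = np.abs(np.diff(V)) / dt
    rising = np.diff(P) / dt > min_dpdt_mmhg_s
    flat = (dvdt < thresh_ml_s) & rising
    best = cur = 0.0
    for ok, h in zip(flat, dt):
        cur = cur + h if ok else 0.0
        best = max(best, cur)
    return float(best)


# ---------------------------------------------------------------------------
# septal shift


def septal_shift(mesh: Mesh, displacement) -> float:
    """Signed basal septal-midpoint shift (mm) in the base plane.

    Perpendicular distance of the deformed septal midpoint marker from
    the deformed anterior-posterior junction line, positive toward the LV
    cavity centroid.
    """
    for k in ("septum_mid", "junction_ant", "junction_post"):
        if k not in mesh.markers:
            raise ValueError(f"mesh is missing marker {k!r}")
    disp = np.asarray(displacement)
    x = mesh.nodes + disp
    a = x[mesh.markers["junction_ant"]][:2]
    b = x[mesh.markers["junction_post"]][:2]
    m = x[mesh.markers["septum_mid"]][:2]
    # LV centroid in the base plane: mean of the deformed annulus ring
    c = x[mesh.annulus_nodes][:, :2].mean(axis=0)
    t = b - a
    nt = np.linalg.norm(t)
    if nt < 1e-12:
        raise ValueError("degenerate junction line")
    n = np.array([-t[1], t[0]]) / nt          # unit normal to the line
    if np.dot(c - a, n) < 0:
        n = -n                                 # orient toward the LV side
    return float(np.dot(m - a, n))


def septal_shift_trace(result: SimulationResult) -> pd.DataFrame:
    """Septal shift (mm) vs time for every stored snapshot."""
    vals = [septal_shift(result.mesh, u) for u in result.snapshots]
    base = septal_shift(result.mesh, np.zeros_like(result.snapshots[0]))
    return pd.DataFrame({"t": result.snapshot_times,
                         "shift_mm": np.asarray(vals) - base})


# ---------------------------------------------------------------------------
# regional stress statistics


def regional_stress_stats(stresses, volumes, region_mask):
    """Volume-weighted mean and SD of element stress over a region."""
    w = np.asarray(volumes, dtype=float)[region_mask]
    s = np.asarray(stresses, dtype=float)[region_mask]
    if len(s) == 0:
        raise ValueError("empty region")
    wt = w.sum()
    mean = float((s * w).sum() / wt)
    var = float((w * (s - mean) ** 2).sum() / wt)
    return mean, float(np.sqrt(var))


def stress_table(result: SimulationResult) -> pd.DataFrame:
    """Regional volumetric-averaged myofiber stress (mean +/- SD, kPa) at
    end diastole and end systole of the last cycle."""
    cyc = result.last_cycle()
    i_ed, i_es = detect_ed_es(cyc["V_LV"].to_numpy(),
                              cyc["P_LV"].to_numpy())
    # snapshot index offset of the last cycle within the full series
    off = len(result.series) - len(cyc)
    rows = []
    for label, idx in (("ED", off + i_ed), ("ES", off + i_es)):
        vols = result.mesh.element_volumes(result.snapshots[idx])
        stress = result.myofiber_stress[idx]
        for region, rid in REGION_IDS.items():
            mask = result.mesh.element_region == rid
            mean, sd = regional_stress_stats(stress, vols, mask)
            rows.append({"rpm": result.rpm, "time": label, "region": region,
                         "mean_kPa": mean, "sd_kPa": sd})
    return pd.DataFrame(rows)


def stress_histogram(stresses, volumes, bins=20):
    """Volume-weighted probability-density histogram of element stress.

    Returns (bin_edges, density); sum(density * bin_width) == 1.
    """
    w = np.asarray(volumes, dtype=float)
    s = np.asarray(stresses, dtype=float)
    if len(s) == 0 or w.sum() <= 0:
        raise ValueError("need elements with positive total volume")
    density, edges = np.histogram(s, bins=bins, weights=w, density=True)
    return edges, density
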