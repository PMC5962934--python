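import dataclasses

import numpy as np
import pytest

from bivent.fibers import assign_fiber_sheet
from bivent.geometry import GeometryConfig, build_idealized_biventricular


@pytest.fixture(scope="session")
def default_mesh():
    return build_idealized_biventricular(GeometryConfig())


@pytest.fixture(scope="session")
def fast_geometry():
    # reduced resolution used by the slower coupled tests
    return GeometryConfig(n_circ=8, n_long=3, n_trans=2, n_trans_rv=2)


@pytest.fixture(scope="session")
def fast_mesh(fast_geometry):
    return build_idealized_biventricular(fast_geometry)


@pytest.fixture(scope="session")
def fast_fibers(fast_mesh):
    return assign_fiber_sheet(fast_mesh)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


# --- shared coupled-simulation artifacts (computed once per session) -------


@pytest.fixture(scope="session")
def fast_model(fast_geometry):
    from bivent.simulator import CoupledModel
    return CoupledModel.build(geometry=fast_geometry)


@pytest.fixture(scope="session")
def fast_run(fast_model):
    """Unsupported three-cycle beat shared by conservation/loop tests."""
    from bivent.simulator import run_simulation
    return run_simulation(fast_model, rpm="off", n_cycles=3, dt=0.02)


@pytest.fixture(scope="session")
def calibrated_fast(fast_model):
    """Full study calibration (stage 2 + preload/TMAX) at fast scale."""
    from bivent.calibration import calibrate_study
    return calibrate_study(fast_model)


@pytest.fixture(scope="session")
def fast_sweep(calibrated_fast):
    """Pump-speed sweep of the calibrated fast model."""
    from bivent.simulator import run_simulation
    model = calibrated_fast["model"]
    return {rpm: run_simulation(model, rpm=rpm, n_cycles=2, dt=0.02)
            for rpm in ("off", "8k", "9k", "10k", "11k", "12k")}


@pytest.fixture(scope="session")
def stage2_recovery(fast_geometry):
    """(A, B) recovery against a course generated from known scalings."""
    from bivent.calibration import fit_passive_scaling, inflation_curve
    from bivent.simulator import CoupledModel
    A_true, B_true = 2.0, 1.2
    model = CoupledModel.build(geometry=fast_geometry)
    truth = model.with_materials(
        passive=model.passive.scaled(A_true, B_true))
    p_levels = np.array([1.5, 3.0, 6.0, 10.0, 15.0, 20.0, 23.0])
    pv = inflation_curve(truth, p_levels, rv_ratio=0.4)
    P_t = np.array([p for p, _ in pv])
    V_t = np.array([v for _, v in pv])

    def target_curve(v):
        return np.interp(v, V_t, P_t)

    scaling, diag = fit_passive_scaling(
        model, EDP=23.0, EDV=float(V_t[-1]), target_curve=target_curve,
        target_V0=float(V_t[0]) - 1.0, target_volumes=V_t,
        B_bounds=(0.5, 2.0))
    return {"A_true": A_true, "B_true": B_true, "scaling": scaling,
            "diag": diag}


@pytest.fixture(scope="session")
def tmax_recovery(fast_model):
    """TMAX round-trip: simulate at 170 kPa, refit to the recorded SV."""
    from bivent.calibration import _beat_metrics, fit_tmax
    met = _beat_metrics(fast_model, n_cycles=2, dt=0.02)
    start = fast_model.with_materials(
        active=dataclasses.replace(fast_model.active, tmax=120.0))
    tmax_fit, diag = fit_tmax(start, target_SV=met["SV"], dt=0.02)
    return {"tmax_true": fast_model.active.tmax, "tmax_fit": tmax_fit,
            "sv_true": met["SV"], "diag": diag}
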