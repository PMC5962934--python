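"""One coupled heartbeat, unsupported and with the pump at 10k RPM.

Uses the reduced-resolution mesh with factory material/circuit defaults
(uncalibrated), so the absolute volumes differ from the calibrated study
values; the point is the coupled dynamics.  Runs a few minutes.
"""

from bivent.geometry import GeometryConfig
from bivent.metrics import functional_metrics, isovolumic_duration
from bivent.simulator import CoupledModel, run_simulation

model = CoupledModel.build(geometry=GeometryConfig(n_circ=8, n_long=3))

for rpm in ("off", "10k"):
    res = run_simulation(model, rpm=rpm, n_cycles=2, dt=0.02)
    fm = functional_metrics(res)
    iso = isovolumic_duration(res.last_cycle())
    print(f"rpm {rpm}: LV EDV {fm.LV_EDV:.1f} ml, ESV {fm.LV_ESV:.1f} ml,"
          f" EF {fm.LV_EF:.1f}%, CO {fm.CO:.2f} L/min,"
          f" PCWP~{fm.PCWP_proxy:.1f} CVP~{fm.CVP_proxy:.1f} mmHg,"
          f" isovolumic phase {iso*1000:.0f} ms")
print("\nWith the pump on, the LV is drained continuously: EDV falls, "
      "EF rises, and the isovolumic plateau of the PV loop disappears "
      "(the loop becomes triangular).")
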