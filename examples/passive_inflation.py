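"""Passive LV inflation against the Klotz single-beat EDPVR.

Inflates the (reduced-resolution) biventricular model quasi-statically
and compares the resulting pressure-volume course with the analytic
end-diastolic pressure-volume relation anchored at (254 ml, 23 mmHg).
Runs in about a minute.
"""

import numpy as np

from bivent import klotz_edpvr
from bivent.calibration import inflation_curve
from bivent.geometry import GeometryConfig
from bivent.simulator import CoupledModel

model = CoupledModel.build(geometry=GeometryConfig(n_circ=8, n_long=3))
klotz = klotz_edpvr(254.0, 23.0)
print(f"Klotz curve: V0 = {klotz.V0:.1f} ml (zero-pressure volume), "
      f"V30 = {klotz.V30:.1f} ml")

levels = np.array([2.0, 5.0, 9.0, 14.0, 19.0, 23.0])
pv = inflation_curve(model, levels)
print("\n  P (mmHg)   V_FE (ml)   P_Klotz(V) (mmHg)")
for p, v in pv:
    print(f"  {p:7.1f}   {v:8.1f}   {float(klotz.pressure(v)):8.1f}")
print("\nBefore stage-2 scaling the FE wall is too stiff to reach "
      "254 ml at 23 mmHg; fit_passive_scaling finds the (A, B) "
      "multipliers that close this gap (see the calibration example).")
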