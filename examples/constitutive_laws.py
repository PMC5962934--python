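"""Evaluate the passive and active myocardium laws at material points.

Passive: orthotropic exponential (Holzapfel-Ogden) response — the six
simple-shear modes have distinct stiffness because fibers, sheets and
their coupling each carry their own exponential term.  Active: the
time-varying-elastance tension rises to its peak at t0 and relaxes over
a sarcomere-length-dependent duration (Frank-Starling behavior).
"""

import numpy as np

from bivent import ActiveParams, CHF_REFERENCE, active_tension
from bivent.fem import SHEAR_MODES, analytic_shear_stress

print("simple-shear stress (kPa) at amount 0.4, calibrated CHF "
      "myocardium:")
for mode in SHEAR_MODES:
    s = analytic_shear_stress(mode, 0.4, CHF_REFERENCE)
    print(f"  mode {mode}: {s:8.2f}")
print("the fiber-loaded modes (fs, fn) are stiffest; sheet-normal "
      "modes are softest - the anisotropy the material model encodes.\n")

ap = ActiveParams()
print(f"active tension over one cycle at fiber stretch 1.10 "
      f"(TMAX = {ap.tmax} kPa):")
for t in (0.0, 0.05, 0.1, ap.t0, 0.25, 0.35, 0.5):
    ta = float(active_tension(t, 1.10, ap))
    print(f"  t = {t:4.2f} s: Ta = {ta:7.2f} kPa")
print("tension is zero at cycle start, peaks at t0 = "
      f"{ap.t0} s, and decays over the length-dependent relaxation "
      "interval, vanishing before the next beat.")

lams = [0.9, 1.0, 1.1, 1.2]
tas = [float(active_tension(ap.t0, l, ap)) for l in lams]
print("\npeak tension vs fiber stretch (Frank-Starling):")
for l, ta in zip(lams, tas):
    print(f"  lambda_f = {l:.2f}: Ta = {ta:7.2f} kPa")
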