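"""The synthetic continuous-flow pump characteristic.

Flow falls monotonically with the pressure head the pump works against
(dP = arterial minus LV pressure); higher rotor speed shifts the whole
curve up.  Tables span dP = 0..200 mmHg at 2 mmHg steps and are
interpolated linearly in between (and extrapolated linearly outside).
"""

from bivent import synthetic_lvad_curves

curves = synthetic_lvad_curves()
heads = [0, 40, 80, 120, 160, 200]
print("flow (L/min) vs pressure head (mmHg):")
print("  dP:   " + "".join(f"{h:>7d}" for h in heads))
for rpm in curves.rpms:
    dp, q = curves.tables[rpm]
    row = "".join(f"{q[list(dp).index(h)]:7.2f}" for h in heads)
    print(f"  {rpm:>4s}: {row}")
print("\nml/s at dP = 75 mmHg, 10k RPM:",
      round(curves.flow(75.0, "10k"), 1))
print("At high head the low-speed curves approach zero flow: the pump "
      "can no longer overcome the arterial-ventricular gradient.")
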