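"""Build the idealized biventricular mesh and report its volumes.

The LV is a thick-walled truncated ellipsoid (unloaded cavity ~180 ml,
the dilated-failure regime), the RV a thinner crescent shell attached to
the LV epicardium; the covered part of the LV wall is the septum.
"""

from bivent import GeometryConfig, build_idealized_biventricular, \
    cavity_volume
from bivent.geometry import REGION_NAMES, analytic_lv_cavity_volume
from bivent.io import write_vtu

cfg = GeometryConfig()
mesh = build_idealized_biventricular(cfg)

print(f"nodes: {mesh.n_nodes}, hexahedral elements: {mesh.n_elements}")
for rid, name in REGION_NAMES.items():
    n = int((mesh.element_region == rid).sum())
    print(f"  {name:13s}: {n} elements")

v_lv = cavity_volume(mesh, None, "LV")
v_rv = cavity_volume(mesh, None, "RV")
print(f"LV cavity volume {v_lv:.1f} ml "
      f"(closed-form ellipsoid segment: "
      f"{analytic_lv_cavity_volume(cfg):.1f} ml)")
print(f"RV cavity volume {v_rv:.1f} ml")
print("A dilated failing LV is unloaded near 180 ml; inflation to the "
      "23 mmHg end-diastolic pressure brings it to ~254 ml after "
      "calibration.")

write_vtu(mesh, "biventricle.vtu")
print("wrote biventricle.vtu (view in ParaView; 'region' labels the "
      "LV free wall / septum / RV free wall)")
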