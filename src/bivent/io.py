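"""Output writers: VTU mesh snapshots and simulation result directories.

The VTU writer emits plain ASCII XML unstructured grids (hexahedron cell
type) with optional point and cell data arrays, viewable in ParaView;
no VTK library dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import Mesh, REGION_NAMES

_VTK_HEX = 12


def write_vtu(mesh: Mesh, path, point_data=None, cell_data=None):
    """Write the mesh (optionally deformed via a 'displacement' point
    array) as an ASCII .vtu file."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements

    def data_array(name, arr, indent):
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        flat = arr.reshape(len(arr), -1)
        body = "\n".join(" ".join(f"{v:.9g}" for v in row) for row in flat)
        return (f'{indent}<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n'
                f"{body}\n{indent}</DataArray>")

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             "  <UnstructuredGrid>",
             f'    <Piece NumberOfPoints="{n_pts}" '
             f'NumberOfCells="{n_cells}">']
    parts.append("      <Points>")
    parts.append(data_array("coordinates", mesh.nodes, "        "))
    parts.append("      </Points>")
    parts.append("      <Cells>")
    conn = "\n".join(" ".join(str(i) for i in row) for row in mesh.elements)
    parts.append('        <DataArray type="Int64" Name="connectivity" '
                 f'format="ascii">\n{conn}\n        </DataArray>')
    offs = " ".join(str(8 * (i + 1)) for i in range(n_cells))
    parts.append('        <DataArray type="Int64" Name="offsets" '
                 f'format="ascii">\n{offs}\n        </DataArray>')
    types = " ".join(str(_VTK_HEX) for _ in range(n_cells))
    parts.append('        <DataArray type="UInt8" Name="types" '
                 f'format="ascii">\n{types}\n        </DataArray>')
    parts.append("      </Cells>")
    if point_data:
        parts.append("      <PointData>")
        for name, arr in point_data.items():
            parts.append(data_array(name, arr, "        "))
        parts.append("      </PointData>")
    cd = dict(cell_data)
    cd.setdefault("region", mesh.element_region.astype(float))
    parts.append("      <CellData>")
    for name, arr in cd.items():
        parts.append(data_array(name, arr, "        "))
    parts.append("      </CellData>")
    parts += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    Path(path).write_text("\n".join(parts))


def dump_mesh_csv(mesh: Mesh, prefix):
    """Debug dumps: <prefix>_nodes.csv (x,y,z mm) and
    <prefix>_elements.csv (8 node ids + region label)."""
    import pandas as pd
    prefix = str(prefix)
    pd.DataFrame(mesh.nodes, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        f"{prefix}_nodes.csv", index_label="node")
    df = pd.DataFrame(mesh.elements,
                      columns=[f"n{i}" for i in range(8)])
    df["region"] = [REGION_NAMES[r] for r in mesh.element_region]
    df.to_csv(f"{prefix}_elements.csv", index_label="element")


def save_result(result, outdir, write_snapshots_vtu=False,
                snapshot_stride=1):
    """Persist a SimulationResult: time-series CSV, snapshot/stress
    arrays (npz) and optional VTU time series."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.series.to_csv(outdir / "series.csv", index=False)
    np.savez_compressed(outdir / "fields.npz",
                        snapshots=result.snapshots,
                        snapshot_times=result.snapshot_times,
                        myofiber_stress=result.myofiber_stress,
                        element_region=result.mesh.element_region,
                        nodes=result.mesh.nodes,
                        elements=result.mesh.elements)
    meta = {"rpm": result.rpm, "T_cycle": result.T_cycle,
            "periodicity_ml": result.periodicity,
            "regions": REGION_NAMES}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    if write_snapshots_vtu:
        fib = result.fibers
        f0_elem = fib.f0.mean(axis=1)
        for k in range(0, len(result.snapshots), snapshot_stride):
            write_vtu(
                result.mesh, outdir / f"snapshot_{k:04d}.vtu",
                point_data={"displacement": result.snapshots[k]},
                cell_data={"myofiber_stress": result.myofiber_stress[k],
                           "fiber": f0_elem})
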