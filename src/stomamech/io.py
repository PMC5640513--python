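"""File I/O: legacy-ASCII VTK export of meshes and result fields, the HDF5
force-map container, E_a image export, and TOML configuration loading.

HDF5 force-map layout (documented container, no vendor formats):

    /z           (ny, nx, ns) float32, piezo extension, nm
    /deflection  (ny, nx, ns) float32, V (raw) or nN (calibrated)
    /meta        attrs: size_um, calibrated, plus any generator metadata

VTK export is the minimal legacy ASCII dialect (POINTS / POLYGONS /
CELL_DATA), readable by ParaView and friends.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import h5py
import numpy as np

from .afm import EaMap, ForceMap
from .geometry import PATCHES, SurfaceMesh

__all__ = [
    "write_vtk",
    "write_force_map",
    "read_force_map",
    "write_ea_map",
    "load_config",
]


def write_vtk(path, mesh: SurfaceMesh, displacements=None, cell_data=None):
    """Write the (optionally deformed) surface with thickness, fiber and
    patch labels as cell data; ``cell_data`` adds extra per-element arrays."""
    nodes = mesh.nodes if displacements is None else mesh.nodes + displacements
    elems = mesh.elements
    fields = {"thickness": mesh.thickness,
              "patch": mesh.patch.astype(float),
              "cell": mesh.cell.astype(float)}
    vectors = {"fiber": mesh.fiber}
    if cell_data:
        for k, v in cell_data.items():
            v = np.asarray(v, float)
            (vectors if v.ndim == 2 else fields)[k] = v
    lines = [
        "# vtk DataFile Version 3.0",
        "stomamech surface (patches: " + ", ".join(PATCHES) + ")",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(nodes)} float",
    ]
    lines += [" ".join(f"{c:.6g}" for c in p) for p in nodes]
    lines.append(f"POLYGONS {len(elems)} {4 * len(elems)}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in elems]
    lines.append(f"CELL_DATA {len(elems)}")
    for name, arr in fields.items():
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.6g}" for v in arr]
    for name, arr in vectors.items():
        lines.append(f"VECTORS {name} float")
        lines += [" ".join(f"{c:.6g}" for c in v) for v in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def write_force_map(path, fmap: ForceMap):
    with h5py.File(path, "w") as h5:
        h5.create_dataset("z", data=fmap.z.astype(np.float32),
                          compression="gzip")
        h5.create_dataset("deflection",
                          data=fmap.deflection.astype(np.float32),
                          compression="gzip")
        g = h5.create_group("meta")
        g.attrs["size_um"] = fmap.size_um
        g.attrs["calibrated"] = fmap.calibrated
        g.attrs["json"] = json.dumps(fmap.meta, default=str)


def read_force_map(path) -> ForceMap:
    with h5py.File(path, "r") as h5:
        meta = {}
        if "meta" in h5:
            g = h5["meta"]
            if "json" in g.attrs:
                meta = json.loads(g.attrs["json"])
            size = float(g.attrs["size_um"])
            cal = bool(g.attrs["calibrated"])
        else:
            raise ValueError("not a stomamech force-map file (missing /meta)")
        return ForceMap(z=np.asarray(h5["z"], float),
                        deflection=np.asarray(h5["deflection"], float),
                        size_um=size, calibrated=cal, meta=meta)


def write_ea_map(path_tiff, eamap: EaMap, path_csv=None):
    """E_a image as 32-bit float TIFF (nan where masked) + optional CSV."""
    import tifffile
    tifffile.imwrite(path_tiff, eamap.Ea.astype(np.float32))
    if path_csv is not None:
        np.savetxt(path_csv, eamap.Ea, delimiter=",", fmt="%.6g")


def load_config(path) -> dict:
    """Read a TOML configuration file (sections: geometry, material,
    protocol, afm, noise, study -- all optional)."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)
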