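"""Artifact I/O: density snapshots, legacy-VTK grids, STL surfaces, metadata.

Densities round-trip through ``.npz`` plus the geometry parameters needed
to rebuild the domain deterministically.  Voxel fields are exported as
ASCII legacy-VTK ``STRUCTURED_POINTS`` with cell data (readable by
ParaView); triangle meshes as STL via ``trimesh``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from vertopt.geometry import AnalysisDomain, DensityField, GeometryParams, build_domain


def write_vtk_cells(path, domain: AnalysisDomain, cell_fields: dict) -> None:
    """Write element fields as an ASCII legacy-VTK structured-points file."""
    nx, ny, nz = domain.shape
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("vertopt voxel fields\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"ORIGIN {domain.lo[0]:.9g} {domain.lo[1]:.9g} {domain.lo[2]:.9g}\n")
        fh.write(f"SPACING {domain.h:.9g} {domain.h:.9g} {domain.h:.9g}\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in cell_fields.items():
            arr = np.asarray(arr)
            if arr.shape != domain.shape:
                raise ValueError(f"field {name!r} shape mismatch")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK cell ordering: x fastest.
            flat = np.transpose(arr, (2, 1, 0)).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.6g")


def write_vtk_point_vectors(path, domain: AnalysisDomain,
                            point_fields: dict) -> None:
    """Write nodal vector fields (e.g. assembled tractions) as legacy VTK.

    Each field must be an ``(n_nodes, 3)`` array on the domain's
    ``(nx+1, ny+1, nz+1)`` node grid, as produced by
    :func:`vertopt.loads.assemble_tractions`.
    """
    nx, ny, nz = domain.shape
    n_pts = (nx + 1) * (ny + 1) * (nz + 1)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("vertopt nodal fields\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"ORIGIN {domain.lo[0]:.9g} {domain.lo[1]:.9g} {domain.lo[2]:.9g}\n")
        fh.write(f"SPACING {domain.h:.9g} {domain.h:.9g} {domain.h:.9g}\n")
        fh.write(f"POINT_DATA {n_pts}\n")
        for name, arr in point_fields.items():
            arr = np.asarray(arr).reshape(nx + 1, ny + 1, nz + 1, 3)
            fh.write(f"VECTORS {name} float\n")
            flat = np.transpose(arr, (2, 1, 0, 3)).reshape(-1, 3)
            np.savetxt(fh, flat, fmt="%.6g")


def write_stl(path, mesh) -> None:
    """Write a trimesh triangle mesh as STL."""
    mesh.export(str(path))


def save_density(path, field: DensityField) -> None:
    dom = field.domain
    params = {f.name: getattr(dom.params, f.name)
              for f in dataclasses.fields(dom.params)}
    np.savez_compressed(
        path, values=field.values, h=dom.h,
        planes=np.array(sorted(dom.symmetry_planes), dtype="U2"),
        params=json.dumps(params))


def load_density(path) -> DensityField:
    with np.load(path, allow_pickle=False) as z:
        params = GeometryParams(**json.loads(str(z["params"])))
        planes = tuple(str(p) for p in z["planes"])
        dom = build_domain(params, float(z["h"]), symmetry=planes)
        return DensityField(dom, np.asarray(z["values"], dtype=float))


def save_result(outdir, result, report=None) -> Path:
    """Persist a DesignResult (and optional FeatureReport) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_density(outdir / "density_full.npz", result.density)
    save_density(outdir / "density_reduced.npz", result.density_reduced)
    meta = dict(result.summary())
    meta["provenance"] = result.provenance
    if result.config is not None:
        meta["optimizer"] = {f.name: getattr(result.config, f.name)
                             for f in dataclasses.fields(result.config)}
    if report is not None:
        meta["feature_counts"] = report.counts()
        meta["components"] = report.to_rows()
    (outdir / "result.json").write_text(json.dumps(meta, indent=2, default=float))
    hist = np.stack([result.objective_history, result.volume_history], axis=1)
    np.savetxt(outdir / "history.csv", hist, delimiter=",",
               header="objective_J,volume_ratio", comments="")
    return outdir
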