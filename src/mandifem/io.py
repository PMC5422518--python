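"""Volume, surface and field file IO.

Volumes travel as MetaImage (``.mha``/``.mhd``) or NIfTI (``.nii``/
``.nii.gz``) through SimpleITK; round-trips preserve voxel values
bit-exactly together with spacing and origin.  Tetrahedral meshes and
finite-element fields are exported as legacy ASCII VTK unstructured
grids (readable by ParaView/VTK); triangle surfaces as STL via trimesh.
"""

from __future__ import annotations

import os
from typing import Dict, Optional

import numpy as np
import SimpleITK as sitk
import trimesh

from mandifem.phantom import LabelVolume, VoxelVolume

_VOLUME_EXTS = (".mha", ".mhd", ".nii", ".nii.gz")


def _check_ext(path: str) -> None:
    if not str(path).endswith(_VOLUME_EXTS):
        raise ValueError(
            f"unsupported volume format for {path!r}; use one of {_VOLUME_EXTS}"
        )


def write_volume(path: str, volume: VoxelVolume | LabelVolume) -> None:
    """Write a grayscale or label volume; array axis order (x, y, z) is
    mapped to ITK's fastest-varying-x convention."""
    _check_ext(path)
    arr = volume.values if isinstance(volume, VoxelVolume) else volume.labels
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: str, labels: bool = False) -> VoxelVolume | LabelVolume:
    """Read a volume written by :func:`write_volume` (or any scalar
    MetaImage/NIfTI volume).  ``labels=True`` returns a :class:`LabelVolume`."""
    _check_ext(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    origin = tuple(float(o) for o in img.GetOrigin())
    spacing = tuple(float(s) for s in img.GetSpacing())
    if labels:
        return LabelVolume(origin, spacing, np.ascontiguousarray(arr))
    return VoxelVolume(origin, spacing, np.ascontiguousarray(arr))


def write_stl(path: str, surface, ascii: bool = False) -> None:
    """Write a :class:`~mandifem.meshing.SurfaceMesh` as binary or ASCII STL."""
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.triangles, process=False
    )
    mesh.export(str(path), file_type="stl_ascii" if ascii else "stl")


def read_stl(path: str):
    """Read an STL file back into vertex/triangle arrays."""
    mesh = trimesh.load_mesh(str(path), process=False)
    return np.asarray(mesh.vertices, float), np.asarray(mesh.faces, np.int64)


def write_vtk_unstructured(
    path: str,
    nodes: np.ndarray,
    elements: np.ndarray,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
    point_data: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write a TET4 mesh with per-cell / per-point fields as legacy ASCII
    VTK (DATASET UNSTRUCTURED_GRID, cell type 10).

    Scalar fields are written as SCALARS, (n, 3) fields as VECTORS and
    (n, 3, 3) or (n, 9) fields as TENSORS.
    """
    nodes = np.asarray(nodes, float)
    elements = np.asarray(elements, np.int64)
    n_pts, n_cells = len(nodes), len(elements)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmandifem unstructured grid\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n_pts} double\n")
        np.savetxt(f, nodes, fmt="%.10g")
        f.write(f"CELLS {n_cells} {5 * n_cells}\n")
        cells = np.column_stack([np.full(n_cells, 4, np.int64), elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {n_cells}\n")
        np.savetxt(f, np.full(n_cells, 10, np.int64), fmt="%d")
        for header, count, data in (
            ("POINT_DATA", n_pts, point_data),
            ("CELL_DATA", n_cells, cell_data),
        ):
            if not data:
                continue
            f.write(f"{header} {count}\n")
            for name, field in data.items():
                field = np.asarray(field)
                if field.ndim == 1:
                    kind = "int" if np.issubdtype(field.dtype, np.integer) else "double"
                    f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, field, fmt="%.10g")
                elif field.shape[1:] == (3,):
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, field, fmt="%.10g")
                elif field.shape[1:] in ((3, 3), (9,)):
                    f.write(f"TENSORS {name} double\n")
                    np.savetxt(f, field.reshape(count, 9), fmt="%.10g")
                else:
                    raise ValueError(f"cannot map field {name!r} of shape {field.shape}")


def write_mesh_vtk(path: str, mesh, result=None) -> None:
    """Export a :class:`~mandifem.meshing.TetMesh`, optionally with an
    :class:`~mandifem.fe.FEResult` (displacements as point data, stress
    tensor and von Mises as cell data)."""
    cell_data = {"tissue": mesh.tissue}
    point_data = None
    if result is not None:
        point_data = {"displacement": result.displacements}
        cell_data["stress"] = result.element_stress
        cell_data["von_mises"] = result.von_mises
    write_vtk_unstructured(
        path, mesh.nodes, mesh.elements, cell_data=cell_data, point_data=point_data
    )


def read_vtk_unstructured(path: str):
    """Minimal reader for the files produced by
    :func:`write_vtk_unstructured` (points and tetrahedral connectivity)."""
    with open(path) as f:
        tokens = f.read().split()
    i = tokens.index("POINTS")
    n_pts = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], float).reshape(n_pts, 3)
    j = tokens.index("CELLS")
    n_cells = int(tokens[j + 1])
    raw = np.array(tokens[j + 3 : j + 3 + 5 * n_cells], np.int64).reshape(n_cells, 5)
    if not (raw[:, 0] == 4).all():
        raise ValueError("only TET4 cells are supported")
    return pts, raw[:, 1:]
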