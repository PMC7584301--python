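"""Mesh text format and legacy-ASCII VTK export.

Mesh text format (documented in the README):

    dressfea-mesh <dim> <n_nodes> <n_elements> <out_of_plane_thickness>
    node <id> <x> <y> [<z>]               (one per node)
    element <id> <region> <n0> <n1> ...   (one per element)
    surface <name> <count> <id ...>       (one per named surface)
"""
from __future__ import annotations

import numpy as np

from .geometry import Mesh

__all__ = ["write_mesh_text", "read_mesh_text", "write_vtk"]

_VTK_CELL = {4: 9, 8: 12}  # quad, hexahedron


def write_mesh_text(mesh: Mesh, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"dressfea-mesh {mesh.dim} {mesh.n_nodes} {mesh.n_elements} "
            f"{mesh.out_of_plane_thickness:.9g}\n"
        )
        for i, xyz in enumerate(mesh.nodes):
            fh.write(f"node {i} " + " ".join(f"{v:.12g}" for v in xyz) + "\n")
        for e, conn in enumerate(mesh.elements):
            fh.write(
                f"element {e} {mesh.region[e]} " + " ".join(map(str, conn)) + "\n"
            )
        for name, ids in mesh.boundary.items():
            ids = np.asarray(ids, int)
            fh.write(f"surface {name} {ids.size} " + " ".join(map(str, ids)) + "\n")


def read_mesh_text(path) -> Mesh:
    with open(path) as fh:
        header = fh.readline().split()
        if not header or header[0] != "dressfea-mesh":
            raise ValueError("not a dressfea mesh text file")
        dim, n_nodes, n_elems = int(header[1]), int(header[2]), int(header[3])
        thickness = float(header[4]) if len(header) > 4 else 1.0
        nodes = np.empty((n_nodes, dim))
        elements = None
        region = []
        boundary = {}
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "node":
                nodes[int(parts[1])] = [float(v) for v in parts[2 : 2 + dim]]
            elif parts[0] == "element":
                conn = [int(v) for v in parts[3:]]
                if elements is None:
                    elements = np.empty((n_elems, len(conn)), dtype=int)
                elements[int(parts[1])] = conn
                region.append((int(parts[1]), parts[2]))
            elif parts[0] == "surface":
                boundary[parts[1]] = np.array([int(v) for v in parts[3:]], int)
    reg = np.empty(n_elems, dtype="U8")
    for e, lab in region:
        reg[e] = lab
    mesh = Mesh(
        nodes=nodes,
        elements=elements,
        region=reg,
        boundary=boundary,
        out_of_plane_thickness=thickness,
    )
    mesh.validate()
    return mesh


def write_vtk(mesh: Mesh, path, point_data=None, cell_data=None) -> None:
    """Legacy ASCII VTK unstructured grid with optional point/cell data."""
    nodes = mesh.nodes
    if mesh.dim == 2:
        nodes = np.column_stack([nodes, np.zeros(mesh.n_nodes)])
    nen = mesh.elements.shape[1]
    ctype = _VTK_CELL[nen]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ndressfea export\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in nodes:
            fh.write(" ".join(f"{v:.9g}" for v in p) + "\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (nen + 1)}\n")
        for conn in mesh.elements:
            fh.write(f"{nen} " + " ".join(map(str, conn)) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        for _ in range(mesh.n_elements):
            fh.write(f"{ctype}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        fh.write(f"{v:.9g}\n")
                else:
                    vec = arr if arr.shape[1] == 3 else np.column_stack(
                        [arr, np.zeros(arr.shape[0])]
                    )
                    fh.write(f"VECTORS {name} double\n")
                    for v in vec:
                        fh.write(" ".join(f"{x:.9g}" for x in v) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {mesh.n_elements}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr, float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    fh.write(f"{v:.9g}\n")
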