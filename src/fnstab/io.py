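"""Mesh and solution export: minimal ASCII VTU and STL surfaces.

The VTU writer emits XML UnstructuredGrid files (linear tetrahedra, cell
type 10) with arbitrary point- and cell-data arrays — enough for
ParaView-style inspection of displacements, stresses and material fields.
"""

from __future__ import annotations

import numpy as np

from . import _mesh

__all__ = ["write_vtu", "write_vtu_solution", "write_surface_stl"]


def _data_array(fh, name: str, data: np.ndarray) -> None:
    data = np.asarray(data)
    comps = 1 if data.ndim == 1 else data.shape[1]
    fh.write(
        f'<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{comps}" format="ascii">\n'
    )
    np.savetxt(fh, data.reshape(len(data), -1), fmt="%.9g")
    fh.write("</DataArray>\n")


def write_vtu(path, nodes, elems, point_data=None, cell_data=None) -> None:
    nodes = np.asarray(nodes, float)
    elems = np.asarray(elems, int)
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        fh.write("<UnstructuredGrid>\n")
        fh.write(f'<Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{len(elems)}">\n')
        fh.write("<Points>\n")
        _data_array(fh, "Points", nodes)
        fh.write("</Points>\n<Cells>\n")
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        np.savetxt(fh, elems, fmt="%d")
        fh.write('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        np.savetxt(fh, np.arange(1, len(elems) + 1)[:, None] * elems.shape[1], fmt="%d")
        fh.write('</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        np.savetxt(fh, np.full((len(elems), 1), 10), fmt="%d")
        fh.write("</DataArray>\n</Cells>\n")
        fh.write("<PointData>\n")
        for name, arr in (point_data or {}).items():
            _data_array(fh, name, arr)
        fh.write("</PointData>\n<CellData>\n")
        for name, arr in (cell_data or {}).items():
            _data_array(fh, name, arr)
        fh.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


def write_vtu_solution(path, mesh: _mesh.VolumeMesh, solution, materials=None) -> None:
    """Displacements, stress state and tags for one solved construct."""
    cell = {
        "region": mesh.region.astype(float),
        "fragment": mesh.fragment.astype(float),
        "von_mises_MPa": solution.von_mises_MPa,
    }
    if materials is not None:
        cell["E_MPa"] = materials.E_MPa
        cell["nu"] = materials.nu
        cell["rho_g_cm3"] = np.nan_to_num(materials.rho_g_cm3)
    write_vtu(path, mesh.nodes, mesh.elems, point_data={"u_mm": solution.u_mm}, cell_data=cell)


def write_mesh_vtu(path, mesh: _mesh.VolumeMesh, hu=None) -> None:
    cell = {"region": mesh.region.astype(float), "part": mesh.part.astype(float)}
    if hu is not None:
        arr = np.full(mesh.n_elements, np.nan)
        arr[hu.element_ids] = hu.values
        cell["HU"] = np.nan_to_num(arr)
    write_vtu(path, mesh.nodes, mesh.elems, cell_data=cell)


def write_surface_stl(path, mesh: _mesh.VolumeMesh, element_mask=None) -> None:
    """Outer surface of (a subset of) the mesh as STL, via trimesh."""
    import trimesh

    tris = _mesh.boundary_facets(mesh.elems, element_mask)
    trimesh.Trimesh(vertices=mesh.nodes, faces=tris, process=False).export(str(path))
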