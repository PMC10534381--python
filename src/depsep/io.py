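"""Plain-text exporters: legacy VTK (fields, trajectories) and Gmsh MSH.

Written in-package so the artifact has no binary I/O dependencies; the
formats are the ASCII dialects every mesh viewer reads.
"""

from __future__ import annotations

import numpy as np

from .meshing import Mesh

__all__ = [
    "export_mesh_vtk",
    "export_fields_vtk",
    "export_mesh_msh",
    "import_mesh_msh",
    "export_trajectories_vtk",
    "sample_line_csv",
]


def _vtk_header(fh, title: str, points: np.ndarray) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
    fh.write(f"POINTS {len(points)} double\n")
    for x, y in points:
        fh.write(f"{x:.9g} {y:.9g} 0\n")


def export_mesh_vtk(path, mesh: Mesh) -> None:
    with open(path, "w") as fh:
        _vtk_header(fh, f"depsep mesh level={mesh.level}", mesh.points)
        tris = mesh.triangles
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("5\n" * len(tris))


def export_fields_vtk(path, result) -> None:
    """Velocity, pressure, potential, |E| and DEP drive on the mesh."""
    mesh = result.mesh
    with open(path, "w") as fh:
        _vtk_header(fh, "depsep fields", mesh.points)
        tris = mesh.triangles
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_TYPES {len(tris)}\n")
        fh.write("5\n" * len(tris))
        nv = mesh.n_points
        fh.write(f"POINT_DATA {nv}\n")
        ux = result.flow.ux[:nv]
        uy = result.flow.uy[:nv]
        fh.write("VECTORS velocity_m_per_s double\n")
        for a, b in zip(ux, uy):
            fh.write(f"{a:.9g} {b:.9g} 0\n")
        fh.write("SCALARS pressure_Pa double 1\nLOOKUP_TABLE default\n")
        for v in result.flow.p:
            fh.write(f"{v:.9g}\n")
        if result.potential is not None:
            fh.write("SCALARS potential_V double 1\nLOOKUP_TABLE default\n")
            for v in result.potential.V[:nv]:
                fh.write(f"{v:.9g}\n")
            emag = result.potential.field_magnitude_nodal()
            fh.write("SCALARS E_magnitude_V_per_m double 1\nLOOKUP_TABLE default\n")
            for v in emag:
                fh.write(f"{v:.9g}\n")
            g = result.potential.dep_drive_nodal
            fh.write("VECTORS dep_drive_V2_per_m3 double\n")
            for a, b in g:
                fh.write(f"{a:.9g} {b:.9g} 0\n")


def export_trajectories_vtk(path, trajectories) -> None:
    """Cell paths as VTK polylines with species index data."""
    pts = []
    lines = []
    species = sorted({tr.species for tr in trajectories})
    line_species = []
    for tr in trajectories:
        start = len(pts)
        pts.extend(tr.positions.tolist())
        lines.append(list(range(start, start + len(tr.positions))))
        line_species.append(species.index(tr.species))
    pts = np.asarray(pts)
    with open(path, "w") as fh:
        _vtk_header(fh, "depsep trajectories " + ",".join(species), pts)
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"CELLS {len(lines)} {total}\n")
        for l in lines:
            fh.write(str(len(l)) + " " + " ".join(map(str, l)) + "\n")
        fh.write(f"CELL_TYPES {len(lines)}\n")
        fh.write("4\n" * len(lines))
        fh.write(f"CELL_DATA {len(lines)}\n")
        fh.write("SCALARS species_index int 1\nLOOKUP_TABLE default\n")
        for s in line_species:
            fh.write(f"{s}\n")


def export_mesh_msh(path, mesh: Mesh) -> None:
    """Gmsh MSH 2.2 ASCII: triangles tagged 0, boundary lines tagged by
    their boundary-tag index; tag names recorded as physical names."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n")
        fh.write(f"{len(mesh.tag_names) + 1}\n")
        fh.write('2 0 "domain"\n')
        for i, name in enumerate(mesh.tag_names):
            fh.write(f'1 {i + 1} "{name}"\n')
        fh.write("$EndPhysicalNames\n")
        fh.write("$Nodes\n")
        fh.write(f"{mesh.n_points}\n")
        for i, (x, y) in enumerate(mesh.points):
            fh.write(f"{i + 1} {x:.9g} {y:.9g} 0\n")
        fh.write("$EndNodes\n")
        fh.write("$Elements\n")
        fh.write(f"{mesh.n_triangles + len(mesh.boundary_edges)}\n")
        eid = 1
        for e, tag in zip(mesh.boundary_edges, mesh.boundary_tags):
            fh.write(f"{eid} 1 2 {tag + 1} {tag + 1} {e[0] + 1} {e[1] + 1}\n")
            eid += 1
        for t in mesh.triangles:
            fh.write(f"{eid} 2 2 0 0 {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
            eid += 1
        fh.write("$EndElements\n")


def import_mesh_msh(path) -> Mesh:
    """Read back a mesh written by :func:`export_mesh_msh`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0

    def seek(tag):
        nonlocal i
        while lines[i].strip() != tag:
            i += 1
        i += 1

    seek("$PhysicalNames")
    n_names = int(lines[i]); i += 1
    tag_names = {}
    for _ in range(n_names):
        dim, num, name = lines[i].split(maxsplit=2)
        i += 1
        if int(dim) == 1:
            tag_names[int(num)] = name.strip('"')
    names = [tag_names[k] for k in sorted(tag_names)]
    seek("$Nodes")
    n_nodes = int(lines[i]); i += 1
    pts = np.empty((n_nodes, 2))
    for k in range(n_nodes):
        parts = lines[i].split(); i += 1
        pts[int(parts[0]) - 1] = (float(parts[1]), float(parts[2]))
    seek("$Elements")
    n_el = int(lines[i]); i += 1
    tris, bedges, btags = [], [], []
    for _ in range(n_el):
        parts = lines[i].split(); i += 1
        etype = int(parts[1])
        ntags = int(parts[2])
        phys = int(parts[3]) if ntags else 0
        conn = [int(v) - 1 for v in parts[3 + ntags:]]
        if etype == 1:
            bedges.append(conn)
            btags.append(phys - 1)
        elif etype == 2:
            tris.append(conn)
    return Mesh(
        points=pts,
        triangles=np.asarray(tris),
        boundary_edges=np.asarray(bedges),
        boundary_tags=np.asarray(btags),
        tag_names=names,
        level="normal",
        h=float("nan"),
    )


def sample_line_csv(path, field_eval, p0, p1, n: int = 200, columns=None) -> None:
    """Sample a field evaluator along a cut line and write CSV."""
    import pandas as pd

    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    t = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    vals = np.atleast_2d(np.asarray(field_eval(pts)))
    if vals.shape[0] != n:
        vals = vals.T
    cols = columns or [f"v{i}" for i in range(vals.shape[1])]
    df = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
    for c, col in zip(cols, vals.T):
        df[c] = col
    df.to_csv(path, index=False)
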