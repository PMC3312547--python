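"""Plain-text import/export: Gmsh MSH v2.2, legacy VTK, CSV/JSON frames.

Only the ASCII flavours of the two mesh formats are produced, with phantom
region labels as volume physical tags and surface/electrode labels as facet
physical tags, so the files load in common mesh viewers.
"""

from __future__ import annotations

import json

import numpy as np

from .forward import MeasurementFrame, StimulationProtocol, adjacent_protocol
from .inverse import LCurveResult
from .phantom import ElectrodeSet, Mesh

__all__ = [
    "write_msh",
    "read_msh",
    "write_vtk",
    "read_vtk",
    "write_frame_csv",
    "read_frame_csv",
    "write_frame_json",
    "write_lcurve_csv",
]

# physical tags in exported meshes
VOLUME_TAG = {0: 1, 1: 2, 2: 3}  # background, lung, target
SURFACE_TAG = {"wall": 10, "top": 11, "bottom": 12, "channel": 13}
ELECTRODE_TAG_BASE = 100  # electrode l -> 100 + l


def _facet_tag_map(mesh: Mesh, electrodes: ElectrodeSet | None) -> dict:
    tags = {}
    for label, faces in mesh.facets.items():
        t = SURFACE_TAG[label]
        for f in faces:
            tags[tuple(sorted(f))] = t
    if electrodes is not None:
        for el in electrodes:
            for f in el.facets:
                tags[tuple(sorted(f))] = ELECTRODE_TAG_BASE + el.number
    return tags


def write_msh(mesh: Mesh, path, electrodes: ElectrodeSet | None = None) -> None:
    """Write a mesh as Gmsh MSH v2.2 ASCII with region and electrode tags."""
    tags = _facet_tag_map(mesh, electrodes)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(mesh.n_vertices)]
    for i, p in enumerate(mesh.vertices, 1):
        lines.append(f"{i} {p[0]:.16g} {p[1]:.16g} {p[2]:.16g}")
    lines += ["$EndNodes", "$Elements", str(len(tags) + mesh.n_elements)]
    eid = 1
    for f, t in sorted(tags.items()):
        lines.append(f"{eid} 2 2 {t} {t} {f[0] + 1} {f[1] + 1} {f[2] + 1}")
        eid += 1
    for tet, reg in zip(mesh.elements, mesh.element_region):
        t = VOLUME_TAG[int(reg)]
        lines.append(
            f"{eid} 4 2 {t} {t} {tet[0] + 1} {tet[1] + 1} {tet[2] + 1} {tet[3] + 1}"
        )
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path):
    """Minimal MSH v2.2 reader; returns (vertices, tets, tet_tags, tris, tri_tags)."""
    with open(path) as fh:
        txt = fh.read().split("\n")
    it = iter(txt)
    verts, tets, tet_tags, tris, tri_tags = [], [], [], [], []
    for line in it:
        if line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                verts.append([float(v) for v in next(it).split()[1:4]])
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype, ntags = int(parts[1]), int(parts[2])
                tag = int(parts[3]) if ntags else 0
                nodes = [int(v) - 1 for v in parts[3 + ntags :]]
                if etype == 2:
                    tris.append(nodes)
                    tri_tags.append(tag)
                elif etype == 4:
                    tets.append(nodes)
                    tet_tags.append(tag)
    return (
        np.array(verts),
        np.array(tets),
        np.array(tet_tags),
        np.array(tris),
        np.array(tri_tags),
    )


def write_vtk(mesh: Mesh, path, cell_data: dict | None = None) -> None:
    """Write the volume mesh as legacy VTK ASCII with per-element scalars."""
    lines = [
        "# vtk DataFile Version 3.0",
        "oeseit phantom",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_vertices} double",
    ]
    for p in mesh.vertices:
        lines.append(f"{p[0]:.16g} {p[1]:.16g} {p[2]:.16g}")
    m = mesh.n_elements
    lines.append(f"CELLS {m} {5 * m}")
    for tet in mesh.elements:
        lines.append("4 " + " ".join(str(v) for v in tet))
    lines.append(f"CELL_TYPES {m}")
    lines += ["10"] * m
    data = {"region": mesh.element_region.astype(float)}
    if cell_data:
        data.update(cell_data)
    lines.append(f"CELL_DATA {m}")
    for name, arr in data.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.16g}" for v in np.asarray(arr, dtype=float)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path):
    """Minimal legacy VTK reader; returns (points, tets, cell_data dict)."""
    with open(path) as fh:
        txt = fh.read().split("\n")
    i = 0
    pts, cells, data = None, None, {}
    while i < len(txt):
        line = txt[i]
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            pts = np.array([[float(v) for v in txt[i + 1 + k].split()] for k in range(n)])
            i += n
        elif line.startswith("CELLS"):
            n = int(line.split()[1])
            cells = np.array(
                [[int(v) for v in txt[i + 1 + k].split()[1:]] for k in range(n)]
            )
            i += n
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            n = len(cells)
            vals = np.array([float(txt[i + 2 + k]) for k in range(n)])
            data[name] = vals
            i += n + 1
        i += 1
    return pts, cells, data


def write_frame_csv(frame: MeasurementFrame, path) -> None:
    """One row per measurement: injection index, m+, m-, voltage (1-based)."""
    p = frame.protocol
    with open(path, "w") as fh:
        fh.write("injection,m_plus,m_minus,voltage\n")
        for (inj, mp, mm), v in zip(p.measurements, frame.values):
            fh.write(f"{inj + 1},{mp + 1},{mm + 1},{v:.16e}\n")


def read_frame_csv(path, protocol: StimulationProtocol | None = None) -> MeasurementFrame:
    rows = np.loadtxt(path, delimiter=",", skiprows=1)
    if protocol is None:
        n_el = int(rows[:, 1].max())
        protocol = adjacent_protocol(n_el)
    return MeasurementFrame(rows[:, 3], protocol)


def write_frame_json(frame: MeasurementFrame, path) -> None:
    p = frame.protocol
    doc = {
        "n_el": p.n_el,
        "amplitude_A": p.amplitude,
        "n_measurements": p.n_measurements,
        "noise_level": frame.noise_level,
        "noise_seed": frame.noise_seed,
        "values_V": frame.values.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_lcurve_csv(lcurve: LCurveResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("lambda,lambda_normalized,residual_norm,solution_seminorm,is_corner\n")
        for i, (lam, r, s) in enumerate(
            zip(lcurve.lambdas, lcurve.residual_norms, lcurve.solution_seminorms)
        ):
            fh.write(
                f"{lam:.16e},{lam / lcurve.lambda_scale:.16e},{r:.16e},{s:.16e},"
                f"{int(i == lcurve.corner_index)}\n"
            )
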