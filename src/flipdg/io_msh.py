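"""Gmsh .msh (v2.2 ASCII) import/export for labelled cell meshes.

Physical groups: surfaces 1 = cytoplasm, 2 = nucleus, 3 = bleach
(bleach elements are cytoplasmic but carry their own tag); lines
10 = outer boundary, 20 = membrane.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError
from .geometry import (
    BLEACH,
    CYTOPLASM,
    EDGE_MEMBRANE,
    EDGE_OUTER,
    NUCLEUS,
    TriMesh,
)

_PHYS_OUTER = 10
_PHYS_MEMBRANE = 20


def write_msh(mesh: TriMesh, path) -> None:
    """Write a labelled mesh as Gmsh v2.2 ASCII."""
    lines = [
        "$MeshFormat", "2.2 0 8", "$EndMeshFormat",
        "$PhysicalNames", "5",
        '2 1 "cytoplasm"', '2 2 "nucleus"', '2 3 "bleach"',
        '1 10 "outer"', '1 20 "membrane"',
        "$EndPhysicalNames",
        "$Nodes", str(len(mesh.vertices)),
    ]
    for i, (x, y) in enumerate(mesh.vertices, start=1):
        lines.append(f"{i} {float(x)!r} {float(y)!r} 0")
    lines.append("$EndNodes")

    boundary = np.nonzero(
        (mesh.edge_class == EDGE_OUTER) | (mesh.edge_class == EDGE_MEMBRANE)
    )[0]
    lines.append("$Elements")
    lines.append(str(len(boundary) + mesh.n_elements))
    eid = 1
    for e in boundary:
        phys = _PHYS_MEMBRANE if mesh.edge_class[e] == EDGE_MEMBRANE else _PHYS_OUTER
        a, b = mesh.edges[e] + 1
        lines.append(f"{eid} 1 2 {phys} {phys} {a} {b}")
        eid += 1
    for t in range(mesh.n_elements):
        if mesh.element_bleach[t]:
            phys = BLEACH
        else:
            phys = int(mesh.element_region[t])
        a, b, c = mesh.triangles[t] + 1
        lines.append(f"{eid} 2 2 {phys} {phys} {a} {b} {c}")
        eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def read_msh(path) -> TriMesh:
    """Read a labelled mesh written by :func:`write_msh` (Gmsh v2.2)."""
    text = Path(path).read_text().splitlines()
    it = iter(text)

    def seek(section: str):
        for line in it:
            if line.strip() == section:
                return
        raise FormatError(f"missing {section} section in .msh file")

    seek("$MeshFormat")
    version = next(it).split()[0]
    if not version.startswith("2.2"):
        raise FormatError(f"unsupported .msh version {version} (need 2.2 ASCII)")
    seek("$Nodes")
    n_nodes = int(next(it))
    vertices = np.empty((n_nodes, 2))
    for _ in range(n_nodes):
        parts = next(it).split()
        vertices[int(parts[0]) - 1] = (float(parts[1]), float(parts[2]))
    seek("$Elements")
    n_elem = int(next(it))
    triangles, regions, bleach = [], [], []
    membrane_lines = []
    for _ in range(n_elem):
        parts = next(it).split()
        etype = int(parts[1])
        n_tags = int(parts[2])
        phys = int(parts[3]) if n_tags else 0
        nodes = [int(v) - 1 for v in parts[3 + n_tags:]]
        if etype == 2:
            triangles.append(nodes)
            bleach.append(phys == BLEACH)
            regions.append(NUCLEUS if phys == NUCLEUS else CYTOPLASM)
        elif etype == 1 and phys == _PHYS_MEMBRANE:
            membrane_lines.append(tuple(sorted(nodes)))
    if not triangles:
        raise FormatError("no triangles in .msh file")
    mesh = TriMesh(
        vertices=vertices,
        triangles=np.asarray(triangles, dtype=np.int64),
        element_region=np.asarray(regions, dtype=np.int8),
        element_bleach=np.asarray(bleach, dtype=bool),
    )
    # cross-check: membrane edges derived from region labels must match tags
    derived = {
        tuple(sorted(mesh.edges[e]))
        for e in np.nonzero(mesh.edge_class == EDGE_MEMBRANE)[0]
    }
    if membrane_lines and derived != set(membrane_lines):
        raise FormatError("membrane line tags inconsistent with region labels")
    return mesh
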