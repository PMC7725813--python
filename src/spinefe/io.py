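"""Legacy-VTK (ASCII) export/import of meshes with optional result fields.

Only the unstructured-grid subset this package emits is supported on read,
enough for round-trip tests and inspection in ParaView.
"""

from __future__ import annotations

import numpy as np

from .mesh import ElementBlock, Mesh

_VTK_TYPE = {"tet4": 10, "tet10": 24, "tri3_membrane": 5, "bar2": 3}
_KIND_OF_TYPE = {10: "tet4", 24: "tet10", 5: "tri3_membrane", 3: "bar2"}


def save_vtk(path: str, mesh: Mesh, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a mesh (all blocks) plus optional nodal fields to a legacy .vtk file."""
    cells = []
    types = []
    block_id = []
    for bi, b in enumerate(mesh.blocks):
        for row in b.connectivity:
            cells.append(row)
            types.append(_VTK_TYPE[b.kind])
            block_id.append(bi)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("spinefe blocks:" + ",".join(f"{b.name}:{b.kind}" for b in mesh.blocks) + "\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        size = sum(len(c) + 1 for c in cells)
        f.write(f"CELLS {len(cells)} {size}\n")
        for c in cells:
            f.write(str(len(c)) + " " + " ".join(str(int(i)) for i in c) + "\n")
        f.write(f"CELL_TYPES {len(cells)}\n")
        for t in types:
            f.write(f"{t}\n")
        f.write(f"CELL_DATA {len(cells)}\n")
        f.write("SCALARS block_id int 1\nLOOKUP_TABLE default\n")
        for b_ in block_id:
            f.write(f"{b_}\n")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        f.write(f"{v:.17g}\n")
                else:
                    f.write(f"VECTORS {name} double\n")
                    for v in arr:
                        f.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")


def load_vtk(path: str) -> tuple[Mesh, dict[str, np.ndarray]]:
    """Read a legacy .vtk file written by :func:`save_vtk`."""
    with open(path) as f:
        lines = f.read().splitlines()
    header = lines[1]
    block_meta = []
    if header.startswith("spinefe blocks:"):
        for part in header[len("spinefe blocks:"):].split(","):
            if part:
                name, kind = part.rsplit(":", 1)
                block_meta.append((name, kind))
    i = 0
    nodes = cells = types = block_id = None
    point_data: dict[str, np.ndarray] = {}
    n_points = 0
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "POINTS":
            n_points = int(tok[1])
            vals = " ".join(lines[i + 1:i + 1 + n_points]).split()
            nodes = np.array(vals, dtype=float).reshape(n_points, 3)
            i += 1 + n_points
        elif tok[0] == "CELLS":
            n_cells = int(tok[1])
            cells = [np.array(lines[i + 1 + j].split()[1:], dtype=np.int64) for j in range(n_cells)]
            i += 1 + n_cells
        elif tok[0] == "CELL_TYPES":
            n = int(tok[1])
            types = np.array(lines[i + 1:i + 1 + n], dtype=int)
            i += 1 + n
        elif tok[0] == "SCALARS" and tok[1] == "block_id":
            n = len(cells)
            block_id = np.array(lines[i + 2:i + 2 + n], dtype=int)
            i += 2 + n
        elif tok[0] == "SCALARS":
            name = tok[1]
            point_data[name] = np.array(lines[i + 2:i + 2 + n_points], dtype=float)
            i += 2 + n_points
        elif tok[0] == "VECTORS":
            name = tok[1]
            vals = " ".join(lines[i + 1:i + 1 + n_points]).split()
            point_data[name] = np.array(vals, dtype=float).reshape(n_points, 3)
            i += 1 + n_points
        else:
            i += 1
    if block_id is None:
        block_id = np.zeros(len(cells), dtype=int)
    blocks = []
    for bi in range(block_id.max() + 1 if len(block_id) else 0):
        sel = np.nonzero(block_id == bi)[0]
        if not len(sel):
            continue
        kind = _KIND_OF_TYPE[int(types[sel[0]])]
        conn = np.stack([cells[j] for j in sel])
        name = block_meta[bi][0] if bi < len(block_meta) else f"block{bi}"
        blocks.append(ElementBlock(name, kind, conn))
    return Mesh(nodes, blocks), point_data
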