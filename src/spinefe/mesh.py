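"""Mesh generation, conformal node-merging, and geometric audits.

All coordinates are in millimetres.  Convention: X = right-lateral,
Y = superior (caudocranial), Z = anterior.  Solid primitives are meshed
with structured (extruded) tetrahedral templates so that node layouts at
interfaces are deterministic; closed shells are surfaces of revolution.

Surface sets store oriented triangular facets with *outward* normals;
:func:`enclosed_volume` raises on inward orientation rather than
silently flipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Mesh",
    "ElementBlock",
    "ShapeSpec",
    "generate_primitive_mesh",
    "merge_coincident_nodes",
    "enclosed_volume",
    "convert_to_quadratic",
    "volume_discrepancy",
    "boundary_surface",
    "surface_is_watertight",
    "icosphere",
]

SOLID_KINDS = ("tet4", "tet10")
ELEMENT_KINDS = ("tet4", "tet10", "tri3_membrane", "bar2")

_NODES_PER_KIND = {"tet4": 4, "tet10": 10, "tri3_membrane": 3, "bar2": 2}


@dataclass
class ElementBlock:
    name: str
    kind: str  # one of ELEMENT_KINDS
    connectivity: np.ndarray  # (n_elements, nodes_per_element) int

    def __post_init__(self):
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")
        self.connectivity = np.asarray(self.connectivity, dtype=np.int64)
        if self.connectivity.ndim != 2 or self.connectivity.shape[1] != _NODES_PER_KIND[self.kind]:
            raise ValueError(
                f"{self.kind} connectivity must be (n, {_NODES_PER_KIND[self.kind]})"
            )


@dataclass
class Mesh:
    """Unstructured mesh: nodes, element blocks, named node and surface sets."""

    nodes: np.ndarray  # (n_nodes, 3) float, mm
    blocks: list[ElementBlock] = field(default_factory=list)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    surface_sets: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (m, 3) facets

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()}
        self.surface_sets = {
            k: np.asarray(v, dtype=np.int64).reshape(-1, 3) for k, v in self.surface_sets.items()
        }

    # -- queries ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def block(self, name: str) -> ElementBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no element block named {name!r}")

    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def validate(self) -> None:
        """Check connectivity indices and set indices refer to existing nodes."""
        n = self.n_nodes
        for b in self.blocks:
            if b.connectivity.size and (b.connectivity.min() < 0 or b.connectivity.max() >= n):
                raise ValueError(f"block {b.name!r} references nonexistent nodes")
        for name, idx in self.node_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"node set {name!r} references nonexistent nodes")
        for name, fac in self.surface_sets.items():
            if fac.size and (fac.min() < 0 or fac.max() >= n):
                raise ValueError(f"surface set {name!r} references nonexistent nodes")

    def copy(self) -> "Mesh":
        return Mesh(
            self.nodes.copy(),
            [ElementBlock(b.name, b.kind, b.connectivity.copy()) for b in self.blocks],
            {k: v.copy() for k, v in self.node_sets.items()},
            {k: v.copy() for k, v in self.surface_sets.items()},
        )

    def translated(self, offset) -> "Mesh":
        m = self.copy()
        m.nodes = m.nodes + np.asarray(offset, dtype=float).reshape(1, 3)
        return m


@dataclass
class ShapeSpec:
    """Parametric primitive: the synthetic stand-in for scanned anatomy parts.

    ``dimensions`` keys depend on ``kind``:

    - ``box``: lx, ly, lz
    - ``cylinder``: radius, height  (axis along Y)
    - ``fusiform_shell``: length, max_radius  (closed lemon-shaped shell, axis Y)
    - ``sheet``: lx, ly and optional arc_radius (wraps the sheet around a
      Y-axis cylinder of that radius; arc length preserved)
    - ``cavity_wall``: length, max_radius  (closed ellipsoidal shell, axis Y)
    """

    kind: str
    dimensions: dict[str, float]
    target_edge_length: float = 3.0
    element_order: int = 1

    def __post_init__(self):
        kinds = ("box", "cylinder", "fusiform_shell", "sheet", "cavity_wall")
        if self.kind not in kinds:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        for k, v in self.dimensions.items():
            if v <= 0:
                raise ValueError(f"dimension {k!r} must be positive, got {v}")
        if self.target_edge_length <= 0:
            raise ValueError("target_edge_length must be positive")
        core = [v for k, v in self.dimensions.items() if k != "arc_radius"]
        if self.target_edge_length > min(core):
            raise ValueError("target_edge_length exceeds the smallest dimension")
        if self.element_order not in (1, 2):
            raise ValueError("element_order must be 1 or 2")


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])  # outward for +vol tet


def _tet_volumes(nodes: np.ndarray, conn: np.ndarray) -> np.ndarray:
    x = nodes[conn]
    return np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0


def _fix_tet_orientation(nodes: np.ndarray, conn: np.ndarray) -> np.ndarray:
    """Swap two nodes of inverted tets so all signed volumes are positive."""
    conn = conn.copy()
    neg = _tet_volumes(nodes, conn) < 0
    conn[neg, 1], conn[neg, 2] = conn[neg, 2].copy(), conn[neg, 1].copy()
    return conn


def boundary_surface(nodes: np.ndarray, conn: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary facets of a tet (tet4 or tet10-corner) mesh.

    For tet10 connectivity only the 4 corner nodes are used, so boundary
    facets remain tri3 (straight-edge conversion keeps geometry identical).
    """
    conn = np.asarray(conn)[:, :4]
    conn = _fix_tet_orientation(nodes, conn)
    faces = conn[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def surface_is_watertight(facets: np.ndarray) -> bool:
    """Every edge shared by exactly two facets, with opposite direction."""
    facets = np.asarray(facets).reshape(-1, 3)
    if len(facets) == 0:
        return False
    edges = np.concatenate(
        [facets[:, [0, 1]], facets[:, [1, 2]], facets[:, [2, 0]]], axis=0
    )
    key = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if not np.all(counts == 2):
        return False
    # opposite orientation: for each undirected edge, one facet must traverse
    # it forward and the other backward -> directed edge signs sum to zero
    sign = np.where(edges[:, 0] < edges[:, 1], 1, -1)
    sums = np.zeros(len(uniq))
    np.add.at(sums, inv, sign)
    return bool(np.all(sums == 0))


def enclosed_volume(facets: np.ndarray, coordinates: np.ndarray) -> float:
    """Volume enclosed by a watertight outward-oriented triangulated surface.

    Divergence theorem: V = (1/3) sum_f (centroid . normal) area, which for
    triangles reduces to the sum of signed origin-tet volumes.  Raises on a
    non-watertight surface and on inward (negative-volume) orientation.
    """
    facets = np.asarray(facets, dtype=np.int64).reshape(-1, 3)
    if not surface_is_watertight(facets):
        raise ValueError("surface is not watertight")
    x = np.asarray(coordinates, dtype=float)[facets]
    # signed volume relative to the surface centroid (exact translation invariance)
    c = x.reshape(-1, 3).mean(axis=0)
    x = x - c
    v = np.einsum("fi,fi->f", x[:, 0], np.cross(x[:, 1], x[:, 2])).sum() / 6.0
    if v < 0:
        raise ValueError("surface is oriented inward (negative enclosed volume)")
    return float(v)


def volume_discrepancy(measured: float, reference: float) -> float:
    """Percent deviation of a measured volume from its reference."""
    if reference <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * abs(measured - reference) / reference


# ---------------------------------------------------------------------------
# structured primitive generators
# ---------------------------------------------------------------------------


def _split_prisms(bot: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tets each, conformally.

    ``bot``/``top`` are (n, 3) node-id triangles with identical ordering.
    Each base triangle is sorted by global id first; quad-face diagonals then
    always run through the smaller id of the shared bottom edge, so adjacent
    prisms (and stacked layers) agree on diagonals.
    """
    order = np.argsort(bot, axis=1)
    a, b, c = (np.take_along_axis(bot, order, axis=1)).T
    A, B, C = (np.take_along_axis(top, order, axis=1)).T
    tets = np.concatenate(
        [
            np.stack([a, b, c, C], axis=1),
            np.stack([a, b, C, B], axis=1),
            np.stack([a, B, C, A], axis=1),
        ]
    )
    return tets


def _disk_triangulation(
    radius: float,
    edge: float,
    radial_edge: float | None = None,
    ring_radii: list[float] | None = None,
):
    """Spider-web triangulation of a disk in the XZ plane (normal +Y).

    Returns (points2d (n,2) in the (x,z) plane, triangles (m,3)).
    Deterministic for identical inputs.  ``radial_edge`` refines the ring
    spacing independently of the circumferential/axial edge length, and
    ``ring_radii`` prescribes the ring radii explicitly (graded boundary-layer
    refinement), the last entry being ``radius``.
    """
    if ring_radii is not None:
        radii = [float(r) for r in ring_radii]
        if abs(radii[-1] - radius) > 1e-9 or any(
            b <= a for a, b in zip(radii, radii[1:])
        ):
            raise ValueError("ring_radii must increase strictly up to the radius")
    else:
        nr = max(2, round(radius / (radial_edge or edge)))
        radii = [radius * k / nr for k in range(1, nr + 1)]
    nr = len(radii)
    # multiple of 4 so the x=0 and z=0 planes are exact symmetry planes
    nt = 4 * max(2, round(np.pi * radius / (2 * edge)))
    pts = [(0.0, 0.0)]
    for k in range(1, nr + 1):
        r = radii[k - 1]
        for j in range(nt):
            th = 2 * np.pi * j / nt
            pts.append((r * np.cos(th), r * np.sin(th)))
    pts = np.array(pts)

    def ring(k, j):
        return 1 + (k - 1) * nt + (j % nt)

    tris = []
    for j in range(nt):  # central fan
        tris.append((0, ring(1, j), ring(1, j + 1)))
    for k in range(1, nr):
        for j in range(nt):
            p00, p01 = ring(k, j), ring(k, j + 1)
            p10, p11 = ring(k + 1, j), ring(k + 1, j + 1)
            tris.append((p00, p10, p11))
            tris.append((p00, p11, p01))
    return pts, np.array(tris, dtype=np.int64)


def _annulus_triangulation(r_in: float, r_out: float, edge: float):
    """Structured triangulation of an annulus in the XZ plane."""
    nr = max(2, round((r_out - r_in) / edge))
    nt = 4 * max(2, round(np.pi * r_out / (2 * edge)))
    pts = []
    for k in range(nr + 1):
        r = r_in + (r_out - r_in) * k / nr
        for j in range(nt):
            th = 2 * np.pi * j / nt
            pts.append((r * np.cos(th), r * np.sin(th)))
    pts = np.array(pts)

    def ring(k, j):
        return k * nt + (j % nt)

    tris = []
    for k in range(nr):
        for j in range(nt):
            p00, p01 = ring(k, j), ring(k, j + 1)
            p10, p11 = ring(k + 1, j), ring(k + 1, j + 1)
            tris.append((p00, p10, p11))
            tris.append((p00, p11, p01))
    return pts, np.array(tris, dtype=np.int64)


def extruded_annulus(r_in: float, r_out: float, y0: float, height: float, edge: float):
    """Structured tet mesh of a thick-walled tube along Y (verification use).

    Returns (nodes, tets); the bore is an exact cylinder of radius ``r_in``.
    """
    pts2d, tris = _annulus_triangulation(r_in, r_out, edge)
    n_slice = len(pts2d)
    nlay = max(1, round(height / edge))
    ys = y0 + height * np.arange(nlay + 1) / nlay
    nodes = np.empty((len(ys) * n_slice, 3))
    for s, y in enumerate(ys):
        nodes[s * n_slice:(s + 1) * n_slice, 0] = pts2d[:, 0]
        nodes[s * n_slice:(s + 1) * n_slice, 1] = y
        nodes[s * n_slice:(s + 1) * n_slice, 2] = pts2d[:, 1]
    all_tets = []
    for s in range(nlay):
        all_tets.append(_split_prisms(tris + s * n_slice, tris + (s + 1) * n_slice))
    tets = _fix_tet_orientation(nodes, np.concatenate(all_tets))
    return nodes, tets


def extruded_cylinder(
    radius: float,
    y0: float,
    y_breaks: list[float],
    edge: float,
    min_layers: list[int] | None = None,
    radial_edge: float | None = None,
    ring_radii: list[float] | None = None,
):
    """Structured tet mesh of a cylinder extruded along Y through ``y_breaks``.

    The cylinder starts at y0; ``y_breaks`` are the cumulative segment end
    heights (relative to y0).  Returns (nodes, tets, layer_of_tet) where
    ``layer_of_tet`` gives the segment index each tet belongs to, so callers
    can partition one conformal extrusion into named blocks (vertebrae and
    discs share interface nodes by construction).  ``min_layers`` optionally
    forces a minimum axial layer count per segment.
    """
    pts2d, tris = _disk_triangulation(radius, edge, radial_edge, ring_radii)
    n_slice = len(pts2d)
    ys = [0.0]
    seg_of_layer = []
    prev = 0.0
    for seg, yb in enumerate(y_breaks):
        nlay = max(1, round((yb - prev) / edge))
        if min_layers is not None:
            nlay = max(nlay, min_layers[seg])
        for i in range(1, nlay + 1):
            ys.append(prev + (yb - prev) * i / nlay)
            seg_of_layer.append(seg)
        prev = yb
    ys = np.array(ys)
    nodes = np.empty((len(ys) * n_slice, 3))
    for s, y in enumerate(ys):
        nodes[s * n_slice:(s + 1) * n_slice, 0] = pts2d[:, 0]
        nodes[s * n_slice:(s + 1) * n_slice, 1] = y0 + y
        nodes[s * n_slice:(s + 1) * n_slice, 2] = pts2d[:, 1]
    all_tets, layer_of_tet = [], []
    for s in range(len(ys) - 1):
        bot = tris + s * n_slice
        top = tris + (s + 1) * n_slice
        tets = _split_prisms(bot, top)
        all_tets.append(tets)
        layer_of_tet.append(np.full(len(tets), seg_of_layer[s]))
    tets = _fix_tet_orientation(nodes, np.concatenate(all_tets))
    return nodes, tets, np.concatenate(layer_of_tet)


def _box_mesh(lx: float, ly: float, lz: float, edge: float) -> Mesh:
    nx, ny, nz = (max(1, round(d / edge)) for d in (lx, ly, lz))
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    # Kuhn (Freudenthal) 6-tet split: conformal across a structured grid
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                for p in perms:
                    idx = [np.array([i, j, k])]
                    for ax in p:
                        nxt = idx[-1].copy()
                        nxt[ax] += 1
                        idx.append(nxt)
                    tets.append([nid(*v) for v in idx])
    tets = _fix_tet_orientation(nodes, np.array(tets, dtype=np.int64))
    m = Mesh(nodes, [ElementBlock("box", "tet4", tets)])
    m.surface_sets["boundary"] = boundary_surface(nodes, tets)
    return m


def _cylinder_mesh(radius: float, height: float, edge: float) -> Mesh:
    nodes, tets, _ = extruded_cylinder(radius, 0.0, [height], edge)
    m = Mesh(nodes, [ElementBlock("cylinder", "tet4", tets)])
    m.surface_sets["boundary"] = boundary_surface(nodes, tets)
    return m


def revolution_shell(
    length: float,
    max_radius: float,
    edge: float,
    profile: str = "fusiform",
    name: str = "shell",
) -> Mesh:
    """Closed tri3 shell of revolution about the Y axis, poles at y=0 and y=length.

    ``profile``: "fusiform" (lemon, r = r_max sin(pi t), y linear) or
    "ellipsoid" (y = L/2 (1 - cos(pi t)), r = r_max sin(pi t)).
    """
    nl = max(6, round(length / edge))
    nc = max(8, round(2 * np.pi * max_radius / edge))
    t = np.linspace(0.0, 1.0, nl + 1)
    if profile == "fusiform":
        yy = length * t
        rr = max_radius * np.sin(np.pi * t)
    elif profile == "ellipsoid":
        yy = 0.5 * length * (1 - np.cos(np.pi * t))
        rr = max_radius * np.sin(np.pi * t)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    pts = [(0.0, yy[0], 0.0)]
    for i in range(1, nl):
        for j in range(nc):
            th = 2 * np.pi * j / nc
            pts.append((rr[i] * np.cos(th), yy[i], rr[i] * np.sin(th)))
    pts.append((0.0, yy[-1], 0.0))
    nodes = np.array(pts)
    apex_bot, apex_top = 0, len(nodes) - 1

    def rid(i, j):  # ring i in 1..nl-1
        return 1 + (i - 1) * nc + (j % nc)

    tris = []
    for j in range(nc):
        tris.append((apex_bot, rid(1, j + 1), rid(1, j)))
    for i in range(1, nl - 1):
        for j in range(nc):
            p00, p01 = rid(i, j), rid(i, j + 1)
            p10, p11 = rid(i + 1, j), rid(i + 1, j + 1)
            tris.append((p00, p01, p11))
            tris.append((p00, p11, p10))
    for j in range(nc):
        tris.append((apex_top, rid(nl - 1, j), rid(nl - 1, j + 1)))
    tris = np.array(tris, dtype=np.int64)
    # enforce outward orientation
    c = nodes.mean(axis=0)
    x = nodes[tris] - c
    v = np.einsum("fi,fi->f", x[:, 0], np.cross(x[:, 1], x[:, 2])).sum()
    if v < 0:
        tris = tris[:, [0, 2, 1]]
    m = Mesh(nodes, [ElementBlock(name, "tri3_membrane", tris)])
    m.surface_sets["closed"] = tris.copy()
    m.node_sets["pole_inferior"] = np.array([apex_bot])
    m.node_sets["pole_superior"] = np.array([apex_top])
    m.node_sets["ring_inferior"] = np.array([rid(1, j) for j in range(nc)])
    m.node_sets["ring_superior"] = np.array([rid(nl - 1, j) for j in range(nc)])
    return m


def _sheet_mesh(lx: float, ly: float, edge: float, arc_radius: float | None) -> Mesh:
    nx = max(2, round(lx / edge))
    ny = max(2, round(ly / edge))
    xs = np.linspace(-lx / 2, lx / 2, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    pts = []
    for j, y in enumerate(ys):
        for i, x in enumerate(xs):
            if arc_radius is None:
                pts.append((x, y, 0.0))
            else:  # wrap around a Y-axis cylinder, arc length preserved
                th = x / arc_radius
                pts.append((arc_radius * np.sin(th), y, arc_radius * (np.cos(th) - 1.0)))
    nodes = np.array(pts)

    def nid(i, j):
        return j * (nx + 1) + i

    tris = []
    for j in range(ny):
        for i in range(nx):
            p00, p10 = nid(i, j), nid(i + 1, j)
            p01, p11 = nid(i, j + 1), nid(i + 1, j + 1)
            tris.append((p00, p10, p11))
            tris.append((p00, p11, p01))
    m = Mesh(nodes, [ElementBlock("sheet", "tri3_membrane", np.array(tris, dtype=np.int64))])
    m.node_sets["edge_inferior"] = np.array([nid(i, 0) for i in range(nx + 1)])
    m.node_sets["edge_superior"] = np.array([nid(i, ny) for i in range(nx + 1)])
    m.node_sets["edge_left"] = np.array([nid(0, j) for j in range(ny + 1)])
    m.node_sets["edge_right"] = np.array([nid(nx, j) for j in range(ny + 1)])
    return m


def generate_primitive_mesh(spec: ShapeSpec) -> Mesh:
    """Generate a deterministic structured mesh for a parametric primitive."""
    d = spec.dimensions
    e = spec.target_edge_length
    if spec.kind == "box":
        mesh = _box_mesh(d["lx"], d["ly"], d["lz"], e)
    elif spec.kind == "cylinder":
        mesh = _cylinder_mesh(d["radius"], d["height"], e)
    elif spec.kind == "fusiform_shell":
        mesh = revolution_shell(d["length"], d["max_radius"], e, "fusiform")
    elif spec.kind == "cavity_wall":
        mesh = revolution_shell(d["length"], d["max_radius"], e, "ellipsoid")
    elif spec.kind == "sheet":
        mesh = _sheet_mesh(d["lx"], d["ly"], e, d.get("arc_radius"))
    else:  # pragma: no cover - guarded by ShapeSpec
        raise ValueError(spec.kind)
    if spec.element_order == 2 and any(b.kind == "tet4" for b in mesh.blocks):
        mesh = convert_to_quadratic(mesh)
    mesh.validate()
    return mesh


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> Mesh:
    """Triangulated sphere by icosahedron subdivision (verification helper)."""
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                v = vlist[a] + vlist[b]
                v = v / np.linalg.norm(v)
                cache[key] = len(vlist)
                vlist.append(v)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    nodes = verts * radius
    m = Mesh(nodes, [ElementBlock("sphere", "tri3_membrane", faces)])
    m.surface_sets["closed"] = faces.copy()
    return m


# ---------------------------------------------------------------------------
# conformal merging
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller root so the representative is the first node seen
            if ra > rb:
                ra, rb = rb, ra
            self.parent[rb] = ra


def merge_coincident_nodes(
    meshes: list[Mesh],
    tolerance: float = 1e-6,
    names: list[str] | None = None,
) -> Mesh:
    """Fuse several meshes into one conformal mesh by clustering coincident nodes.

    Each cluster of nodes within ``tolerance`` collapses to one representative,
    so loads applied at a fused interface distribute through shared nodes with
    no contact formulation.  Two nodes of the *same* source mesh within
    tolerance are rejected (degenerate input, not an interface).  Block and
    set names are preserved with source prefixes when ``names`` is given.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if isinstance(meshes, Mesh):
        meshes = [meshes]
    if not meshes:
        raise ValueError("no meshes to merge")
    if names is not None and len(names) != len(meshes):
        raise ValueError("names must match meshes")

    offsets = np.cumsum([0] + [m.n_nodes for m in meshes])
    all_nodes = np.concatenate([m.nodes for m in meshes], axis=0)
    source = np.concatenate(
        [np.full(m.n_nodes, i, dtype=np.int64) for i, m in enumerate(meshes)]
    )

    uf = _UnionFind(len(all_nodes))
    if tolerance == 0.0:
        _, inv = np.unique(all_nodes, axis=0, return_inverse=True)
        groups: dict[int, int] = {}
        for i, g in enumerate(inv):
            g = int(g)
            if g in groups:
                uf.union(groups[g], i)
            else:
                groups[g] = i
    else:
        tree = cKDTree(all_nodes)
        for i, j in tree.query_pairs(tolerance):
            uf.union(i, j)
    roots = np.array([uf.find(i) for i in range(len(all_nodes))])
    # same-source duplicates are degenerate input
    for r in np.unique(roots):
        members = np.nonzero(roots == r)[0]
        if len(members) > 1:
            src = source[members]
            if len(np.unique(src)) != len(src):
                raise ValueError(
                    "two nodes of the same source mesh fall within the merge "
                    "tolerance (degenerate input)"
                )
    uniq_roots, new_index = np.unique(roots, return_inverse=True)
    new_nodes = all_nodes[uniq_roots]

    def prefix(i, label):
        return f"{names[i]}_{label}" if names is not None else label

    blocks, node_sets, surface_sets = [], {}, {}
    for i, m in enumerate(meshes):
        remap = new_index[offsets[i]:offsets[i + 1]]
        for b in m.blocks:
            blocks.append(ElementBlock(prefix(i, b.name), b.kind, remap[b.connectivity]))
        for k, v in m.node_sets.items():
            node_sets[prefix(i, k)] = np.unique(remap[v])
        for k, v in m.surface_sets.items():
            surface_sets[prefix(i, k)] = remap[v]
    merged = Mesh(new_nodes, blocks, node_sets, surface_sets)
    merged.validate()
    return merged


# ---------------------------------------------------------------------------
# element-order conversion
# ---------------------------------------------------------------------------

_TET10_EDGES = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]


def convert_to_quadratic(mesh: Mesh) -> Mesh:
    """Convert tet4 blocks to tet10 by inserting shared mid-edge nodes.

    Straight edges are preserved so the boundary geometry (and any enclosed
    volume) is unchanged.  Membrane and bar blocks pass through untouched;
    a mesh with no tet4 block is rejected.
    """
    if not any(b.kind == "tet4" for b in mesh.blocks):
        raise ValueError("mesh contains no tet4 blocks to convert")
    edge_ids: dict[tuple[int, int], int] = {}
    # deterministic mid-node numbering: sorted unique edges over all tet blocks
    all_edges = []
    for b in mesh.blocks:
        if b.kind != "tet4":
            continue
        c = b.connectivity
        for i, j in _TET10_EDGES:
            e = np.sort(np.stack([c[:, i], c[:, j]], axis=1), axis=1)
            all_edges.append(e)
    uniq = np.unique(np.concatenate(all_edges, axis=0), axis=0)
    n0 = mesh.n_nodes
    for k, (a, b_) in enumerate(uniq):
        edge_ids[(int(a), int(b_))] = n0 + k
    new_nodes = np.concatenate(
        [mesh.nodes, 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])], axis=0
    )
    blocks = []
    for b in mesh.blocks:
        if b.kind != "tet4":
            blocks.append(ElementBlock(b.name, b.kind, b.connectivity.copy()))
            continue
        c = b.connectivity
        mids = []
        for i, j in _TET10_EDGES:
            lo = np.minimum(c[:, i], c[:, j])
            hi = np.maximum(c[:, i], c[:, j])
            mids.append([edge_ids[(int(a), int(bb))] for a, bb in zip(lo, hi)])
        conn10 = np.concatenate([c, np.array(mids, dtype=np.int64).T], axis=1)
        blocks.append(ElementBlock(b.name, "tet10", conn10))
    # node sets denote regions: mid-edge nodes whose edge endpoints both
    # belong to a set join that set (otherwise driven/fixed regions would pin
    # only their corner nodes after conversion)
    new_sets = {}
    for name, ids in mesh.node_sets.items():
        members = set(int(i) for i in ids)
        extra = [
            mid
            for (a, b_), mid in edge_ids.items()
            if a in members and b_ in members
        ]
        new_sets[name] = np.array(sorted(members.union(extra)), dtype=np.int64)
    out = Mesh(
        new_nodes,
        blocks,
        new_sets,
        {k: v.copy() for k, v in mesh.surface_sets.items()},
    )
    out.validate()
    return out
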