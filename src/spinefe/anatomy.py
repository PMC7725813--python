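"""Parametric synthetic torso assemblies.

Stand-ins for scanned anatomy: the vertebral column is one conformal
structured extrusion (vertebrae and discs share interface nodes by
construction, so the node-merge step is a no-op check), muscles are closed
fusiform membrane shells backed by incompressible cavities and tied to the
column by tendon bars, the thoracolumbar fascia is a curved sheet anchored
to dorsal vertebra points, and the abdominal cavity is a closed ellipsoidal
wall anchored anteriorly.

Geometry is deliberately idealized; absolute outputs are geometry-bound, so
dimensions are exposed as parameters and the harness checks trends and
properties rather than absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import engine as eng
from . import mesh as msh
from .cavity import CavitySpec
from .materials import MaterialLaw

__all__ = [
    "AnatomyParams",
    "TissueTable",
    "MuscleForceCase",
    "default_materials",
    "muscle_force_case",
    "build_lumbar_model",
    "build_full_spine_model",
    "analytic_part_volumes",
]

LUMBAR_LEVELS = ["L5", "L4", "L3", "L2", "L1"]
THORACIC_LEVELS = [f"T{i}" for i in range(12, 0, -1)]  # T12 (caudal) .. T1


@dataclass
class MuscleShellSpec:
    """One bilateral muscle pair: fusiform shell + cavity + tendon ends."""

    name: str
    length: float  # mm
    max_radius: float  # mm
    offset: tuple[float, float, float]  # centre of the left/right shells (+x mirrored)
    superior_level: str  # column level receiving the superior tendon
    inferior_level: str  # column level (or "sacrum") receiving the inferior tendon
    bilateral: bool = True


@dataclass
class AnatomyParams:
    # column
    column_radius: float = 17.0
    lumbar_vertebra_height: float = 28.0
    thoracic_vertebra_height: float = 20.0
    lumbar_ivd_height: float = 10.0
    lumbosacral_ivd_height: float | None = None  # defaults to lumbar_ivd_height
    thoracic_ivd_height: float = 7.0
    sacrum_height: float = 30.0
    include_lumbosacral_ivd: bool = True
    # meshing
    edge_length: float = 4.5
    radial_edge: float | None = None  # finer ring spacing for the column disk
    muscle_edge_length: float = 6.0
    element_order: int = 1
    # two-phase disc
    nucleus_radius_fraction: float = 0.6
    bore_refinement: bool = False  # graded rings outside the nucleus radius
    ivd_min_layers: int = 2
    nucleus_mid_band: bool = False  # cap the cavity with soft disc tissue
    endplate_height: float = 2.5  # cartilaginous endplates around the two-phase disc
    use_endplates: bool = False
    # psoas (used by both assemblies)
    psoas_length: float = 240.0
    psoas_max_radius: float = 35.0
    psoas_offset_x: float = 60.0
    # tendons
    tendon_area: float = 30.0  # mm^2 total per insertion
    # fascia sheet
    tlf_width: float = 110.0
    tlf_arc_radius: float = 32.0
    tlf_offset_z: float = -34.0
    # abdominal cavity
    abdomen_length: float = 240.0
    abdomen_radius: float = 70.0
    abdomen_offset_z: float = 80.0

    def __post_init__(self):
        for name in (
            "column_radius", "lumbar_vertebra_height", "thoracic_vertebra_height",
            "lumbar_ivd_height", "thoracic_ivd_height", "sacrum_height",
            "edge_length", "muscle_edge_length", "nucleus_radius_fraction",
            "psoas_length", "psoas_max_radius", "tendon_area",
            "tlf_width", "tlf_arc_radius", "abdomen_length", "abdomen_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.element_order not in (1, 2):
            raise ValueError("element_order must be 1 or 2")
        if not (0.2 <= self.nucleus_radius_fraction <= 0.8):
            raise ValueError("nucleus_radius_fraction must lie in [0.2, 0.8]")


TissueTable = dict[str, MaterialLaw]


def default_materials(scenario: str) -> TissueTable:
    """Tissue tables for the two validation scenarios (moduli in MPa, mm)."""
    base: TissueTable = {
        "vertebra": MaterialLaw("linear_elastic", 12000.0, 0.3),
        "ivd": MaterialLaw("neo_hookean_incompressible", 42.7, 0.499),
        "psoas": MaterialLaw("neo_hookean_incompressible", 0.52, 0.499, thickness=2.73),
        "tendon": MaterialLaw("neo_hookean_incompressible", 1000.0, 0.499),
        # two-phase fifth disc
        "annulus": MaterialLaw("linear_elastic", 8.0, 0.45),
        "nucleus_shell": MaterialLaw("neo_hookean_incompressible", 1.0, 0.49, thickness=1.0),
        "endplate": MaterialLaw("linear_elastic", 24.0, 0.4),  # cartilaginous endplate
    }
    if scenario == "lumbar_test":
        return base
    if scenario == "full_spine_test":
        soft = 0.03687  # 36.87 kPa in MPa
        base.update(
            {
                "multifidus": MaterialLaw("neo_hookean_incompressible", soft, 0.499, thickness=4.5),
                "longissimus": MaterialLaw("neo_hookean_incompressible", soft, 0.499, thickness=4.03),
                "latissimus": MaterialLaw("neo_hookean_incompressible", soft, 0.499, thickness=4.5),
                "intertransversarius": MaterialLaw(
                    "neo_hookean_incompressible", soft, 0.499, thickness=1.0
                ),
                "tlf": MaterialLaw("neo_hookean_incompressible", 450.0, 0.499, thickness=2.0),
                "abdominal_wall": MaterialLaw("linear_elastic", 0.025, 0.45, thickness=9.7),
            }
        )
        return base
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass(frozen=True)
class MuscleForceCase:
    """One column of the muscle-force input table (total force per muscle, N)."""

    case_id: int
    forces: dict[str, float]
    expected_t1_load: float  # N, for reporting only


_FORCE_TABLE = {
    "longissimus": [210.0, 30.0, 85.0, 120.0, 185.0, 198.0],
    "multifidus": [71.0, 15.0, 30.0, 45.0, 65.0, 71.0],
    "psoas": [275.0, 40.0, 100.0, 140.0, 235.0, 260.0],
    "intertransversarius": [25.0, 5.0, 10.0, 15.0, 25.0, 25.0],
}
_T1_LOADS = [382.0, 54.4, 136.0, 203.0, 314.0, 346.0]


def muscle_force_case(case_id: int) -> MuscleForceCase:
    if case_id not in range(6):
        raise ValueError("case_id must be in 0..5")
    return MuscleForceCase(
        case_id,
        {k: v[case_id] for k, v in _FORCE_TABLE.items()},
        _T1_LOADS[case_id],
    )


# ---------------------------------------------------------------------------
# column
# ---------------------------------------------------------------------------


def _nucleus_radius(params: AnatomyParams) -> float:
    """Nucleus radius aligned with a mesh ring of the column disk."""
    R = params.column_radius
    if params.bore_refinement:
        r_in = params.nucleus_radius_fraction * R
        n_in = max(2, round(r_in / params.edge_length))
        return float(np.linspace(0.0, r_in, n_in + 1)[-1])
    nr = max(2, round(R / (params.radial_edge or params.edge_length)))
    k_in = min(nr - 1, max(1, round(params.nucleus_radius_fraction * nr)))
    return R * k_in / nr


def _column_segments(params: AnatomyParams, full_spine: bool, endplates: bool = False):
    """Ordered (name, height) pairs from the base (sacrum) upward.

    ``endplates`` inserts thin cartilaginous layers around the lumbosacral
    disc (used by the two-phase disc: they cap the nucleus cavity with soft
    tissue instead of stiff vertebral bone).
    """
    segs = [("sacrum", params.sacrum_height)]
    # the full-spine count follows the source model: 17 vertebrae linked by 16
    # discs, with the sacrum fused directly below L5
    if params.include_lumbosacral_ivd and not full_spine:
        if endplates:
            segs.append(("endplate5i", params.endplate_height))
        segs.append(("ivd5", params.lumbosacral_ivd_height or params.lumbar_ivd_height))
        if endplates:
            segs.append(("endplate5s", params.endplate_height))
    for i, lvl in enumerate(LUMBAR_LEVELS):
        segs.append((lvl, params.lumbar_vertebra_height))
        if lvl != "L1":
            segs.append((f"ivd{4 - i}", params.lumbar_ivd_height))
        elif full_spine:
            segs.append(("ivdT12L1", params.lumbar_ivd_height))
    if full_spine:
        for lvl in THORACIC_LEVELS:
            segs.append((lvl, params.thoracic_vertebra_height))
            if lvl != "T1":
                n = int(lvl[1:])
                segs.append((f"ivdT{n - 1}T{n}", params.thoracic_ivd_height))
    return segs


def _build_column(
    params: AnatomyParams, full_spine: bool, endplates: bool = False
) -> tuple[msh.Mesh, dict]:
    segs = _column_segments(params, full_spine, endplates)
    breaks = np.cumsum([h for _, h in segs])
    # discs always get at least two axial layers (they are the flexible
    # joints; a single fully prescribed layer inverts kinematically on coarse
    # meshes); extra layers only where the two-phase surgery needs them
    min_layers = [
        params.ivd_min_layers
        if name == "ivd5"
        else (2 if name.startswith("ivd") else 1)
        for name, _ in segs
    ]
    ring_radii = None
    if params.bore_refinement:
        R = params.column_radius
        r_in = _nucleus_radius(params)
        inner = list(np.linspace(0.0, r_in, max(2, round(r_in / params.edge_length)) + 1))[1:]
        # geometrically graded boundary layer outside the nucleus radius
        offsets = [0.5, 1.2, 2.2, 3.6]
        outer = [r_in + o for o in offsets if r_in + o < R - 1.0]
        coarse = list(np.linspace(outer[-1] if outer else r_in, R, 3))[1:]
        ring_radii = inner + outer + coarse
    nodes, tets, layer = msh.extruded_cylinder(
        params.column_radius, 0.0, list(breaks), params.edge_length, min_layers,
        params.radial_edge, ring_radii,
    )
    blocks = []
    node_sets = {}
    seg_ranges = {}
    y0 = 0.0
    for i, (name, h) in enumerate(segs):
        conn = tets[layer == i]
        blocks.append(msh.ElementBlock(name, "tet4", conn))
        node_sets[name] = np.unique(conn)
        seg_ranges[name] = (y0, y0 + h)
        y0 += h
    mesh = msh.Mesh(nodes, blocks, node_sets)
    mesh.surface_sets["column_boundary"] = msh.boundary_surface(nodes, tets)
    info = {
        "segments": segs,
        "segment_ranges": seg_ranges,
        "height": float(breaks[-1]),
        "vertebrae": [
            n
            for n, _ in segs
            if not n.startswith(("ivd", "endplate")) and n != "sacrum"
        ],
        "ivds": [n for n, _ in segs if n.startswith("ivd")],
        "endplates": [n for n, _ in segs if n.startswith("endplate")],
    }
    return mesh, info


def _disc_interface_facets(mesh: msh.Mesh, disc: str) -> np.ndarray:
    """Transverse facets of a disc block (its interfaces with the vertebrae),
    oriented outward from the disc."""
    conn = mesh.block(disc).connectivity
    bf = msh.boundary_surface(mesh.nodes, conn)
    x = mesh.nodes[bf]
    n = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return bf[np.abs(n[:, 1]) > 0.7]


def _split_two_phase_disc(
    mesh: msh.Mesh, params: AnatomyParams, disc: str, seg_range: tuple[float, float]
):
    """Replace the core of one disc with a nucleus membrane + cavity surface.

    The core tets (all nodes within the nucleus radius, which is aligned to a
    mesh ring by construction) are removed from the disc block; the exposed
    interior boundary becomes both the cavity bounding surface and a thin
    nucleus membrane sharing the solid nodes.
    """
    r_in = _nucleus_radius(params)

    blk = mesh.block(disc)
    conn = blk.connectivity
    rad = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 2])
    core = np.all(rad[conn] <= r_in + 1e-6, axis=1)
    # optionally keep the first and last axial layers as a soft cover, so the
    # cavity is capped by disc tissue rather than by the stiff vertebrae
    ys = np.unique(np.round(mesh.nodes[np.unique(conn), 1], 9))
    if params.nucleus_mid_band and len(ys) >= 4:
        y_lo, y_hi = ys[1], ys[-2]
        yel = mesh.nodes[conn][:, :, 1]
        core &= np.all((yel >= y_lo - 1e-6) & (yel <= y_hi + 1e-6), axis=1)
    if not np.any(core):
        raise ValueError("no core elements found for the two-phase disc")
    blk.connectivity = conn[~core]
    blk.name = "annulus5"

    # cavity boundary: faces of remaining solids exposed by the removal
    all_tets = np.concatenate(
        [b.connectivity[:, :4] for b in mesh.blocks if b.kind in ("tet4", "tet10")]
    )
    bf = msh.boundary_surface(mesh.nodes, all_tets)
    fc = mesh.nodes[bf].mean(axis=1)
    frad = np.hypot(fc[:, 0], fc[:, 2])
    y0, y1 = seg_range
    tol = 1e-6
    inside = (frad < r_in - tol + 0.5 * params.edge_length) & (
        (fc[:, 1] > y0 - tol) & (fc[:, 1] < y1 + tol)
    )
    cav = bf[inside][:, [0, 2, 1]]  # flip: outward from the enclosed fluid
    if not msh.surface_is_watertight(cav):
        raise ValueError("two-phase disc cavity surface is not watertight")
    # the shell lines the lateral (bore) facets; transverse facets are backed
    # by solid covers and carry the fluid tractions directly, which avoids
    # spurious wrinkling of a biaxially compressed membrane cap
    x = mesh.nodes[cav]
    nrm = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    shell = cav[np.abs(nrm[:, 1]) < 0.5]
    if len(shell) == 0:
        shell = cav
    mesh.blocks.append(msh.ElementBlock("nucleus5", "tri3_membrane", shell.copy()))
    mesh.surface_sets["nucleus5_cavity"] = cav
    return CavitySpec("nucleus5", cav, "incompressible")


# ---------------------------------------------------------------------------
# soft parts
# ---------------------------------------------------------------------------


def _make_shell_part(
    name: str, length: float, max_radius: float, edge: float, offset, profile="fusiform"
) -> msh.Mesh:
    shell = msh.revolution_shell(length, max_radius, edge, profile, name=f"{name}_shell")
    shell.nodes += np.asarray(offset, dtype=float)
    shell.surface_sets = {f"{name}_closed": shell.surface_sets["closed"]}
    shell.node_sets = {
        f"{name}_inf": np.concatenate(
            [shell.node_sets["pole_inferior"], shell.node_sets["ring_inferior"]]
        ),
        f"{name}_sup": np.concatenate(
            [shell.node_sets["pole_superior"], shell.node_sets["ring_superior"]]
        ),
    }
    return shell


def _tendon_bars(
    mesh: msh.Mesh, from_set: str, target_nodes: np.ndarray, block_name: str
) -> None:
    """Connect each node of ``from_set`` to its two nearest target column
    nodes; the angular spread braces the otherwise-floppy transverse modes of
    a shell hanging on slender trusses."""
    ids = mesh.node_sets[from_set]
    tree = cKDTree(mesh.nodes[target_nodes])
    k = min(2, len(target_nodes))
    _, nearest = tree.query(mesh.nodes[ids], k=k)
    nearest = np.atleast_2d(nearest.reshape(len(ids), -1))
    pairs = []
    for col in range(nearest.shape[1]):
        pairs.append(np.stack([ids, target_nodes[nearest[:, col]]], axis=1))
    bars = np.unique(np.concatenate(pairs, axis=0), axis=0)
    mesh.blocks.append(msh.ElementBlock(block_name, "bar2", bars))


def _column_surface_nodes(mesh: msh.Mesh, info, level: str, side: str) -> np.ndarray:
    """Lateral-surface nodes of one column level, filtered by direction.

    side: '+x', '-x', '+z', '-z' or 'any'.
    """
    surf = np.unique(mesh.surface_sets["column_boundary"])
    y0, y1 = info["segment_ranges"][level]
    x = mesh.nodes[surf]
    sel = (x[:, 1] >= y0 - 1e-6) & (x[:, 1] <= y1 + 1e-6)
    rad = np.hypot(x[:, 0], x[:, 2])
    sel &= rad > 0.8 * rad[sel].max() if np.any(sel) else sel
    if side == "+x":
        sel &= x[:, 0] > 0.3 * rad
    elif side == "-x":
        sel &= x[:, 0] < -0.3 * rad
    elif side == "+z":
        sel &= x[:, 2] > 0.3 * rad
    elif side == "-z":
        sel &= x[:, 2] < -0.3 * rad
    out = surf[sel]
    if len(out) == 0:
        raise ValueError(f"no surface nodes found for level {level} side {side}")
    return out


# ---------------------------------------------------------------------------
# assemblies
# ---------------------------------------------------------------------------


def build_lumbar_model(
    params: AnatomyParams | None = None,
    include_psoas: bool = False,
    two_phase_ivd5: bool = False,
    materials: TissueTable | None = None,
    psoas_tendons: str = "both",
) -> eng.Model:
    """L1-L5 column with sacrum and discs, optional bilateral psoas shells
    with incompressible cavities and tendons, optional two-phase fifth disc.

    The returned model carries an ``info`` dict (levels, cavity names, part
    volumes) used by the experiment harness.
    """
    params = params or AnatomyParams()
    mats = dict(materials or default_materials("lumbar_test"))
    column, info = _build_column(
        params, full_spine=False, endplates=two_phase_ivd5 and params.use_endplates
    )

    parts = [column]
    cavities: list[CavitySpec] = []
    muscle_names = []
    if include_psoas:
        y_top = info["segment_ranges"]["L1"][1]
        for sgn, tag in ((1.0, "psoas_r"), (-1.0, "psoas_l")):
            # distal apex below the sacrum (femoral side): the inferior
            # tendons then run upward and stay taut under muscle tension
            off = (sgn * params.psoas_offset_x, y_top - params.psoas_length - 15.0, 10.0)
            parts.append(
                _make_shell_part(
                    tag, params.psoas_length, params.psoas_max_radius,
                    params.muscle_edge_length, off,
                )
            )
            muscle_names.append(tag)

    mesh = msh.merge_coincident_nodes(parts, tolerance=1e-6)

    two_phase_cavity = None
    if two_phase_ivd5:
        if "ivd5" not in mesh.block_names():
            raise ValueError("two_phase_ivd5 requires the lumbosacral disc")
        two_phase_cavity = _split_two_phase_disc(
            mesh, params, "ivd5", info["segment_ranges"]["ivd5"]
        )
        cavities.append(two_phase_cavity)

    if psoas_tendons not in ("both", "inferior", "none"):
        raise ValueError("psoas_tendons must be 'both', 'inferior' or 'none'")
    bar_areas = {}
    for tag in muscle_names:
        side = "+x" if tag.endswith("_r") else "-x"
        if psoas_tendons == "both":
            # anchor on the upper half of L1 so the superior tendons stay in
            # tension (and brace shell torsion) when the muscle pulls upward
            sup_t = _column_surface_nodes(mesh, info, "L1", side)
            y0, y1 = info["segment_ranges"]["L1"]
            sup_t = sup_t[mesh.nodes[sup_t, 1] >= 0.5 * (y0 + y1)]
            _tendon_bars(mesh, f"{tag}_sup", sup_t, f"{tag}_tendon_sup")
            n_sup = len(mesh.node_sets[f"{tag}_sup"])
            bar_areas[f"{tag}_tendon_sup"] = params.tendon_area / n_sup
        if psoas_tendons in ("both", "inferior"):
            inf_t = _column_surface_nodes(mesh, info, "sacrum", side)
            _tendon_bars(mesh, f"{tag}_inf", inf_t, f"{tag}_tendon_inf")
            n_inf = len(mesh.node_sets[f"{tag}_inf"])
            bar_areas[f"{tag}_tendon_inf"] = params.tendon_area / n_inf
        cavities.append(CavitySpec(tag, mesh.surface_sets[f"{tag}_closed"], "incompressible"))

    if params.element_order == 2:
        mesh = msh.convert_to_quadratic(mesh)

    # per-disc transverse interface surfaces (for the normal-stress extractor)
    for disc in info["ivds"]:
        blk = "annulus5" if (two_phase_ivd5 and disc == "ivd5") else disc
        mesh.surface_sets[f"{disc}_interfaces"] = _disc_interface_facets(mesh, blk)

    material_map = {}
    for b in mesh.blocks:
        if b.name == "sacrum" or b.name in info["vertebrae"]:
            material_map[b.name] = mats["vertebra"]
        elif b.name.startswith("endplate"):
            material_map[b.name] = mats["endplate"]
        elif b.name == "annulus5":
            material_map[b.name] = mats["annulus"]
        elif b.name == "nucleus5":
            material_map[b.name] = mats["nucleus_shell"]
        elif b.name.startswith("ivd"):
            material_map[b.name] = mats["ivd"]
        elif b.name.endswith("_shell"):
            material_map[b.name] = mats["psoas"]
        elif "tendon" in b.name:
            material_map[b.name] = mats["tendon"]
        else:  # pragma: no cover
            raise ValueError(f"no material rule for block {b.name!r}")

    model = eng.Model(mesh, material_map, cavities, bar_areas)
    info["muscles"] = muscle_names
    info["two_phase_ivd5"] = two_phase_ivd5
    info["params"] = params
    model.info = info
    return model


_FULL_SPINE_MUSCLES = [
    MuscleShellSpec("longissimus", 380.0, 22.0, (22.0, 0.0, -46.0), "T2", "sacrum"),
    MuscleShellSpec("multifidus", 220.0, 16.0, (14.0, 0.0, -40.0), "T12", "sacrum"),
    MuscleShellSpec("psoas", 240.0, 35.0, (60.0, 0.0, 10.0), "L1", "sacrum"),
    MuscleShellSpec("intertransversarius", 260.0, 9.0, (30.0, 0.0, 0.0), "T10", "sacrum"),
    MuscleShellSpec("latissimus", 200.0, 18.0, (55.0, 0.0, -40.0), "T3", "T12"),
]


def build_full_spine_model(
    params: AnatomyParams | None = None,
    muscles: bool = False,
    tlf: bool = False,
    abdominal_cavity: bool = False,
    tendons: bool = True,
    materials: TissueTable | None = None,
    muscle_cavity_mode: str = "incompressible",
) -> eng.Model:
    """T1-L5 column (+ sacrum); optional muscle shells with cavities, fascia
    sheet with per-level anchor bars, and a closed abdominal cavity wall."""
    params = params or AnatomyParams()
    mats = dict(materials or default_materials("full_spine_test"))
    column, info = _build_column(params, full_spine=True)

    parts = [column]
    cavities: list[CavitySpec] = []
    muscle_specs: list[MuscleShellSpec] = []
    if muscles:
        for spec in _FULL_SPINE_MUSCLES:
            y_sup = info["segment_ranges"][spec.superior_level][1]
            y_base = y_sup - spec.length + 10.0
            sides = ((1.0, f"{spec.name}_r"), (-1.0, f"{spec.name}_l"))
            for sgn, tag in sides:
                off = (sgn * spec.offset[0], y_base, spec.offset[2])
                parts.append(
                    _make_shell_part(
                        tag, spec.length, spec.max_radius,
                        params.muscle_edge_length, off,
                    )
                )
            muscle_specs.append(spec)

    tlf_part = None
    if tlf:
        height = info["segment_ranges"]["T6"][0]
        sheet = msh.generate_primitive_mesh(
            msh.ShapeSpec(
                "sheet",
                {"lx": params.tlf_width, "ly": height, "arc_radius": params.tlf_arc_radius},
                max(params.muscle_edge_length, params.edge_length),
            )
        )
        sheet.blocks[0].name = "tlf_sheet"
        # concave side faces the column: centre line at tlf_offset_z, edges
        # curving further posterior
        sheet.nodes[:, 2] += params.tlf_offset_z
        sheet.node_sets = {f"tlf_{k}": v for k, v in sheet.node_sets.items()}
        tlf_part = sheet
        parts.append(sheet)

    abd_part = None
    if abdominal_cavity:
        abd = _make_shell_part(
            "abdomen", params.abdomen_length, params.abdomen_radius,
            max(params.muscle_edge_length, 8.0),
            (0.0, params.sacrum_height + 10.0, params.abdomen_offset_z),
            profile="ellipsoid",
        )
        abd.blocks[0].name = "abdominal_wall"
        abd_part = abd
        parts.append(abd)

    mesh = msh.merge_coincident_nodes(parts, tolerance=1e-6)

    bar_areas = {}
    if muscles:
        for spec in muscle_specs:
            for tag in (f"{spec.name}_r", f"{spec.name}_l"):
                side = "+x" if tag.endswith("_r") else "-x"
                sup_t = _column_surface_nodes(mesh, info, spec.superior_level, side)
                inf_t = _column_surface_nodes(mesh, info, spec.inferior_level, side)
                if tendons:
                    _tendon_bars(mesh, f"{tag}_sup", sup_t, f"{tag}_tendon_sup")
                    _tendon_bars(mesh, f"{tag}_inf", inf_t, f"{tag}_tendon_inf")
                    bar_areas[f"{tag}_tendon_sup"] = params.tendon_area / len(
                        mesh.node_sets[f"{tag}_sup"]
                    )
                    bar_areas[f"{tag}_tendon_inf"] = params.tendon_area / len(
                        mesh.node_sets[f"{tag}_inf"]
                    )
                cavities.append(
                    CavitySpec(tag, mesh.surface_sets[f"{tag}_closed"], muscle_cavity_mode)
                )

    anchor_levels = []
    if tlf:
        # per-level anchors from the sheet to dorsal vertebra points
        sheet_nodes = np.unique(mesh.block("tlf_sheet").connectivity)
        levels = [lv for lv in LUMBAR_LEVELS + ["T12", "T11", "T10", "T9", "T8", "T7"]]
        for lv in levels:
            y0, y1 = info["segment_ranges"][lv]
            target = _column_surface_nodes(mesh, info, lv, "-z")
            x = mesh.nodes[sheet_nodes]
            near = sheet_nodes[
                (x[:, 1] > y0) & (x[:, 1] <= y1) & (np.abs(x[:, 0]) < 0.25 * params.tlf_width)
            ]
            if len(near) == 0:
                continue
            set_name = f"tlf_anchor_{lv}"
            mesh.node_sets[set_name] = near
            _tendon_bars(mesh, set_name, target, set_name)
            bar_areas[set_name] = params.tendon_area / len(near)
            anchor_levels.append(lv)

    if abdominal_cavity:
        wall_nodes = np.unique(mesh.block("abdominal_wall").connectivity)
        xw = mesh.nodes[wall_nodes]
        posterior = wall_nodes[xw[:, 2] < params.abdomen_offset_z - 0.55 * params.abdomen_radius]
        mesh.node_sets["abd_posterior"] = posterior
        target = np.unique(mesh.surface_sets["column_boundary"])
        xt = mesh.nodes[target]
        target = target[xt[:, 2] > 0.3 * params.column_radius]
        _tendon_bars(mesh, "abd_posterior", target, "abd_anchor")
        bar_areas["abd_anchor"] = params.tendon_area / len(posterior)
        cavities.append(
            CavitySpec("abdomen", mesh.surface_sets["abdomen_closed"], "incompressible")
        )

    if params.element_order == 2:
        mesh = msh.convert_to_quadratic(mesh)

    material_map = {}
    for b in mesh.blocks:
        if b.name == "sacrum" or b.name in info["vertebrae"]:
            material_map[b.name] = mats["vertebra"]
        elif b.name.startswith("ivd"):
            material_map[b.name] = mats["ivd"]
        elif b.name.endswith("_shell"):
            muscle = b.name.rsplit("_", 2)[0]
            material_map[b.name] = mats[muscle]
        elif "tendon" in b.name or b.name.startswith("tlf_anchor") or b.name == "abd_anchor":
            material_map[b.name] = mats["tendon"]
        elif b.name == "tlf_sheet":
            material_map[b.name] = mats["tlf"]
        elif b.name == "abdominal_wall":
            material_map[b.name] = mats["abdominal_wall"]
        else:  # pragma: no cover
            raise ValueError(f"no material rule for block {b.name!r}")

    model = eng.Model(mesh, material_map, cavities, bar_areas)
    info["muscles"] = [s.name for s in muscle_specs]
    info["tlf_anchor_levels"] = anchor_levels
    info["has_tlf"] = tlf
    info["has_abdomen"] = abdominal_cavity
    info["params"] = params
    model.info = info
    return model


# ---------------------------------------------------------------------------
# flexion drive helpers
# ---------------------------------------------------------------------------


def lumbar_flexion_bc(
    model: eng.Model,
    angle_deg: float,
    compression_per_deg: float = 0.03,
    joint_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0),
):
    """Chained flexion of L5..L1 about the subjacent disc centres (equal
    increments), plus a smooth predictor field for the solver.

    ``compression_per_deg`` (mm per joint per degree of joint rotation) adds
    the axial shortening a flexing segmented column carries; it is what turns
    the kinematic arc into a compressed posture (the source protocol reported
    the resulting follower compression as an output, not an input).

    ``joint_weights`` distributes the total angle over the joints from the
    lumbosacral joint upward (normalised internally); the default gives the
    lumbosacral level a reduced share, as segmental in-vivo flexion does.
    """
    info = model.info
    levels = ["L5", "L4", "L3", "L2", "L1"]
    discs = [d for d in ("ivd5", "ivd4", "ivd3", "ivd2", "ivd1") if d in info["segment_ranges"]]
    joints = []
    for lvl in levels:
        below = {"L5": "ivd5", "L4": "ivd4", "L3": "ivd3", "L2": "ivd2", "L1": "ivd1"}[lvl]
        if below in info["segment_ranges"]:
            y0, y1 = info["segment_ranges"][below]
        else:  # no lumbosacral disc: hinge at the sacrum top
            y1 = info["segment_ranges"]["sacrum"][1]
            y0 = y1
        joints.append((lvl, (0.0, 0.5 * (y0 + y1), 0.0), (y0, y1)))
    n_j = len(joints)
    w = np.asarray(joint_weights[:n_j], dtype=float)
    w = w / w.sum()
    joint_angles = [angle_deg * wi for wi in w]
    shift = compression_per_deg * angle_deg / n_j  # mm per joint at full scale
    bc = eng.ChainedRotationBC(
        [j[0] for j in joints],
        [j[1] for j in joints],
        (1.0, 0.0, 0.0),
        joint_angles,
        axial_shifts=[shift] * n_j,
    )

    X = model.mesh.nodes
    y = X[:, 1]

    def predictor(scale: float) -> np.ndarray:
        dshift = scale * shift
        Rtot = np.eye(3)
        ttot = np.zeros(3)
        u = np.zeros_like(X)
        done = np.zeros(len(X), dtype=bool)
        ymin = -np.inf
        for (_, pivot, (y0, y1)), ang_j in zip(joints, joint_angles):
            ang = np.deg2rad(scale * ang_j)
            # nodes inside the joint gap blend between the two rigid maps
            in_gap = (~done) & (y >= ymin) & (y < y1)
            frac = np.clip((y[in_gap] - y0) / max(y1 - y0, 1e-9), 0.0, 1.0)
            g = Rtot @ np.asarray(pivot) + ttot
            for sub, fr in zip(np.nonzero(in_gap)[0], frac):
                a = fr * ang
                Rj = np.array(
                    [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
                )
                xm = Rtot @ X[sub] + ttot
                axis_l = (Rj @ Rtot) @ np.array([0.0, 1.0, 0.0])
                u[sub] = Rj @ (xm - g) + g - fr * dshift * axis_l - X[sub]
            done[in_gap] = True
            c, s_ = np.cos(ang), np.sin(ang)
            Rj = np.array([[1, 0, 0], [0, c, -s_], [0, s_, c]])
            ttot = Rj @ (ttot - g) + g
            Rtot = Rj @ Rtot
            ttot = ttot - dshift * (Rtot @ np.array([0.0, 1.0, 0.0]))
            ymin = y1
        rest = (~done) & (y >= ymin)
        u[rest] = X[rest] @ Rtot.T + ttot - X[rest]
        return u

    return bc, predictor


# ---------------------------------------------------------------------------
# analytic volume references (model-form audit)
# ---------------------------------------------------------------------------


def analytic_part_volumes(params: AnatomyParams, full_spine: bool = False) -> dict[str, float]:
    """Exact volumes of the parametric column parts (cylinders), mm^3."""
    segs = _column_segments(params, full_spine)
    area = np.pi * params.column_radius**2
    return {name: area * h for name, h in segs}
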