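"""Hydrostatic fluid-cavity elements.

A cavity is a closed, oriented, deforming triangulated surface whose enclosed
fluid carries a single pressure unknown (the shared hydrostatic pressure
node).  The pressure applies follower tractions p n dA on the deformed
surface; in ``incompressible`` mode the pressure is the Lagrange multiplier
enforcing V(u) = V0, in ``prescribed_pressure`` mode it is an input.

The kernel below supplies the enclosed volume V, its exact gradient dV/dx
(nodal follower-force directions) and Hessian d2V/dx2 (follower-load
tangent), all per-facet closed forms:

    V = sum_f det(x1, x2, x3) / 6
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import enclosed_volume, surface_is_watertight

__all__ = [
    "CavitySpec",
    "CavityState",
    "MPA_PER_MMHG",
    "mpa_to_mmhg",
    "cavity_volume",
    "volume_gradient",
    "volume_hessian",
    "facet_pressure_forces",
    "facet_pressure_tangent",
    "cavity_pressure",
]

MPA_PER_MMHG = 1.33322e-4  # 1 mmHg in MPa


def mpa_to_mmhg(p_mpa: float) -> float:
    return p_mpa / MPA_PER_MMHG


@dataclass
class CavitySpec:
    """Closed bounding surface plus one hydrostatic pressure unknown."""

    name: str
    facets: np.ndarray  # (m, 3) oriented outward (away from the fluid)
    mode: str = "incompressible"  # or "prescribed_pressure"
    prescribed_pressure: float = 0.0  # MPa, end-of-schedule value

    def __post_init__(self):
        self.facets = np.asarray(self.facets, dtype=np.int64).reshape(-1, 3)
        if self.mode not in ("incompressible", "prescribed_pressure"):
            raise ValueError(f"unknown cavity mode {self.mode!r}")
        if not surface_is_watertight(self.facets):
            raise ValueError(f"cavity {self.name!r}: bounding surface is not watertight")


@dataclass
class CavityState:
    """Converged pressure (MPa, gauge) and enclosed volume (mm^3)."""

    pressure: float
    volume: float
    reference_volume: float

    @property
    def pressure_mmhg(self) -> float:
        return mpa_to_mmhg(self.pressure)

    @property
    def volume_drift(self) -> float:
        return abs(self.volume - self.reference_volume) / self.reference_volume


def cavity_volume(facets: np.ndarray, coordinates: np.ndarray) -> float:
    """Enclosed volume in the (possibly displaced) configuration; exact for
    polyhedral surfaces.  Rejects inverted (negative) volumes."""
    return enclosed_volume(facets, coordinates)


def volume_gradient(facets: np.ndarray, coordinates: np.ndarray, n_nodes: int) -> np.ndarray:
    """dV/dx as an (n_nodes, 3) array.

    Per facet: dV/dx1 = (x2 x x3)/6 and cyclic.  For a closed outward surface
    the rows sum to zero (pressure self-equilibrium) and p * gradient is the
    consistent follower nodal force vector.
    """
    x = np.asarray(coordinates, dtype=float)[facets]
    g = np.empty_like(x)
    g[:, 0] = np.cross(x[:, 1], x[:, 2]) / 6.0
    g[:, 1] = np.cross(x[:, 2], x[:, 0]) / 6.0
    g[:, 2] = np.cross(x[:, 0], x[:, 1]) / 6.0
    out = np.zeros((n_nodes, 3))
    np.add.at(out, facets.ravel(), g.reshape(-1, 3))
    return out


def _skew(v: np.ndarray) -> np.ndarray:
    """Batched skew matrices: (m,3) -> (m,3,3) with S w = v x w."""
    m = len(v)
    s = np.zeros((m, 3, 3))
    s[:, 0, 1], s[:, 0, 2] = -v[:, 2], v[:, 1]
    s[:, 1, 0], s[:, 1, 2] = v[:, 2], -v[:, 0]
    s[:, 2, 0], s[:, 2, 1] = -v[:, 1], v[:, 0]
    return s


def volume_hessian(facets: np.ndarray, coordinates: np.ndarray):
    """d2V/dx2 as COO triplets (rows, cols, vals) over displacement dofs 3*node+i.

    Off-diagonal node blocks only (diagonal blocks vanish):
    d2V/dx1 dx2 = -skew(x3)/6, d2V/dx1 dx3 = skew(x2)/6, d2V/dx2 dx3 = -skew(x1)/6,
    with the transposed blocks completing symmetry.
    """
    x = np.asarray(coordinates, dtype=float)[facets]
    blocks = [
        (0, 1, -_skew(x[:, 2]) / 6.0),
        (0, 2, _skew(x[:, 1]) / 6.0),
        (1, 2, -_skew(x[:, 0]) / 6.0),
    ]
    rows, cols, vals = [], [], []
    for a, b, B in blocks:
        na, nb = facets[:, a], facets[:, b]
        for i in range(3):
            for j in range(3):
                rows.append(3 * na + i)
                cols.append(3 * nb + j)
                vals.append(B[:, i, j])
                rows.append(3 * nb + j)
                cols.append(3 * na + i)
                vals.append(B[:, i, j])
    return (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(vals),
    )


def facet_pressure_forces(
    facets: np.ndarray, coordinates: np.ndarray, n_nodes: int
) -> np.ndarray:
    """Consistent nodal forces of a *unit* follower pressure on an oriented
    facet set (open or closed): each node of a facet receives A n / 3.

    Unlike :func:`volume_gradient` this is valid for open surfaces; for
    closed surfaces the two coincide after assembly.
    """
    x = np.asarray(coordinates, dtype=float)[facets]
    an = 0.5 * np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])  # area vectors
    out = np.zeros((n_nodes, 3))
    share = np.repeat(an / 3.0, 3, axis=0)
    np.add.at(out, facets.ravel(), share)
    return out


def facet_pressure_tangent(facets: np.ndarray, coordinates: np.ndarray):
    """COO triplets of d(f)/d(x) for a unit follower pressure on a facet set.

    Per facet the force on every node is f = (1/6)(x2 x x3 + x3 x x1 + x1 x x2),
    so df/dx1 = skew(x3 - x2)/6 etc., identical for the three force rows.
    The block is nonsymmetric for open surfaces (nonconservative load).
    """
    x = np.asarray(coordinates, dtype=float)[facets]
    dB = [
        _skew(x[:, 2] - x[:, 1]) / 6.0,  # wrt x1
        _skew(x[:, 0] - x[:, 2]) / 6.0,  # wrt x2
        _skew(x[:, 1] - x[:, 0]) / 6.0,  # wrt x3
    ]
    rows, cols, vals = [], [], []
    for a in range(3):  # force row (node a)
        na = facets[:, a]
        for b in range(3):  # position column (node b)
            nb = facets[:, b]
            B = dB[b]
            for i in range(3):
                for j in range(3):
                    rows.append(3 * na + i)
                    cols.append(3 * nb + j)
                    vals.append(B[:, i, j])
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(vals)


def cavity_pressure(solution, cavity_name: str, unit: str = "MPa") -> float:
    """Converged cavity pressure from a solved state, in MPa or mmHg."""
    try:
        state = solution.cavity_states[cavity_name]
    except KeyError:
        raise KeyError(f"unknown cavity {cavity_name!r}") from None
    p = state.pressure
    if unit == "MPa":
        return p
    if unit == "mmHg":
        return mpa_to_mmhg(p)
    raise ValueError(f"unknown unit {unit!r}")
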