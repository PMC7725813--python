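"""Quasi-static nonlinear finite-element engine.

Total-Lagrangian formulation with Newton-Raphson and incremental load
stepping.  Element set:

- ``tet4`` / ``tet10`` solids: Saint Venant-Kirchhoff for ``linear_elastic``
  materials (exact small-strain Hooke limit, passes the patch test), and a
  deviatoric neo-Hookean plus condensed constant-pressure volumetric term for
  ``neo_hookean_incompressible`` materials (the pressure p = kappa (J - 1)
  is an independent per-element/per-point unknown eliminated locally, never a
  raw bulk modulus in the displacement stiffness).
- ``tri3_membrane``: plane-stress, convective-coordinate membranes with no
  bending stiffness (muscle shells, abdominal wall, nucleus shell, fascia).
- ``bar2``: large-displacement trusses (tendons, anchors).

Cavities couple through the exact enclosed-volume gradient/Hessian
(follower pressure loads plus, in incompressible mode, one Lagrange
multiplier per cavity).  Geometric stiffness and follower-load tangents are
included; the solver is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import cavity as cav
from .materials import MaterialLaw
from .mesh import Mesh

__all__ = [
    "Model",
    "FixedBC",
    "RigidRotationBC",
    "ChainedRotationBC",
    "PrescribedDisplacementBC",
    "NodalForce",
    "SurfacePressure",
    "LoadCase",
    "SolverOptions",
    "SolutionState",
    "NonConvergenceError",
    "SingularSystemError",
    "CavityConstraintError",
    "InvertedElementError",
    "solve_static",
    "reaction_force",
    "bending_moment",
    "surface_average_normal_stress",
    "max_principal_strain",
    "block_stress",
    "block_green_strain",
    "bar_axial_forces",
    "center_of_gravity",
]


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class NonConvergenceError(RuntimeError):
    def __init__(self, message, step=None, history=None):
        super().__init__(message)
        self.step = step
        self.history = history or []


class SingularSystemError(RuntimeError):
    """Singular tangent: insufficient constraints or mechanism."""


class CavityConstraintError(RuntimeError):
    """Newton converged but a cavity volume constraint did not."""


class InvertedElementError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model and load case
# ---------------------------------------------------------------------------


@dataclass
class Model:
    """Mesh + materials + cavities + bar section areas."""

    mesh: Mesh
    materials: dict[str, MaterialLaw]
    cavities: list[cav.CavitySpec] = field(default_factory=list)
    bar_areas: dict[str, float] = field(default_factory=dict)  # block -> mm^2
    # fraction of the bulk response kept element-local in nearly incompressible
    # tet4 blocks; < 1 activates nodal-averaged-Jacobian pressures (removes
    # volumetric locking and checkerboard modes, at some robustness cost under
    # very large flexion)
    kappa_local_fraction: float = 1.0

    def __post_init__(self):
        self.mesh.validate()
        for b in self.mesh.blocks:
            if b.name not in self.materials:
                raise ValueError(f"no material assigned to block {b.name!r}")
            if b.kind == "tri3_membrane" and self.materials[b.name].thickness is None:
                raise ValueError(f"membrane block {b.name!r} needs a material thickness")
            if b.kind == "bar2" and b.name not in self.bar_areas:
                raise ValueError(f"bar block {b.name!r} needs an entry in bar_areas")
        names = [c.name for c in self.cavities]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cavity names")
        self.reference_volumes = {
            c.name: cav.cavity_volume(c.facets, self.mesh.nodes) for c in self.cavities
        }

    @property
    def n_dofs(self) -> int:
        return 3 * self.mesh.n_nodes + sum(
            1 for c in self.cavities if c.mode == "incompressible"
        )

    def cavity_dof(self, name: str) -> int:
        i = 3 * self.mesh.n_nodes
        for c in self.cavities:
            if c.mode != "incompressible":
                continue
            if c.name == name:
                return i
            i += 1
        raise KeyError(f"cavity {name!r} has no pressure dof")


@dataclass
class FixedBC:
    """Prescribe displacement components on a node set (default: fully fixed)."""

    node_set: str
    components: tuple[int, ...] = (0, 1, 2)
    values: tuple[float, ...] = (0.0, 0.0, 0.0)


@dataclass
class RigidRotationBC:
    """Drive a node set as a rigid body rotating about axis through center."""

    node_set: str
    axis: tuple[float, float, float]
    center: tuple[float, float, float]
    angle_deg: float


@dataclass
class ChainedRotationBC:
    """Flexion arc: node set j is carried by the composition of rotations
    1..j, where rotation j acts about ``axis`` through the (current image of)
    ``pivots[j]``.  Models a segmented column bending about its joint centres
    with rigid segments; exact at every load scale."""

    node_sets: list[str]
    pivots: list[tuple[float, float, float]]
    axis: tuple[float, float, float]
    angles_deg: list[float]  # incremental angle per joint
    # optional axial shortening per joint (mm at full scale, along the rotated
    # segment axis): produces the compressive follower component a segmented
    # flexion carries in vivo
    axial_shifts: list[float] | None = None

    def __post_init__(self):
        if not (len(self.node_sets) == len(self.pivots) == len(self.angles_deg)):
            raise ValueError("node_sets, pivots and angles_deg must have equal length")
        if self.axial_shifts is not None and len(self.axial_shifts) != len(self.node_sets):
            raise ValueError("axial_shifts must match node_sets")


@dataclass
class PrescribedDisplacementBC:
    """Prescribe a full displacement vector per node of a set (values is
    (len(set), 3), ordered like the node set)."""

    node_set: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1, 3)


@dataclass
class NodalForce:
    """Total force vector distributed evenly over a node set (dead load)."""

    node_set: str
    total_force: tuple[float, float, float]


@dataclass
class SurfacePressure:
    """Follower pressure on an (open or closed) oriented facet set.

    Positive pressure pushes along the facet normals.
    """

    surface_set: str
    pressure: float  # MPa at full load


@dataclass
class LoadCase:
    dirichlet: list = field(default_factory=list)  # FixedBC | RigidRotationBC
    nodal_forces: list[NodalForce] = field(default_factory=list)
    surface_pressures: list[SurfacePressure] = field(default_factory=list)
    cavity_pressures: dict[str, float] = field(default_factory=dict)  # overrides
    n_load_steps: int | None = None
    schedule: list[float] | None = None  # explicit load scales in (0, 1]
    # optional smooth initial guess: callable(scale) -> (n_nodes, 3) applied to
    # free dofs at the start of each load step (prevents the prescribed-node
    # jump from inverting thin elements before Newton corrects the interior)
    predictor: object | None = None


@dataclass
class SolverOptions:
    newton_tol: float = 1e-9  # relative force residual
    max_iterations: int = 30
    n_load_steps: int = 5
    line_search: bool = False  # classic residual backtracking (opt-in)
    stabilization: float = 0.0  # relative diagonal shift for floppy membranes
    # weak springs (N/mm per node) tying every free node to its reference
    # position: regularises rigid/wrinkling modes of shell assemblies; keep
    # orders of magnitude below structural stiffnesses
    ground_spring: float = 0.0
    max_update: float | None = None  # trust-region cap on |du|_inf per iteration (mm)
    volume_tol: float = 1e-9  # relative cavity volume drift at convergence
    store_steps: bool = False  # keep per-step displacement/reaction snapshots

    def __post_init__(self):
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")


@dataclass
class SolutionState:
    """Converged displacements, cavity states, reactions, convergence log."""

    model: Model
    u: np.ndarray  # (n_nodes, 3) mm
    cavity_states: dict[str, cav.CavityState]
    reactions: np.ndarray  # (n_nodes, 3) N, nonzero only at constrained dofs
    prescribed: np.ndarray  # boolean (n_nodes, 3)
    log: list = field(default_factory=list)  # per-step dicts
    external_force: np.ndarray | None = None  # (n_nodes, 3) assembled f_ext
    steps: list = field(default_factory=list)  # per-step SolutionState snapshots

    @property
    def displacements(self) -> np.ndarray:
        return self.u


# ---------------------------------------------------------------------------
# element data (precomputed per block)
# ---------------------------------------------------------------------------

_TET4_DNDXI = np.array(
    [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)

# 4-point rule for tet10 (degree 2)
_TET_A, _TET_B = 0.5854101966249685, 0.1381966011250105
_TET10_GP = np.array(
    [
        [_TET_A, _TET_B, _TET_B],
        [_TET_B, _TET_A, _TET_B],
        [_TET_B, _TET_B, _TET_A],
        [_TET_B, _TET_B, _TET_B],
    ]
)


def _tet10_dndxi(xi):
    """Shape-function derivatives (10, 3) at natural point xi for the node
    ordering: corners 0-3, then midedges (0,1),(1,2),(0,2),(0,3),(1,3),(2,3)."""
    L = np.array([1 - xi.sum(), xi[0], xi[1], xi[2]])
    dL = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    dN = np.zeros((10, 3))
    for i in range(4):
        dN[i] = (4 * L[i] - 1) * dL[i]
    edges = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    for k, (i, j) in enumerate(edges):
        dN[4 + k] = 4 * (L[i] * dL[j] + L[j] * dL[i])
    return dN


class _SolidData:
    def __init__(self, block, law: MaterialLaw, X: np.ndarray, kappa_local_fraction=1.0):
        self.name = block.name
        self.conn = block.connectivity
        self.law = law
        self.mixed = law.kind == "neo_hookean_incompressible"
        Xe = X[self.conn]  # (ne, nn, 3)
        if block.kind == "tet4":
            dndxi = _TET4_DNDXI[None]  # (1, 4, 3)
            w = np.array([1.0 / 6.0])
        else:
            dndxi = np.stack([_tet10_dndxi(xi) for xi in _TET10_GP])  # (4, 10, 3)
            w = np.full(4, 1.0 / 24.0)
        # Jacobian per (e, gp): J_ik = sum_a X_a,i dN_a,k
        Jm = np.einsum("eai,gak->egik", Xe, dndxi)
        detJ = np.linalg.det(Jm)
        if np.any(detJ <= 0):
            raise ValueError(f"block {block.name!r}: non-positive Jacobian")
        Jinv = np.linalg.inv(Jm)
        # gradN_a,I = dN_a,k Jinv_k,I
        self.gradN = np.einsum("gak,egkI->egaI", dndxi, Jinv)
        self.wdetJ = w[None, :] * detJ
        self.edof = (3 * self.conn[:, :, None] + np.arange(3)).reshape(len(self.conn), -1)
        self._Xe = Xe
        self.n_nodes_total = len(X)
        # nearly incompressible tet4: volumetric response from nodal-averaged
        # Jacobians (kills the checkerboard pressure modes and the locking of
        # a constant-pressure linear tet)
        self.LOCAL_KAPPA_FRACTION = kappa_local_fraction
        self.nodal_pressure = (
            self.mixed and block.kind == "tet4" and kappa_local_fraction < 1.0
        )
        # mixed tet10: mean dilatation (one constant pressure per element)
        self.mean_dilatation = self.mixed and block.kind == "tet10"
        if self.nodal_pressure:
            ne = len(self.conn)
            Vel = self.wdetJ.sum(axis=1)
            rows = np.repeat(np.arange(ne), 4)
            cols = self.conn.ravel()
            C = sp.csr_matrix(
                (np.full(4 * ne, 0.25), (rows, cols)), shape=(ne, len(X))
            )
            Vn = np.asarray(C.T @ Vel).ravel()
            Vn_inv = np.where(Vn > 0, 1.0 / np.maximum(Vn, 1e-300), 0.0)
            self._Vel = Vel
            self._Wv = (C @ sp.diags(Vn_inv) @ C.T).tocsr()

    def kinematics(self, u_nodes):
        ue = u_nodes[self.conn]
        F = np.einsum("eai,egaI->egiI", ue, self.gradN)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        return F

    def _gp_kinematics(self, ue, g):
        F = np.einsum("eai,eaI->eiI", ue, self.gradN[:, g])
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        return F

    def _nodal_pbar(self, J):
        # element pressures from nodal-averaged Jacobians: p = kappa (Jbar - 1)
        Jbar_e = np.asarray(self._Wv @ (self._Vel * J)).ravel()
        return (1.0 - self.LOCAL_KAPPA_FRACTION) * self.law.kappa * (Jbar_e - 1.0)

    def force_and_tangent(self, u_nodes, want_K):
        ue = u_nodes[self.conn]
        ne, nn = self.conn.shape
        f = np.zeros((ne, nn, 3))
        K = np.zeros((ne, 3 * nn, 3 * nn)) if want_K else None
        extra = None
        I3 = np.eye(3)
        if self.nodal_pressure:
            kappa_local = self.LOCAL_KAPPA_FRACTION * self.law.kappa
        elif self.mean_dilatation:
            kappa_local = None  # volumetric response added per element below
        else:
            kappa_local = self.law.kappa
        md_pbar = md_D = None
        if self.mean_dilatation:
            ngp = self.gradN.shape[1]
            V = np.zeros(ne)
            D = np.zeros((ne, nn, 3))
            for g in range(ngp):
                F = self._gp_kinematics(ue, g)
                try:
                    J, G = _det_grad_terms(F)
                except InvertedElementError as exc:
                    raise InvertedElementError(
                        f"{exc} in block {self.name!r}"
                    ) from None
                w = self.wdetJ[:, g]
                V += w * J
                D += (w * J)[:, None, None] * np.einsum(
                    "eiI,eaI->eai", G, self.gradN[:, g]
                )
            V0 = self.wdetJ.sum(axis=1)
            md_pbar = self.law.kappa * (V / V0 - 1.0)
            md_D = D.reshape(ne, -1)
        for g in range(self.gradN.shape[1]):
            gN = self.gradN[:, g]  # (ne, nn, 3)
            w = self.wdetJ[:, g]
            F = self._gp_kinematics(ue, g)
            try:
                if self.mixed:
                    P, A = _neo_hookean_pk1(F, self.law.mu, kappa_local, want_K)
                else:
                    P, A = _svk_pk1(F, self.law.lame_lambda, self.law.mu, want_K)
            except InvertedElementError as exc:
                raise InvertedElementError(f"{exc} in block {self.name!r}") from None
            if self.nodal_pressure or self.mean_dilatation:
                try:
                    J, G = _det_grad_terms(F)
                except InvertedElementError as exc:
                    raise InvertedElementError(
                        f"{exc} in block {self.name!r}"
                    ) from None
                pbar = md_pbar if self.mean_dilatation else self._nodal_pbar(J)
                P = P + (pbar * J)[:, None, None] * G
                if want_K:
                    GxG = np.einsum("eiJ,ekL->eiJkL", G, G)
                    GG_swap = np.einsum("eiL,ekJ->eiJkL", G, G)
                    A = A + (pbar * J)[:, None, None, None, None] * (GxG - GG_swap)
                if want_K and self.nodal_pressure:
                    # cross-element volumetric coupling: kappa Ghat^T Wv Ghat
                    D = (
                        (self._Vel * J)[:, None, None]
                        * np.einsum("eiI,eaI->eai", G, gN)
                    ).reshape(ne, -1)
                    rows = np.repeat(np.arange(ne), 3 * nn)
                    Ghat = sp.csr_matrix(
                        (D.ravel(), (rows, self.edof.ravel())),
                        shape=(ne, 3 * self.n_nodes_total),
                    )
                    extra = (
                        (1.0 - self.LOCAL_KAPPA_FRACTION)
                        * self.law.kappa
                        * (Ghat.T @ self._Wv @ Ghat)
                    )
                elif want_K and self.mean_dilatation and g == 0:
                    # rank-one in-element volumetric coupling (added once)
                    K += (self.law.kappa / self.wdetJ.sum(axis=1))[
                        :, None, None
                    ] * np.einsum("ei,ej->eij", md_D, md_D)
            f += w[:, None, None] * np.einsum("eiJ,eaJ->eai", P, gN)
            if want_K:
                # K_(ai)(bk) = gN_aJ A_iJkL gN_bL as batched matmuls
                B = np.einsum("ik,eaJ->eaikJ", I3, gN).reshape(ne, 3 * nn, 9)
                A9 = A.reshape(ne, 9, 9)
                K += w[:, None, None] * (B @ A9 @ B.transpose(0, 2, 1))
        return f.reshape(ne, -1), K, extra

    def stress_strain(self, u_nodes):
        """gp-averaged Cauchy stress and Green-Lagrange strain per element."""
        F = self.kinematics(u_nodes)
        E = 0.5 * (np.einsum("egiI,egiJ->egIJ", F, F) - np.eye(3))
        if self.mixed:
            if self.nodal_pressure:
                kl = self.LOCAL_KAPPA_FRACTION * self.law.kappa
            elif self.mean_dilatation:
                kl = None
            else:
                kl = self.law.kappa
            P, _ = _neo_hookean_pk1(F, self.law.mu, kl, False)
            if self.nodal_pressure:
                Jg, Gg = _det_grad_terms(F[:, 0])
                pbar = self._nodal_pbar(Jg)
                P = P + ((pbar * Jg)[:, None, None] * Gg)[:, None]
            elif self.mean_dilatation:
                Jall = np.linalg.det(F)  # (ne, gp)
                V = (self.wdetJ * Jall).sum(axis=1)
                V0 = self.wdetJ.sum(axis=1)
                pbar = self.law.kappa * (V / V0 - 1.0)
                Gall = np.swapaxes(np.linalg.inv(F), -1, -2)
                P = P + (pbar[:, None] * Jall)[..., None, None] * Gall
        else:
            P, _ = _svk_pk1(F, self.law.lame_lambda, self.law.mu, False)
        J = np.linalg.det(F)
        sig = np.einsum("egiJ,egkJ->egik", P, F) / J[..., None, None]
        wsum = self.wdetJ.sum(axis=1)
        sig = np.einsum("eg,egik->eik", self.wdetJ, sig) / wsum[:, None, None]
        E = np.einsum("eg,egIJ->eIJ", self.wdetJ, E) / wsum[:, None, None]
        return sig, E

    def corner_stress(self, u_nodes):
        """Cauchy stress evaluated at the 4 corner nodes of each element
        (constant for tet4, the exact linear field for tet10)."""
        ue = u_nodes[self.conn]
        if self.conn.shape[1] == 4:
            sig, _ = self.stress_strain(u_nodes)
            return np.repeat(sig[:, None], 4, axis=1)
        X = self._Xe
        corners = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        )
        out = np.empty((len(self.conn), 4, 3, 3))
        for ci, xi in enumerate(corners):
            dN = _tet10_dndxi(xi)
            Jm = np.einsum("eai,ak->eik", X, dN)
            gN = np.einsum("ak,ekI->eaI", dN, np.linalg.inv(Jm))
            F = np.einsum("eai,eaI->eiI", ue, gN) + np.eye(3)
            if self.mixed:
                P, _ = _neo_hookean_pk1(F, self.law.mu, self.law.kappa, False)
            else:
                P, _ = _svk_pk1(F, self.law.lame_lambda, self.law.mu, False)
            J = np.linalg.det(F)
            out[:, ci] = np.einsum("eiJ,ekJ->eik", P, F) / J[..., None, None]
        return out

    def volumes(self, u_nodes=None):
        if u_nodes is None:
            return self.wdetJ.sum(axis=1)
        J = np.linalg.det(self.kinematics(u_nodes))
        return (self.wdetJ * J).sum(axis=1)


def _svk_pk1(F, lam, mu, want_K):
    """Saint Venant-Kirchhoff first Piola stress and tangent dP/dF."""
    C = np.einsum("...iI,...iJ->...IJ", F, F)
    E = 0.5 * (C - np.eye(3))
    trE = np.trace(E, axis1=-2, axis2=-1)
    S = 2.0 * mu * E
    S[..., 0, 0] += lam * trE
    S[..., 1, 1] += lam * trE
    S[..., 2, 2] += lam * trE
    P = np.einsum("...iI,...IJ->...iJ", F, S)
    if not want_K:
        return P, None
    I3 = np.eye(3)
    B = np.einsum("...iI,...kI->...ik", F, F)
    A = (
        np.einsum("ik,...JL->...iJkL", I3, S)
        + lam * np.einsum("...iJ,...kL->...iJkL", F, F)
        + mu * np.einsum("...ik,JL->...iJkL", B, I3)
        + mu * np.einsum("...iL,...kJ->...iJkL", F, F)
    )
    return P, A


def _neo_hookean_pk1(F, mu, kappa, want_K):
    """Deviatoric neo-Hookean + condensed pressure p = kappa (J - 1).

    ``kappa=None`` returns the deviatoric part only (the volumetric response
    is then supplied externally, e.g. by the nodal-averaged-Jacobian path).
    """
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedElementError("element inversion (J <= 0)")
    Finv = np.linalg.inv(F)
    G = np.swapaxes(Finv, -1, -2)  # F^{-T}
    Jm23 = J ** (-2.0 / 3.0)
    I1 = np.einsum("...iJ,...iJ->...", F, F)
    Fd = F - (I1 / 3.0)[..., None, None] * G
    P = mu * Jm23[..., None, None] * Fd
    if kappa is not None:
        pvol = kappa * (J - 1.0) * J
        P = P + pvol[..., None, None] * G
    if not want_K:
        return P, None
    I3 = np.eye(3)
    GxG = np.einsum("...iJ,...kL->...iJkL", G, G)
    GG_swap = np.einsum("...iL,...kJ->...iJkL", G, G)
    A = mu * Jm23[..., None, None, None, None] * (
        -(2.0 / 3.0) * np.einsum("...kL,...iJ->...iJkL", G, Fd)
        + np.einsum("ik,JL->iJkL", I3, I3)
        - (2.0 / 3.0) * np.einsum("...kL,...iJ->...iJkL", F, G)
        + (I1 / 3.0)[..., None, None, None, None] * GG_swap
    )
    if kappa is not None:
        A = A + (kappa * (2 * J - 1.0) * J)[..., None, None, None, None] * GxG
        A = A - (kappa * (J - 1.0) * J)[..., None, None, None, None] * GG_swap
    return P, A


def _det_grad_terms(F):
    """J, F^{-T}, and d2J/dF2 building blocks for volumetric coupling."""
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedElementError("element inversion (J <= 0)")
    G = np.swapaxes(np.linalg.inv(F), -1, -2)
    return J, G


_MEM_M = np.array([[-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])  # dg_a = sum_n M[a,n] dx_n


class _MembraneData:
    """Convective-coordinate plane-stress membrane (no bending stiffness)."""

    def __init__(self, block, law: MaterialLaw, X: np.ndarray):
        self.name = block.name
        self.conn = block.connectivity
        self.law = law
        Xe = X[self.conn]
        Gvec = np.einsum("an,eni->eai", _MEM_M, Xe)  # reference tangents (e,2,3)
        Gm = np.einsum("eai,ebi->eab", Gvec, Gvec)
        detG = Gm[:, 0, 0] * Gm[:, 1, 1] - Gm[:, 0, 1] * Gm[:, 1, 0]
        if np.any(detG <= 0):
            raise ValueError(f"membrane block {block.name!r}: degenerate facet")
        self.Gm = Gm
        self.Ginv = np.linalg.inv(Gm)
        self.area0 = 0.5 * np.sqrt(detG)
        t = law.thickness
        coef = law.E / (1.0 - law.nu**2)
        Gi = self.Ginv
        self.Cmat = coef * (
            law.nu * np.einsum("eab,ecd->eabcd", Gi, Gi)
            + 0.5 * (1 - law.nu) * (
                np.einsum("eac,ebd->eabcd", Gi, Gi)
                + np.einsum("ead,ebc->eabcd", Gi, Gi)
            )
        )
        self.tA = t * self.area0
        self.edof = (3 * self.conn[:, :, None] + np.arange(3)).reshape(len(self.conn), -1)
        self._X = X[self.conn]

    def _strain_stress(self, u_nodes):
        xe = u_nodes[self.conn] + self._X
        g = np.einsum("an,eni->eai", _MEM_M, xe)
        Em = 0.5 * (np.einsum("eai,ebi->eab", g, g) - self.Gm)
        S = np.einsum("eabcd,ecd->eab", self.Cmat, Em)
        return g, Em, S

    def force_and_tangent(self, u_nodes, want_K):
        g, _, S = self._strain_stress(u_nodes)
        f = np.einsum("e,eab,an,ebi->eni", self.tA, S, _MEM_M, g).reshape(
            len(self.conn), -1
        )
        K = None
        if want_K:
            Kmat = np.einsum(
                "e,an,ebi,eabcd,cm,edk->enimk", self.tA, _MEM_M, g, self.Cmat, _MEM_M, g
            )
            Kgeo = np.einsum("e,eab,an,bm->enm", self.tA, S, _MEM_M, _MEM_M)
            K = Kmat + np.einsum("enm,ik->enimk", Kgeo, np.eye(3))
            K = K.reshape(len(self.conn), 9, 9)
        return f, K, None

    def stress_strain(self, u_nodes):
        """In-plane Cauchy stress pushed to 3D, and mixed-basis Green strain."""
        g, Em, S = self._strain_stress(u_nodes)
        gm = np.einsum("eai,ebi->eab", g, g)
        detg = gm[:, 0, 0] * gm[:, 1, 1] - gm[:, 0, 1] * gm[:, 1, 0]
        detG = (2.0 * self.area0) ** 2
        Ja = np.sqrt(detg / detG)  # area stretch
        sig = np.einsum("eab,eai,ebj->eij", S, g, g) / Ja[:, None, None]
        Emix = np.einsum("eab,ebc->eac", self.Ginv, Em)  # mixed components: eigs are strains
        return sig, Emix


class _BarData:
    def __init__(self, block, law: MaterialLaw, area: float, X: np.ndarray):
        self.name = block.name
        self.conn = block.connectivity
        self.EA = law.E * area
        d = X[self.conn[:, 1]] - X[self.conn[:, 0]]
        self.L0 = np.linalg.norm(d, axis=1)
        if np.any(self.L0 <= 0):
            raise ValueError(f"bar block {block.name!r}: zero-length bar")
        self.edof = (3 * self.conn[:, :, None] + np.arange(3)).reshape(len(self.conn), -1)
        self._X = X[self.conn]

    def force_and_tangent(self, u_nodes, want_K):
        x = u_nodes[self.conn] + self._X
        d = x[:, 1] - x[:, 0]
        l2 = np.einsum("ei,ei->e", d, d)
        e = (l2 - self.L0**2) / (2.0 * self.L0**2)  # Green axial strain
        coef = self.EA / self.L0
        f2 = (coef * e)[:, None] * d
        f = np.concatenate([-f2, f2], axis=1)
        K = None
        if want_K:
            I3 = np.eye(3)
            k22 = (coef / self.L0**2)[:, None, None] * np.einsum("ei,ej->eij", d, d)
            k22 = k22 + (coef * e)[:, None, None] * I3
            K = np.empty((len(d), 6, 6))
            K[:, :3, :3] = k22
            K[:, 3:, 3:] = k22
            K[:, :3, 3:] = -k22
            K[:, 3:, :3] = -k22
        return f, K, None

    def axial_forces(self, u_nodes):
        x = u_nodes[self.conn] + self._X
        d = x[:, 1] - x[:, 0]
        l2 = np.einsum("ei,ei->e", d, d)
        e = (l2 - self.L0**2) / (2.0 * self.L0**2)
        return self.EA / self.L0 * e * np.sqrt(l2) / self.L0  # engineering axial force


def _build_block_data(model: Model):
    X = model.mesh.nodes
    data = []
    for b in model.mesh.blocks:
        law = model.materials[b.name]
        if b.kind in ("tet4", "tet10"):
            data.append(
                _SolidData(
                    b, law, X, getattr(model, "kappa_local_fraction", 1.0)
                )
            )
        elif b.kind == "tri3_membrane":
            data.append(_MembraneData(b, law, X))
        elif b.kind == "bar2":
            data.append(_BarData(b, law, model.bar_areas[b.name], X))
        else:  # pragma: no cover
            raise ValueError(b.kind)
    return data


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


class _Assembler:
    def __init__(self, model: Model, load: LoadCase):
        self.model = model
        self.load = load
        self.n = model.mesh.n_nodes
        self.ndof = model.n_dofs
        self.blocks = _build_block_data(model)
        # dead nodal loads (unit scale)
        self.f_dead = np.zeros(self.ndof)
        for nf in load.nodal_forces:
            ids = model.mesh.node_sets[nf.node_set]
            share = np.asarray(nf.total_force, dtype=float) / len(ids)
            for i, comp in enumerate(range(3)):
                self.f_dead[3 * ids + comp] += share[i]
        self.surface_loads = [
            (model.mesh.surface_sets[sl.surface_set], sl.pressure)
            for sl in load.surface_pressures
        ]
        self.cavity_p_final = {}
        for c in model.cavities:
            if c.mode == "prescribed_pressure":
                self.cavity_p_final[c.name] = load.cavity_pressures.get(
                    c.name, c.prescribed_pressure
                )

    ground_spring = 0.0  # set by the solver from SolverOptions

    def assemble(self, u: np.ndarray, scale: float, want_K: bool):
        """Residual R = f_int - f_ext (+ cavity constraint rows), tangent
        triplets, a force reference norm, and cavity volumes."""
        model, n = self.model, self.n
        u_nodes = u[: 3 * n].reshape(n, 3)
        coords = model.mesh.nodes + u_nodes
        R = np.zeros(self.ndof)
        rows, cols, vals = [], [], []

        f_int_norm2 = 0.0
        extra_mats = []
        for bd in self.blocks:
            f, K, extra = bd.force_and_tangent(u_nodes, want_K)
            np.add.at(R, bd.edof.ravel(), f.ravel())
            f_int_norm2 += float((f**2).sum())
            if want_K and K is not None:
                m = bd.edof.shape[1]
                rows.append(np.repeat(bd.edof, m, axis=1).ravel())
                cols.append(np.tile(bd.edof, (1, m)).ravel())
                vals.append(K.ravel())
            if want_K and extra is not None:
                coo = extra.tocoo()
                rows.append(coo.row.astype(np.int64))
                cols.append(coo.col.astype(np.int64))
                vals.append(coo.data)

        f_ext = np.zeros(self.ndof)
        f_ext[: len(self.f_dead)] += scale * self.f_dead

        def add_follower(facets, p):
            # closed-surface (cavity) pressure: exact volume gradient/Hessian
            g = cav.volume_gradient(facets, coords, n).ravel()
            f_ext[: 3 * n] += p * g
            if want_K:
                r, c, v = cav.volume_hessian(facets, coords)
                rows.append(r)
                cols.append(c)
                vals.append(-p * v)  # dR/du = K_int - p d2V

        for facets, p0 in self.surface_loads:
            p = scale * p0
            f_ext[: 3 * n] += p * cav.facet_pressure_forces(facets, coords, n).ravel()
            if want_K:
                r, c, v = cav.facet_pressure_tangent(facets, coords)
                rows.append(r)
                cols.append(c)
                vals.append(-p * v)

        cavity_volumes = {}
        for c in model.cavities:
            V = cav.cavity_volume(c.facets, coords)
            cavity_volumes[c.name] = V
            if c.mode == "prescribed_pressure":
                add_follower(c.facets, scale * self.cavity_p_final[c.name])
            else:
                dof = model.cavity_dof(c.name)
                p = u[dof]
                add_follower(c.facets, p)
                V0 = model.reference_volumes[c.name]
                R[dof] = -(V - V0)
                if want_K:
                    g = cav.volume_gradient(c.facets, coords, n)
                    nz = np.nonzero(np.any(g != 0.0, axis=1))[0]
                    gd = np.concatenate([3 * nz, 3 * nz + 1, 3 * nz + 2])
                    gv = np.concatenate([g[nz, 0], g[nz, 1], g[nz, 2]])
                    rows.append(np.concatenate([gd, np.full(len(gd), dof)]))
                    cols.append(np.concatenate([np.full(len(gd), dof), gd]))
                    vals.append(np.concatenate([-gv, -gv]))

        R = R - f_ext
        if self.ground_spring > 0.0:
            R[: 3 * n] += self.ground_spring * u[: 3 * n]
            if want_K:
                gd = np.arange(3 * n)
                rows.append(gd)
                cols.append(gd)
                vals.append(np.full(3 * n, self.ground_spring))
        ref = max(np.sqrt(f_int_norm2), float(np.linalg.norm(f_ext)))
        trip = None
        if want_K:
            trip = (np.concatenate(rows), np.concatenate(cols), np.concatenate(vals))
        return R, trip, ref, cavity_volumes, f_ext


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------


def _block_solve(Kff: sp.csc_matrix, rhs: np.ndarray, n_disp: int) -> np.ndarray:
    """Solve with the trailing (cavity-multiplier) dofs eliminated by a dense
    Schur complement; falls back to a plain factorization without them."""
    n = Kff.shape[0]
    m = n - n_disp
    if m == 0:
        return spla.splu(Kff).solve(rhs)
    A = Kff[:n_disp, :n_disp].tocsc()
    B = np.asarray(Kff[:n_disp, n_disp:].todense())
    C = np.asarray(Kff[n_disp:, :n_disp].todense())
    D = np.asarray(Kff[n_disp:, n_disp:].todense())
    luA = spla.splu(A)
    X = luA.solve(B) if m else np.zeros((n_disp, 0))
    S = D - C @ X
    b1, b2 = rhs[:n_disp], rhs[n_disp:]
    y1 = luA.solve(b1)
    x2 = np.linalg.solve(S, b2 - C @ y1)
    x1 = y1 - X @ x2
    return np.concatenate([x1, x2])


def _rotation_matrix(axis, angle_rad):
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def _prescribed(model: Model, load: LoadCase):
    """Boolean mask over dofs and a function target(scale) -> values array."""
    n = model.mesh.n_nodes
    mask = np.zeros(model.n_dofs, dtype=bool)
    entries = []
    for bc in load.dirichlet:
        ids = model.mesh.node_sets[bc.node_set] if hasattr(bc, "node_set") else None
        if isinstance(bc, FixedBC):
            for k, comp in enumerate(bc.components):
                mask[3 * ids + comp] = True
            entries.append(("fixed", ids, bc))
        elif isinstance(bc, RigidRotationBC):
            for comp in range(3):
                mask[3 * ids + comp] = True
            entries.append(("rot", ids, bc))
        elif isinstance(bc, PrescribedDisplacementBC):
            if len(bc.values) != len(ids):
                raise ValueError("values length must match node set")
            for comp in range(3):
                mask[3 * ids + comp] = True
            entries.append(("field", ids, bc))
        elif isinstance(bc, ChainedRotationBC):
            for set_name in bc.node_sets:
                sids = model.mesh.node_sets[set_name]
                for comp in range(3):
                    mask[3 * sids + comp] = True
            entries.append(("chain", None, bc))
        else:
            raise TypeError(f"unknown Dirichlet entry {bc!r}")

    X = model.mesh.nodes

    def target(scale: float) -> np.ndarray:
        vals = np.zeros(model.n_dofs)
        for kind, ids, bc in entries:
            if kind == "fixed":
                for k, comp in enumerate(bc.components):
                    vals[3 * ids + comp] = scale * bc.values[k]
            elif kind == "field":
                for comp in range(3):
                    vals[3 * ids + comp] = scale * bc.values[:, comp]
            elif kind == "chain":
                # compose rotations joint by joint; pivots ride on the chain
                Rtot = np.eye(3)
                ttot = np.zeros(3)
                shifts = bc.axial_shifts or [0.0] * len(bc.node_sets)
                for set_name, pivot, ang, shift in zip(
                    bc.node_sets, bc.pivots, bc.angles_deg, shifts
                ):
                    g = Rtot @ np.asarray(pivot, dtype=float) + ttot
                    Rj = _rotation_matrix(bc.axis, np.deg2rad(scale * ang))
                    ttot = Rj @ (ttot - g) + g
                    Rtot = Rj @ Rtot
                    ttot = ttot - scale * shift * (Rtot @ np.array([0.0, 1.0, 0.0]))
                    sids = model.mesh.node_sets[set_name]
                    disp = model.mesh.nodes[sids] @ Rtot.T + ttot - model.mesh.nodes[sids]
                    for comp in range(3):
                        vals[3 * sids + comp] = disp[:, comp]
            else:
                R = _rotation_matrix(bc.axis, np.deg2rad(scale * bc.angle_deg))
                c = np.asarray(bc.center, dtype=float)
                disp = (X[ids] - c) @ R.T + c - X[ids]
                for comp in range(3):
                    vals[3 * ids + comp] = disp[:, comp]
        return vals

    return mask, target


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def solve_static(model: Model, load_case: LoadCase, opts: SolverOptions | None = None) -> SolutionState:
    """Newton-Raphson with incremental load stepping; deterministic.

    Raises :class:`NonConvergenceError` with the failing step and residual
    history, :class:`SingularSystemError` for insufficient constraints, and
    :class:`CavityConstraintError` if a volume constraint fails to close.
    """
    opts = opts or SolverOptions()
    asm = _Assembler(model, load_case)
    asm.ground_spring = opts.ground_spring
    mask, target = _prescribed(model, load_case)
    free = np.nonzero(~mask)[0]
    # displacement dofs come first in `free`; cavity multipliers follow.  The
    # multiplier rows/columns are dense (a cavity couples every surface
    # node), which destroys sparse-LU orderings, so they are eliminated by a
    # small Schur complement instead.
    n_free_disp = int(np.searchsorted(free, 3 * model.mesh.n_nodes))
    u = np.zeros(model.n_dofs)
    n_steps = load_case.n_load_steps or opts.n_load_steps
    log = []
    snapshots = []
    last = None

    n = model.mesh.n_nodes
    scales = load_case.schedule or [k / n_steps for k in range(1, n_steps + 1)]
    if any(s <= 0 or s > 1 for s in scales) or any(
        b <= a for a, b in zip(scales, scales[1:])
    ):
        raise ValueError("schedule must be strictly increasing within (0, 1]")
    # work queue of load scales; a failing step is bisected automatically
    queue = [(s, 0) for s in scales]
    step = 0
    prev_u = u.copy()
    prev_prev = None  # (scale, u) of the step before the previous one
    prev_scale = 0.0
    while queue:
        s, depth = queue.pop(0)
        step += 1
        if load_case.predictor is not None:
            guess = np.asarray(load_case.predictor(s), dtype=float).reshape(n, 3)
            u[: 3 * n] = guess.ravel()
        elif prev_prev is not None and prev_scale > prev_prev[0]:
            # linear extrapolation of the converged path as the initial guess
            fac = (s - prev_scale) / (prev_scale - prev_prev[0])
            u = prev_u + fac * (prev_u - prev_prev[1])
        tv = target(s)
        u[mask] = tv[mask]
        history = []
        converged = False
        accepted = True
        last_inversion = ""


        def _bisect(exc):
            import os

            if os.environ.get("SPINEFE_DEBUG"):
                print(f"[spinefe] step {step} scale {s:.4f} failed: {exc}; bisecting")
            if depth >= 5 or (s - prev_scale) < 1e-4:
                raise exc
            queue.insert(0, (s, depth))
            queue.insert(0, (0.5 * (prev_scale + s), depth + 1))

        for it in range(opts.max_iterations):
            try:
                R, trip, ref, vols, f_ext = asm.assemble(u, s, want_K=True)
            except (InvertedElementError, ValueError) as exc0:
                # the step-start (predictor/prescribed) state is inverted
                _bisect(NonConvergenceError(str(exc0), step, history))
                u = prev_u.copy()
                converged = None  # handled via bisection
                break
            res = float(np.linalg.norm(R[free]))
            history.append(res)
            import os as _os

            if _os.environ.get("SPINEFE_DEBUG"):
                print(f"[spinefe] step {step} it {it} res {res:.3e} ref {ref:.3e}", flush=True)
            if not np.isfinite(res) or res > 1e10 * max(history[0], 1.0):
                raise SingularSystemError(
                    f"diverged at step {step}: insufficient constraints or "
                    f"singular system (residual {res:.3e})"
                )
            tol_abs = opts.newton_tol * max(ref, 1.0)
            drift_ok = all(
                abs(vols[c.name] - model.reference_volumes[c.name])
                <= opts.volume_tol * model.reference_volumes[c.name]
                for c in model.cavities
                if c.mode == "incompressible"
            )
            if (res <= tol_abs or len(free) == 0) and drift_ok:
                converged = True
                last = (R, vols, f_ext)
                break
            K = sp.csr_matrix(
                (trip[2], (trip[0], trip[1])), shape=(model.n_dofs, model.n_dofs)
            )
            Kff = K[free][:, free].tocsc()
            if opts.stabilization > 0.0:
                d = np.abs(Kff.diagonal())
                shift = opts.stabilization * (d[d > 0].mean() if np.any(d > 0) else 1.0)
                Kff = Kff + shift * sp.identity(len(free), format="csc")
            try:
                du = _block_solve(Kff, -R[free], n_free_disp)
            except RuntimeError:
                # singular: one stabilization retry, then report
                d = np.abs(Kff.diagonal())
                shift = 1e-8 * (d[d > 0].mean() if np.any(d > 0) else 1.0)
                try:
                    du = _block_solve(
                        Kff + shift * sp.identity(len(free), format="csc"),
                        -R[free],
                        n_free_disp,
                    )
                except RuntimeError as exc:
                    raise SingularSystemError(
                        f"singular tangent at step {step} (insufficient constraints?)"
                    ) from exc
            if not np.all(np.isfinite(du)):
                raise SingularSystemError(f"non-finite Newton update at step {step}")
            if opts.max_update is not None:
                big = float(np.abs(du).max())
                if big > opts.max_update:
                    du = du * (opts.max_update / big)

            # full Newton step, backtracking only on element inversion or a
            # non-finite residual (a force-residual merit function falsely
            # rejects valid steps of slender bending-stretching structures);
            # optional classic backtracking via opts.line_search
            t = 1.0
            accepted = False
            while t >= 1.0 / 64.0:
                u_try = u.copy()
                u_try[free] += t * du
                try:
                    R2, _, _, _, _ = asm.assemble(u_try, s, want_K=False)
                    res2 = float(np.linalg.norm(R2[free]))
                except (InvertedElementError, ValueError) as exc_ls:
                    # inverted element or collapsed cavity: shorten the step
                    last_inversion = str(exc_ls)
                    t *= 0.5
                    continue
                if not np.isfinite(res2):
                    t *= 0.5
                    continue
                if opts.line_search and res2 > res and res2 > tol_abs and t > 1.0 / 16.0:
                    t *= 0.5
                    continue
                accepted = True
                break
            if not accepted:
                break
            u = u_try
        if converged is None:
            continue
        if not converged:
            exc: RuntimeError
            if not accepted:
                exc = NonConvergenceError(
                    f"element inversion during step {step} ({last_inversion})",
                    step,
                    history,
                )
            else:
                try:
                    R, _, ref, vols, _ = asm.assemble(u, s, want_K=False)
                    res = float(np.linalg.norm(R[free]))
                except (InvertedElementError, ValueError):
                    res = np.inf
                if res <= opts.newton_tol * max(ref, 1.0):
                    # force residual closed but a cavity constraint did not
                    exc = CavityConstraintError(
                        f"cavity volume constraint not met at step {step}"
                    )
                else:
                    exc = NonConvergenceError(
                        f"Newton did not converge at step {step} "
                        f"(residual {history[-1]:.3e} after {len(history)} iterations)",
                        step,
                        history,
                    )
            _bisect(exc)
            u = prev_u.copy()
            continue
        prev_prev = (prev_scale, prev_u)
        prev_u = u.copy()
        prev_scale = s
        step_rec = {
            "scale": s,
            "iterations": len(history),
            "residuals": history,
            "cavity": {},
        }
        for c in model.cavities:
            V0 = model.reference_volumes[c.name]
            V = last[1][c.name]
            if c.mode == "incompressible":
                p = u[model.cavity_dof(c.name)]
            else:
                p = s * asm.cavity_p_final[c.name]
            step_rec["cavity"][c.name] = {
                "V": V,
                "p": p,
                "drift": abs(V - V0) / V0,
            }
        log.append(step_rec)
        if opts.store_steps:
            Rk, volsk, fek = last
            nn = model.mesh.n_nodes
            pres3 = mask[: 3 * nn].reshape(nn, 3)
            reac = np.zeros((nn, 3))
            Rn = Rk[: 3 * nn].reshape(nn, 3)
            reac[pres3] = Rn[pres3]
            cst = {}
            for c in model.cavities:
                V0 = model.reference_volumes[c.name]
                pk = (
                    u[model.cavity_dof(c.name)]
                    if c.mode == "incompressible"
                    else s * asm.cavity_p_final[c.name]
                )
                cst[c.name] = cav.CavityState(pk, volsk[c.name], V0)
            snapshots.append(
                SolutionState(
                    model=model,
                    u=u[: 3 * nn].reshape(nn, 3).copy(),
                    cavity_states=cst,
                    reactions=reac,
                    prescribed=pres3,
                    log=[step_rec],
                    external_force=fek[: 3 * nn].reshape(nn, 3).copy(),
                )
            )

    R, vols, f_ext = last
    n = model.mesh.n_nodes
    reactions = np.zeros((n, 3))
    pres3 = mask[: 3 * n].reshape(n, 3)
    Rn = R[: 3 * n].reshape(n, 3)
    reactions[pres3] = Rn[pres3]
    cavity_states = {}
    for c in model.cavities:
        V0 = model.reference_volumes[c.name]
        if c.mode == "incompressible":
            p = u[model.cavity_dof(c.name)]
        else:
            p = asm.cavity_p_final[c.name]
        cavity_states[c.name] = cav.CavityState(p, vols[c.name], V0)
    return SolutionState(
        model=model,
        u=u[: 3 * n].reshape(n, 3).copy(),
        cavity_states=cavity_states,
        reactions=reactions,
        prescribed=pres3,
        log=log,
        external_force=f_ext[: 3 * n].reshape(n, 3).copy(),
        steps=snapshots,
    )


# ---------------------------------------------------------------------------
# extractors
# ---------------------------------------------------------------------------


def reaction_force(solution: SolutionState, node_set: str) -> np.ndarray:
    """Sum of constraint forces (N) over a fully constrained node set."""
    ids = solution.model.mesh.node_sets[node_set]
    if not solution.prescribed[ids].all():
        raise ValueError(f"node set {node_set!r} is not fully constrained")
    return solution.reactions[ids].sum(axis=0)


def bending_moment(reaction: np.ndarray, moment_arm_mm: float) -> float:
    """M = F_y * d, returned in N m (inputs N and mm)."""
    if moment_arm_mm < 0:
        raise ValueError("moment arm must be non-negative")
    Fy = float(np.asarray(reaction).reshape(3)[1])
    return Fy * moment_arm_mm / 1000.0


def center_of_gravity(solution: SolutionState) -> np.ndarray:
    """Deformed centre of gravity, uniform density per part (solids by
    volume, membranes by thickness * area)."""
    model = solution.model
    coords = model.mesh.nodes + solution.u
    tot_w = 0.0
    acc = np.zeros(3)
    for b in model.mesh.blocks:
        if b.kind in ("tet4", "tet10"):
            x = coords[b.connectivity[:, :4]]
            w = np.abs(np.linalg.det(x[:, 1:] - x[:, :1]) / 6.0)
            cen = x.mean(axis=1)
        elif b.kind == "tri3_membrane":
            x = coords[b.connectivity]
            a = 0.5 * np.linalg.norm(
                np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1
            )
            w = a * (model.materials[b.name].thickness or 1.0)
            cen = x.mean(axis=1)
        else:
            continue
        acc += (w[:, None] * cen).sum(axis=0)
        tot_w += w.sum()
    return acc / tot_w


def _solid_data_by_name(model: Model):
    return {
        bd.name: bd for bd in _build_block_data(model) if isinstance(bd, _SolidData)
    }


def block_stress(solution: SolutionState, block_name: str):
    """Element-averaged Cauchy stress (ne,3,3) for a solid or membrane block."""
    model = solution.model
    for bd in _build_block_data(model):
        if bd.name == block_name and isinstance(bd, (_SolidData, _MembraneData)):
            return bd.stress_strain(solution.u)[0]
    raise KeyError(f"no stress-bearing block named {block_name!r}")


def block_green_strain(solution: SolutionState, block_name: str):
    model = solution.model
    for bd in _build_block_data(model):
        if bd.name == block_name and isinstance(bd, (_SolidData, _MembraneData)):
            return bd.stress_strain(solution.u)[1]
    raise KeyError(f"no strain-bearing block named {block_name!r}")


def bar_axial_forces(solution: SolutionState, block_name: str) -> np.ndarray:
    """Axial force (N, tension positive) in each bar of a bar2 block."""
    for bd in _build_block_data(solution.model):
        if bd.name == block_name and isinstance(bd, _BarData):
            return bd.axial_forces(solution.u)
    raise KeyError(f"no bar block named {block_name!r}")


def max_principal_strain(solution: SolutionState, block_name: str) -> float:
    """Largest principal Green-Lagrange strain over a block (objective: zero
    for rigid-body motion)."""
    E = block_green_strain(solution, block_name)
    return float(np.linalg.eigvals(E).real.max())


def surface_average_normal_stress(
    solution: SolutionState,
    surface: str | np.ndarray,
    block: str | None = None,
) -> float:
    """Area-weighted average of n . sigma . n over a facet set, with
    compression reported positive (reads as a pressure).

    Element stresses carry an O(h) centroid-offset bias at a boundary, so the
    average is recovered by layered extrapolation: elements of the owning
    solid block(s) are binned by distance to the surface, each bin's
    volume-weighted mean normal stress is computed (large samples cancel the
    per-element noise of structured tet splits), and a quadratic fit through
    the first three layer means is evaluated at zero distance.  ``block``
    restricts facet ownership when a facet lies on an interface.
    """
    from scipy.spatial import cKDTree

    model = solution.model
    if isinstance(surface, str):
        facets = model.mesh.surface_sets[surface]
    else:
        facets = np.asarray(surface, dtype=np.int64).reshape(-1, 3)
    if len(facets) == 0:
        raise ValueError("empty surface set")

    solids = _solid_data_by_name(model)
    if block is not None:
        solids = {block: solids[block]}

    # facet -> owning (block, element)
    face_owner: dict[tuple, tuple[str, int]] = {}
    for name, bd in solids.items():
        conn = bd.conn[:, :4]
        from .mesh import _TET_FACES  # reuse the face table

        fcs = conn[:, _TET_FACES].reshape(-1, 3)
        eids = np.repeat(np.arange(len(conn)), 4)
        for k, e in zip(map(tuple, np.sort(fcs, axis=1)), eids):
            face_owner.setdefault(k, (name, int(e)))

    owner_of_facet = []
    owner_elem = []
    for f in facets:
        k = tuple(np.sort(f))
        if k not in face_owner:
            raise ValueError("facet has no adjacent solid element in the given block(s)")
        owner_of_facet.append(face_owner[k][0])
        owner_elem.append(face_owner[k][1])
    owner_of_facet = np.array(owner_of_facet)
    owner_elem = np.array(owner_elem)

    X = model.mesh.nodes
    coords = X + solution.u
    # all sampling geometry lives in the deformed configuration (reference
    # distances against deformed normals would scramble the layers under
    # large rotations)
    xf_def = coords[facets]
    fcen_def = xf_def.mean(axis=1)
    nvec = np.cross(xf_def[:, 1] - xf_def[:, 0], xf_def[:, 2] - xf_def[:, 0])
    areas = 0.5 * np.linalg.norm(nvec, axis=1)
    nhat = nvec / (2.0 * areas[:, None])

    total = 0.0
    total_area = 0.0
    for name in np.unique(owner_of_facet):
        sel_f = owner_of_facet == name
        tree = cKDTree(fcen_def[sel_f])
        bd = solids[name]
        sig, _ = bd.stress_strain(solution.u)
        cen = coords[bd.conn[:, :4]].mean(axis=1)
        vol = bd.volumes()
        _, fi = tree.query(cen)
        n_loc = nhat[sel_f][fi]
        # normal distance to the nearest facet plane (not to its centroid)
        dvec = cen - fcen_def[sel_f][fi]
        d = np.abs(np.einsum("ei,ei->e", dvec, n_loc))
        # keep only elements within the lateral footprint of their nearest
        # facet, else elements far along the surface plane pollute the layers
        d_tan2 = np.einsum("ei,ei->e", dvec, dvec) - d**2
        falen = np.sqrt(areas[sel_f][fi])
        in_foot = d_tan2 <= (1.6 * falen) ** 2
        ns_e = np.einsum("ei,eij,ej->e", n_loc, sig, n_loc)
        d_all = d
        d, ns_e, vol_f = d[in_foot], ns_e[in_foot], vol[in_foot]
        # layer width from the facet-owning elements: a tet with a face on the
        # surface has its centroid at one quarter of the layer height
        d_own = np.abs(
            np.einsum(
                "ei,ei->e",
                cen[owner_elem[sel_f]] - fcen_def[sel_f],
                nhat[sel_f],
            )
        )
        h0 = 4.0 * float(np.median(d_own))
        if h0 <= 0:
            h0 = 1.5 * float(np.mean(vol) ** (1.0 / 3.0))
        means, dmeans = [], []
        for k in range(3):
            in_bin = (d >= k * h0) & (d < (k + 1) * h0)
            if in_bin.sum() == 0:
                break
            w = vol_f[in_bin]
            means.append(float(np.average(ns_e[in_bin], weights=w)))
            dmeans.append(float(np.average(d[in_bin], weights=w)))
        if len(means) == 3:  # quadratic Lagrange extrapolation to d = 0
            d1, d2, d3 = dmeans
            l1 = d2 * d3 / ((d1 - d2) * (d1 - d3))
            l2 = d1 * d3 / ((d2 - d1) * (d2 - d3))
            l3 = d1 * d2 / ((d3 - d1) * (d3 - d2))
            val = l1 * means[0] + l2 * means[1] + l3 * means[2]
        elif len(means) == 2:
            val = means[0] + (means[1] - means[0]) * (0.0 - dmeans[0]) / (
                dmeans[1] - dmeans[0]
            )
        else:
            val = means[0]
        a_blk = float(areas[sel_f].sum())
        total += val * a_blk
        total_area += a_blk
    return -total / total_area  # compression positive
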