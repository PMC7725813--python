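"""Constitutive laws: isotropic elasticity and quasi-incompressible neo-Hookean.

Units: MPa for moduli and stresses, mm for thicknesses.

The quasi-incompressible law is the standard two-field (displacement +
pressure) neo-Hookean: deviatoric energy (mu/2)(I1_bar - 3) with the
hydrostatic pressure supplied as an independent field, so nu -> 0.5 never
enters a displacement-only stiffness (no volumetric locking by raw bulk
modulus).  At a converged state the constitutive pressure equals the
independent pressure field value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialLaw",
    "DeformationState",
    "shear_modulus",
    "bulk_modulus",
    "evaluate_stress",
    "strain_energy",
]

KINDS = ("linear_elastic", "neo_hookean_incompressible")


def shear_modulus(E: float, nu: float) -> float:
    """mu = E / (2 (1 + nu)).  Rejects the incompressible limit nu >= 0.5."""
    if E <= 0:
        raise ValueError("E must be positive")
    if nu >= 0.5:
        raise ValueError(
            "nu >= 0.5: the incompressible limit is handled by the mixed "
            "formulation, not by a shear modulus"
        )
    if nu <= -1:
        raise ValueError("nu must exceed -1")
    return E / (2.0 * (1.0 + nu))


def bulk_modulus(E: float, nu: float) -> float:
    """kappa = E / (3 (1 - 2 nu)), used as the pressure-field compliance."""
    if not (-1 < nu < 0.5):
        raise ValueError("nu must lie in (-1, 0.5)")
    return E / (3.0 * (1.0 - 2.0 * nu))


@dataclass(frozen=True)
class MaterialLaw:
    """Isotropic material parameters, optionally with a membrane thickness."""

    kind: str
    E: float  # Young's modulus, MPa
    nu: float  # Poisson ratio
    thickness: float | None = None  # mm, membrane use only

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown material kind {self.kind!r}")
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not (-1 < self.nu < 0.5):
            raise ValueError("nu must lie in (-1, 0.5)")
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError("thickness must be positive")

    @property
    def mu(self) -> float:
        return shear_modulus(self.E, self.nu)

    @property
    def kappa(self) -> float:
        return bulk_modulus(self.E, self.nu)

    @property
    def lame_lambda(self) -> float:
        return self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))


@dataclass
class DeformationState:
    """Pointwise kinematic state: deformation gradient plus pressure field."""

    F: np.ndarray = field(default_factory=lambda: np.eye(3))
    p_bar: float = 0.0  # independent hydrostatic pressure field value, MPa

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float).reshape(3, 3)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))


def strain_energy(law: MaterialLaw, state: DeformationState) -> float:
    """Stored energy density per reference volume (deviatoric part only for
    the mixed law; the pressure-volume coupling p (J - 1) is added by the
    element that owns the pressure unknown)."""
    F = state.F
    J = state.J
    if J <= 0:
        raise ValueError("J <= 0: inverted state")
    if law.kind == "neo_hookean_incompressible":
        I1b = J ** (-2.0 / 3.0) * np.tensordot(F, F)
        return 0.5 * law.mu * (I1b - 3.0) + state.p_bar * (J - 1.0)
    eps = 0.5 * (F + F.T) - np.eye(3)
    lam, mu = law.lame_lambda, law.mu
    return 0.5 * lam * np.trace(eps) ** 2 + mu * np.tensordot(eps, eps)


def evaluate_stress(law: MaterialLaw, state: DeformationState) -> np.ndarray:
    """Cauchy stress (3x3, MPa) at a pointwise deformation state.

    neo_hookean_incompressible: sigma = mu J^(-5/3) dev(F F^T) + p I with the
    hydrostatic pressure p taken from the independent field value, so
    trace(sigma)/3 = p whenever the deviatoric part vanishes.
    linear_elastic: small-strain Hooke stress from eps = sym(F) - I.
    """
    F = state.F
    J = state.J
    if J <= 0:
        raise ValueError("J <= 0: inverted element")
    if law.kind == "neo_hookean_incompressible":
        b = F @ F.T
        dev_b = b - np.trace(b) / 3.0 * np.eye(3)
        return law.mu * J ** (-5.0 / 3.0) * dev_b + state.p_bar * np.eye(3)
    eps = 0.5 * (F + F.T) - np.eye(3)
    lam, mu = law.lame_lambda, law.mu
    return lam * np.trace(eps) * np.eye(3) + 2.0 * mu * eps
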