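"""Incompressible one-term modified Ogden constitutive model.

The strain-energy density is

    psi(l1, l2, l3) = (2*mu / alpha**2) * (l1**alpha + l2**alpha + l3**alpha - 3)

with classical shear modulus ``mu`` (Pa) and dimensionless nonlinearity
parameter ``alpha``.  At ``alpha = 2`` the model reduces to the
incompressible neo-Hookean solid.  Under uniaxial loading of an
incompressible, isotropic sample the lateral stretches are
``l1 = l2 = lam**-0.5`` and the lateral traction-free condition fixes the
hydrostatic pressure, leaving the closed-form axial nominal (first Piola)
stress

    Pzz(lam) = (2*mu / alpha) * (lam**(alpha - 1) - lam**(-alpha/2 - 1))

which is negative in compression (``lam < 1``) for ``mu > 0``.  The
small-strain slope dPzz/dlam at ``lam = 1`` is ``3*mu``, which under
incompressibility (Poisson ratio 0.5) is the apparent Young's modulus
``E_app = 2*mu*(1 + nu) = 3*mu`` — the stiffness summary reported per
experimental condition.

The full spectral Piola stress (eigenvector dyads of the Cauchy-Green
tensors) collapses to the scalar expression above because the uniaxial
deformation gradient is diagonal; a finite-difference oracle in the test
suite guards this reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ALPHA_MIN",
    "OgdenParameters",
    "ModulusReport",
    "strain_energy",
    "uniaxial_strain_energy",
    "hydrostatic_pressure",
    "uniaxial_nominal_stress",
    "apparent_young_modulus",
]

#: Smallest admissible |alpha|.  The energy divides by alpha**2, so the
#: parameterization is singular at alpha = 0 (the neo-Hookean-like regime
#: is reached at alpha = 2, not alpha -> 0).
ALPHA_MIN = 0.01


@dataclass(frozen=True)
class OgdenParameters:
    """Material parameters (mu, alpha) of the one-term modified Ogden model.

    Attributes
    ----------
    mu : float
        Classical shear modulus, Pa. Must be positive.
    alpha : float
        Dimensionless nonlinearity parameter. ``|alpha| >= ALPHA_MIN``;
        soft brain-like tissues commonly fit with negative alpha.
    """

    mu: float
    alpha: float

    def __post_init__(self):
        if not np.isfinite(self.mu) or self.mu <= 0:
            raise ValueError(f"shear modulus mu must be finite and > 0, got {self.mu}")
        if not np.isfinite(self.alpha) or abs(self.alpha) < ALPHA_MIN:
            raise ValueError(
                f"alpha must be finite with |alpha| >= {ALPHA_MIN}, got {self.alpha}"
            )


@dataclass(frozen=True)
class ModulusReport:
    """Apparent Young's modulus under the incompressibility constraint.

    ``e_app = 3 * mu`` exactly; the Poisson ratio is fixed at 0.5.
    """

    e_app: float
    nu: float = 0.5


def _check_stretch(lam: np.ndarray | float, name: str = "lambda") -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError(f"{name} must be finite and > 0")
    return lam


def strain_energy(l1, l2, l3, params: OgdenParameters):
    """Strain-energy density psi (J/m^3) for a principal-stretch triple.

    Symmetric in (l1, l2, l3); zero in the undeformed reference
    configuration l1 = l2 = l3 = 1.
    """
    l1 = _check_stretch(l1, "l1")
    l2 = _check_stretch(l2, "l2")
    l3 = _check_stretch(l3, "l3")
    a = params.alpha
    return (2.0 * params.mu / a**2) * (l1**a + l2**a + l3**a - 3.0)


def uniaxial_strain_energy(lam, params: OgdenParameters):
    """Energy along the incompressible uniaxial path, psi_uni(lam).

    With lateral stretches lam**-0.5 forced by incompressibility:
    ``psi_uni = (2*mu/alpha**2) * (2*lam**(-alpha/2) + lam**alpha - 3)``.
    Its derivative with respect to lam is the uniaxial nominal stress.
    """
    lam = _check_stretch(lam)
    a = params.alpha
    return (2.0 * params.mu / a**2) * (2.0 * lam ** (-a / 2.0) + lam**a - 3.0)


def hydrostatic_pressure(lam, params: OgdenParameters):
    """Lagrange-multiplier pressure p (Pa) from the lateral traction-free BC.

    ``p = (2*mu/alpha) * lam**(-alpha/2)``; substituting it into the
    spectral Piola stress makes the lateral components vanish.
    """
    lam = _check_stretch(lam)
    a = params.alpha
    return (2.0 * params.mu / a) * lam ** (-a / 2.0)


def uniaxial_nominal_stress(lam, params: OgdenParameters):
    """Axial nominal (first Piola) stress Pzz (Pa) at stretch ``lam``.

    ``Pzz = (2*mu/alpha) * (lam**(alpha-1) - lam**(-alpha/2 - 1))``.
    Negative in compression (lam < 1) for mu > 0; at alpha = 2 it reduces
    to the neo-Hookean form ``mu * (lam - lam**-2)``.
    """
    lam = _check_stretch(lam)
    a = params.alpha
    return (2.0 * params.mu / a) * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))


def apparent_young_modulus(mu: float) -> ModulusReport:
    """Apparent Young's modulus E_app = 3*mu (Pa) at Poisson ratio 0.5."""
    if not np.isfinite(mu) or mu <= 0:
        raise ValueError(f"mu must be finite and > 0, got {mu}")
    return ModulusReport(e_app=3.0 * mu, nu=0.5)
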