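"""Constitutive layer for the dielectric-elastomer membrane.

The membrane (3M VHB 4910 acrylic elastomer) is modeled as an incompressible
Yeoh solid,

    W(I1) = C10 (I1 - 3) + C20 (I1 - 3)^2 + C30 (I1 - 3)^3,

with I1 the first invariant of the left Cauchy-Green tensor.  An applied
voltage V across a membrane of thickness t squeezes it through the Maxwell
stress

    sigma_M = eps0 * pr * (V / t)^2,

acting as an equibiaxial reduction of the in-plane true stresses.

Units: Yeoh constants are stored in MPa exactly as tabulated for VHB 4910;
electrical quantities are SI (V, m) and the Maxwell stress is returned in Pa.
All functions here are pure and accept NumPy arrays where a stretch or
invariant is expected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "YeohMaterial",
    "StretchState",
    "VHB4910",
    "strain_energy",
    "equibiaxial_cauchy_stress",
    "maxwell_stress",
    "STRETCH_VALIDITY_WINDOW",
]

#: Stretch window over which the cubic Yeoh fit for VHB 4910 is trusted.
#: C20 < 0 makes dW/dI1 turn over at large stretch; the device never
#: operates beyond lambda ~ 3.2, so [1, 4] is generous.
STRETCH_VALIDITY_WINDOW = (1.0, 4.0)


@dataclass(frozen=True)
class YeohMaterial:
    """Yeoh constants plus dielectric parameters of the membrane.

    Parameters
    ----------
    c10, c20, c30 : float
        Yeoh coefficients, MPa.
    eps0 : float
        Vacuum permittivity, A s / (V m).
    pr : float
        Relative dielectric constant (dimensionless), taken
        stretch-independent.
    """

    c10: float = 0.0693
    c20: float = -8.88e-4
    c30: float = 16.7e-6
    eps0: float = 8.85e-12
    pr: float = 4.7

    def __post_init__(self) -> None:
        if self.c10 <= 0:
            raise ValueError(f"c10 must be positive, got {self.c10}")
        if self.eps0 <= 0:
            raise ValueError(f"eps0 must be positive, got {self.eps0}")
        if self.pr <= 0:
            raise ValueError(f"pr must be positive, got {self.pr}")


#: Built-in default profile: the published VHB 4910 parameter set.
VHB4910 = YeohMaterial()


@dataclass(frozen=True)
class StretchState:
    """Equibiaxial incompressible stretch state.

    For in-plane stretch ``lam`` applied equally in both directions the
    thickness stretch is ``lam**-2`` and the first invariant is
    ``I1 = 2 lam^2 + lam^-4``, which is >= 3 with equality only at lam = 1.
    """

    lam: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"stretch must be positive, got {self.lam}")

    @property
    def i1(self) -> float:
        return first_invariant_equibiaxial(self.lam)


def first_invariant_equibiaxial(lam):
    """I1 = 2 lam^2 + lam^-4 for equibiaxial incompressible stretch."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    out = 2.0 * lam**2 + lam**-4
    return float(out) if out.ndim == 0 else out


def strain_energy(mat: YeohMaterial, i1):
    """Yeoh strain-energy density (MPa) at first invariant ``i1``.

    Raises ``ValueError`` for i1 < 3, which is unreachable for a real
    incompressible deformation.
    """
    i1 = np.asarray(i1, dtype=float)
    if np.any(i1 < 3.0 - 1e-12):
        raise ValueError("first invariant must be >= 3")
    x = np.maximum(i1 - 3.0, 0.0)
    out = mat.c10 * x + mat.c20 * x**2 + mat.c30 * x**3
    return float(out) if out.ndim == 0 else out


def _dw_di1(mat: YeohMaterial, i1):
    """W1 = dW/dI1 = C10 + 2 C20 (I1-3) + 3 C30 (I1-3)^2."""
    x = np.asarray(i1, dtype=float) - 3.0
    return mat.c10 + 2.0 * mat.c20 * x + 3.0 * mat.c30 * x**2


def equibiaxial_cauchy_stress(mat: YeohMaterial, lam):
    """In-plane true (Cauchy) stress, MPa, for equibiaxial stretch ``lam``.

    From incompressibility and vanishing through-thickness stress,

        sigma = 2 (lam^2 - lam^-4) * W1(I1),   W1 = dW/dI1.

    Zero at lam = 1 and strictly increasing over the validity window
    [1, 4]; evaluation outside the window triggers a warning (the cubic
    fit is not trusted there) but still returns the formula value.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    lo, hi = STRETCH_VALIDITY_WINDOW
    if np.any(lam < lo - 1e-12) or np.any(lam > hi + 1e-12):
        warnings.warn(
            f"stretch outside the fitted validity window {STRETCH_VALIDITY_WINDOW}",
            stacklevel=2,
        )
    i1 = 2.0 * lam**2 + lam**-4
    out = 2.0 * (lam**2 - lam**-4) * _dw_di1(mat, i1)
    return float(out) if out.ndim == 0 else out


def maxwell_stress(mat: YeohMaterial, voltage, thickness):
    """Maxwell (electrostatic) compressive stress, Pa.

    sigma_M = eps0 * pr * (V / t)^2 depends on voltage and thickness only
    through the electric field E = V / t.
    """
    voltage = np.asarray(voltage, dtype=float)
    thickness = np.asarray(thickness, dtype=float)
    if np.any(thickness <= 0):
        raise ValueError("thickness must be positive")
    if np.any(voltage < 0):
        raise ValueError("voltage must be non-negative")
    out = mat.eps0 * mat.pr * (voltage / thickness) ** 2
    return float(out) if out.ndim == 0 else out
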