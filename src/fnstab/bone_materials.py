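"""Hounsfield-based bone material mapping and the implant material card.

Apparent density is estimated from CT attenuation as
``rho [g/cm^3] = 0.000968*HU + 0.5`` and converted to an isotropic linear
elastic modulus by the two-branch power law

    rho <  1.2:  E = 2014 * rho**2.5  [MPa],  nu = 0.20
    rho >= 1.2:  E = 1763 * rho**3.2  [MPa],  nu = 0.32

The branch point is assigned to the high branch (the law as published
leaves rho == 1.2 exactly undefined); the ~0.6 % modulus jump across the
branch is left as-is.  The implant is Ti-6Al-7Nb titanium alloy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialCard",
    "MaterialMap",
    "hu_to_density",
    "density_to_elasticity",
    "implant_material",
    "assign_materials",
    "DENSITY_BRANCH_G_CM3",
]

DENSITY_BRANCH_G_CM3 = 1.2


@dataclass(frozen=True)
class MaterialCard:
    youngs_modulus_MPa: float
    poissons_ratio: float
    density_g_cm3: float | None = None
    yield_strength_MPa: float | None = None

    def __post_init__(self):
        if not self.youngs_modulus_MPa > 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 < self.poissons_ratio < 0.5):
            raise ValueError("Poisson's ratio must lie in (0, 0.5)")


def hu_to_density(hu):
    """Apparent density in g/cm^3 from Hounsfield units."""
    hu = np.asarray(hu, float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("non-finite Hounsfield value")
    out = 0.000968 * hu + 0.5
    return float(out) if out.ndim == 0 else out


def density_to_elasticity(rho):
    """(E [MPa], nu) from apparent density; vectorized over rho."""
    rho = np.asarray(rho, float)
    if not np.all(rho > 0):
        raise ValueError("density must be positive")
    high = rho >= DENSITY_BRANCH_G_CM3
    E = np.where(high, 1763.0 * rho**3.2, 2014.0 * rho**2.5)
    nu = np.where(high, 0.32, 0.20)
    if E.ndim == 0:
        return float(E), float(nu)
    return E, nu


def implant_material() -> MaterialCard:
    """Ti-6Al-7Nb card: E = 105 GPa, nu = 0.34, yield 800 MPa."""
    return MaterialCard(
        youngs_modulus_MPa=105_000.0,
        poissons_ratio=0.34,
        yield_strength_MPa=800.0,
    )


@dataclass
class MaterialMap:
    """Per-element isotropic elastic constants for a construct mesh."""

    E_MPa: np.ndarray
    nu: np.ndarray
    rho_g_cm3: np.ndarray  # NaN on implant elements

    def __len__(self) -> int:
        return len(self.E_MPa)

    def card(self, element: int) -> MaterialCard:
        rho = self.rho_g_cm3[element]
        if np.isnan(rho):
            return implant_material()
        return MaterialCard(
            youngs_modulus_MPa=float(self.E_MPa[element]),
            poissons_ratio=float(self.nu[element]),
            density_g_cm3=float(rho),
        )


def assign_materials(mesh, hu) -> MaterialMap:
    """Map a Hounsfield field through the density/elasticity laws on bone
    elements and assign the titanium card to implant elements.

    ``hu`` may be an HUField (values + element ids) or a plain array
    covering every bone element in mesh order.
    """
    n = mesh.n_elements
    bone = mesh.bone_mask()
    values = np.full(n, np.nan)
    if hasattr(hu, "element_ids"):
        values[hu.element_ids] = hu.values
    else:
        arr = np.asarray(hu, float)
        if arr.shape[0] == n:
            values[:] = arr
        else:
            idx = np.flatnonzero(bone)
            if arr.shape[0] != idx.size:
                raise ValueError("HU field length does not match bone element count")
            values[idx] = arr
    if np.any(~np.isfinite(values[bone])):
        missing = int(np.sum(~np.isfinite(values[bone])))
        raise ValueError(f"missing HU for {missing} bone element(s)")

    E = np.empty(n)
    nu = np.empty(n)
    rho = np.full(n, np.nan)
    if bone.any():
        rho_b = hu_to_density(values[bone])
        E_b, nu_b = density_to_elasticity(rho_b)
        E[bone], nu[bone], rho[bone] = E_b, nu_b, rho_b
    imp = ~bone
    card = implant_material()
    E[imp] = card.youngs_modulus_MPa
    nu[imp] = card.poissons_ratio
    return MaterialMap(E_MPa=E, nu=nu, rho_g_cm3=rho)
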