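"""Magneto-mechanical forces on and around the particle.

Covers three force paths relevant to mechanosensitive channel gating:

1. pulling force from an external laboratory field gradient, F = m·∇B
   (the negative control — bounded well below the ~1 pN gating threshold);
2. the inter-particle attraction of two saturated particles in contact,
   using the surface field gradient ∇B = 2·μ0·M_S/r of a uniformly
   magnetized sphere (can reach ~100 pN);
3. the repulsive diamagnetic force on the water-like membrane sitting in
   the particle's combined field and gradient, F/V = −|χ|·B·∇B/μ0, and the
   resulting flat-punch indentation d = 2(1−ν²)·r·(F/A)/E of the soft
   elastic half-space.

Spatial field variation is collapsed to the surface maximum everywhere
(the "maximum possible" convention): results are upper bounds, reported as
magnitudes with the orientation carried separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from .constants import VACUUM_PERMEABILITY
from .params import Membrane

__all__ = [
    "surface_field_gradient",
    "pole_field",
    "total_channel_field",
    "gradient_pull_force",
    "max_torque",
    "b_grad_b",
    "diamagnetic_force_density",
    "membrane_patch_force",
    "membrane_deformation",
    "PatchForce",
]


def surface_field_gradient(saturation_magnetization: float, radius: float) -> float:
    """Maximum field gradient at the surface of a saturated sphere, T/m.

    ∇B = 2·μ0·M_S / r — the radial decay rate of the dipole field evaluated
    at the particle surface.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    return 2.0 * VACUUM_PERMEABILITY * saturation_magnetization / radius


def pole_field(saturation_magnetization: float) -> float:
    """Field on the pole of a uniformly magnetized sphere, T.

    B_particle = (2/3)·μ0·M_S, the on-axis surface field of the equivalent
    dipole.
    """
    if saturation_magnetization < 0:
        raise ValueError("saturation magnetization must be non-negative")
    return (2.0 / 3.0) * VACUUM_PERMEABILITY * saturation_magnetization


def total_channel_field(b_external: float, b_particle: float) -> float:
    """Total field at the channel: scalar sum of external and particle
    fields (maximal-alignment convention), T."""
    if b_external < 0 or b_particle < 0:
        raise ValueError("fields must be non-negative")
    return b_external + b_particle


def gradient_pull_force(moment: float, gradient: float) -> float:
    """Pulling force magnitude F = m·∇B on a point moment, N."""
    if gradient < 0:
        raise ValueError("gradient must be non-negative")
    return moment * gradient


def max_torque(moment: float, b_field: float) -> float:
    """Maximum torque |m × B| = m·B (perpendicular geometry), N·m."""
    if b_field < 0:
        raise ValueError("b_field must be non-negative")
    return moment * b_field


def b_grad_b(b_total: float, gradient: float) -> float:
    """Diamagnetic driving parameter B·∇B, T²/m."""
    if b_total < 0 or gradient < 0:
        raise ValueError("inputs must be non-negative")
    return b_total * gradient


def diamagnetic_force_density(
    susceptibility: float, b_field: float, gradient: float
) -> float:
    """Diamagnetic body-force magnitude |χ|·B·∇B/μ0, N/m³.

    χ ≤ 0 for diamagnets; the force points down the gradient (repulsion
    from the particle). The sign convention is carried by the caller; this
    returns the magnitude.
    """
    if susceptibility > 0:
        raise ValueError("susceptibility must be diamagnetic (χ ≤ 0)")
    return abs(susceptibility) * b_grad_b(b_field, gradient) / VACUUM_PERMEABILITY


@dataclass(frozen=True)
class PatchForce:
    """Diamagnetic load on the membrane patch: total force (N) and the
    equivalent uniform pressure F/A (Pa). Oriented away from the particle."""

    force: float
    pressure: float
    repulsive: bool = True


def membrane_patch_force(force_density: float, membrane: Membrane) -> PatchForce:
    """Integrate the body force over the loaded shell of the patch.

    The force density is taken uniform over a disc of ``patch_radius``
    through ``loaded_thickness`` (the field and gradient fall off too
    steeply to load more than ~1 nm of membrane), so
    F = (F/V)·π·r²·t and F/A = (F/V)·t.
    """
    area = math.pi * membrane.patch_radius**2
    force = force_density * area * membrane.loaded_thickness
    pressure = force_density * membrane.loaded_thickness
    return PatchForce(force=force, pressure=pressure)


def membrane_deformation(pressure: float, membrane: Membrane) -> float:
    """Flat-punch indentation of the elastic half-space, m.

    d = 2·(1−ν²)·r·(F/A) / E for a uniform pressure F/A over a circular
    region of radius r on a half-space of Young's modulus E and Poisson
    ratio ν.
    """
    if membrane.young_modulus <= 0:
        raise ValueError("Young's modulus must be positive")
    nu = membrane.poisson_ratio
    return 2.0 * (1.0 - nu**2) * membrane.patch_radius * pressure / membrane.young_modulus
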