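"""Magneto-thermal mechanisms: magneto-caloric energy transfer and the
Einstein–de Haas effect.

Magneto-caloric: applying a field aligns the n cluster moments and lowers
the spin entropy by

    ΔS = n·k_B·[1 − x·coth(x) + ln(sinh(x)/x)],   x = (N/n)·m_Fe·B/(k_B·T),

which in an adiabatic process transfers ΔE = T·|ΔS| to the particle
lattice. At fixed B and T the transfer is maximized at an intermediate
cluster number: large clusters saturate (the bracket plateaus at
1 − ln(2x)) while many small clusters each contribute only ~x²/6.

Einstein–de Haas: reversing the particle moment m changes its spin angular
momentum by ΔL = 2m/γ (γ = e/m_e), which conservation converts into either
free rotation with kinetic energy ΔL²/(2I) (I = (2/5)·mass·r² for the
sphere) or, for a particle fixed in its protein cage, a torque ΔL/Δt on
the surrounding medium during the reversal time Δt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .constants import BOLTZMANN
from .params import EdHParams, FerritinParticle, SpinPartition, ThermalField
from .spin import reduced_field, saturation_moment, thermal_energy

__all__ = [
    "entropy_bracket",
    "entropy_change",
    "magnetocaloric_energy",
    "MagnetocaloricResult",
    "optimal_cluster_number",
    "particle_mass",
    "moment_of_inertia",
    "edh_delta_l",
    "edh_rotational_energy",
    "edh_specific_loss",
    "edh_torque",
]

_SMALL_X = 1e-3
_LARGE_X = 30.0  # sinh overflows near x ~ 709; switch to the log form well before


def entropy_bracket(x):
    """Per-cluster entropy change in units of k_B:
    1 − x·coth(x) + ln(sinh(x)/x). Always ≤ 0; −x²/6 for small x;
    → 1 − ln(2x) for large x.

    Evaluated piecewise for numerical stability: a series for small x
    (the direct form cancels catastrophically) and a log-sum form
    ln(sinh(x)/x) = x − ln(2x) + ln(1 − e^(−2x)) for large x (sinh
    overflows).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    out = np.empty_like(x)

    small = x < _SMALL_X
    large = x > _LARGE_X
    mid = ~small & ~large

    xs = x[small]
    out[small] = -(xs**2) / 6.0 + xs**4 / 60.0

    xm = x[mid]
    out[mid] = 1.0 - xm / np.tanh(xm) + np.log(np.sinh(xm) / xm)

    xl = x[large]
    # coth(x) ~ 1 to machine precision here
    out[large] = 1.0 - xl + (xl - np.log(2.0 * xl) + np.log1p(-np.exp(-2.0 * xl)))

    return out.item() if out.ndim == 0 else out


def entropy_change(
    particle: FerritinParticle, partition: SpinPartition, field: ThermalField
) -> float:
    """Spin-entropy change ΔS on applying the field, J/K (signed, ≤ 0)."""
    x = reduced_field(particle, partition, field)
    return partition.n_clusters * BOLTZMANN * entropy_bracket(x)


@dataclass(frozen=True)
class MagnetocaloricResult:
    """Magneto-caloric outcome for one (n, B, T) point."""

    n_clusters: int
    reduced_field: float
    entropy_change: float  # J/K, signed (≤ 0)
    energy_transfer: float  # J, T·|ΔS| ≥ 0
    ratio_to_kbt: float


def magnetocaloric_energy(
    particle: FerritinParticle, partition: SpinPartition, field: ThermalField
) -> MagnetocaloricResult:
    """Adiabatic energy transfer ΔE = T·|ΔS| to the particle lattice."""
    ds = entropy_change(particle, partition, field)
    de = field.temperature * abs(ds)
    return MagnetocaloricResult(
        n_clusters=partition.n_clusters,
        reduced_field=reduced_field(particle, partition, field),
        entropy_change=ds,
        energy_transfer=de,
        ratio_to_kbt=de / thermal_energy(field.temperature),
    )


def optimal_cluster_number(
    particle: FerritinParticle,
    field: ThermalField,
    candidate_ns: Iterable[int],
) -> int:
    """Candidate cluster number n maximizing the magneto-caloric transfer.

    Ties break deterministically to the smaller n.
    """
    candidates = sorted(set(int(n) for n in candidate_ns))
    if not candidates:
        raise ValueError("candidate_ns must be non-empty")
    best_n, best_e = candidates[0], -np.inf
    for n in candidates:
        e = magnetocaloric_energy(
            particle, SpinPartition(n_clusters=n), field
        ).energy_transfer
        if e > best_e:
            best_n, best_e = n, e
    return best_n


def particle_mass(particle: FerritinParticle) -> float:
    """Mass of the mineral core, kg (density × sphere volume)."""
    return particle.mineral_density * particle.volume


def moment_of_inertia(particle: FerritinParticle) -> float:
    """Rotational inertia of the solid sphere, I = (2/5)·mass·r², kg·m²."""
    return 0.4 * particle_mass(particle) * particle.radius**2


def edh_delta_l(moment: float, params: EdHParams) -> float:
    """Angular-momentum change ΔL = 2m/γ of a full moment reversal,
    kg·m²/s."""
    if moment < 0:
        raise ValueError("moment must be non-negative")
    return 2.0 * moment / params.gyromagnetic_ratio


def edh_rotational_energy(particle: FerritinParticle, params: EdHParams) -> float:
    """Rotational kinetic energy ΔL²/(2I) imparted by one full reversal of
    the saturation moment, J. Independent of the reversal time."""
    dl = edh_delta_l(saturation_moment(particle), params)
    return dl**2 / (2.0 * moment_of_inertia(particle))


def edh_specific_loss(particle: FerritinParticle, params: EdHParams) -> float:
    """Specific energy deposited per full AC cycle (two reversals),
    2·ΔE/mass, J/kg. Comparable to hyperthermia loss-per-cycle figures."""
    return 2.0 * edh_rotational_energy(particle, params) / particle_mass(particle)


def edh_torque(moment: float, params: EdHParams) -> float:
    """Torque ΔL/Δt = 2m/(γ·Δt) on the surroundings when the particle is
    fixed and cannot rotate, per half cycle, N·m."""
    if params.reversal_time <= 0:
        raise ValueError("reversal_time must be positive")
    return edh_delta_l(moment, params) / params.reversal_time
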