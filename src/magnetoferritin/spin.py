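"""Clusterparamagnetic magnetization of the ferritin core.

The N iron spins are grouped into n independent exchange-coupled clusters
of N/n spins. Each cluster behaves as one classical moment
m_cluster = (N/n)·m_Fe whose thermal average alignment in a field B at
temperature T follows the Langevin function

    L(x) = coth(x) − 1/x,    x = (N/n)·m_Fe·B / (k_B·T),

and the particle's total moment along the field is m_TOT = n·m_cluster·L(x).
n = 1 recovers superparamagnetism (a single macro-spin saturating in modest
fields); n = N recovers the weak classical paramagnet. The clusters are
assumed magnetically independent and the treatment is classical throughout
(no Brillouin quantization, no anisotropy barriers).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import BOLTZMANN
from .params import FerritinParticle, SpinPartition, ThermalField

__all__ = [
    "langevin",
    "reduced_field",
    "total_moment",
    "saturation_moment",
    "saturation_magnetization",
    "interaction_energy",
    "thermal_energy",
    "magnetization_curve",
]

# Below this |x| the direct form coth(x) - 1/x loses all precision to
# cancellation; the series x/3 - x^3/45 is exact to ~1e-20 there.
_SERIES_CUTOFF = 1e-4


def langevin(x):
    """Langevin function L(x) = coth(x) − 1/x.

    The classical thermal-average alignment ⟨cosθ⟩ of a dipole of energy
    −m·B·cosθ. Odd, strictly increasing, |L| < 1, L(±∞) = ±1. Accepts
    scalars or arrays; L(0) = 0 by the limit, never NaN.
    """
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SERIES_CUTOFF
    # np.where evaluates both branches: mask the small-x points out of the
    # direct branch to avoid 1/0 warnings.
    xs = np.where(small, 1.0, x)
    direct = 1.0 / np.tanh(xs) - 1.0 / xs
    series = x / 3.0 - x**3 / 45.0
    out = np.where(small, series, direct)
    return out.item() if out.ndim == 0 else out


def reduced_field(
    particle: FerritinParticle, partition: SpinPartition, field: ThermalField
) -> float:
    """Dimensionless field parameter x = (N/n)·m_Fe·B / (k_B·T)."""
    partition.validate_against(particle)
    cluster_moment = partition.cluster_size(particle) * particle.moment_per_iron_si
    return cluster_moment * field.b_field / (BOLTZMANN * field.temperature)


def saturation_moment(particle: FerritinParticle) -> float:
    """Fully aligned particle moment N·m_Fe, in A·m².

    Independent of the spin partition: every cluster saturates at the same
    total moment.
    """
    return particle.n_iron * particle.moment_per_iron_si


def saturation_magnetization(particle: FerritinParticle) -> float:
    """Saturation magnetization M_S = N·m_Fe / V of the core, in A/m."""
    return saturation_moment(particle) / particle.volume


def total_moment(
    particle: FerritinParticle, partition: SpinPartition, field: ThermalField
) -> float:
    """Thermal-average particle moment m_TOT = n·(N/n)·m_Fe·L(x), in A·m²."""
    x = reduced_field(particle, partition, field)
    return saturation_moment(particle) * langevin(x)


def interaction_energy(
    particle: FerritinParticle, partition: SpinPartition, field: ThermalField
) -> float:
    """Field-interaction energy magnitude E = m_TOT(B)·B, in J."""
    return total_moment(particle, partition, field) * field.b_field


def thermal_energy(temperature: float) -> float:
    """Thermal energy scale k_B·T, in J."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN * temperature


def magnetization_curve(
    particle: FerritinParticle,
    partitions: Iterable[SpinPartition | int],
    b_grid: Sequence[float],
    temperature: float,
) -> pd.DataFrame:
    """Moment and interaction energy over a field grid for several partitions.

    Parameters
    ----------
    particle : FerritinParticle
    partitions : iterable of SpinPartition or int
        Cluster numbers to evaluate.
    b_grid : sequence of float
        Non-empty, non-negative, sorted field values in Tesla.
    temperature : float
        Temperature in Kelvin.

    Returns
    -------
    pandas.DataFrame
        Columns ``n_clusters, b_tesla, moment_am2, energy_joule,
        energy_over_kbt``; rows sorted by n ascending then B ascending.
    """
    b = np.asarray(list(b_grid), dtype=float)
    if b.size == 0:
        raise ValueError("b_grid must be non-empty")
    if np.any(b < 0):
        raise ValueError("b_grid values must be non-negative")
    if np.any(np.diff(b) < 0):
        raise ValueError("b_grid must be sorted ascending")

    kbt = thermal_energy(temperature)
    rows = []
    ns = sorted(
        p.n_clusters if isinstance(p, SpinPartition) else int(p) for p in partitions
    )
    for n in ns:
        part = SpinPartition(n_clusters=n)
        part.validate_against(particle)
        x = (
            part.cluster_size(particle)
            * particle.moment_per_iron_si
            * b
            / kbt
        )
        moment = saturation_moment(particle) * langevin(x)
        energy = moment * b
        rows.append(
            pd.DataFrame(
                {
                    "n_clusters": n,
                    "b_tesla": b,
                    "moment_am2": moment,
                    "energy_joule": energy,
                    "energy_over_kbt": energy / kbt,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


#: Field grid of the standard laboratory scan: 0 to 2 T in 0.01 T steps.
DEFAULT_B_GRID = np.round(np.arange(0.0, 2.0 + 1e-12, 0.01), 10)
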