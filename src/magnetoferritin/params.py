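"""Parameter containers for the ferritin magnetogenetics calculations.

All quantities are SI internally (metres, Tesla, Kelvin, Pascal); the only
non-SI convenience is ``moment_per_iron``, carried in Bohr magnetons because
that is how atomic moments are tabulated.

The pydantic models validate physical invariants on construction so the
computational modules can assume well-formed inputs.
"""

from __future__ import annotations

import math
import warnings

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .constants import BOHR_MAGNETON


class FerritinParticle(BaseModel):
    """Magnetic mineral core of an iron-loaded ferritin protein.

    Parameters
    ----------
    n_iron : int
        Number N of iron atoms mineralized in the core.
    moment_per_iron : float
        Atomic magnetic moment m_Fe in Bohr magnetons; iron in oxide form
        carries at most 5 μ_B.
    diameter : float
        Core diameter in metres (canonically 8 nm).
    mineral_density : float
        Mass density of the mineral phase in kg/m³ (magnetite: 5.24e3).
    """

    model_config = ConfigDict(frozen=True)

    n_iron: int = Field(ge=1)
    moment_per_iron: float = Field(ge=0.0, le=5.0)
    diameter: float = Field(gt=0.0)
    mineral_density: float = Field(gt=0.0)

    @property
    def radius(self) -> float:
        """Core radius in metres."""
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        """Core volume in m³."""
        return (4.0 / 3.0) * math.pi * self.radius**3

    @property
    def moment_per_iron_si(self) -> float:
        """Atomic moment in A·m²."""
        return self.moment_per_iron * BOHR_MAGNETON


class SpinPartition(BaseModel):
    """Partition of the N iron spins into n independent exchange-coupled
    clusters of N/n spins each.

    n = 1 is the superparamagnetic (single macro-spin) limit, n = N the
    paramagnetic limit, and intermediate n the clusterparamagnetic states.
    The cluster size N/n need not be an integer: the magnetization model is
    continuous in cluster size, and cluster-number scans treat n as a free
    parameter.
    """

    model_config = ConfigDict(frozen=True)

    n_clusters: int = Field(ge=1)

    def validate_against(self, particle: FerritinParticle) -> None:
        """Check n ≤ N; warn when N is not divisible by n."""
        if self.n_clusters > particle.n_iron:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds n_iron={particle.n_iron}"
            )
        if particle.n_iron % self.n_clusters != 0:
            warnings.warn(
                f"N={particle.n_iron} is not divisible by n={self.n_clusters}; "
                "using non-integer cluster size N/n",
                stacklevel=2,
            )

    def cluster_size(self, particle: FerritinParticle) -> float:
        """Spins per cluster, N/n (may be non-integer)."""
        return particle.n_iron / self.n_clusters


class ThermalField(BaseModel):
    """Applied magnetic field and temperature, with an optional externally
    generated field gradient (e.g. ~50 T/m at the bore of an MRI magnet)."""

    model_config = ConfigDict(frozen=True)

    b_field: float = Field(ge=0.0)
    temperature: float = Field(gt=0.0)
    external_gradient: float = Field(default=0.0, ge=0.0)


class Membrane(BaseModel):
    """Elastic and diamagnetic description of the channel-bearing membrane
    patch loaded by the particle's field.

    The neural membrane is treated as an incompressible (ν = 0.5), extremely
    soft (E ~ 100 Pa) elastic half-space with water-like diamagnetic
    susceptibility (χ ~ −1e−5); the diamagnetic body force is taken to act
    over a thin shell (``loaded_thickness``, canonically 1 nm) because the
    particle's field and gradient decay steeply with distance.
    """

    model_config = ConfigDict(frozen=True)

    young_modulus: float = Field(gt=0.0)
    poisson_ratio: float = Field(ge=0.0, le=0.5)
    susceptibility: float = Field(le=0.0)
    patch_radius: float = Field(gt=0.0)
    loaded_thickness: float = Field(gt=0.0)


class EdHParams(BaseModel):
    """Einstein–de Haas parameters: moment-reversal time Δt and the
    spin gyromagnetic ratio γ = e/m_e."""

    model_config = ConfigDict(frozen=True)

    reversal_time: float = Field(gt=0.0)
    gyromagnetic_ratio: float = Field(gt=0.0)


class Scenario(BaseModel):
    """A fully self-describing parameter scenario: one particle, one spin
    partition, one field/temperature setting, plus optional membrane and
    Einstein–de Haas blocks."""

    model_config = ConfigDict(frozen=True)

    label: str
    particle: FerritinParticle
    partition: SpinPartition
    field: ThermalField
    membrane: Membrane | None = None
    edh: EdHParams | None = None

    @model_validator(mode="after")
    def _check_partition(self) -> "Scenario":
        if self.partition.n_clusters > self.particle.n_iron:
            raise ValueError("partition has more clusters than iron spins")
        return self


def canonical_particle() -> FerritinParticle:
    """Fully loaded ferritin core: N = 4500 iron atoms at 5 μ_B each in an
    8 nm magnetite sphere (density 5.24e3 kg/m³)."""
    return FerritinParticle(
        n_iron=4500, moment_per_iron=5.0, diameter=8e-9, mineral_density=5.24e3
    )


def canonical_membrane() -> Membrane:
    """Neural membrane defaults: E = 100 Pa, ν = 0.5, χ = −1e−5, 4 nm patch
    radius, 1 nm loaded shell."""
    return Membrane(
        young_modulus=100.0,
        poisson_ratio=0.5,
        susceptibility=-1e-5,
        patch_radius=4e-9,
        loaded_thickness=1e-9,
    )


def canonical_edh() -> EdHParams:
    """Moment reversal in Δt = 1 ns with γ = e/m_e."""
    from .constants import GYROMAGNETIC_RATIO

    return EdHParams(reversal_time=1e-9, gyromagnetic_ratio=GYROMAGNETIC_RATIO)


#: Cluster numbers plotted in the magnetization and magnetocaloric scans.
CANONICAL_CLUSTER_NUMBERS: tuple[int, ...] = (1, 5, 15, 45, 450, 4500)

#: Physiological temperature, K.
BODY_TEMPERATURE: float = 310.0
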