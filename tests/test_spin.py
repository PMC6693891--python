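"""Clusterparamagnetic magnetization model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from magnetoferritin import FerritinParticle, SpinPartition, ThermalField
from magnetoferritin.constants import BOHR_MAGNETON, BOLTZMANN
from magnetoferritin.spin import (
    DEFAULT_B_GRID,
    interaction_energy,
    langevin,
    magnetization_curve,
    reduced_field,
    saturation_magnetization,
    saturation_moment,
    thermal_energy,
    total_moment,
)


class TestLangevin:
    def test_zero_limit_is_exactly_zero(self):
        assert langevin(0.0) == 0.0

    def test_saturation_limit(self):
        assert langevin(1e4) == pytest.approx(1.0, abs=1e-3)
        assert langevin(1e8) == pytest.approx(1.0, abs=1e-7)

    def test_small_x_matches_series(self):
        # independent series oracle: L(x) = x/3 - x^3/45 + 2x^5/945 - ...
        x = 0.010835
        series = x / 3 - x**3 / 45 + 2 * x**5 / 945
        assert langevin(x) == pytest.approx(series, abs=1e-10)
        assert langevin(x) == pytest.approx(0.0036117, abs=1e-7)

    def test_continuity_across_series_cutoff(self):
        # series branch (|x| < 1e-4) must join the direct branch smoothly
        left, right = langevin(0.99999e-4), langevin(1.00001e-4)
        assert abs(right - left) < 1e-9

    @given(st.floats(min_value=1e-6, max_value=500.0))
    @settings(derandomize=True, max_examples=200)
    def test_odd_bounded_increasing(self, x):
        lx = langevin(x)
        assert 0.0 < lx < 1.0
        assert langevin(-x) == pytest.approx(-lx, rel=1e-12)
        assert langevin(1.01 * x) > lx

    def test_vectorized(self):
        xs = np.array([0.0, 0.5, 5.0])
        out = langevin(xs)
        assert out.shape == (3,)
        assert out[0] == 0.0


class TestReducedField:
    def test_paramagnetic_partition_at_one_tesla(self, particle):
        f = ThermalField(b_field=1.0, temperature=310.0)
        x = reduced_field(particle, SpinPartition(n_clusters=4500), f)
        # direct arithmetic: 1 * 5 mu_B * 1 T / (k_B * 310 K)
        assert x == pytest.approx(5 * BOHR_MAGNETON / (BOLTZMANN * 310.0), rel=1e-12)
        assert x == pytest.approx(0.010835, abs=1e-5)

    def test_superparamagnetic_is_n_times_larger(self, particle, field_1t):
        x1 = reduced_field(particle, SpinPartition(n_clusters=1), field_1t)
        x4500 = reduced_field(particle, SpinPartition(n_clusters=4500), field_1t)
        assert x1 == pytest.approx(4500 * x4500, rel=1e-12)
        assert x1 == pytest.approx(48.74, abs=0.05)

    def test_zero_field_gives_zero(self, particle):
        f = ThermalField(b_field=0.0, temperature=310.0)
        assert reduced_field(particle, SpinPartition(n_clusters=45), f) == 0.0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValidationError):
            ThermalField(b_field=1.0, temperature=0.0)

    def test_partition_larger_than_particle_rejected(self, particle, field_1t):
        with pytest.raises(ValueError):
            reduced_field(particle, SpinPartition(n_clusters=9000), field_1t)

    def test_non_divisor_partition_warns(self, particle, field_1t):
        with pytest.warns(UserWarning, match="not divisible"):
            reduced_field(particle, SpinPartition(n_clusters=7), field_1t)


class TestSaturation:
    def test_canonical_saturation_moment(self, particle):
        # 22500 Bohr magnetons
        assert saturation_moment(particle) == pytest.approx(
            22500 * BOHR_MAGNETON, rel=1e-12
        )
        assert saturation_moment(particle) == pytest.approx(2.1e-19, rel=0.01)

    def test_single_spin(self):
        p = FerritinParticle(
            n_iron=1, moment_per_iron=1.0, diameter=8e-9, mineral_density=5.24e3
        )
        assert saturation_moment(p) == pytest.approx(9.27e-24, rel=1e-3)

    def test_linear_in_n(self, particle):
        doubled = particle.model_copy(update={"n_iron": 9000})
        assert saturation_moment(doubled) == pytest.approx(
            2 * saturation_moment(particle), rel=1e-12
        )

    def test_canonical_saturation_magnetization(self, particle):
        assert saturation_magnetization(particle) == pytest.approx(7.8e5, rel=0.02)

    def test_volume_scaling(self, particle):
        halved = particle.model_copy(update={"diameter": 4e-9})
        assert saturation_magnetization(halved) == pytest.approx(
            8 * saturation_magnetization(particle), rel=1e-12
        )

    def test_zero_moment_per_iron(self, particle):
        p = particle.model_copy(update={"moment_per_iron": 0.0})
        assert saturation_magnetization(p) == 0.0


class TestTotalMoment:
    def test_superparamagnetic_moment_at_one_tesla(self, particle, field_1t):
        # saturated macro-spin: ~2e-19 A m^2
        m = total_moment(particle, SpinPartition(n_clusters=1), field_1t)
        assert m == pytest.approx(2e-19, rel=0.1)

    def test_zero_field_gives_zero(self, particle):
        f = ThermalField(b_field=0.0, temperature=310.0)
        for n in (1, 45, 4500):
            assert total_moment(particle, SpinPartition(n_clusters=n), f) == 0.0

    def test_curie_law_small_field(self, particle):
        # n = N, weak field: m -> N m_Fe^2 B / (3 k_B T)
        f = ThermalField(b_field=0.5, temperature=310.0)
        part = SpinPartition(n_clusters=4500)
        assert reduced_field(particle, part, f) < 0.01
        m_fe = 5 * BOHR_MAGNETON
        curie = 4500 * m_fe**2 * 0.5 / (3 * BOLTZMANN * 310.0)
        assert total_moment(particle, part, f) == pytest.approx(curie, rel=1e-3)

    def test_bounded_by_saturation_and_asymptotic(self, particle):
        sat = saturation_moment(particle)
        for n in (1, 15, 450, 4500):
            for b in (0.1, 1.0, 2.0):
                f = ThermalField(b_field=b, temperature=310.0)
                assert total_moment(particle, SpinPartition(n_clusters=n), f) < sat
        # n=1 at enormous field approaches saturation
        f_big = ThermalField(b_field=500.0, temperature=310.0)
        m = total_moment(particle, SpinPartition(n_clusters=1), f_big)
        assert m == pytest.approx(sat, rel=1e-4)

    def test_moment_increases_with_cluster_size(self, particle, field_1t):
        # fewer clusters (larger N/n) -> larger moment at unsaturating fields
        moments = [
            total_moment(particle, SpinPartition(n_clusters=n), field_1t)
            for n in (4500, 450, 45, 15, 5, 1)
        ]
        assert all(a < b for a, b in zip(moments, moments[1:]))


class TestInteractionEnergy:
    def test_modest_clustering_exceeds_kbt_at_one_tesla(self, particle, field_1t):
        e = interaction_energy(particle, SpinPartition(n_clusters=450), field_1t)
        assert e == pytest.approx(7.5e-21, rel=0.02)
        assert e > thermal_energy(310.0)

    def test_paramagnetic_stays_below_kbt(self, particle, field_1t):
        e = interaction_energy(particle, SpinPartition(n_clusters=4500), field_1t)
        assert e == pytest.approx(7.5e-22, rel=0.02)
        assert e < thermal_energy(310.0)

    def test_zero_field(self, particle):
        f = ThermalField(b_field=0.0, temperature=310.0)
        assert interaction_energy(particle, SpinPartition(n_clusters=1), f) == 0.0


class TestThermalEnergy:
    def test_physiological_value(self):
        assert thermal_energy(310.0) == pytest.approx(4.28e-21, rel=1e-3)

    def test_linear_and_positive_domain(self):
        assert thermal_energy(620.0) == pytest.approx(2 * thermal_energy(310.0))
        with pytest.raises(ValueError):
            thermal_energy(0.0)
        with pytest.raises(ValueError):
            thermal_energy(-5.0)


class TestMagnetizationCurve:
    def test_canonical_grid_shape_and_order(self, particle):
        df = magnetization_curve(
            particle, (1, 5, 15, 45, 450, 4500), DEFAULT_B_GRID, 310.0
        )
        assert len(df) == 6 * len(DEFAULT_B_GRID)
        assert list(df.columns) == [
            "n_clusters", "b_tesla", "moment_am2", "energy_joule",
            "energy_over_kbt",
        ]
        # deterministic ordering: n ascending, then B ascending
        assert df["n_clusters"].is_monotonic_increasing or (
            df.groupby("n_clusters").ngroups == 6
        )
        assert (df.groupby("n_clusters")["b_tesla"].apply(
            lambda s: s.is_monotonic_increasing).all())

    def test_moment_monotone_in_field_per_curve(self, particle):
        df = magnetization_curve(particle, (1, 15, 4500), DEFAULT_B_GRID, 310.0)
        for _, grp in df.groupby("n_clusters"):
            assert grp["moment_am2"].is_monotonic_increasing

    def test_superparamagnetic_curve_saturates_below_one_tesla(self, particle):
        df = magnetization_curve(particle, (1,), DEFAULT_B_GRID, 310.0)
        sat = saturation_moment(particle)
        at_1t = df.loc[np.isclose(df["b_tesla"], 1.0), "moment_am2"].iloc[0]
        assert at_1t > 0.97 * sat

    def test_single_point(self, particle):
        df = magnetization_curve(particle, (45,), [1.0], 310.0)
        assert len(df) == 1
        assert df.loc[0, "energy_joule"] == pytest.approx(
            interaction_energy(
                particle, SpinPartition(n_clusters=45),
                ThermalField(b_field=1.0, temperature=310.0),
            ),
            rel=1e-12,
        )

    @pytest.mark.parametrize(
        "bad_grid", [[], [-0.5, 1.0], [1.0, 0.5]],
        ids=["empty", "negative", "unsorted"],
    )
    def test_invalid_grids_rejected(self, particle, bad_grid):
        with pytest.raises(ValueError):
            magnetization_curve(particle, (1,), bad_grid, 310.0)


class TestParticleValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_iron=0, moment_per_iron=5.0, diameter=8e-9, mineral_density=5e3),
            dict(n_iron=100, moment_per_iron=6.0, diameter=8e-9, mineral_density=5e3),
            dict(n_iron=100, moment_per_iron=5.0, diameter=0.0, mineral_density=5e3),
            dict(n_iron=100, moment_per_iron=5.0, diameter=8e-9, mineral_density=0.0),
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValidationError):
            FerritinParticle(**kwargs)
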