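"""Breakage-model equations: stiffness, probability, damage, fragmentation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.special import erfinv

from wheatdem.tavares_core import (
    DropWeightConfig,
    ElasticProps,
    EnergySaturationError,
    MaterialParams,
    ParticleState,
    SupercriticalImpactError,
    apply_impact,
    breakage_probability,
    collision_energy_ratio,
    damage_fixed_point,
    impact_energy,
    median_fracture_energy_for_size,
    plane_strain_stiffness,
    relative_fracture_energy,
    solve_damage,
    spawn_progeny,
    t10_fraction,
)


def make_particle(Ef=2000.0, dn=4.0, mass=3.5e-5):
    return ParticleState(dn=dn, mass=mass, Ef=Ef)


class TestElasticProps:
    def test_young_from_shear(self):
        p = ElasticProps(poisson_ratio=0.42, shear_modulus=6.484e7)
        assert p.young_modulus == pytest.approx(2 * 6.484e7 * 1.42)

    def test_shear_from_young(self):
        p = ElasticProps(poisson_ratio=0.25, young_modulus=1.125e11)
        assert p.shear_modulus == pytest.approx(4.5e10)

    @pytest.mark.parametrize("kwargs", [
        dict(poisson_ratio=0.3),                                   # neither
        dict(poisson_ratio=0.3, young_modulus=1e9, shear_modulus=1e9),
        dict(poisson_ratio=0.6, young_modulus=1e9),                # nu range
        dict(poisson_ratio=0.3, young_modulus=-1e9),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ElasticProps(**kwargs)


class TestPlaneStrainStiffness:
    def test_zero_poisson_is_identity(self):
        p = ElasticProps(poisson_ratio=1e-12, young_modulus=5e8)
        assert plane_strain_stiffness(p) == pytest.approx(5e8)

    def test_wheat_value(self, wheat_props):
        # Y = 2G(1+nu) = 1.841e8 Pa; K = Y/(1-nu^2)
        assert plane_strain_stiffness(wheat_props) == pytest.approx(
            2 * 6.484e7 * 1.42 / (1 - 0.42**2))
        assert plane_strain_stiffness(wheat_props) == pytest.approx(
            2.236e8, rel=1e-3)

    def test_roller_value(self, roller_props):
        assert plane_strain_stiffness(roller_props) == pytest.approx(1.2e11)


class TestCollisionEnergyRatio:
    def test_symmetric_bodies_split_evenly(self):
        p = ElasticProps(poisson_ratio=0.3, young_modulus=1e9)
        assert collision_energy_ratio(p, p) == pytest.approx(0.5)

    def test_rigid_tool_limit(self):
        soft = ElasticProps(poisson_ratio=0.3, young_modulus=1e3)
        hard = ElasticProps(poisson_ratio=0.3, young_modulus=1e15)
        assert collision_energy_ratio(soft, hard) == pytest.approx(1.0,
                                                                   abs=1e-9)

    def test_wheat_on_cast_iron(self, wheat_props, roller_props):
        assert collision_energy_ratio(wheat_props, roller_props) == \
            pytest.approx(0.99814, abs=1e-5)


class TestRelativeFractureEnergy:
    def test_untruncated_is_identity(self):
        assert relative_fracture_energy(100.0, math.inf) == 100.0

    def test_truncated_value(self):
        assert relative_fracture_energy(100.0, 200.0) == pytest.approx(200.0)

    def test_saturation_signalled(self):
        with pytest.raises(EnergySaturationError):
            relative_fracture_energy(100.0, 100.0)


class TestBreakageProbability:
    def test_median_gives_half(self):
        assert breakage_probability(2000.0, 2000.0, 0.32) == pytest.approx(0.5)

    def test_cdf_limits(self):
        assert breakage_probability(0.0, 2000.0, 0.32) == 0.0
        assert breakage_probability(1e12, 2000.0, 0.32) == pytest.approx(1.0)

    def test_quantile_inversion(self):
        # E at the 90% quantile of the log-normal
        E = 2000.0 * math.exp(0.32 * math.sqrt(2) * erfinv(0.8))
        assert breakage_probability(E, 2000.0, 0.32) == pytest.approx(0.9)

    def test_truncation_saturates(self):
        assert breakage_probability(250.0, 200.0, 0.3, Emax=250.0) == 1.0

    @given(st.floats(0.05, 0.9), st.floats(0.1, 1.0))
    def test_nondecreasing_cdf(self, sigma, scale):
        E = np.linspace(0.0, 4000.0 * scale, 200)
        P = breakage_probability(E, 1000.0 * scale, sigma)
        assert np.all(np.diff(P) >= -1e-12)
        assert P[0] == 0.0


class TestMedianFractureEnergySizeLaw:
    def test_symmetry_point(self, wheat_props, material):
        rigid = ElasticProps(poisson_ratio=0.3, young_modulus=1e18)
        params = MaterialParams(E_inf=100.0, d0=4.0, phi=2.0, sigma=0.3,
                                gamma=5.0)
        # at dn = d0 with a rigid tool: E50 = 2 E_inf
        assert median_fracture_energy_for_size(
            4.0, wheat_props, rigid, params) == pytest.approx(200.0, rel=1e-6)

    def test_direct_evaluation(self, wheat_props):
        rigid = ElasticProps(poisson_ratio=0.3, young_modulus=1e18)
        params = MaterialParams(E_inf=100.0, d0=4.0, phi=2.0, sigma=0.3,
                                gamma=5.0)
        assert median_fracture_energy_for_size(
            2.0, wheat_props, rigid, params) == pytest.approx(500.0, rel=1e-6)

    def test_strictly_decreasing_to_asymptote(self, wheat_props,
                                              roller_props):
        params = MaterialParams(E_inf=100.0, d0=4.0, phi=2.0, sigma=0.3,
                                gamma=5.0)
        dns = np.geomspace(0.5, 500.0, 50)
        vals = [median_fracture_energy_for_size(d, wheat_props, roller_props,
                                                params) for d in dns]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        ratio = plane_strain_stiffness(wheat_props) / \
            plane_strain_stiffness(roller_props)
        floor = params.E_inf * (1 + ratio)
        assert vals[-1] == pytest.approx(floor, rel=1e-3)

    def test_zero_size_rejected(self, wheat_props, roller_props, material):
        with pytest.raises(ValueError):
            median_fracture_energy_for_size(0.0, wheat_props, roller_props,
                                            material)


class TestImpactEnergy:
    def test_reference_drop_weight(self):
        cfg = DropWeightConfig(mb=0.032, H1=0.03, g=9.8, m0=3.5e-5)
        assert impact_energy(cfg) == pytest.approx(268.8)

    def test_zero_height(self):
        cfg = DropWeightConfig(mb=0.032, H1=0.0, g=9.8, m0=3.5e-5)
        assert impact_energy(cfg) == 0.0

    def test_linear_in_height(self):
        e1 = impact_energy(DropWeightConfig(mb=0.032, H1=0.03))
        e2 = impact_energy(DropWeightConfig(mb=0.032, H1=0.06))
        assert e2 == pytest.approx(2 * e1)


class TestSolveDamage:
    def test_no_stressing_no_damage(self):
        assert solve_damage(0.0, make_particle(), 5.0, 1.0) == 0.0

    @pytest.mark.parametrize("gamma", [1.0, 2.0, 5.0, 10.0])
    @pytest.mark.parametrize("r", np.arange(0.1, 0.95, 0.1))
    def test_agrees_with_bisection_oracle(self, gamma, r):
        """Fixed point matches a bisection root of f(D) = D - rhs(D)."""
        p = 2 * gamma / 5

        def f(D):
            return D - (2 * gamma / (2 * gamma - 5 * D + 5) * r) ** p

        D_bis = brentq(f, 0.0, 1.0, xtol=1e-12)
        D_fp = damage_fixed_point(r, gamma)
        assert D_fp == pytest.approx(D_bis, abs=1e-6)

    def test_large_gamma_means_no_damage(self):
        assert damage_fixed_point(0.5, 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_supercritical_rejected(self):
        with pytest.raises(SupercriticalImpactError):
            solve_damage(3000.0, make_particle(Ef=2000.0), 5.0, 1.0)


class TestApplyImpact:
    def test_supercritical_breaks(self):
        s = apply_impact(make_particle(Ef=100.0), 200.0, 5.0, 1.0)
        assert s.broken

    def test_repeated_impacts_weaken_monotonically(self):
        s = make_particle(Ef=2000.0)
        s1 = apply_impact(s, 268.8, 5.0, 0.998)
        s2 = apply_impact(s1, 268.8, 5.0, 0.998)
        assert s1.Ef < s.Ef
        assert s2.Ef < s1.Ef
        assert 0 < s1.damage < s2.damage <= 1

    def test_broken_state_rejected(self):
        s = apply_impact(make_particle(Ef=100.0), 200.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            apply_impact(s, 10.0, 5.0, 1.0)

    def test_impacts_to_breakage_matches_hand_replay(self):
        """Step-by-step replay of the weakening recursion on one kernel."""
        gamma, e, Ek, Ef0 = 5.0, 0.998, 268.8, 900.0
        # independent replay using only the scalar recursion
        Ef, n_oracle = Ef0, 0
        while True:
            n_oracle += 1
            if e * Ek >= Ef:
                break
            D = damage_fixed_point(e * Ek / Ef, gamma)
            Ef *= 1 - D

        s = make_particle(Ef=Ef0)
        n = 0
        while not s.broken:
            s = apply_impact(s, Ek, gamma, e)
            n += 1
            assert n < 10_000
        assert n == n_oracle

    def test_impacts_to_breakage_nonincreasing_in_energy(self):
        def n_impacts(Ek):
            s = make_particle(Ef=1500.0)
            n = 0
            while not s.broken and n < 5000:
                s = apply_impact(s, Ek, 5.0, 1.0)
                n += 1
            return n

        counts = [n_impacts(Ek) for Ek in (200.0, 400.0, 800.0, 1600.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestT10:
    def test_zero_energy(self):
        assert t10_fraction(0.0, 2000.0, 1.0, 50.0, 0.1808) == 0.0

    def test_asymptote_is_A(self):
        assert t10_fraction(1e12, 2000.0, 1.0, 50.0, 0.1808) == \
            pytest.approx(50.0)

    def test_direct_evaluation(self):
        # e*Ek = E50 -> A (1 - exp(-b))
        assert t10_fraction(2000.0, 2000.0, 1.0, 50.0, 0.1808) == \
            pytest.approx(50 * (1 - math.exp(-0.1808)))
        assert t10_fraction(2000.0, 2000.0, 1.0, 50.0, 0.1808) == \
            pytest.approx(8.27, abs=0.005)


class TestSpawnProgeny:
    @pytest.fixture
    def broken(self):
        s = make_particle(Ef=100.0)
        return apply_impact(s, 200.0, 5.0, 1.0)

    def test_zero_t10_single_fragment(self, broken, material):
        frags = spawn_progeny(broken, 0.0, material)
        assert len(frags) == 1
        assert frags[0].mass == pytest.approx(broken.mass)

    @given(st.floats(0.0, 4.97))
    def test_mass_conserved(self, t10):
        s = apply_impact(make_particle(Ef=100.0), 200.0, 5.0, 1.0)
        from wheatdem import datasets

        frags = spawn_progeny(s, t10, datasets.default_material())
        total = sum(f.mass for f in frags)
        assert total == pytest.approx(s.mass, rel=1e-9)

    def test_fine_bin_fraction_at_cap(self, broken, material):
        frags = spawn_progeny(broken, 4.97, material)
        fine = min(frags, key=lambda f: f.dn)
        assert fine.mass / broken.mass == pytest.approx(0.0497)
        assert fine.dn <= max(broken.dn / 10, material.d_min_break)

    def test_tiny_parent_not_fragmented(self, material):
        s = ParticleState(dn=0.2, mass=1e-7, Ef=100.0, broken=True)
        out = spawn_progeny(s, 3.0, material)
        assert len(out) == 1
        assert not out[0].broken
        assert out[0].mass == s.mass

    def test_requires_broken_parent(self, material):
        with pytest.raises(ValueError):
            spawn_progeny(make_particle(), 1.0, material)
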