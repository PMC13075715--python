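"""Fracture-energy calibration: De, curve energies, log-normal fits, gamma."""

import math

import numpy as np
import pytest
from scipy import stats

from wheatdem import datasets
from wheatdem.fracture_calibration import (
    CompressionCurve,
    ImpactSeries,
    KernelDims,
    SizeClassStats,
    assign_size_class,
    detect_fracture_point,
    equivalent_diameter,
    estimate_gamma,
    fit_E50_size_law,
    fit_lognormal_fracture_energy,
    rank_breakage_probability,
    specific_fracture_energy,
    weighted_E50,
)


def make_curve(disp, force, mass=0.035):
    dims = KernelDims(L=6.0, W=3.2, T=3.2, mass=mass)
    return CompressionCurve(displacement=np.asarray(disp, float),
                            force=np.asarray(force, float), dims=dims)


class TestEquivalentDiameter:
    def test_cube_consistent_case(self):
        # L = W = T = d gives De = d exactly
        d = 3.7
        assert equivalent_diameter(KernelDims(d, d, d, 0.03)) == \
            pytest.approx(d)

    @pytest.mark.parametrize("L,W,T,expected", [
        (5.6, 3.18, 2.79, 3.68),
        (6.0, 3.06, 3.49, 4.01),
        (6.4, 3.21, 3.78, 4.28),
        (6.8, 3.32, 3.86, 4.44),
    ])
    def test_reference_size_classes(self, L, W, T, expected):
        assert round(equivalent_diameter(KernelDims(L, W, T, 0.035)), 2) == \
            expected


class TestSpecificFractureEnergy:
    def test_rectangle(self):
        c = make_curve([0, 1, 2], [5.0, 5.0, 5.0], mass=0.035)
        # 5 N x 2 mm = 10 mJ over 0.035 g -> 285.7 J/kg
        assert specific_fracture_energy(c, 2) == pytest.approx(10 / 0.035)

    def test_triangle(self):
        d = np.linspace(0, 2, 101)
        c = make_curve(d, 3.0 * d, mass=0.05)
        assert specific_fracture_energy(c, 100) == pytest.approx(
            3.0 * 2**2 / 2 / 0.05, rel=1e-12)

    def test_constructed_reference_magnitude(self):
        """A curve enclosing 155.70 mJ over a 0.035 g kernel: 4448.6 J/kg."""
        area_mJ = 155.70
        d = np.linspace(0, 1.0, 200)
        c = make_curve(d, np.full_like(d, area_mJ / 1.0), mass=0.035)
        assert specific_fracture_energy(c, 199) == pytest.approx(4448.6,
                                                                 abs=0.05)

    def test_additive_over_abutting_intervals(self):
        d = np.linspace(0, 1.5, 301)
        f = 10 * d**1.5
        c = make_curve(d, f)
        e_full = specific_fracture_energy(c, 300)
        e_half = specific_fracture_energy(c, 150)
        tail = np.trapezoid(f[150:], d[150:]) / c.dims.mass
        assert e_half + tail == pytest.approx(e_full, rel=1e-12)


class TestDetectFracturePoint:
    def test_single_cliff(self):
        d = np.linspace(0, 1, 50)
        f = np.concatenate([10 * d[:40], np.zeros(10)])
        assert detect_fracture_point(make_curve(d, f)) == 39

    def test_first_of_two_cliffs(self):
        d = np.linspace(0, 1, 60)
        f = np.concatenate([20 * d[:30], 5 * np.ones(10), 22 * np.ones(10),
                            np.zeros(10)])
        assert detect_fracture_point(make_curve(d, f)) == 29

    def test_injected_fracture_recovered_within_one_sample(self):
        """Hertz-type ramp with a fracture injected at a known sample."""
        rng = np.random.default_rng(5)
        d = np.linspace(0, 0.8, 300)
        f = 40.0 * d**1.5
        cut = 250
        f[cut + 1:] = f[cut] * 0.02
        f = np.clip(f + rng.normal(0, 0.05, f.size), 0, None)
        idx = detect_fracture_point(make_curve(d, f))
        assert abs(idx - cut) <= 1

    def test_monotone_curve_raises(self):
        d = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="manually"):
            detect_fracture_point(make_curve(d, 10 * d))


class TestRankProbability:
    def test_single_sample(self):
        assert rank_breakage_probability(1) == pytest.approx([0.5])

    def test_reference_sample_size(self):
        p = rank_breakage_probability(80)
        assert p[0] == pytest.approx(0.00625)
        assert p[-1] == pytest.approx(1 - 0.00625)

    def test_strictly_increasing_in_unit_interval(self):
        p = rank_breakage_probability(37)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))


class TestLognormalFit:
    def test_exact_quantiles_recovered(self):
        N = 40
        P = rank_breakage_probability(N)
        e = 2000.0 * np.exp(0.3 * stats.norm.ppf(P))
        e50, sg, r2 = fit_lognormal_fracture_energy(e)
        assert e50 == pytest.approx(2000.0, rel=1e-6)
        assert sg == pytest.approx(0.3, rel=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_recovery_within_5pct(self):
        rng = np.random.default_rng(2)
        e = 2000.0 * np.exp(0.3 * rng.standard_normal(500))
        e50, sg, _ = fit_lognormal_fracture_energy(e)
        assert e50 == pytest.approx(2000.0, rel=0.05)
        assert sg == pytest.approx(0.3, rel=0.05)

    def test_sorting_invariance(self):
        rng = np.random.default_rng(3)
        e = 1500.0 * np.exp(0.25 * rng.standard_normal(60))
        a = fit_lognormal_fracture_energy(e)
        b = fit_lognormal_fracture_energy(e[::-1])
        assert a == pytest.approx(b)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        e = 1000.0 * np.exp(0.2 * rng.standard_normal(50))
        e50a, sga, _ = fit_lognormal_fracture_energy(e)
        e50b, sgb, _ = fit_lognormal_fracture_energy(3.0 * e)
        assert e50b == pytest.approx(3.0 * e50a, rel=1e-6)
        assert sgb == pytest.approx(sga, rel=1e-6)

    def test_nonpositive_energies_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_fracture_energy([1.0, 2.0, -1.0, 4.0, 5.0])


class TestWeightedE50:
    def _stats(self, e50s, weights):
        return [SizeClassStats(De_class=4.0, n=10, E50=e, sigma=0.3, weight=w)
                for e, w in zip(e50s, weights)]

    def test_equal_weights_arithmetic_mean(self):
        s = self._stats([100.0, 300.0], [0.5, 0.5])
        assert weighted_E50(s) == pytest.approx(200.0)

    def test_single_class(self):
        assert weighted_E50(self._stats([123.0], [1.0])) == 123.0

    def test_reference_class_table(self):
        """Weighted sum of the reference class E50s: 2080.4 J/kg."""
        s = self._stats(datasets.SIZE_CLASSES["E50_J_per_kg"],
                        datasets.CLASS_WEIGHTS)
        assert weighted_E50(s) == pytest.approx(2080.41, abs=0.05)

    def test_weight_sum_enforced(self):
        with pytest.raises(ValueError):
            weighted_E50(self._stats([100.0, 200.0], [0.5, 0.4]))


class TestSizeLaw:
    def test_noiseless_recovery(self):
        des = [3.5, 4.0, 4.5, 5.0, 6.0]
        pairs = [(d, 100.0 * (1 + (5.0 / d) ** 3)) for d in des]
        fit = fit_E50_size_law(pairs)
        assert fit.E_inf == pytest.approx(100.0, rel=1e-4)
        assert fit.d0 == pytest.approx(5.0, rel=1e-4)
        assert fit.phi == pytest.approx(3.0, rel=1e-4)
        assert not fit.degenerate

    def test_flat_data_flagged_degenerate(self):
        pairs = [(d, 500.0) for d in (3.5, 4.0, 4.5, 5.0)]
        fit = fit_E50_size_law(pairs)
        assert fit.degenerate or fit.phi < 1e-2

    def test_fitted_curve_decreasing_when_phi_positive(self):
        pairs = [(d, 80.0 * (1 + (4.5 / d) ** 2.5))
                 for d in (3.0, 3.8, 4.6, 5.4)]
        fit = fit_E50_size_law(pairs)
        d = np.linspace(3.0, 6.0, 50)
        pred = fit.E_inf * (1 + (fit.d0 / d) ** fit.phi)
        assert np.all(np.diff(pred) < 0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_E50_size_law([(4.0, 100.0)] * 3)


class TestAssignSizeClass:
    def test_nearest_class(self):
        des = datasets.SIZE_CLASSES["De_mm"]
        assert assign_size_class(3.7, des) == 0
        assert assign_size_class(4.43, des) == 3


class TestEstimateGamma:
    def test_single_candidate_grid(self):
        series = ImpactSeries(Ek=268.8, impacts_to_breakage=[3, 5, 8, 10])
        est = estimate_gamma(series, E50=2069.78, sigma=0.32, e=0.998,
                             grid=np.array([4.0]), n_kernels=200, seed=0)
        assert est.gamma == 4.0
        assert est.gamma_grid_best == 4.0

    def test_sse_shifts_with_gamma(self):
        """Larger gamma weakens slower: later breaks, higher SSE vs a
        fast-breaking empirical curve."""
        from wheatdem.impact_sim import simulate_repeated_impacts

        cfg = datasets.default_drop_weight()
        mat = datasets.default_material()
        low = simulate_repeated_impacts(cfg, mat, 2069.78, 0.32, 2000, seed=8,
                                        n_max=60, gamma=3.0)
        high = simulate_repeated_impacts(cfg, mat, 2069.78, 0.32, 2000, seed=8,
                                         n_max=60, gamma=8.0)
        assert low.p_break.sum() > high.p_break.sum()

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_gamma(
                ImpactSeries(Ek=268.8, impacts_to_breakage=np.empty(0, int)),
                E50=2069.78, sigma=0.32, e=0.998)

    def test_coarse_recovery(self):
        """Self-consistency on a coarse grid with a modest kernel count."""
        from wheatdem.synthetic_data import SyntheticConfig, gen_impact_outcomes

        syn = SyntheticConfig(seed=13, n_impact_kernels=3000)
        series = gen_impact_outcomes(syn)
        est = estimate_gamma(series, E50=syn.pooled_e50,
                             sigma=syn.pooled_sigma, e=0.99814,
                             grid=np.arange(3.0, 7.5, 0.5),
                             n_kernels=3000, seed=99)
        assert est.gamma_grid_best == pytest.approx(5.0, abs=0.5)
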