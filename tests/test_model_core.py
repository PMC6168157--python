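import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from hscpolarity.model_core import (
    SIGMA2_MIN, CellState, Fate, OdeParams, PolarityDistribution,
    PopulationConfig, calibrate_bistable, bifurcation_scan,
    daughter_concentrations, kplus_lognormal_mu, partition_division,
    partition_shares, pseudo_potential, relax_fate, separatrix,
    sigma2_from_active_fraction, simulate_population, steady_states)


def grid_roots(params, n=50001, c_max=None, refine=True):
    """Brute-force root bracketing of the rate function on a dense grid,
    optionally refined by plain bisection."""
    if c_max is None:
        c_max = (params.alpha + params.beta) / params.k_c + 1
    c = np.linspace(0, c_max, n)
    v = params.rate(c)
    idx = np.where(np.sign(v[:-1]) * np.sign(v[1:]) < 0)[0]
    roots = []
    for i in idx:
        lo, hi = c[i], c[i + 1]
        if refine:
            flo = params.rate(lo)
            for _ in range(60):
                mid = (lo + hi) / 2
                fm = params.rate(mid)
                if flo * fm <= 0:
                    hi = mid
                else:
                    lo, flo = mid, fm
        roots.append((lo + hi) / 2)
    return np.array(roots)


class TestSteadyStates:
    def test_default_is_bistable_with_separatrix_at_two(self, params):
        ss = steady_states(params)
        assert len(ss) == 3
        assert [s for _, s in ss] == [True, False, True]
        roots = [c for c, _ in ss]
        assert roots == sorted(roots)
        assert roots[1] == pytest.approx(2.0, abs=1e-9)

    def test_no_autoregulation_gives_single_linear_root(self):
        p = OdeParams(beta=0.0, alpha=0.8, k_c=0.5)
        ss = steady_states(p)
        assert len(ss) == 1
        c, stable = ss[0]
        assert c == pytest.approx(0.8 / 0.5, abs=1e-9)
        assert stable

    @pytest.mark.parametrize("low,sep,high", [(1, 2, 4), (0.5, 1.5, 3.0),
                                              (1.0, 2.5, 5.0)])
    def test_roots_match_dense_grid_oracle(self, low, sep, high):
        p = calibrate_bistable(low=low, sep=sep, high=high)
        roots = np.array([c for c, _ in steady_states(p)])
        oracle = grid_roots(p)
        assert len(roots) == len(oracle)
        assert np.allclose(roots, oracle, atol=1e-6)

    def test_calibration_reproduces_requested_fixed_points(self):
        p = calibrate_bistable(low=1, sep=2, high=4)
        assert p.alpha == pytest.approx(4 / 7, rel=1e-9)
        assert p.beta == pytest.approx(45 / 7, rel=1e-9)
        assert p.K == pytest.approx(math.sqrt(14), rel=1e-9)


class TestRelaxFate:
    def test_zero_start_is_progenitor(self, params):
        out = relax_fate(CellState(c_tot=0.0, c_act=0.0), params)
        assert out.fate is Fate.PROGENITOR
        assert out.c_tot == pytest.approx(1.0, abs=1e-3)

    def test_just_above_separatrix_is_hsc(self, params):
        sep = separatrix(params)
        out = relax_fate(CellState(c_tot=sep + 0.01, c_act=0.0), params)
        assert out.fate is Fate.HSC
        assert out.c_tot == pytest.approx(4.0, abs=1e-3)

    def test_fate_equals_separatrix_sign_mapping(self, params, rng):
        sep = separatrix(params)
        for c0 in rng.uniform(0, 6, size=100):
            if abs(c0 - sep) < 0.01:
                continue
            out = relax_fate(CellState(c_tot=float(c0), c_act=0.0), params)
            expected = Fate.HSC if c0 > sep else Fate.PROGENITOR
            assert out.fate is expected, c0

    def test_fate_stable_under_doubled_t_max(self, params):
        for c0 in (0.3, 1.7, 2.4, 5.0):
            a = relax_fate(CellState(c_tot=c0, c_act=0.0), params, t_max=500)
            b = relax_fate(CellState(c_tot=c0, c_act=0.0), params, t_max=1000)
            assert a.fate is b.fate

    def test_decided_state_never_undecided_and_act_bounded(self, params):
        p = replace(params, k_plus=0.5)
        out = relax_fate(CellState(c_tot=3.0, c_act=1.0), p)
        assert out.fate is not Fate.UNDECIDED
        assert 0 <= out.c_act <= out.c_tot

    def test_requires_undecided_input(self, params):
        st = CellState(c_tot=3.0, c_act=0.0, fate=Fate.HSC)
        with pytest.raises(ValueError):
            relax_fate(st, params)


class TestPartition:
    def test_uniform_limit_always_halves(self):
        d = PolarityDistribution(mu=0.3, sigma2=math.inf, c_tot=4.0)
        for cut in (-math.pi, -1.0, 0.0, 2.0):
            assert partition_division(d, cut) == (0.5, 0.5)

    def test_point_mass_goes_to_one_daughter(self):
        d = PolarityDistribution(mu=0.0, sigma2=1e-8, c_tot=4.0)
        share_a, share_b = partition_division(d, -math.pi / 2)
        assert share_a == pytest.approx(1.0, abs=1e-9)
        assert share_b == pytest.approx(0.0, abs=1e-9)

    def test_share_matches_adaptive_quadrature(self):
        mu, sigma2 = 0.0, 0.25
        d = PolarityDistribution(mu=mu, sigma2=sigma2, c_tot=4.0)
        share_a, _ = partition_division(d, -math.pi / 2)

        def wrapped_pdf(theta):
            sd = math.sqrt(sigma2)
            return sum(norm.pdf(theta - mu + 2 * math.pi * k, scale=sd)
                       for k in range(-6, 7))

        oracle, err = quad(wrapped_pdf, -math.pi / 2, math.pi / 2, limit=200)
        assert err < 1e-9
        assert share_a == pytest.approx(oracle, abs=1e-6)

    def test_shares_sum_to_one_exactly(self, rng):
        for _ in range(50):
            d = PolarityDistribution(mu=float(rng.uniform(-3, 3)),
                                     sigma2=float(rng.uniform(0.01, 30)),
                                     c_tot=4.0)
            a, b = partition_division(d, float(rng.uniform(-math.pi, math.pi)))
            assert a + b == 1.0

    def test_vectorized_shares_agree_with_scalar(self, rng):
        d = PolarityDistribution(mu=0.7, sigma2=0.5, c_tot=4.0)
        cuts = rng.uniform(-math.pi, math.pi, size=20)
        vec = partition_shares(d, cuts)
        for c, v in zip(cuts, vec):
            assert partition_division(d, float(c))[0] == pytest.approx(v, abs=1e-12)

    def test_larger_variance_means_more_even_split(self, rng):
        """|share - 1/2| is stochastically smaller at larger sigma2."""
        cuts = rng.uniform(-math.pi, math.pi, size=10000)
        devs = []
        for sigma2 in (0.1, 1.0, 10.0):
            d = PolarityDistribution(mu=0.0, sigma2=sigma2, c_tot=4.0)
            devs.append(np.sort(np.abs(partition_shares(d, cuts) - 0.5)))
        # stochastic dominance: every quantile shrinks as sigma2 grows
        assert np.all(devs[1] <= devs[0] + 1e-12)
        assert np.all(devs[2] <= devs[1] + 1e-12)
        assert devs[0].mean() > devs[1].mean() > devs[2].mean()

    def test_daughter_concentrations_split_amount_over_half_volume(self):
        d = PolarityDistribution(mu=0.0, sigma2=1.0, c_tot=4.0)
        c_a, c_b = daughter_concentrations(d, 0.75)
        assert c_a == pytest.approx(6.0)
        assert c_b == pytest.approx(2.0)


class TestPopulation:
    def test_same_seed_is_bit_identical(self, params):
        cfg = PopulationConfig(n_cells=20, seed=5)
        r1 = simulate_population(cfg, params)
        r2 = simulate_population(cfg, params)
        assert r1.per_cell.equals(r2.per_cell)
        assert r1.summary() == r2.summary()

    def test_aged_pool_selfrenews_more_than_young(self, params):
        young_mu = kplus_lognormal_mu(0.75)
        aged_mu = kplus_lognormal_mu(0.32)
        assert aged_mu > young_mu
        for seed in (0, 1):
            ry = simulate_population(
                PopulationConfig(n_cells=120, k_plus_mean=young_mu, seed=seed), params)
            ra = simulate_population(
                PopulationConfig(n_cells=120, k_plus_mean=aged_mu, seed=seed), params)
            assert ra.hsc_progenitor_ratio > ry.hsc_progenitor_ratio
            assert ra.fraction_asymmetric < ry.fraction_asymmetric

    def test_polar_fraction_tracks_lognormal_target(self, params):
        mu = kplus_lognormal_mu(0.75)
        r = simulate_population(PopulationConfig(n_cells=400, k_plus_mean=mu,
                                                 seed=3), params)
        assert r.per_cell["polar"].mean() == pytest.approx(0.75, abs=0.06)


class TestBifurcationAndPotential:
    def test_default_k_c_inside_bistable_window(self, params):
        rows = bifurcation_scan(params, [1.0])
        assert rows[0]["bistable"]
        assert len(rows[0]["roots"]) == 3

    def test_small_k_c_leaves_single_high_root(self, params):
        rows = bifurcation_scan(params, [0.05])
        assert len(rows[0]["roots"]) == 1
        assert rows[0]["stable"] == [True]
        assert rows[0]["roots"][0] > 4

    def test_window_endpoints_match_dense_scan(self, params):
        grid = np.arange(0.55, 1.61, 0.01)
        rows = bifurcation_scan(params, grid)
        flags = np.array([r["bistable"] for r in rows])
        oracle = np.array([len(grid_roots(replace(params, k_c=float(k)),
                                          n=50001, refine=False)) == 3
                           for k in grid])
        assert np.array_equal(flags, oracle)

    def test_potential_extrema_at_fixed_points(self, params):
        c = np.linspace(0, 6, 6001)
        U = pseudo_potential(params, c)
        ss = steady_states(params)
        stable = [r for r, s in ss if s]
        unstable = [r for r, s in ss if not s]
        # local minima / maxima of U
        interior = (np.diff(np.sign(np.diff(U))) != 0).nonzero()[0] + 1
        minima = [c[i] for i in interior if U[i - 1] > U[i] < U[i + 1]]
        maxima = [c[i] for i in interior if U[i - 1] < U[i] > U[i + 1]]
        step = c[1] - c[0]
        assert sorted(minima) == pytest.approx(sorted(stable), abs=2 * step)
        assert maxima == pytest.approx(unstable, abs=2 * step)

    def test_linear_case_matches_analytic_antiderivative(self):
        p = OdeParams(beta=0.0, alpha=0.8, k_c=0.5)
        c = np.linspace(0, 5, 2001)
        U = pseudo_potential(p, c)
        analytic = -(p.alpha * c - p.k_c * c ** 2 / 2)
        assert np.allclose(U, analytic, atol=1e-6)


class TestValidation:
    def test_hill_coefficient_below_two_rejected(self):
        with pytest.raises(ValueError):
            OdeParams(n=1)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            OdeParams(k_c=-1.0)

    def test_sigma2_link_is_monotone(self):
        afs = np.linspace(0, 1, 11)
        vals = [sigma2_from_active_fraction(a) for a in afs]
        assert vals[0] == SIGMA2_MIN
        assert all(np.diff(vals) > 0)
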