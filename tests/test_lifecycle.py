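"""Discrete events: seed production, dispersal kernel, establishment,
and the two death processes."""

import numpy as np
import pytest

from aridpatch import (DispersalKernel, Population, SimConfig, SoilGrid,
                       death_step, expected_seeds, lifecycle_step,
                       sample_dispersal, try_establish)


def make_pop(x, y, age, B, Bmax=None):
    pop = Population.empty()
    pop.add(x, y, age, B)
    if Bmax is not None:
        pop.Bmax = np.asarray(Bmax, dtype=float)
    return pop


class TestExpectedSeeds:
    def test_zero_biomass(self):
        assert expected_seeds(0.0, SimConfig(), 0.2) == 0.0

    def test_default_maturity_convention(self):
        # m=0: E = B*s*dt = 100*0.002*0.2 = 0.04
        assert expected_seeds(100.0, SimConfig(), 0.2) == pytest.approx(0.04)

    def test_maturity_equal_lifespan(self):
        # l/m = 1 when m = l
        cfg = SimConfig(m=365.0)
        assert expected_seeds(100.0, cfg, 0.2) == pytest.approx(0.04)

    def test_delayed_maturity_compensation(self):
        cfg = SimConfig(m=73.0)  # l/m = 5
        assert expected_seeds(100.0, cfg, 0.2) == pytest.approx(0.2)


class TestKernel:
    def test_degenerate_kernel_is_deterministic(self, rng):
        k = DispersalKernel(10.0, 0.0)
        assert np.all(k.sample(rng, 100) == 10.0)

    def test_moments_match_closed_forms(self):
        k = DispersalKernel(10.0, 1.5)
        d = k.sample(np.random.default_rng(0), 100_000)
        assert np.all(d > 0)
        assert 9.5 <= d.mean() <= 10.5          # mean parameterization
        # median = mu*exp(-sigma^2/2) ~ 3.247
        assert np.median(d) == pytest.approx(10.0 * np.exp(-1.125), rel=0.05)

    def test_corner_origin_long_kernel_loses_most_seeds(self, rng):
        k = DispersalKernel(1000.0, 1.5)
        lost = sum(sample_dispersal((0.0, 0.0), k, (20.0, 20.0), rng) is None
                   for _ in range(500))
        assert lost > 450

    def test_inside_positions_are_in_bounds(self, rng):
        k = DispersalKernel(10.0, 1.5)
        for _ in range(200):
            hit = sample_dispersal((10.0, 10.0), k, (20.0, 20.0), rng)
            if hit is not None:
                assert 0 <= hit[0] < 20 and 0 <= hit[1] < 20


class TestEstablishment:
    def test_empty_parcel_roots_a_seedling(self):
        cfg = SimConfig(nx=2, ny=2)
        pop = Population.empty()
        grid = SoilGrid(np.zeros((2, 2)), np.full((2, 2), 5.0), cfg.dx)
        assert try_establish((1.0, 1.0), pop, grid, cfg)
        assert len(pop) == 1
        assert pop.B[0] == 1.0 and pop.age[0] == 0.0
        assert grid.Bsum[0, 0] == 1.0

    def test_crowded_parcel_blocks(self):
        # 500 g on 16 m^2 = 31.25 g/m^2 > K_a = 30
        cfg = SimConfig(nx=2, ny=2)
        grid = SoilGrid(np.zeros((2, 2)), np.full((2, 2), 5.0), cfg.dx)
        grid.Bsum[0, 0] = 500.0
        pop = Population.empty()
        assert not try_establish((1.0, 1.0), pop, grid, cfg)
        assert len(pop) == 0

    def test_doomed_seedlings_establish_by_default(self):
        # dry parcel (negative growth rate) still accepts the seedling
        cfg = SimConfig(nx=2, ny=2)
        grid = SoilGrid(np.zeros((2, 2)), np.zeros((2, 2)), cfg.dx)
        pop = Population.empty()
        assert try_establish((1.0, 1.0), pop, grid, cfg)

    def test_preemptive_removal_flag(self):
        cfg = SimConfig(nx=2, ny=2, preemptive_seedling_removal=True)
        grid = SoilGrid(np.zeros((2, 2)), np.zeros((2, 2)), cfg.dx)
        pop = Population.empty()
        assert not try_establish((1.0, 1.0), pop, grid, cfg)


class TestDeath:
    def test_at_threshold_no_stress_death(self, rng):
        cfg = SimConfig(age_mortality_enabled=False)
        pop = make_pop(np.ones(500), np.ones(500), np.ones(500),
                       np.full(500, 0.8), np.full(500, 1.0))
        for _ in range(50):
            death_step(pop, cfg, 1.0, rng)
        assert len(pop) == 500  # B/Bmax = d_b exactly: p_day = 0

    def test_vanishing_biomass_is_lethal(self, rng):
        cfg = SimConfig(age_mortality_enabled=False)
        pop = make_pop(np.ones(200), np.ones(200), np.ones(200),
                       np.full(200, 1e-12), np.full(200, 1.0))
        death_step(pop, cfg, 1.0, rng)
        assert len(pop) == 0

    def test_halfway_decline_death_rate(self):
        # B/Bmax = 0.4 with d_b = 0.8: p_day = 1 - 0.5 = 0.5
        cfg = SimConfig(age_mortality_enabled=False)
        n = 40_000
        pop = make_pop(np.ones(n), np.ones(n), np.ones(n),
                       np.full(n, 0.4), np.full(n, 1.0))
        death_step(pop, cfg, 1.0, np.random.default_rng(3))
        frac = 1.0 - len(pop) / n
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_abrupt_mode_is_harsher_at_onset(self):
        cfg = SimConfig(age_mortality_enabled=False,
                        stress_death_mode="abrupt")
        n = 40_000
        pop = make_pop(np.ones(n), np.ones(n), np.ones(n),
                       np.full(n, 0.79), np.full(n, 1.0))
        death_step(pop, cfg, 1.0, np.random.default_rng(4))
        frac = 1.0 - len(pop) / n
        # p_day = 1 - 0.79*0.8 = 0.368
        assert frac == pytest.approx(0.368, abs=0.01)

    def test_age_hazard_mean_lifetime(self):
        """Age hazard alone gives exponential lifetimes of mean l."""
        cfg = SimConfig()
        n = 20_000
        rng = np.random.default_rng(9)
        pop = make_pop(np.ones(n), np.ones(n), np.zeros(n),
                       np.ones(n), np.ones(n))
        lifetimes = np.zeros(0)
        t, dt = 0.0, 5.0
        while len(pop) and t < 30 * 365:
            before = len(pop)
            death_step(pop, cfg, dt, rng)
            t += dt
            lifetimes = np.append(lifetimes, np.full(before - len(pop), t))
        mean = lifetimes.mean()
        se = lifetimes.std() / np.sqrt(lifetimes.size)
        assert abs(mean - cfg.l) < 3 * se + dt  # binning adds <= dt bias

    def test_age_cutoff_mode(self, rng):
        cfg = SimConfig(age_mortality_mode="cutoff")
        pop = make_pop([1, 1], [1, 1], [100.0, 400.0], [5.0, 5.0])
        death_step(pop, cfg, 0.2, rng)
        assert pop.age.tolist() == [100.0]


class TestLifecycleStep:
    def _setup(self, cfg, n=50, B=50.0, age=100.0):
        rng = np.random.default_rng(11)
        pop = Population.empty()
        pop.add(rng.uniform(0, cfg.Lx, n), rng.uniform(0, cfg.Ly, n),
                np.full(n, age), np.full(n, B))
        grid = SoilGrid(np.full((cfg.ny, cfg.nx), 10.0),
                        np.full((cfg.ny, cfg.nx), 10.0), cfg.dx,
                        pop.biomass_per_parcel(cfg.dx, cfg.nx, cfg.ny))
        return pop, grid

    def test_immature_plants_do_not_reproduce(self):
        cfg = SimConfig(nx=10, ny=10, m=240.0, age_mortality_enabled=False)
        pop, grid = self._setup(cfg, age=10.0)
        ev = lifecycle_step(pop, grid, cfg, np.random.default_rng(0))
        assert ev.births == 0 and ev.seeds_lost == 0

    def test_determinism_under_fixed_seed(self):
        cfg = SimConfig(nx=10, ny=10)
        results = []
        for _ in range(2):
            pop, grid = self._setup(cfg)
            for step in range(200):
                lifecycle_step(pop, grid, cfg, np.random.default_rng(42))
            results.append((len(pop), pop.x.sum(), pop.B.sum()))
        assert results[0] == results[1]

    def test_ageing_by_event_step(self):
        cfg = SimConfig(nx=10, ny=10, s=0.0, age_mortality_enabled=False)
        pop, grid = self._setup(cfg, age=7.0)
        lifecycle_step(pop, grid, cfg, np.random.default_rng(0))
        assert np.all(pop.age == 7.2)

    def test_seed_production_expectation(self):
        """Seed attempts match the binomial expectation sum(B)*s*dt."""
        cfg = SimConfig(nx=25, ny=25, age_mortality_enabled=False)
        rng = np.random.default_rng(5)
        attempts = 0
        n_steps = 1000
        pop, grid = self._setup(cfg, n=100, B=40.0)
        E_step = 100 * 40.0 * cfg.s * cfg.dt_event  # 1.6 seeds/step
        for _ in range(n_steps):
            frozen = pop.copy()  # keep the population composition fixed
            ev = lifecycle_step(frozen, grid, cfg, rng)
            attempts += ev.births + ev.seeds_lost + ev.establishment_blocked
        per_plant = 40.0 * cfg.s * cfg.dt_event
        var = n_steps * 100 * per_plant * (1 - per_plant)
        assert abs(attempts - n_steps * E_step) < 3 * np.sqrt(var)

    def test_extinction_is_absorbing(self):
        cfg = SimConfig(nx=5, ny=5)
        pop = Population.empty()
        grid = SoilGrid(np.zeros((5, 5)), np.zeros((5, 5)), cfg.dx)
        for _ in range(10):
            lifecycle_step(pop, grid, cfg, np.random.default_rng(0))
        assert len(pop) == 0

    def test_healthy_plants_never_die_of_stress(self):
        cfg = SimConfig(nx=10, ny=10, s=0.0, age_mortality_enabled=False)
        pop, grid = self._setup(cfg)
        pop.Bmax = pop.B.copy()  # ratio exactly 1 >= d_b
        for _ in range(500):
            lifecycle_step(pop, grid, cfg, np.random.default_rng(1))
        assert len(pop) == 50

    def test_established_never_exceeds_dispersed(self):
        cfg = SimConfig(nx=10, ny=10, mu_disp=50.0,
                        age_mortality_enabled=False)
        pop, grid = self._setup(cfg, B=100.0)
        rng = np.random.default_rng(2)
        births = lost = blocked = 0
        for _ in range(100):
            frozen = pop.copy()
            ev = lifecycle_step(frozen, grid, cfg, rng)
            births += ev.births
            lost += ev.seeds_lost
            blocked += ev.establishment_blocked
        assert births <= births + lost + blocked
        assert lost > 0  # 50 m kernel on a 40 m plot loses seeds
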