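"""Discrete stochastic plant events: seed production, dispersal,
establishment, and death.

Seeds travel an isotropic direction and a lognormal distance whose
distribution mean equals the configured mean dispersal distance (the
kernel is leptokurtic, reflecting the short-range dispersal typical of
arid-land vegetation). Seeds landing outside the plot are lost
(absorbing boundary); establishment on a parcel is blocked when its
biomass density already exceeds K_a. Death combines a water-stress
hazard, active once a plant's biomass falls below the fraction d_b of
its running maximum, with an optional age-related hazard of mean l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SimConfig
from .hydrology import SoilGrid
from .metabolism import growth_rate
from .population import Population

__all__ = ["DispersalKernel", "expected_seeds", "sample_dispersal",
           "try_establish", "death_step", "lifecycle_step", "EventCounts"]

SEEDLING_BIOMASS = 1.0  # g, biomass of a freshly established seedling


@dataclass
class DispersalKernel:
    """Lognormal distance kernel parameterised by its MEAN.

    mu_disp is the distribution mean (m); sigma_disp the log-scale
    standard deviation, so the underlying normal has location
    ln(mu_disp) - sigma_disp^2/2.
    """

    mu_disp: float = 10.0
    sigma_disp: float = 1.5

    @property
    def log_location(self) -> float:
        return math.log(self.mu_disp) - 0.5 * self.sigma_disp ** 2

    @property
    def median(self) -> float:
        return math.exp(self.log_location)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        if self.sigma_disp == 0.0:
            return np.full(size if size is not None else (), self.mu_disp)
        return rng.lognormal(self.log_location, self.sigma_disp, size=size)


def _maturity_factor(cfg: SimConfig) -> float:
    # l/m compensation keeps lifetime fecundity roughly constant as
    # maturity is delayed; at the default m=0 the factor is 1.
    return cfg.l / cfg.m if cfg.m > 0 else 1.0


def expected_seeds(B, cfg: SimConfig, dt_event: float):
    """Expected seed count per event step: B*s*(l/m)*dt (l/m -> 1 at m=0).

    When the expectation exceeds one it is split into a deterministic
    floor plus a Bernoulli remainder by the caller.
    """
    return np.asarray(B, dtype=np.float64) * cfg.s * _maturity_factor(cfg) * dt_event


def sample_dispersal(origin, kernel: DispersalKernel, plot_bounds,
                     rng: np.random.Generator):
    """Disperse one seed from origin; return (x, y) or None if lost.

    Direction uniform on [0, 2*pi), distance from the kernel; landing
    outside [0, Lx) x [0, Ly) loses the seed (no wrapping, no re-draw).
    """
    Lx, Ly = plot_bounds
    theta = rng.uniform(0.0, 2.0 * math.pi)
    dist = float(kernel.sample(rng))
    x = origin[0] + dist * math.cos(theta)
    y = origin[1] + dist * math.sin(theta)
    if 0.0 <= x < Lx and 0.0 <= y < Ly:
        return (x, y)
    return None


def try_establish(position, pop: Population, grid: SoilGrid,
                  cfg: SimConfig) -> bool:
    """Attempt to root a seedling at position; mutates pop on success.

    Blocked when the target parcel's biomass density (g/m^2) exceeds
    K_a. With preemptive_seedling_removal on, additionally blocked where
    a 1 g seedling would have a non-positive growth rate (a shortcut
    that biases pattern formation; off by default).
    """
    x, y = position
    ix = int(x // grid.dx)
    iy = int(y // grid.dx)
    density = grid.Bsum[iy, ix] / grid.dx ** 2
    if density > cfg.K_a:
        return False
    if cfg.preemptive_seedling_removal:
        if growth_rate(SEEDLING_BIOMASS, grid.W[iy, ix], cfg) <= 0.0:
            return False
    pop.add(x, y, 0.0, SEEDLING_BIOMASS)
    grid.Bsum[iy, ix] += SEEDLING_BIOMASS
    return True


def death_step(pop: Population, cfg: SimConfig, dt_event: float,
               rng: np.random.Generator):
    """Remove plants killed by water stress or age during one event step.

    Water stress: once B/Bmax < d_b, the daily death probability is
    p_day = 1 - B/(d_b*Bmax), converted to the event step as
    1 - (1 - p_day)**dt. Age: a constant hazard 1/l (exponential
    lifetime of mean l) or, in "cutoff" mode, certain death past age l.
    Returns (n_stress_deaths, n_age_deaths).
    """
    n = len(pop)
    if n == 0:
        return 0, 0
    ratio = np.divide(pop.B, pop.Bmax, out=np.ones(n), where=pop.Bmax > 0)
    if cfg.stress_death_mode == "abrupt":
        p_day = np.where(ratio < cfg.d_b, 1.0 - ratio * cfg.d_b, 0.0)
    else:
        p_day = np.where(ratio < cfg.d_b, 1.0 - ratio / cfg.d_b, 0.0)
    p_day = np.clip(p_day, 0.0, 1.0)
    p_step = 1.0 - (1.0 - p_day) ** dt_event
    stress = rng.random(n) < p_step

    age_dead = np.zeros(n, dtype=bool)
    if cfg.age_mortality_enabled:
        if cfg.age_mortality_mode == "hazard":
            p_age = 1.0 - math.exp(-dt_event / cfg.l)
            age_dead = rng.random(n) < p_age
        else:
            age_dead = pop.age > cfg.l
    n_stress = int(np.count_nonzero(stress))
    n_age = int(np.count_nonzero(age_dead & ~stress))
    pop.remove(stress | age_dead)
    return n_stress, n_age


@dataclass
class EventCounts:
    births: int = 0
    deaths_stress: int = 0
    deaths_age: int = 0
    seeds_lost: int = 0
    establishment_blocked: int = 0


def lifecycle_step(pop: Population, grid: SoilGrid, cfg: SimConfig,
                   rng: np.random.Generator,
                   dt_event: float | None = None) -> EventCounts:
    """One discrete event step: dispersal, establishment, death, ageing.

    Mutates pop and grid.Bsum in place. Seeds are attempted in a
    randomised order so that same-parcel establishment races carry no
    systematic bias. grid.Bsum must be current on entry.
    """
    if dt_event is None:
        dt_event = cfg.dt_event
    ev = EventCounts()
    n = len(pop)
    if n > 0:
        mature = pop.age >= cfg.m
        E = np.where(mature, expected_seeds(pop.B, cfg, dt_event), 0.0)
        counts = np.floor(E).astype(np.int64)
        counts += rng.random(n) < (E - counts)
        total = int(counts.sum())
        if total > 0:
            origin_idx = np.repeat(np.arange(n), counts)
            origin_idx = rng.permutation(origin_idx)
            ox = pop.x[origin_idx]
            oy = pop.y[origin_idx]
            theta = rng.uniform(0.0, 2.0 * math.pi, size=total)
            kernel = DispersalKernel(cfg.mu_disp, cfg.sigma_disp)
            dist = kernel.sample(rng, size=total)
            sx = ox + dist * np.cos(theta)
            sy = oy + dist * np.sin(theta)
            inside = (sx >= 0.0) & (sx < cfg.Lx) & (sy >= 0.0) & (sy < cfg.Ly)
            ev.seeds_lost = total - int(np.count_nonzero(inside))
            area = grid.dx ** 2
            W_grid = grid.W
            new_x, new_y = [], []
            for x, y in zip(sx[inside], sy[inside]):
                ix = int(x // grid.dx)
                iy = int(y // grid.dx)
                if grid.Bsum[iy, ix] / area > cfg.K_a:
                    ev.establishment_blocked += 1
                    continue
                if cfg.preemptive_seedling_removal and growth_rate(
                        SEEDLING_BIOMASS, W_grid[iy, ix], cfg) <= 0.0:
                    ev.establishment_blocked += 1
                    continue
                new_x.append(x)
                new_y.append(y)
                grid.Bsum[iy, ix] += SEEDLING_BIOMASS
                ev.births += 1
            if new_x:
                zeros = np.zeros(len(new_x))
                pop.add(np.array(new_x), np.array(new_y), zeros,
                        np.full(len(new_x), SEEDLING_BIOMASS))
    ev.deaths_stress, ev.deaths_age = death_step(pop, cfg, dt_event, rng)
    pop.age += dt_event
    return ev
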