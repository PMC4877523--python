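"""Initial conditions: bare-soil water grid and founding plant populations.

The bare-soil grid starts at the plant-free steady state of the water
equations, O = R/(alpha*W0) and W = R/r_w, so a simulation with no
plants sits exactly at its fixed point. Founding populations come in
two spatial modes: "aggregated" (all plants packed into patches
covering 1% of the parcels) and "random" (uniform scatter over the
plot).
"""

from __future__ import annotations

import math

import numpy as np

from .config import ConfigError, SimConfig
from .hydrology import SoilGrid
from .population import Population

__all__ = ["bare_soil_grid", "init_population"]


def bare_soil_grid(cfg: SimConfig) -> SoilGrid:
    """Uniform grid at the bare-soil equilibrium of the baseline rainfall."""
    R0 = cfg.rain.rate(0.0)
    if R0 == 0.0:
        O_eq, W_eq = 0.0, 0.0
    else:
        if cfg.alpha == 0.0 or cfg.W0 == 0.0 or cfg.r_w == 0.0:
            raise ConfigError(
                "bare-soil equilibrium undefined: alpha, W0 and r_w must be "
                "positive when rainfall is positive")
        O_eq = R0 / (cfg.alpha * cfg.W0)
        W_eq = R0 / cfg.r_w
    shape = (cfg.ny, cfg.nx)
    return SoilGrid(np.full(shape, O_eq), np.full(shape, W_eq), cfg.dx)


def _grow_patches(cfg: SimConfig, n_patches: int, n_parcels: int,
                  rng: np.random.Generator) -> list:
    """Pick n_patches distinct seed parcels and grow contiguous patches
    until n_parcels parcels are covered (round-robin growth)."""
    total = cfg.nx * cfg.ny
    seeds = rng.choice(total, size=n_patches, replace=False)
    patches = [[int(s)] for s in seeds]
    covered = set(int(s) for s in seeds)
    i = 0
    while len(covered) < n_parcels:
        patch = patches[i % n_patches]
        # random frontier parcel: neighbour of a random member, not covered
        grown = False
        order = rng.permutation(len(patch))
        for j in order:
            cell = patch[j]
            iy, ix = divmod(cell, cfg.nx)
            nbrs = []
            if ix > 0:
                nbrs.append(cell - 1)
            if ix < cfg.nx - 1:
                nbrs.append(cell + 1)
            if iy > 0:
                nbrs.append(cell - cfg.nx)
            if iy < cfg.ny - 1:
                nbrs.append(cell + cfg.nx)
            free = [n for n in nbrs if n not in covered]
            if free:
                pick = free[rng.integers(len(free))]
                patch.append(pick)
                covered.add(pick)
                grown = True
                break
        i += 1
        if not grown and i > 4 * n_parcels * n_patches:
            break  # pathological geometry; accept partial coverage
    return patches


def init_population(cfg: SimConfig, mode: str, n_plants: int,
                    n_patches: int = 25,
                    rng: np.random.Generator | None = None) -> Population:
    """Instantiate the founding population.

    mode="aggregated" packs plants round-robin into ``n_patches``
    contiguous patches whose total footprint is ceil(1% of parcels);
    mode="random" scatters them uniformly. Initial biomass is drawn
    uniformly from cfg.B_init_range and initial age uniformly from the
    integers 1..l (desynchronising the founding cohort).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if n_plants < 0:
        raise ConfigError("n_plants must be non-negative")
    pop = Population.empty()
    if n_plants == 0:
        return pop
    if cfg.plot_area <= 0:
        raise ConfigError("cannot place plants on a zero-area plot")

    lo, hi = cfg.B_init_range
    B = rng.uniform(lo, hi, size=n_plants)
    age = rng.integers(1, int(cfg.l) + 1, size=n_plants).astype(float)

    if mode == "random":
        x = rng.uniform(0.0, cfg.Lx, size=n_plants)
        y = rng.uniform(0.0, cfg.Ly, size=n_plants)
    elif mode == "aggregated":
        n_parcels = math.ceil(0.01 * cfg.nx * cfg.ny)
        if n_patches > n_parcels:
            raise ConfigError(
                f"n_patches={n_patches} exceeds the 1% parcel budget "
                f"({n_parcels} parcels)")
        patches = _grow_patches(cfg, n_patches, n_parcels, rng)
        x = np.empty(n_plants)
        y = np.empty(n_plants)
        for i in range(n_plants):
            patch = patches[i % n_patches]
            cell = patch[rng.integers(len(patch))]
            iy, ix = divmod(cell, cfg.nx)
            x[i] = (ix + rng.random()) * cfg.dx
            y[i] = (iy + rng.random()) * cfg.dx
    else:
        raise ConfigError(f"unknown initial-condition mode {mode!r}")

    pop.add(x, y, age, B)
    return pop
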