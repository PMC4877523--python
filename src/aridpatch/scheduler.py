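"""Hybrid time loop: continuous water/biomass integration interleaved
with discrete dispersal and death events.

Per event step (default 0.2 d): (1) the plant biomass ODEs and the
parcel water ODEs are advanced together over the step ("coupled" mode:
shared RK4 substeps with per-stage biomass totals; "split" mode:
plants integrate against frozen water, then water against frozen
biomass); (2) seed dispersal, establishment, death, and ageing happen
as stochastic discrete events; (3) population summaries are recorded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from .config import SimConfig
from .hydrology import NumericalInstabilityError, SoilGrid, water_step
from .initial import bare_soil_grid
from .lifecycle import EventCounts, lifecycle_step
from .metabolism import metabolism_step
from .population import Population

__all__ = ["SimOutput", "run", "child_rngs"]

SEEDLING_AGE = 30.0  # d; "young plant" threshold for the seedling fraction


def child_rngs(seed: int) -> dict:
    """Independent per-submodule RNG streams from one root seed.

    Keeps the lifecycle event stream unaffected by how much randomness
    initialization consumes (and vice versa).
    """
    init_ss, life_ss = np.random.SeedSequence(seed).spawn(2)
    return {"init": np.random.default_rng(init_ss),
            "lifecycle": np.random.default_rng(life_ss)}


@dataclass
class SimOutput:
    """Time series of population summaries plus periodic state snapshots."""

    config: SimConfig
    times: np.ndarray = None
    n_plants: np.ndarray = None
    total_biomass: np.ndarray = None
    mean_age: np.ndarray = None
    mean_biomass: np.ndarray = None
    biomass_density: np.ndarray = None
    seedling_fraction: np.ndarray = None
    snapshots: list = field(default_factory=list)  # (t, plant df, O, W)
    final_population: Optional[Population] = None
    final_grid: Optional[SoilGrid] = None
    events: EventCounts = field(default_factory=EventCounts)
    n_clamped: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "n_plants": self.n_plants,
            "total_biomass": self.total_biomass,
            "mean_age": self.mean_age,
            "mean_biomass": self.mean_biomass,
            "biomass_density": self.biomass_density,
            "seedling_fraction": self.seedling_fraction,
        })

    def snapshot_at(self, t: float):
        """Snapshot tuple closest to time t."""
        if not self.snapshots:
            raise ValueError("no snapshots recorded")
        times = np.array([s[0] for s in self.snapshots])
        return self.snapshots[int(np.argmin(np.abs(times - t)))]


def _summaries(pop: Population, area: float):
    n = len(pop)
    if n == 0:
        return 0, 0.0, 0.0, 0.0, 0.0, 0.0
    tb = pop.total_biomass
    return (n, tb, float(pop.age.mean()), float(pop.B.mean()), tb / area,
            float(np.count_nonzero(pop.age < SEEDLING_AGE)) / n)


def run(cfg: SimConfig, pop0: Optional[Population] = None,
        grid0: Optional[SoilGrid] = None, t0: float = 0.0,
        rng: Optional[np.random.Generator] = None,
        snapshot_times=None) -> SimOutput:
    """Simulate from t0 to t0 + cfg.T_end.

    pop0 defaults to an empty population and grid0 to the bare-soil
    equilibrium grid. ``rng`` defaults to the lifecycle child stream of
    cfg.seed; pass an explicit generator to continue an event stream
    across chained runs. ``snapshot_times`` overrides the cadence
    implied by cfg.snapshot_every.
    """
    pop = pop0.copy() if pop0 is not None else Population.empty()
    grid = grid0.copy() if grid0 is not None else bare_soil_grid(cfg)
    if grid.shape != (cfg.ny, cfg.nx):
        raise ValueError("grid shape does not match config geometry")
    if rng is None:
        rng = child_rngs(cfg.seed)["lifecycle"]

    n_steps = int(round(cfg.T_end / cfg.dt_event))
    if snapshot_times is None:
        if cfg.snapshot_every and cfg.snapshot_every > 0:
            snapshot_times = np.arange(t0, t0 + cfg.T_end + 1e-9,
                                       cfg.snapshot_every)
        else:
            snapshot_times = []
    snapshot_times = sorted(float(s) for s in snapshot_times)
    next_snap = 0

    out = SimOutput(config=cfg)
    series = {k: [] for k in ("t", "n", "tb", "ma", "mb", "bd", "sf")}

    rain = cfg.rain
    mode_code = _kernel.rain_mode_code(rain.mode)
    r1 = rain.R1 if rain.R1 is not None else 0.0
    ts = rain.t_shift if rain.t_shift is not None else 0.0
    area = cfg.plot_area
    periodic = cfg.boundary == "periodic"
    age_off_at = getattr(cfg, "age_mortality_off_after", None)
    cfg_now = cfg

    def record(t):
        n, tb, ma, mb, bd, sf = _summaries(pop, area)
        series["t"].append(t)
        series["n"].append(n)
        series["tb"].append(tb)
        series["ma"].append(ma)
        series["mb"].append(mb)
        series["bd"].append(bd)
        series["sf"].append(sf)

    def maybe_snapshot(t):
        nonlocal next_snap
        while (next_snap < len(snapshot_times)
               and snapshot_times[next_snap] <= t + cfg.dt_event / 2):
            out.snapshots.append((t, pop.to_dataframe(),
                                  grid.O.copy(), grid.W.copy()))
            next_snap += 1

    record(t0)
    maybe_snapshot(t0)

    for step in range(n_steps):
        t = t0 + step * cfg.dt_event
        if (age_off_at is not None and cfg_now.age_mortality_enabled
                and t >= age_off_at):
            cfg_now = cfg.replace(age_mortality_enabled=False)

        # --- continuous block over [t, t + dt_event] ---
        if cfg.coupling == "coupled":
            pix = pop.parcel_index(cfg.dx, cfg.nx)
            Oflat = grid.O.reshape(-1)
            Wflat = grid.W.reshape(-1)
            out.n_clamped += _kernel.integrate_event_step(
                Oflat, Wflat, pop.B, pix, t, cfg.dt_event, cfg.n_substeps,
                mode_code, rain.R0, r1, ts, rain.amplitude, rain.period,
                cfg.nx, cfg.ny, cfg.alpha, cfg.k2, cfg.W0, cfg.r_w,
                cfg.g_max, cfg.k1, cfg.b, cfg.Kp, cfg.d, cfg.D_O, cfg.D_W,
                cfg.dx ** 2, periodic, cfg.infiltration_literal_denominator,
                1.0 / cfg.dx ** 2 if cfg.biomass_density_coupling else 1.0)
            if not (np.all(np.isfinite(Oflat)) and np.all(np.isfinite(pop.B))):
                raise NumericalInstabilityError(
                    f"non-finite state at t={t + cfg.dt_event:.2f} d; "
                    "reduce dt_int")
            np.maximum(pop.Bmax, pop.B, out=pop.Bmax)
        else:
            grid.Bsum = pop.biomass_per_parcel(cfg.dx, cfg.nx, cfg.ny)
            new_pop = metabolism_step(pop, grid, cfg, cfg.dt_event)
            grid.Bsum = new_pop.biomass_per_parcel(cfg.dx, cfg.nx, cfg.ny)
            grid = water_step(grid, rain.rate, cfg, cfg.dt_event, t0=t)
            pop = new_pop

        # --- discrete events ---
        grid.Bsum = pop.biomass_per_parcel(cfg.dx, cfg.nx, cfg.ny)
        ev = lifecycle_step(pop, grid, cfg_now, rng)
        out.events.births += ev.births
        out.events.deaths_stress += ev.deaths_stress
        out.events.deaths_age += ev.deaths_age
        out.events.seeds_lost += ev.seeds_lost
        out.events.establishment_blocked += ev.establishment_blocked

        t_next = t0 + (step + 1) * cfg.dt_event
        record(t_next)
        maybe_snapshot(t_next)

    grid.Bsum = pop.biomass_per_parcel(cfg.dx, cfg.nx, cfg.ny)
    out.times = np.array(series["t"])
    out.n_plants = np.array(series["n"])
    out.total_biomass = np.array(series["tb"])
    out.mean_age = np.array(series["ma"])
    out.mean_biomass = np.array(series["mb"])
    out.biomass_density = np.array(series["bd"])
    out.seedling_fraction = np.array(series["sf"])
    out.final_population = pop
    out.final_grid = grid
    return out
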