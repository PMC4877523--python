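"""Canned experiment presets and replicate runners.

Four study designs are packaged:

* exp1a — precipitation sweep on a large plot: pattern morphology
  (spots / labyrinth / gaps / uniform) across constant rainfall levels
  and two founding spatial modes.
* exp1a demographic variant — smaller plot, low seed factor; population
  structure (biomass density, mean plant biomass, seedling fraction,
  plant density) across rainfall.
* exp1b — plant-trait sweep (mean dispersal distance or reproductive
  maturity) scored by the quadrat dispersion indices IP and ICS.
* exp2a — step shift to drier rainfall at day 1500 with age mortality
  disabled afterwards; pre/post spatial indices and per-class mortality.
* exp2b — sinusoidal seasonal rainfall over 12 years; biomass
  mean/max/min over the last 4 years and dominant oscillation period.

Every runner accepts a linear ``scale`` factor: plot sides scale by it
and founding plant/patch numbers by its square, so the founding density
is preserved. Replicate seeds are derived from one root seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig, RainfallRegime
from .initial import bare_soil_grid, init_population
from .population import Population
from .scheduler import SimOutput, child_rngs, run
from .spatial import (index_of_cluster_size, index_of_patchiness,
                      mortality_by_class, quadrat_counts)

__all__ = ["ExperimentSpec", "demographic_config", "pattern_config",
           "shift_config", "seasonal_config", "replicate_seeds",
           "run_replicate", "exp1a_precip_sweep", "demographic_table",
           "exp1b_trait_sweep", "exp2a_shift", "exp2b_seasonal",
           "occupied_fraction", "occupancy_autocorrelation", "PRESETS"]

YEAR = 365.0


def replicate_seeds(root_seed: int, reps: int) -> np.ndarray:
    """Derive independent per-replicate seeds (< 2^31) from a root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(reps)
    return (state & 0x7FFFFFFF).astype(np.int64)


def _scaled(n: float, scale: float) -> int:
    return max(1, int(round(n * scale * scale)))


@dataclass
class ExperimentSpec:
    """A preset: base configuration plus founding population layout."""

    preset: str
    config: SimConfig
    ic_mode: str = "aggregated"
    n_plants: int = 250
    n_patches: int = 25
    sweep: dict = field(default_factory=dict)
    n_replicates: int = 1

    def build(self, seed: int):
        cfg = self.config.replace(seed=int(seed))
        rngs = child_rngs(cfg.seed)
        pop = init_population(cfg, self.ic_mode, self.n_plants,
                              self.n_patches, rngs["init"])
        grid = bare_soil_grid(cfg)
        return cfg, pop, grid, rngs["lifecycle"]


def pattern_config(R: float = 1.3, scale: float = 1.0, years: float = 10.0,
                   ic_mode: str = "aggregated", seed: int = 0) -> ExperimentSpec:
    """Large-plot pattern-formation design: 400x400 m (100x100 parcels),
    1000 founding plants, s = 0.002."""
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must lie in (0, 1]")
    nx = max(4, int(round(100 * scale)))
    cfg = SimConfig(nx=nx, ny=nx, T_end=years * YEAR, s=0.002,
                    rain=RainfallRegime("constant", R0=R), seed=seed,
                    B_init_range=(1.0, 1.0), dt_int=0.04)
    return ExperimentSpec("exp1a", cfg, ic_mode,
                          n_plants=_scaled(1000, scale),
                          n_patches=min(_scaled(100, scale),
                                        math.ceil(0.01 * nx * nx)))


def demographic_config(R: float = 1.3, scale: float = 1.0,
                       seed: int = 0) -> ExperimentSpec:
    """Demographic design: 200x200 m (50x50 parcels), 250 plants in 25
    patches, s = 0.001, 5 years."""
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must lie in (0, 1]")
    nx = max(4, int(round(50 * scale)))
    cfg = SimConfig(nx=nx, ny=nx, T_end=5 * YEAR, s=0.001,
                    rain=RainfallRegime("constant", R0=R), seed=seed,
                    dt_int=0.04)
    return ExperimentSpec("exp1a-demography", cfg, "aggregated",
                          n_plants=_scaled(250, scale),
                          n_patches=min(_scaled(25, scale),
                                        math.ceil(0.01 * nx * nx)))


def shift_config(R_pre: float = 1.3, R_post: float = 0.8,
                 t_shift: float = 1500.0, settle: float = 365.0,
                 scale: float = 1.0, seed: int = 0,
                 ic_mode: str = "aggregated",
                 n_plants: int = 250) -> ExperimentSpec:
    """Precipitation-shift design: grow at R_pre until t_shift, then
    drop to R_post with age mortality disabled; run ``settle`` more days."""
    nx = max(4, int(round(50 * scale)))
    cfg = SimConfig(nx=nx, ny=nx, T_end=t_shift + settle,
                    rain=RainfallRegime("shift", R0=R_pre, R1=R_post,
                                        t_shift=t_shift),
                    age_mortality_off_after=t_shift, seed=seed, dt_int=0.04)
    return ExperimentSpec("exp2a", cfg, ic_mode,
                          n_plants=_scaled(n_plants, scale),
                          n_patches=min(_scaled(25, scale),
                                        math.ceil(0.01 * nx * nx)))


def seasonal_config(amplitude: float, R0: float = 1.3, scale: float = 1.0,
                    years: float = 12.0, seed: int = 0) -> ExperimentSpec:
    """Seasonal design: sinusoidal rainfall R0 +/- amplitude, 12 years,
    250 plants in 25 patches on 200x200 m."""
    nx = max(4, int(round(50 * scale)))
    cfg = SimConfig(nx=nx, ny=nx, T_end=years * YEAR,
                    rain=RainfallRegime("sinusoid", R0=R0,
                                        amplitude=amplitude), seed=seed,
                    dt_int=0.04)
    return ExperimentSpec("exp2b", cfg, "aggregated",
                          n_plants=_scaled(250, scale),
                          n_patches=min(_scaled(25, scale),
                                        math.ceil(0.01 * nx * nx)))


def ring_config(seed: int = 0) -> ExperimentSpec:
    """Qualitative ring-formation scenario: one 10-plant patch on a
    50x50 m plot at 1 m resolution, rainfall oscillating 1.0-1.6 mm/d,
    short mean dispersal (5 m)."""
    cfg = SimConfig(nx=50, ny=50, dx=1.0, mu_disp=5.0, T_end=10 * YEAR,
                    rain=RainfallRegime("sinusoid", R0=1.3, amplitude=0.3),
                    seed=seed)
    return ExperimentSpec("ring", cfg, "aggregated", n_plants=10, n_patches=1)


PRESETS = {
    "exp1a": pattern_config,
    "exp1a-demography": demographic_config,
    "exp2a": shift_config,
    "exp2b": seasonal_config,
    "ring": ring_config,
}


def run_replicate(spec: ExperimentSpec, seed: int,
                  snapshot_times=None) -> SimOutput:
    cfg, pop, grid, rng = spec.build(seed)
    return run(cfg, pop, grid, rng=rng, snapshot_times=snapshot_times)


# ---------------------------------------------------------------------
# pattern metrics

def occupied_fraction(pop: Population, cfg: SimConfig) -> float:
    """Fraction of parcels holding at least one living plant."""
    occ = pop.biomass_per_parcel(cfg.dx, cfg.nx, cfg.ny) > 0
    return float(occ.mean())


def occupancy_autocorrelation(pop: Population, cfg: SimConfig,
                              lag: int) -> float:
    """Spatial autocorrelation of parcel occupancy at an axial lag
    (average of the x and y directions); positive at short lags for
    clumped patterns, negative near the typical inter-patch distance."""
    occ = (pop.biomass_per_parcel(cfg.dx, cfg.nx, cfg.ny) > 0).astype(float)
    occ = occ - occ.mean()
    var = (occ * occ).mean()
    if var == 0.0:
        return 0.0
    cx = (occ[:, :-lag] * occ[:, lag:]).mean()
    cy = (occ[:-lag, :] * occ[lag:, :]).mean()
    return float(0.5 * (cx + cy) / var)


# ---------------------------------------------------------------------
# runners

def exp1a_precip_sweep(R_values=(0.6, 0.9, 1.3, 1.7), ic_modes=("aggregated",),
                       scale: float = 1.0, reps: int = 1, seed: int = 0,
                       years: float = 5.0) -> pd.DataFrame:
    """Precipitation sweep on the pattern design; one row per run with
    final biomass density, occupancy and short/long-lag autocorrelation."""
    rows = []
    for R in R_values:
        for ic in ic_modes:
            spec = pattern_config(R=R, scale=scale, years=years, ic_mode=ic)
            for rep, s_rep in enumerate(replicate_seeds(seed, reps)):
                out = run_replicate(spec, s_rep)
                pop, cfg = out.final_population, out.config
                rows.append({
                    "R": R, "ic": ic, "rep": rep,
                    "n_plants": len(pop),
                    "biomass_density": out.biomass_density[-1],
                    "occupied_fraction": occupied_fraction(pop, cfg),
                    "autocorr_lag1": occupancy_autocorrelation(pop, cfg, 1),
                    "autocorr_lag10": occupancy_autocorrelation(
                        pop, cfg, min(10, cfg.nx - 1)),
                })
    return pd.DataFrame(rows)


def demographic_table(R_values=(0.9, 1.3, 1.5, 1.7), scale: float = 1.0,
                      reps: int = 5, seed: int = 0) -> pd.DataFrame:
    """Demographic sweep: per-run population structure after 5 years."""
    rows = []
    for R in R_values:
        spec = demographic_config(R=R, scale=scale)
        for rep, s_rep in enumerate(replicate_seeds(seed, reps)):
            out = run_replicate(spec, s_rep)
            pop, cfg = out.final_population, out.config
            n = len(pop)
            rows.append({
                "R": R, "rep": rep, "n_plants": n,
                "biomass_density": out.biomass_density[-1],
                "mean_biomass": out.mean_biomass[-1],
                "seedling_fraction": out.seedling_fraction[-1],
                "plant_density": n / cfg.plot_area,
            })
    return pd.DataFrame(rows)


def exp1b_trait_sweep(param: str = "mu_disp", values=(1.0, 5.0, 20.0, 80.0),
                      scale: float = 1.0, reps: int = 5, seed: int = 0,
                      quadrat: float = 4.0) -> pd.DataFrame:
    """Trait sweep scored by IP and ICS on the final population."""
    if param not in ("mu_disp", "m"):
        raise ValueError("param must be 'mu_disp' or 'm'")
    rows = []
    for value in values:
        base = demographic_config(scale=scale)
        spec = ExperimentSpec(base.preset, base.config.replace(**{param: value}),
                              base.ic_mode, base.n_plants, base.n_patches)
        for rep, s_rep in enumerate(replicate_seeds(seed, reps)):
            out = run_replicate(spec, s_rep)
            pop, cfg = out.final_population, out.config
            if len(pop) == 0:
                ip = ics = np.nan
            else:
                qc = quadrat_counts(pop, quadrat, (cfg.Lx, cfg.Ly))
                ip = index_of_patchiness(qc)
                ics = index_of_cluster_size(qc)
            rows.append({param: value, "rep": rep, "n_plants": len(pop),
                         "IP": ip, "ICS": ics})
    return pd.DataFrame(rows)


def exp2a_shift(scale: float = 1.0, reps: int = 5, seed: int = 0,
                R_post: float = 0.8, t_shift: float = 1500.0,
                settle: float = 365.0, quadrat: float = 4.0):
    """Precipitation-shift experiment.

    Returns (table, mortality) where ``table`` has one row per
    replicate with pre/post IP, ICS and survival, and ``mortality``
    stacks per-class death fractions between the shift and the
    assessment time (classes tagged at the shift).
    """
    age_bins = [0, 7, 14, 30, 45, 90, 180, 365, 1e9]
    biomass_bins = [0, 1, 5, 15, 30, 60, 120, 1e9]
    rows, mort_frames = [], []
    for rep, s_rep in enumerate(replicate_seeds(seed, reps)):
        spec = shift_config(R_post=R_post, t_shift=t_shift, settle=settle,
                            scale=scale)
        out = run_replicate(spec, s_rep, snapshot_times=[t_shift])
        cfg = out.config
        _, pre_df, _, _ = out.snapshot_at(t_shift)
        pre_pop = Population.from_dataframe(pre_df)
        post_pop = out.final_population
        row = {"rep": rep, "n_pre": len(pre_pop), "n_post": len(post_pop),
               "survived": len(post_pop) > 0}
        for label, p in (("pre", pre_pop), ("post", post_pop)):
            if len(p) == 0:
                row[f"IP_{label}"] = np.nan
                row[f"ICS_{label}"] = np.nan
            else:
                qc = quadrat_counts(p, quadrat, (cfg.Lx, cfg.Ly))
                row[f"IP_{label}"] = index_of_patchiness(qc)
                row[f"ICS_{label}"] = index_of_cluster_size(qc)
        rows.append(row)
        mort = mortality_by_class(pre_pop, post_pop, age_bins, biomass_bins)
        mort.insert(0, "rep", rep)
        mort_frames.append(mort)
    return pd.DataFrame(rows), pd.concat(mort_frames, ignore_index=True)


def _dominant_period(times: np.ndarray, series: np.ndarray) -> float:
    """Dominant oscillation period (days) of a detrended series by FFT."""
    y = series - series.mean()
    if np.allclose(y, 0.0):
        return np.inf
    dt = times[1] - times[0]
    freqs = np.fft.rfftfreq(y.size, d=dt)
    power = np.abs(np.fft.rfft(y)) ** 2
    k = int(np.argmax(power[1:]) + 1)
    return float(1.0 / freqs[k])


def exp2b_seasonal(amplitudes=(0.0, 0.3, 0.45, 0.6, 0.9), scale: float = 1.0,
                   reps: int = 3, seed: int = 0,
                   years: float = 12.0, window_years: float = 4.0
                   ) -> pd.DataFrame:
    """Seasonal-rainfall experiment: total-biomass statistics over the
    last ``window_years`` of each run plus the dominant period of the
    biomass oscillation."""
    rows = []
    for A in amplitudes:
        spec = seasonal_config(A, scale=scale, years=years)
        for rep, s_rep in enumerate(replicate_seeds(seed, reps)):
            out = run_replicate(spec, s_rep)
            sel = out.times >= (years - window_years) * YEAR
            tb = out.total_biomass[sel]
            rows.append({
                "amplitude": A, "rep": rep,
                "mean_biomass_total": float(tb.mean()),
                "max_biomass_total": float(tb.max()),
                "min_biomass_total": float(tb.min()),
                "oscillation_range": float(tb.max() - tb.min()),
                "dominant_period": _dominant_period(out.times[sel], tb),
                "extinct": len(out.final_population) == 0,
            })
    return pd.DataFrame(rows)
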