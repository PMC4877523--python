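"""Simulation configuration: model parameters, grid geometry, rainfall forcing.

All quantities use the model's native unit system: biomass in grams,
water volumes per unit area in mm (strictly mm^-1 m^2, i.e. litres per
square metre), distances in metres, time in days.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = ["ConfigError", "RainfallRegime", "SimConfig"]


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass
class RainfallRegime:
    """Time-dependent precipitation R(t) in mm/day.

    Modes
    -----
    constant : R(t) = R0
    shift    : R(t) = R0 for t < t_shift, R1 afterwards (step change)
    sinusoid : R(t) = R0 + amplitude * sin(2*pi*t / period)
    """

    mode: str = "constant"
    R0: float = 1.3
    R1: Optional[float] = None
    t_shift: Optional[float] = None
    amplitude: float = 0.0
    period: float = 365.0

    def validate(self, t_end: float) -> None:
        if self.mode not in ("constant", "shift", "sinusoid"):
            raise ConfigError(f"unknown rainfall mode {self.mode!r}")
        if self.R0 < 0:
            raise ConfigError("R0 must be non-negative")
        if self.mode == "shift":
            if self.R1 is None or self.t_shift is None:
                raise ConfigError("shift regime requires R1 and t_shift")
            if self.R1 < 0:
                raise ConfigError("post-shift rainfall R1 must be non-negative")
        if self.mode == "sinusoid":
            if self.period <= 0:
                raise ConfigError("sinusoid period must be positive")
            # reject forcing that would drive rainfall negative at the trough
            if self.R0 - abs(self.amplitude) < 0:
                raise ConfigError(
                    "sinusoidal regime goes negative: |amplitude| exceeds R0"
                )

    def rate(self, t: float) -> float:
        """Precipitation at time t (days)."""
        if self.mode == "constant":
            return self.R0
        if self.mode == "shift":
            return self.R0 if t < self.t_shift else self.R1
        return self.R0 + self.amplitude * math.sin(2.0 * math.pi * t / self.period)


@dataclass
class SimConfig:
    """All tunable parameters of the hybrid vegetation model.

    Defaults are the standard calibration of the model (see docs/methods.md
    for the meaning and provenance of each value).
    """

    # -- plant metabolism --
    b: float = 10.0          # water-to-biomass conversion (g mm^-1 m^2)
    g_max: float = 0.05      # maximum water uptake (mm^-1 m^2 g^-1 d^-1)
    k1: float = 3.0          # half-saturation of growth/uptake (mm^-1 m^2)
    Kp: float = 800.0        # plant size limiting factor (g)
    d: float = 0.3           # biomass turnover rate (d^-1)

    # -- life cycle and dispersal --
    l: float = 365.0         # mean life expectancy (d)
    d_b: float = 0.8         # death threshold on B/Bmax (dimensionless)
    m: float = 0.0           # reproductive maturity (d)
    s: float = 0.002         # biomass-to-seedlings factor (seeds g^-1 d^-1)
    mu_disp: float = 10.0    # mean dispersal distance (m)
    sigma_disp: float = 1.5  # lognormal shape (log-sd, dimensionless)
    K_a: float = 30.0        # max biomass density for establishment (g m^-2)

    # -- soil hydrology --
    rain: RainfallRegime = field(default_factory=RainfallRegime)
    alpha: float = 0.1       # maximum infiltration rate (g^-1 d^-1)
    k2: float = 5.0          # infiltration saturation constant (g)
    W0: float = 0.15         # bare-soil infiltration rate (dimensionless)
    r_w: float = 0.1         # evaporation + drainage rate (d^-1)
    D_O: float = 10.0        # surface water diffusion (m^2 d^-1)
    D_W: float = 0.01        # soil water diffusion (m^2 d^-1)

    # -- grid geometry --
    dx: float = 4.0          # parcel side (m)
    nx: int = 100            # parcels along x
    ny: int = 100            # parcels along y

    # -- time stepping --
    dt_event: float = 0.2    # discrete event step (d)
    dt_int: float = 0.02     # RK4 integration substep (d)
    T_end: float = 1825.0    # simulation horizon (d)

    # -- randomness & behaviour switches --
    seed: int = 0
    age_mortality_enabled: bool = True
    age_mortality_mode: str = "hazard"  # "hazard" (exp lifetime) or "cutoff"
    age_mortality_off_after: Optional[float] = None  # disable age death past t
    # water-stress death law once B/Bmax < d_b:
    #   "graded": p_day = 1 - B/(d_b*Bmax), rising smoothly from 0
    #   "abrupt": p_day = 1 - (B/Bmax)*d_b, jumping to 1-d_b^2 at onset
    stress_death_mode: str = "graded"
    B_init_range: tuple = (1.0, 2.0)
    preemptive_seedling_removal: bool = False
    # infiltration denominator: the printed water equation divides the
    # vegetation infiltration factor by (W + k2); the saturating
    # variant of the parent grid-hydrology models divides by (P + k2)
    # instead (and makes the bare-soil initialization an exact fixed
    # point). See docs/methods.md.
    infiltration_literal_denominator: bool = True
    # couple the water equations to biomass density (g/m^2, volume draw
    # divided by parcel area) rather than raw per-parcel totals; at
    # dx = 1 m the two coincide
    biomass_density_coupling: bool = True
    boundary: str = "zero-flux"  # or "periodic"
    coupling: str = "coupled"    # "coupled" (shared RK4) or "split" (frozen-W)
    snapshot_every: float = 30.0  # snapshot cadence (d); 0 disables

    # ------------------------------------------------------------------
    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("b", "g_max", "k1", "Kp", "d", "l", "s", "mu_disp",
                     "sigma_disp", "K_a", "alpha", "k2", "W0", "r_w",
                     "D_O", "D_W", "dx", "m"):
            if getattr(self, name) < 0:
                raise ConfigError(f"parameter {name} must be non-negative")
        if not (0.0 < self.d_b <= 1.0):
            raise ConfigError("death threshold d_b must lie in (0, 1]")
        if self.nx < 1 or self.ny < 1:
            raise ConfigError("grid must contain at least one parcel")
        if self.dt_int <= 0 or self.dt_event <= 0:
            raise ConfigError("time steps must be positive")
        if self.dt_int > self.dt_event + 1e-12:
            raise ConfigError("dt_int must not exceed dt_event")
        # event steps must tile whole days so daily probabilities convert cleanly
        steps_per_day = 1.0 / self.dt_event
        if abs(steps_per_day - round(steps_per_day)) > 1e-9:
            raise ConfigError("dt_event must divide evenly into whole days")
        lo, hi = self.B_init_range
        if not (0 < lo <= hi):
            raise ConfigError("B_init_range must satisfy 0 < lo <= hi")
        if self.age_mortality_mode not in ("hazard", "cutoff"):
            raise ConfigError("age_mortality_mode must be 'hazard' or 'cutoff'")
        if self.stress_death_mode not in ("graded", "abrupt"):
            raise ConfigError("stress_death_mode must be 'graded' or 'abrupt'")
        if self.boundary not in ("zero-flux", "periodic"):
            raise ConfigError("boundary must be 'zero-flux' or 'periodic'")
        if self.coupling not in ("coupled", "split"):
            raise ConfigError("coupling must be 'coupled' or 'split'")
        self.rain.validate(self.T_end)

    # -- derived geometry ----------------------------------------------
    @property
    def Lx(self) -> float:
        """Plot extent along x (m)."""
        return self.nx * self.dx

    @property
    def Ly(self) -> float:
        """Plot extent along y (m)."""
        return self.ny * self.dx

    @property
    def plot_area(self) -> float:
        """Plot area (m^2)."""
        return self.Lx * self.Ly

    @property
    def n_substeps(self) -> int:
        """RK4 substeps per event step (at least 1)."""
        return max(1, round(self.dt_event / self.dt_int))

    # -- serialization --------------------------------------------------
    def replace(self, **kwargs) -> "SimConfig":
        """Return a validated copy with fields replaced."""
        rain_kwargs = {}
        for key in ("mode", "R0", "R1", "t_shift", "amplitude", "period"):
            if key in kwargs:
                rain_kwargs[key] = kwargs.pop(key)
        cfg = dataclasses.replace(self, **kwargs)
        if rain_kwargs:
            cfg.rain = dataclasses.replace(cfg.rain, **rain_kwargs)
            cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        rain = out.pop("rain")
        out["rain_mode"] = rain["mode"]
        out["R0"] = rain["R0"]
        out["R1"] = rain["R1"]
        out["t_shift"] = rain["t_shift"]
        out["amplitude"] = rain["amplitude"]
        out["period"] = rain["period"]
        out["B_init_range"] = list(out["B_init_range"])
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        rain = RainfallRegime(
            mode=data.pop("rain_mode", "constant"),
            R0=data.pop("R0", 1.3),
            R1=data.pop("R1", None),
            t_shift=data.pop("t_shift", None),
            amplitude=data.pop("amplitude", 0.0),
            period=data.pop("period", 365.0),
        )
        if "B_init_range" in data:
            data["B_init_range"] = tuple(data["B_init_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(rain=rain, **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
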