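"""Parcel-grid water dynamics: infiltration, uptake, diffusion, RK4 stepping.

The state of each parcel is a surface-water depth O and a soil-water
depth W (both mm). Surface water is fed by rainfall R and lost to
infiltration; soil water gains the infiltrated flux and is depleted by
evaporation/drainage (rate r_w) and plant uptake. Both layers diffuse
laterally between neighbouring parcels:

    dW/dt = alpha*O*(SB + k2*W0)/(SB + k2) - g_max*W/(W + k1)*SB
            - r_w*W + D_W*lap(W)
    dO/dt = R - alpha*O*(SB + k2*W0)/(SB + k2) + D_O*lap(O)

with SB the total plant biomass on the parcel. Vegetated soil
infiltrates faster than bare soil (crust-breaking feedback): the
infiltration factor rises from W0 on bare soil towards 1 as SB grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig

__all__ = ["SoilGrid", "infiltration", "uptake_field", "laplacian",
           "water_step", "NumericalInstabilityError"]


class NumericalInstabilityError(RuntimeError):
    """Raised when the integrator produces NaN; reduce dt_int."""


@dataclass
class SoilGrid:
    """Per-parcel surface water O, soil water W and plant biomass totals."""

    O: np.ndarray          # surface water, (ny, nx), mm
    W: np.ndarray          # soil water, (ny, nx), mm
    dx: float              # parcel side, m
    Bsum: np.ndarray = None  # total plant biomass per parcel, g

    def __post_init__(self):
        self.O = np.asarray(self.O, dtype=np.float64)
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.O.shape != self.W.shape:
            raise ValueError("O and W must have identical shapes")
        if self.Bsum is None:
            self.Bsum = np.zeros_like(self.O)
        self.Bsum = np.asarray(self.Bsum, dtype=np.float64)
        if self.Bsum.shape != self.O.shape:
            raise ValueError("Bsum shape must match O and W")

    @property
    def shape(self):
        return self.O.shape

    def copy(self) -> "SoilGrid":
        return SoilGrid(self.O.copy(), self.W.copy(), self.dx, self.Bsum.copy())


def infiltration(O, Bsum, cfg: SimConfig, W=None):
    """Infiltration flux (mm/d): alpha*O*(Bsum + k2*W0)/(Bsum + k2).

    Saturating in vegetation biomass: equals alpha*O*W0 on bare soil and
    tends to alpha*O under dense cover. When the config selects the
    literal soil-water denominator variant, (W + k2) replaces
    (Bsum + k2) and W must be supplied.
    """
    O = np.asarray(O, dtype=np.float64)
    Bsum = np.asarray(Bsum, dtype=np.float64)
    P = Bsum / cfg.dx ** 2 if cfg.biomass_density_coupling else Bsum
    num = P + cfg.k2 * cfg.W0
    if cfg.infiltration_literal_denominator:
        if W is None:
            raise ValueError("literal denominator variant requires W")
        den = np.asarray(W, dtype=np.float64) + cfg.k2
    else:
        den = P + cfg.k2
    return cfg.alpha * O * num / den


def uptake_field(W, Bsum, cfg: SimConfig):
    """Plant water uptake per parcel (mm/d): g_max*W/(W+k1)*P.

    P is the parcel biomass (density g/m^2 under the default coupling,
    so the depth drawn equals the summed per-plant volume demand over
    the parcel area; raw grams otherwise)."""
    W = np.asarray(W, dtype=np.float64)
    Bsum = np.asarray(Bsum, dtype=np.float64)
    P = Bsum / cfg.dx ** 2 if cfg.biomass_density_coupling else Bsum
    return cfg.g_max * W / (W + cfg.k1) * P


def laplacian(field, dx: float, boundary: str = "zero-flux"):
    """Discrete 5-point Laplacian (per m^2) of a rectangular field.

    zero-flux reflects the edge cells (closed plot, mass conserving);
    periodic wraps.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 2:
        raise ValueError("field must be 2-D")
    if boundary == "zero-flux":
        padded = np.pad(field, 1, mode="edge")
    elif boundary == "periodic":
        padded = np.pad(field, 1, mode="wrap")
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    return (padded[:-2, 1:-1] + padded[2:, 1:-1]
            + padded[1:-1, :-2] + padded[1:-1, 2:]
            - 4.0 * field) / dx ** 2


def _water_rhs(O, W, Bsum, R_t, cfg):
    inf = infiltration(O, Bsum, cfg, W=W)
    upt = uptake_field(W, Bsum, cfg)
    dW = inf - upt - cfg.r_w * W + cfg.D_W * laplacian(W, cfg.dx, cfg.boundary)
    dO = R_t - inf + cfg.D_O * laplacian(O, cfg.dx, cfg.boundary)
    return dO, dW


def water_step(grid: SoilGrid, R_t, cfg: SimConfig, dt: float,
               t0: float = 0.0) -> SoilGrid:
    """Advance O and W over dt by RK4 substeps of size <= cfg.dt_int.

    Bsum is held frozen for the whole step (the coupled scheduler
    instead refreshes it every substep). ``R_t`` may be a constant or a
    callable R(t). Returns a new grid; states clamped non-negative.
    """
    rate = R_t if callable(R_t) else (lambda t: R_t)
    n_sub = max(1, int(round(dt / cfg.dt_int)))
    h = dt / n_sub
    O, W = grid.O.copy(), grid.W.copy()
    Bsum = grid.Bsum
    for i in range(n_sub):
        t = t0 + i * h
        k1o, k1w = _water_rhs(O, W, Bsum, rate(t), cfg)
        k2o, k2w = _water_rhs(O + 0.5 * h * k1o, W + 0.5 * h * k1w, Bsum,
                              rate(t + 0.5 * h), cfg)
        k3o, k3w = _water_rhs(O + 0.5 * h * k2o, W + 0.5 * h * k2w, Bsum,
                              rate(t + 0.5 * h), cfg)
        k4o, k4w = _water_rhs(O + h * k3o, W + h * k3w, Bsum,
                              rate(t + h), cfg)
        O = O + (h / 6.0) * (k1o + 2 * k2o + 2 * k3o + k4o)
        W = W + (h / 6.0) * (k1w + 2 * k2w + 2 * k3w + k4w)
        np.maximum(O, 0.0, out=O)
        np.maximum(W, 0.0, out=W)
    if not (np.all(np.isfinite(O)) and np.all(np.isfinite(W))):
        raise NumericalInstabilityError(
            "water integration produced non-finite values; reduce dt_int")
    return SoilGrid(O, W, grid.dx, Bsum.copy())
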