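"""Per-plant biomass dynamics and water demand.

Biomass follows a water-limited logistic-type growth with constant
turnover:

    dB/dt = B * b * g_max * (1 - B/Kp) * W/(W + k1) - B * d

where W is the soil water of the parcel the plant sits on. Water drawn
by a plant is proportional to its biomass, g_max*W/(W+k1)*B, so the
parcel total matches the uptake term of the water equations. Note the
asymmetry: the (1 - B/Kp) size cap limits growth only, not water draw.
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig
from .hydrology import NumericalInstabilityError, SoilGrid
from .population import Population

__all__ = ["growth_rate", "plant_water_demand", "metabolism_step"]


def growth_rate(B, W_local, cfg: SimConfig):
    """dB/dt (g/d) for biomass B under local soil water W_local."""
    B = np.asarray(B, dtype=np.float64)
    W = np.asarray(W_local, dtype=np.float64)
    return (B * cfg.b * cfg.g_max * (1.0 - B / cfg.Kp) * W / (W + cfg.k1)
            - B * cfg.d)


def plant_water_demand(B, W_local, cfg: SimConfig):
    """Water drawn by a plant (mm/d): g_max*W/(W+k1)*B, linear in B."""
    B = np.asarray(B, dtype=np.float64)
    W = np.asarray(W_local, dtype=np.float64)
    return cfg.g_max * W / (W + cfg.k1) * B


def metabolism_step(pop: Population, grid: SoilGrid, cfg: SimConfig,
                    dt: float) -> Population:
    """Integrate every plant's biomass over dt with frozen parcel water.

    RK4 with substeps of size <= cfg.dt_int; Bmax updated afterwards.
    This is the "frozen-W" half of the split coupling mode (the default
    coupled mode co-integrates plants and water instead). Returns a new
    population; no births or deaths happen here.
    """
    out = pop.copy()
    if len(out) == 0 or dt == 0.0:
        return out
    idx = out.parcel_index(cfg.dx, cfg.nx)
    W_local = grid.W.ravel()[idx]
    n_sub = max(1, int(round(dt / cfg.dt_int)))
    h = dt / n_sub
    B = out.B.copy()
    for _ in range(n_sub):
        r1 = growth_rate(B, W_local, cfg)
        r2 = growth_rate(B + 0.5 * h * r1, W_local, cfg)
        r3 = growth_rate(B + 0.5 * h * r2, W_local, cfg)
        r4 = growth_rate(B + h * r3, W_local, cfg)
        B = B + (h / 6.0) * (r1 + 2 * r2 + 2 * r3 + r4)
        np.maximum(B, 0.0, out=B)
    if not np.all(np.isfinite(B)):
        raise NumericalInstabilityError(
            "biomass integration produced non-finite values; reduce dt_int")
    out.B = B
    np.maximum(out.Bmax, B, out=out.Bmax)
    return out
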