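"""Fused RK4 integrator for the coupled water/biomass continuous block.

The scheduler advances one event step at a time; within the step the
surface water, soil water and every plant's biomass form one ODE system
integrated together (per-parcel biomass totals are refreshed at every
RK4 stage). This kernel is the hot loop and is compiled with numba; the
pure-NumPy operations in ``hydrology`` and ``metabolism`` provide the
reference semantics it is tested against.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

RAIN_CONSTANT = 0
RAIN_SHIFT = 1
RAIN_SINUSOID = 2


@njit(cache=True)
def _rain(mode, R0, R1, t_shift, amp, period, t):
    if mode == RAIN_SHIFT:
        return R0 if t < t_shift else R1
    if mode == RAIN_SINUSOID:
        return R0 + amp * math.sin(2.0 * math.pi * t / period)
    return R0


@njit(cache=True)
def _deriv(Of, Wf, Bf, pix, Bsum, dOf, dWf, dBf, R, nx, ny,
           alpha, k2, W0, rw, gmax, k1, b, Kp, d, DO, DW, dx2,
           periodic, literal, inv_area):
    ncell = nx * ny
    for c in range(ncell):
        Bsum[c] = 0.0
    for i in range(Bf.size):
        Bsum[pix[i]] += Bf[i] * inv_area
    for iy in range(ny):
        iyu = iy + 1 if iy + 1 < ny else (0 if periodic else iy)
        iyd = iy - 1 if iy - 1 >= 0 else (ny - 1 if periodic else iy)
        for ix in range(nx):
            ixr = ix + 1 if ix + 1 < nx else (0 if periodic else ix)
            ixl = ix - 1 if ix - 1 >= 0 else (nx - 1 if periodic else ix)
            c = iy * nx + ix
            o = Of[c]
            w = Wf[c]
            sb = Bsum[c]
            den = (w + k2) if literal else (sb + k2)
            inf = alpha * o * (sb + k2 * W0) / den
            upt = gmax * w / (w + k1) * sb
            lapo = (Of[iy * nx + ixr] + Of[iy * nx + ixl]
                    + Of[iyu * nx + ix] + Of[iyd * nx + ix] - 4.0 * o) / dx2
            lapw = (Wf[iy * nx + ixr] + Wf[iy * nx + ixl]
                    + Wf[iyu * nx + ix] + Wf[iyd * nx + ix] - 4.0 * w) / dx2
            dWf[c] = inf - upt - rw * w + DW * lapw
            dOf[c] = R - inf + DO * lapo
    for i in range(Bf.size):
        w = Wf[pix[i]]
        Bi = Bf[i]
        dBf[i] = Bi * b * gmax * (1.0 - Bi / Kp) * w / (w + k1) - d * Bi


@njit(cache=True)
def integrate_event_step(O, W, B, pix, t0, dt_event, n_sub,
                         rain_mode, R0, R1, t_shift, amp, period,
                         nx, ny, alpha, k2, W0, rw, gmax, k1, b, Kp, d,
                         DO, DW, dx2, periodic, literal, inv_area):
    """Advance flat O, W (length nx*ny) and B (per plant) in place over
    one event step using n_sub shared RK4 substeps.

    Returns the number of state entries clamped to zero.
    """
    ncell = nx * ny
    n = B.size
    h = dt_event / n_sub
    Bsum = np.empty(ncell)
    k1O = np.empty(ncell); k1W = np.empty(ncell); k1B = np.empty(n)
    k2O = np.empty(ncell); k2W = np.empty(ncell); k2B = np.empty(n)
    k3O = np.empty(ncell); k3W = np.empty(ncell); k3B = np.empty(n)
    k4O = np.empty(ncell); k4W = np.empty(ncell); k4B = np.empty(n)
    sO = np.empty(ncell); sW = np.empty(ncell); sB = np.empty(n)
    nclamp = 0
    for sub in range(n_sub):
        t = t0 + sub * h
        Ra = _rain(rain_mode, R0, R1, t_shift, amp, period, t)
        Rm = _rain(rain_mode, R0, R1, t_shift, amp, period, t + 0.5 * h)
        Rb = _rain(rain_mode, R0, R1, t_shift, amp, period, t + h)
        _deriv(O, W, B, pix, Bsum, k1O, k1W, k1B, Ra, nx, ny,
               alpha, k2, W0, rw, gmax, k1, b, Kp, d, DO, DW, dx2,
               periodic, literal, inv_area)
        for c in range(ncell):
            sO[c] = O[c] + 0.5 * h * k1O[c]
            sW[c] = W[c] + 0.5 * h * k1W[c]
        for i in range(n):
            sB[i] = B[i] + 0.5 * h * k1B[i]
        _deriv(sO, sW, sB, pix, Bsum, k2O, k2W, k2B, Rm, nx, ny,
               alpha, k2, W0, rw, gmax, k1, b, Kp, d, DO, DW, dx2,
               periodic, literal, inv_area)
        for c in range(ncell):
            sO[c] = O[c] + 0.5 * h * k2O[c]
            sW[c] = W[c] + 0.5 * h * k2W[c]
        for i in range(n):
            sB[i] = B[i] + 0.5 * h * k2B[i]
        _deriv(sO, sW, sB, pix, Bsum, k3O, k3W, k3B, Rm, nx, ny,
               alpha, k2, W0, rw, gmax, k1, b, Kp, d, DO, DW, dx2,
               periodic, literal, inv_area)
        for c in range(ncell):
            sO[c] = O[c] + h * k3O[c]
            sW[c] = W[c] + h * k3W[c]
        for i in range(n):
            sB[i] = B[i] + h * k3B[i]
        _deriv(sO, sW, sB, pix, Bsum, k4O, k4W, k4B, Rb, nx, ny,
               alpha, k2, W0, rw, gmax, k1, b, Kp, d, DO, DW, dx2,
               periodic, literal, inv_area)
        h6 = h / 6.0
        for c in range(ncell):
            O[c] += h6 * (k1O[c] + 2.0 * k2O[c] + 2.0 * k3O[c] + k4O[c])
            W[c] += h6 * (k1W[c] + 2.0 * k2W[c] + 2.0 * k3W[c] + k4W[c])
            if O[c] < 0.0:
                O[c] = 0.0
                nclamp += 1
            if W[c] < 0.0:
                W[c] = 0.0
                nclamp += 1
        for i in range(n):
            B[i] += h6 * (k1B[i] + 2.0 * k2B[i] + 2.0 * k3B[i] + k4B[i])
            if B[i] < 0.0:
                B[i] = 0.0
                nclamp += 1
    return nclamp


def rain_mode_code(mode: str) -> int:
    return {"constant": RAIN_CONSTANT, "shift": RAIN_SHIFT,
            "sinusoid": RAIN_SINUSOID}[mode]
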