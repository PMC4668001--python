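"""Numba kernels for the overdamped Langevin chain and the core-water
birth-death process.

Kept free of any package imports so the jitted signatures stay simple:
everything arrives as plain float64/int64 arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _force(x, i, n_coords, kT, well_c, well_w, well_lw, n_wells,
           couple, sw_c, sw_w, bias_k, bias_r0):
    """Force on coordinate i at position x[i] (kcal/mol/A, along +x)."""
    xi = x[i]
    # landscape term: U_i = -kT * ln sum_j exp(lw_j - (xi-c_j)^2 / (2 w_j^2))
    s = 0.0
    g = 0.0
    for j in range(n_wells[i]):
        d = xi - well_c[i, j]
        inv_w2 = 1.0 / (well_w[i, j] * well_w[i, j])
        e = np.exp(well_lw[i, j] - 0.5 * d * d * inv_w2)
        s += e
        g += e * d * inv_w2
    f = -kT * g / s

    # zipper coupling: U_c = -C * sum_k sig_k(x_k) * sig_{k+1}(x_{k+1})
    if couple != 0.0:
        sig_i = 1.0 / (1.0 + np.exp(-(xi - sw_c[i]) / sw_w))
        dsig_i = sig_i * (1.0 - sig_i) / sw_w
        neigh = 0.0
        if i > 0:
            neigh += 1.0 / (1.0 + np.exp(-(x[i - 1] - sw_c[i - 1]) / sw_w))
        if i < n_coords - 1:
            neigh += 1.0 / (1.0 + np.exp(-(x[i + 1] - sw_c[i + 1]) / sw_w))
        f += couple * dsig_i * neigh

    # half-harmonic restraint, repulsive branch only (r < r0)
    if bias_k[i] > 0.0 and xi < bias_r0[i]:
        f += bias_k[i] * (bias_r0[i] - xi)
    return f


@njit(cache=True)
def langevin_chain(x0, n_frames, stride, dt, gamma, kT,
                   well_c, well_w, well_lw, n_wells,
                   couple, sw_c, sw_w, bias_k, bias_r0, seed):
    """Euler-Maruyama integration of the coupled distance coordinates.

    Records every `stride` steps starting after the first stride block.
    Returns (frames[n_frames, n_coords], ok_flag, bad_frame).
    """
    np.random.seed(seed)
    n_coords = x0.shape[0]
    x = x0.copy()
    out = np.empty((n_frames, n_coords))
    amp = np.sqrt(2.0 * kT * dt / gamma)
    for fr in range(n_frames):
        for _ in range(stride):
            for i in range(n_coords):
                f = _force(x, i, n_coords, kT, well_c, well_w, well_lw,
                           n_wells, couple, sw_c, sw_w, bias_k, bias_r0)
                x[i] = x[i] + dt * f / gamma + amp * np.random.normal()
                if x[i] < 0.5:          # distances stay positive
                    x[i] = 1.0 - x[i]
                if not np.isfinite(x[i]):
                    return out, False, fr
        for i in range(n_coords):
            out[fr, i] = x[i]
    return out, True, -1


@njit(cache=True)
def water_process(gate, gate_threshold, entry_lam, entry_cap,
                  residual_lam, residual_cap, survive, seed, n0_entry,
                  n0_residual):
    """Immigration-death water count, exact per-frame transition.

    Each frame every water survives with probability `survive`
    (= exp(-off_rate * dt)) and Poisson(lam * (1 - survive)) new waters
    arrive, where lam is the stationary mean of the uncapped process.
    Entry immigration is gated on `gate > gate_threshold`; the residual
    component is always on.  Counts are capped.
    """
    np.random.seed(seed)
    n = gate.shape[0]
    out = np.empty(n, dtype=np.int64)
    ne = n0_entry
    nr = n0_residual
    arrival = 1.0 - survive
    for t in range(n):
        ne = np.random.binomial(ne, survive)
        nr = np.random.binomial(nr, survive)
        if gate[t] > gate_threshold and entry_lam > 0.0:
            ne += np.random.poisson(entry_lam * arrival)
        if residual_lam > 0.0:
            nr += np.random.poisson(residual_lam * arrival)
        if ne > entry_cap:
            ne = entry_cap
        if nr > residual_cap:
            nr = residual_cap
        out[t] = ne + nr
    return out
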