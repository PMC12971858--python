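"""Compiled forward-Euler inner loops for the delay and transit models.

The distributed-delay convolution makes the integration O(n_steps * kernel
length); these loops are JIT-compiled so that step-halving convergence runs
stay cheap.  All state flooring (nonnegativity) and divergence detection
happens here; the wrappers in :mod:`phagedyn.solvers` own the public API.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["euler_delay_loop", "euler_tc_loop"]


@njit(cache=True)
def euler_delay_loop(
    n_steps,
    dt,
    r_max,
    K_C,
    phi_max,
    P_50,
    delta_U,
    delta_I,
    delta_P,
    U0,
    P0,
    k_min,
    wI,
    wP,
):
    """Forward Euler for the delay model (fixed or distributed latent period).

    ``wI[j]`` / ``wP[j]`` are the infected-outflow and phage-source
    convolution weights for delay ``k_min + j`` grid steps: survival-weighted
    kernel mass  e^{-delta_I tau_k} w_k  and its burst-weighted variant
    beta_0(tau_k) e^{-delta_I tau_k} w_k.  The convolved history is
    H(s) = phi(s) U(s) P(s), zero before t = 0.

    Returns (U, I, P, status, n_floor): status is 0 on success or the 1-based
    step index at which a non-finite state appeared; n_floor counts
    negative-state floorings.
    """
    U = np.zeros(n_steps + 1)
    I = np.zeros(n_steps + 1)
    P = np.zeros(n_steps + 1)
    H = np.zeros(n_steps + 1)
    U[0] = U0
    P[0] = P0
    n_w = wI.shape[0]
    # reversed weights let each convolution run as one contiguous BLAS dot
    wIr = wI[::-1].copy()
    wPr = wP[::-1].copy()
    status = 0
    n_floor = 0
    for i in range(n_steps):
        phi = phi_max * P_50 / (P_50 + P[i])
        H[i] = phi * U[i] * P[i]
        s_out = 0.0
        s_src = 0.0
        j_hi = i - k_min + 1
        if j_hi > n_w:
            j_hi = n_w
        if j_hi > 0:
            lo = i - k_min - j_hi + 1
            hseg = H[lo:i - k_min + 1]
            s_out = np.dot(wIr[n_w - j_hi:], hseg)
            s_src = np.dot(wPr[n_w - j_hi:], hseg)
        r = r_max * (1.0 - (U[i] + I[i]) / K_C)
        dU = r * U[i] - delta_U * U[i] - H[i]
        dI = H[i] - delta_I * I[i] - s_out
        dP = s_src - delta_P * P[i] - phi * (U[i] + I[i]) * P[i]
        u = U[i] + dt * dU
        v = I[i] + dt * dI
        p = P[i] + dt * dP
        if u < 0.0:
            u = 0.0
            n_floor += 1
        if v < 0.0:
            v = 0.0
            n_floor += 1
        if p < 0.0:
            p = 0.0
            n_floor += 1
        if not (np.isfinite(u) and np.isfinite(v) and np.isfinite(p)):
            status = i + 1
            break
        U[i + 1] = u
        I[i + 1] = v
        P[i + 1] = p
    return U, I, P, status, n_floor


@njit(cache=True)
def euler_tc_loop(
    n_steps,
    dt,
    r_max,
    K_C,
    phi_max,
    P_50,
    delta_U,
    delta_I,
    delta_P,
    beta,
    N,
    k_tr,
    U0,
    P0,
):
    """Forward Euler for the N-stage transit-compartment (Erlang) model.

    Infection inflow enters stage 1; stages advance at rate k_tr and decay at
    delta_I; the outflow of stage N releases ``beta`` phages per cell.
    Reported I(t) is the sum over stages.  Returns like euler_delay_loop.
    """
    U = np.zeros(n_steps + 1)
    Isum = np.zeros(n_steps + 1)
    P = np.zeros(n_steps + 1)
    comp = np.zeros(N)
    U[0] = U0
    P[0] = P0
    status = 0
    n_floor = 0
    for i in range(n_steps):
        phi = phi_max * P_50 / (P_50 + P[i])
        inflow = phi * U[i] * P[i]
        itot = 0.0
        for j in range(N):
            itot += comp[j]
        r = r_max * (1.0 - (U[i] + itot) / K_C)
        dU = r * U[i] - delta_U * U[i] - inflow
        dP = beta * k_tr * comp[N - 1] - delta_P * P[i] \
            - phi * (U[i] + itot) * P[i]
        u = U[i] + dt * dU
        p = P[i] + dt * dP
        # update stages backward so each uses the previous-step upstream value
        for j in range(N - 1, 0, -1):
            c = comp[j] + dt * (k_tr * comp[j - 1] - (k_tr + delta_I) * comp[j])
            if c < 0.0:
                c = 0.0
                n_floor += 1
            comp[j] = c
        c = comp[0] + dt * (inflow - (k_tr + delta_I) * comp[0])
        if c < 0.0:
            c = 0.0
            n_floor += 1
        comp[0] = c
        if u < 0.0:
            u = 0.0
            n_floor += 1
        if p < 0.0:
            p = 0.0
            n_floor += 1
        itot = 0.0
        ok = True
        for j in range(N):
            itot += comp[j]
            if not np.isfinite(comp[j]):
                ok = False
        if not (np.isfinite(u) and np.isfinite(p) and ok):
            status = i + 1
            break
        U[i + 1] = u
        Isum[i + 1] = itot
        P[i + 1] = p
    return U, Isum, P, status, n_floor
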