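"""Fused numba kernel for iterating many generations quickly.

This is a performance twin of the reference path in
:mod:`tagkin.engine`; the test suite asserts the two agree to near
machine precision.  Importing this module raises if numba is missing, in
which case the engine silently falls back to the numpy reference path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_generations_fast"]


@njit(cache=True)
def _one_generation(x, F, phi, gamma, G, alpha, c_search, b, c,
                    mu_trait, mu_tag, N, m, r):
    L = x.shape[0]
    x_i = np.empty(L)
    p_i = np.empty(L)
    for i in range(L):
        x_i[i] = x[i, 0] + x[i, 1]
        p_i[i] = x[i, 1] / x_i[i] if x_i[i] > 0.0 else 0.0

    # --- M-terms -----------------------------------------------------------
    mint = np.empty(L)
    den = np.empty(L)
    for i in range(L):
        d = 1.0 - alpha * (1.0 - x_i[i]) * (1.0 - F)
        den[i] = d
        mint[i] = (F + (1.0 - F) * x_i[i]) / d if d > 0.0 else 0.0

    helper_freq = 0.0
    w_reach_num = 0.0
    uw_reach = 0.0
    for l in range(L):
        reach_l = x_i[l] + (1.0 - x_i[l]) * alpha * mint[l]
        helper_freq += x_i[l] * p_i[l]
        w_reach_num += x_i[l] * p_i[l] * reach_l
        uw_reach += p_i[l] * x_i[l] * reach_l
    w_reach = w_reach_num / helper_freq if helper_freq > 0.0 else 0.0

    pop_helped = 0.0
    for l in range(L):
        pop_helped += p_i[l] * x_i[l] * mint[l]

    frac = (N - 2.0) / N
    ind1 = np.empty(L)
    ind0 = np.empty(L)
    deme1 = np.empty(L)
    deme0 = np.empty(L)
    for i in range(L):
        if den[i] > 0.0:
            ind1[i] = (phi + (F - phi) * p_i[i] + (F - phi) * x_i[i]
                       + (1.0 - 2.0 * F + phi) * p_i[i] * x_i[i]) / den[i]
            ind0[i] = ((F - phi) * p_i[i]
                       + (1.0 - 2.0 * F + phi) * p_i[i] * x_i[i]) / den[i]
        else:
            ind1[i] = 0.0
            ind0[i] = 0.0
        deme1[i] = (mint[i] / N + ind1[i] / N
                    + frac * (gamma + (F - gamma) * helper_freq
                              + (F - gamma) * w_reach
                              + (1.0 - 2.0 * F + gamma) * uw_reach))
        deme0[i] = (ind0[i] / N
                    + frac * ((F - gamma) * helper_freq
                              + (1.0 - 2.0 * F + gamma) * uw_reach))

    # --- fitness -----------------------------------------------------------
    comp = 1.0 - m
    w = np.empty((L, 2))
    for i in range(L):
        w[i, 1] = (1.0 - c * mint[i] + b * ind1[i]
                   - (b - c) * (comp * deme1[i] + m * pop_helped))
        w[i, 0] = (1.0 + b * ind0[i]
                   - (b - c) * (comp * deme0[i] + m * pop_helped))

    if c_search > 0.0:
        ind_ab = np.empty(L)
        for i in range(L):
            q = alpha * (1.0 - F) * (1.0 - x_i[i])
            if q >= 1.0:
                # unbounded abandonment requires c_search = 0: signal failure
                bad = np.empty((L, 2))
                bad[:] = np.nan
                return bad
            ind_ab[i] = q / (1.0 - q)
        total_ab = 0.0
        sum_self = 0.0
        for l in range(L):
            total_ab += x_i[l] * ind_ab[l]
            sum_self += x_i[l] * (1.0 - x_i[l]) * alpha * (1.0 + ind_ab[l])
        for i in range(L):
            excl = total_ab - x_i[i] * ind_ab[i]
            deme_ab = (ind_ab[i] / N
                       + (1.0 / N) * (1.0 - F) * alpha * ((1.0 - x_i[i]) + excl)
                       + frac * ((F - G) * (1.0 - x_i[i]) * alpha
                                 * (1.0 + ind_ab[i])
                                 + (F - G) * alpha * ((1.0 - x_i[i]) + excl)
                                 + (1.0 - 3.0 * F + 2.0 * G) * sum_self))
            search = c_search * (ind_ab[i] - comp * deme_ab - m * total_ab)
            w[i, 0] -= search
            w[i, 1] -= search

    # --- selection ---------------------------------------------------------
    out = np.empty((L, 2))
    total = 0.0
    for i in range(L):
        for j in range(2):
            v = x[i, j] * w[i, j]
            if v < 0.0:
                out0 = np.empty((L, 2))
                out0[:] = np.nan
                return out0
            out[i, j] = v
            total += v
    for i in range(L):
        out[i, 0] /= total
        out[i, 1] /= total

    # --- recombination -----------------------------------------------------
    A = (2.0 * F - phi) * comp * comp
    Sd = 0.0
    Sh = 0.0
    for i in range(L):
        Sd += out[i, 0]
        Sh += out[i, 1]
    rec = np.empty((L, 2))
    for i in range(L):
        xd = out[i, 0]
        xh = out[i, 1]
        od = Sd - xd
        oh = Sh - xh
        rec[i, 1] = A * xh + (1.0 - A) * (
            xh * (xh + xd + (1.0 - r) * od + oh) + r * xd * oh)
        rec[i, 0] = A * xd + (1.0 - A) * (
            xd * (xd + xh + (1.0 - r) * oh + od) + r * xh * od)

    # --- mutation ----------------------------------------------------------
    fin = np.empty((L, 2))
    if mu_tag > 0.0 and L > 1:
        col0 = 0.0
        col1 = 0.0
        for i in range(L):
            col0 += rec[i, 0]
            col1 += rec[i, 1]
        for i in range(L):
            fin[i, 0] = (rec[i, 0] * (1.0 - mu_trait - mu_tag)
                         + rec[i, 1] * mu_trait
                         + (col0 - rec[i, 0]) * mu_tag / (L - 1.0))
            fin[i, 1] = (rec[i, 1] * (1.0 - mu_trait - mu_tag)
                         + rec[i, 0] * mu_trait
                         + (col1 - rec[i, 1]) * mu_tag / (L - 1.0))
    else:
        for i in range(L):
            fin[i, 0] = rec[i, 0] * (1.0 - mu_trait) + rec[i, 1] * mu_trait
            fin[i, 1] = rec[i, 1] * (1.0 - mu_trait) + rec[i, 0] * mu_trait
    return fin


@njit(cache=True)
def run_generations_fast(x, steps, F, phi, gamma, G, alpha, c_search, b, c,
                         mu_trait, mu_tag, N, m, r):
    """Run ``steps`` generations; returns (state, sum of sum(x_i^2), sum of p_bar)."""
    cur = x.copy()
    sumsq_acc = 0.0
    coop_acc = 0.0
    L = cur.shape[0]
    for _ in range(steps):
        cur = _one_generation(cur, F, phi, gamma, G, alpha, c_search, b, c,
                              mu_trait, mu_tag, float(N), m, r)
        if not np.isfinite(cur[0, 0]):
            break
        sumsq = 0.0
        coop = 0.0
        for i in range(L):
            t = cur[i, 0] + cur[i, 1]
            sumsq += t * t
            coop += cur[i, 1]
        sumsq_acc += sumsq
        coop_acc += coop
    return cur, sumsq_acc, coop_acc
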