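"""Numba-compiled ODE right-hand sides used by the integrator.

These mirror the reference implementations in :mod:`repsync.core_model`
exactly (a test pins the equivalence); they exist only because the parameter
sweeps integrate thousands of trajectories and the pure-numpy versions are
too slow inside an adaptive stepper.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def classic_rhs_jit(y, t, alpha, alpha0, n, beta):
    """Single repressilator with linear degradation; y = (m1..m3, p1..p3)."""
    out = np.empty(6)
    for i in range(3):
        p_prev = y[3 + (i - 1) % 3]
        if p_prev < 0.0:
            p_prev = 0.0
        out[i] = -y[i] + alpha / (1.0 + p_prev ** n) + alpha0
        out[3 + i] = -beta * (y[3 + i] - y[i])
    return out


@njit(cache=True)
def coupled_rhs_jit(y, t, alphas, alpha0s, betas, n, k, km, kp):
    """Three repressilators sharing degradation enzymes; y = (m.flat, p.flat).

    Layout: y[3*i + j] is mRNA (i,j), y[9 + 3*i + j] is protein (i,j),
    i = repressilator, j = species within the cycle (0-based).
    """
    out = np.empty(18)
    m_sum = 0.0
    p_sum = 0.0
    for q in range(9):
        mv = y[q]
        pv = y[9 + q]
        if mv > 0.0:
            m_sum += mv
        if pv > 0.0:
            p_sum += pv
    for i in range(3):
        for j in range(3):
            q = 3 * i + j
            p_prev = y[9 + 3 * i + (j - 1) % 3]
            if p_prev < 0.0:
                p_prev = 0.0
            m = y[q]
            p = y[9 + q]
            m_pos = m if m > 0.0 else 0.0
            p_pos = p if p > 0.0 else 0.0
            out[q] = (alphas[i] / (1.0 + p_prev ** n) + alpha0s[i]
                      - k * m_pos / (km + m_sum))
            out[9 + q] = betas[i] * m - k * p_pos / (kp + p_sum)
    return out


@njit(cache=True)
def single_coupled_rhs_jit(y, t, alpha, alpha0, beta, n, k, km, kp):
    """One repressilator with the same saturating degradation, isolated.

    The saturation sums run over its own three mRNAs / proteins only; used to
    probe whether the weakest oscillator can sustain oscillations on its own.
    """
    out = np.empty(6)
    m_sum = 0.0
    p_sum = 0.0
    for j in range(3):
        mv = y[j]
        pv = y[3 + j]
        if mv > 0.0:
            m_sum += mv
        if pv > 0.0:
            p_sum += pv
    for j in range(3):
        p_prev = y[3 + (j - 1) % 3]
        if p_prev < 0.0:
            p_prev = 0.0
        m = y[j]
        p = y[3 + j]
        m_pos = m if m > 0.0 else 0.0
        p_pos = p if p > 0.0 else 0.0
        out[j] = alpha / (1.0 + p_prev ** n) + alpha0 - k * m_pos / (km + m_sum)
        out[3 + j] = beta * m - k * p_pos / (kp + p_sum)
    return out
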