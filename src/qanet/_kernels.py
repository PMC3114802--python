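"""Numerical core of the mass-action trajectory solver.

The integrator is the modified Euler (Heun) predictor-corrector with a
fixed step and clamping of negative concentrations to zero. The inner loop
is compiled with numba when available; the pure-Python fallback is the same
function uncompiled, so both paths produce identical arithmetic.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def _deriv(x, k, f_idx, f_off, s_idx, s_coef, s_off, rates, dx):
    n_r = k.size
    for i in range(x.size):
        dx[i] = 0.0
    for j in range(n_r):
        r = k[j]
        for t in range(f_off[j], f_off[j + 1]):
            r *= x[f_idx[t]]
        rates[j] = r
    for j in range(n_r):
        for t in range(s_off[j], s_off[j + 1]):
            dx[s_idx[t]] += s_coef[t] * rates[j]


@njit(cache=False)
def heun_integrate(x0, k, f_idx, f_off, s_idx, s_coef, s_off, h, n_steps):
    """Integrate n_steps of size h from x0.

    Returns (trajectory[(n_steps+1) x n_species], n_clamped, finite_flag).
    """
    n_s = x0.size
    traj = np.empty((n_steps + 1, n_s))
    x = x0.copy()
    for i in range(n_s):
        traj[0, i] = x[i]
    rates = np.empty(k.size)
    dx1 = np.empty(n_s)
    dx2 = np.empty(n_s)
    xt = np.empty(n_s)
    n_clamped = 0
    for step in range(n_steps):
        _deriv(x, k, f_idx, f_off, s_idx, s_coef, s_off, rates, dx1)
        for i in range(n_s):
            v = x[i] + h * dx1[i]
            if v < 0.0:
                v = 0.0
                n_clamped += 1
            xt[i] = v
        _deriv(xt, k, f_idx, f_off, s_idx, s_coef, s_off, rates, dx2)
        finite = True
        for i in range(n_s):
            v = x[i] + 0.5 * h * (dx1[i] + dx2[i])
            if v < 0.0:
                v = 0.0
                n_clamped += 1
            x[i] = v
            traj[step + 1, i] = v
            if not np.isfinite(v):
                finite = False
        if not finite:
            return traj, n_clamped, False
    return traj, n_clamped, True
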