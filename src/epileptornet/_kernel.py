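"""Numba-compiled fixed-step RK4 integrator for the coupled Epileptor network.

The kernel is shared by the single-oscillator and network front ends (a
single node is a 1-node network with zero coupling).  All branching
conventions (which variable feeds the slow low-pass filter g, which variable
the f2 branch condition tests, and the sign of the permittivity coupling)
are passed in as scalars so a single compiled function covers every
configuration.

State layout per node: (x1, y1, z, x2, y2, g).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: index meaning of the last state axis
STATE_VARS = ("x1", "y1", "z", "x2", "y2", "g")


@njit(cache=True)
def _rhs(y, S, has_coupling, x0, I1, I2, inv_tau0, inv_tau2, gamma,
         g_from_x2, f2_on_x2, coupling_sign, dy):  # pragma: no cover - compiled
    n = y.shape[0]
    for i in range(n):
        x1 = y[i, 0]
        y1 = y[i, 1]
        z = y[i, 2]
        x2 = y[i, 3]
        y2 = y[i, 4]
        g = y[i, 5]

        if x1 < 0.0:
            f1v = x1 * x1 * x1 - 3.0 * x1 * x1
        else:
            d = z - 4.0
            f1v = (x2 - 0.6 * d * d) * x1

        c = 0.0
        if has_coupling:
            for j in range(n):
                c += S[i, j] * (x1 - y[j, 0])

        bvar = x2 if f2_on_x2 else x1
        f2v = 0.0 if bvar < -0.25 else 6.0 * (x2 + 0.25)
        gin = x2 if g_from_x2 else x1

        dy[i, 0] = y1 - f1v - z + I1
        dy[i, 1] = 1.0 - 5.0 * x1 * x1 - y1
        dy[i, 2] = inv_tau0 * (4.0 * (x1 - x0[i]) - z + coupling_sign * c)
        dy[i, 3] = -y2 + x2 - x2 * x2 * x2 + I2 + 0.002 * g - 0.3 * (z - 3.5)
        dy[i, 4] = inv_tau2 * (-y2 + f2v)
        dy[i, 5] = gin - gamma * g


@njit(cache=True)
def _rk4_run(y0, S, has_coupling, x0, I1, I2, tau0, tau2, gamma,
             g_from_x2, f2_on_x2, coupling_sign, dt, n_steps, record_every,
             noise, guard):  # pragma: no cover - compiled
    """Integrate; returns (records, n_recorded, bad_step).

    ``records`` holds the state every ``record_every``-th step, starting with
    the initial condition.  ``bad_step`` is 0 on success, else the 1-based
    index of the first step at which the overflow guard tripped.  ``noise``
    has shape (n_steps, n) and is added to x2 after each full RK4 step
    (Euler-Maruyama style; pass a (0, 0) array to disable).
    """
    n = y0.shape[0]
    inv_tau0 = 1.0 / tau0
    inv_tau2 = 1.0 / tau2
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, n, 6))
    y = y0.copy()
    out[0] = y
    k1 = np.empty((n, 6))
    k2 = np.empty((n, 6))
    k3 = np.empty((n, 6))
    k4 = np.empty((n, 6))
    yt = np.empty((n, 6))
    has_noise = noise.shape[0] > 0
    rec = 1
    for step in range(1, n_steps + 1):
        _rhs(y, S, has_coupling, x0, I1, I2, inv_tau0, inv_tau2, gamma,
             g_from_x2, f2_on_x2, coupling_sign, k1)
        for i in range(n):
            for v in range(6):
                yt[i, v] = y[i, v] + 0.5 * dt * k1[i, v]
        _rhs(yt, S, has_coupling, x0, I1, I2, inv_tau0, inv_tau2, gamma,
             g_from_x2, f2_on_x2, coupling_sign, k2)
        for i in range(n):
            for v in range(6):
                yt[i, v] = y[i, v] + 0.5 * dt * k2[i, v]
        _rhs(yt, S, has_coupling, x0, I1, I2, inv_tau0, inv_tau2, gamma,
             g_from_x2, f2_on_x2, coupling_sign, k3)
        for i in range(n):
            for v in range(6):
                yt[i, v] = y[i, v] + dt * k3[i, v]
        _rhs(yt, S, has_coupling, x0, I1, I2, inv_tau0, inv_tau2, gamma,
             g_from_x2, f2_on_x2, coupling_sign, k4)
        sixth = dt / 6.0
        for i in range(n):
            for v in range(6):
                y[i, v] = y[i, v] + sixth * (
                    k1[i, v] + 2.0 * k2[i, v] + 2.0 * k3[i, v] + k4[i, v])
        if has_noise:
            for i in range(n):
                y[i, 3] += noise[step - 1, i]
        ok = True
        for i in range(n):
            for v in range(6):
                val = y[i, v]
                if not (-guard <= val <= guard):
                    ok = False
        if not ok:
            return out, rec, step
        if step % record_every == 0:
            out[rec] = y
            rec += 1
    return out, rec, 0
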