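"""Inner integration loop of the muscle-tendon-unit simulator.

Kept free of Python objects so it can be JIT-compiled with numba when
available; falls back to the identical pure-Python loop otherwise.

Model: activation follows first-order dynamics toward the commanded
drive; contractile-element (CE) force is a * fl(l) * fv(v) * f_max with
a Gaussian force-length curve and a hyperbolic (concentric) /
exponential (eccentric) force-velocity curve; the series-elastic
element (SEE) has a quadratic toe and linear region. With the MTU end
fixed, SEE force is an algebraic function of fascicle length, and the
CE velocity is obtained each step by inverting the force-velocity curve
at the force-balance ratio.
"""

from __future__ import annotations

import math

import numpy as np


def _simulate_loop(
    desired_frac,  # float64[:] commanded torque / model MVT, may exceed 0..1 for MVC
    drive_mode,  # 0: closed-loop PI on desired_frac; 1: desired_frac is the drive u
    dt,
    lf0,
    f_max,
    l_opt,
    fl_width,
    vmax,
    fv_k,
    passive_lf,
    ext_toe,
    f_toe,
    k_lin,
    tau_up,
    tau_down,
    kp,
    ki,
    i_max,
    mvt,
):
    n = desired_frac.shape[0]
    force = np.empty(n)
    act = np.empty(n)
    fas = np.empty(n)
    a = 0.0
    lf = lf0
    integ = 0.0
    for i in range(n):
        # SEE force from fascicle length (fixed-end constraint)
        ext = passive_lf - lf
        if ext <= 0.0:
            f = 0.0
        elif ext <= ext_toe:
            r = ext / ext_toe
            f = f_toe * r * r
        else:
            f = f_toe + k_lin * (ext - ext_toe)

        # drive
        if drive_mode == 0:
            e = desired_frac[i] - f / mvt
            integ += e * dt
            if integ > i_max:
                integ = i_max
            elif integ < -i_max:
                integ = -i_max
            u = desired_frac[i] + kp * e + ki * integ
        else:
            u = desired_frac[i]
        if u < 0.0:
            u = 0.0
        elif u > 1.0:
            u = 1.0

        # first-order activation dynamics
        tau = tau_up if u > a else tau_down
        a += (u - a) / tau * dt
        if a < 0.0:
            a = 0.0
        elif a > 1.0:
            a = 1.0

        # CE velocity from force balance
        rel = (lf - l_opt) / (fl_width * l_opt)
        fl = math.exp(-rel * rel)
        denom = a * fl * f_max
        if denom < 1e-6 * f_max:
            v = 0.0 if f <= 1e-9 else 0.1 * vmax  # slack CE dragged by residual force
        else:
            fvr = f / denom
            if fvr > 1.499:
                fvr = 1.499
            if fvr <= 1.0:
                v = vmax * (fvr - 1.0) / (1.0 + fvr / fv_k)
            else:
                v = -0.1 * vmax * math.log(2.0 * (1.5 - fvr))
        lf += v * dt

        force[i] = f
        act[i] = a
        fas[i] = lf
    return force, act, fas


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    simulate_loop = njit(cache=False, fastmath=False)(_simulate_loop)
except Exception:  # pragma: no cover
    simulate_loop = _simulate_loop
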