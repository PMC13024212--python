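"""Compiled fixed-step RK4 integrator for the 5-state system.

Used as an optional fast path (``method="rk4"``) by :mod:`cysredox.simulate`
for evaluation-heavy workloads (calibration inner loops, Sobol designs,
bootstrap replicates).  The right-hand side is duplicated here in scalar
form so numba can compile it; :mod:`tests` pin it against the reference
implementation in :mod:`cysredox.model`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _rhs(y, p, out):
    C, G, R, S, A = y[0], y[1], y[2], y[3], y[4]
    kin, Cext, VG, KG, VS, KS, kC, alpha = p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7]
    kRG, kROS, beta, kS, kAO, kAS, kAd, H = p[8], p[9], p[10], p[11], p[12], p[13], p[14], p[15]
    mmG = VG * C / (KG + C)
    mmS = VS * C / (KS + C)
    detox = kRG * G * R
    out[0] = kin * Cext - mmG - mmS - kC * C
    out[1] = (1.0 + alpha * H) * mmG - detox
    out[2] = (1.0 + beta * H) * kROS - detox
    out[3] = mmS - kS * S
    out[4] = kAO * G * (1.0 - H) + kAS * S - kAd * A


@njit(cache=True)
def rk4_integrate(p, y0, t_end, dt):
    """Classic RK4 with a uniform step of at most ``dt`` over [0, t_end].

    Returns ``(ts, ys)`` with ``ts`` of length n+1 and ``ys`` of shape
    (n+1, 5); ``ys[0]`` is ``y0`` exactly.
    """
    n = int(np.ceil(t_end / dt))
    h = t_end / n
    ts = np.empty(n + 1)
    ys = np.empty((n + 1, 5))
    y = y0.copy()
    k1 = np.empty(5)
    k2 = np.empty(5)
    k3 = np.empty(5)
    k4 = np.empty(5)
    tmp = np.empty(5)
    ts[0] = 0.0
    ys[0] = y
    for i in range(n):
        _rhs(y, p, k1)
        for j in range(5):
            tmp[j] = y[j] + 0.5 * h * k1[j]
        _rhs(tmp, p, k2)
        for j in range(5):
            tmp[j] = y[j] + 0.5 * h * k2[j]
        _rhs(tmp, p, k3)
        for j in range(5):
            tmp[j] = y[j] + h * k3[j]
        _rhs(tmp, p, k4)
        for j in range(5):
            y[j] = y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        ts[i + 1] = (i + 1) * h
        ys[i + 1] = y
    return ts, ys
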