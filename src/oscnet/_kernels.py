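"""Inner integration/measure loops, numba-jitted when numba is available.

The noise streams are pre-drawn with numpy so that results are
bit-reproducible for a given seed regardless of the jit backend.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def sl_loop(r, theta, omegas, dst, src, dsteps, pref, lam, dt, noise_r, noise_th):
    """Euler–Maruyama loop for the Stuart-Landau system (in place)."""
    n, T = r.shape
    E = dst.shape[0]
    cr = np.zeros(n)
    cth = np.zeros(n)
    for t in range(T - 1):
        for j in range(n):
            cr[j] = 0.0
            cth[j] = 0.0
        for e in range(E):
            td = t - dsteps[e]
            if td < 0:
                td = 0
            rd = r[src[e], td]
            dph = theta[src[e], td] - theta[dst[e], t]
            cr[dst[e]] += rd * math.cos(dph)
            cth[dst[e]] += rd * math.sin(dph)
        for j in range(n):
            rt = r[j, t]
            dr = (lam - rt * rt) * rt + pref[j] * cr[j]
            denom = rt if rt > 1e-8 else 1e-8
            dth = omegas[j] + pref[j] * cth[j] / denom
            rn = rt + dt * dr + noise_r[j, t]
            r[j, t + 1] = rn if rn > 0.0 else 0.0
            theta[j, t + 1] = theta[j, t] + dt * dth + noise_th[j, t]


@njit(cache=True)
def kuramoto_loop(theta, omegas, dst, src, dsteps, pref, dt, noise_th):
    """Euler–Maruyama loop for the phase-only (Kuramoto) system (in place)."""
    n, T = theta.shape
    E = dst.shape[0]
    cth = np.zeros(n)
    for t in range(T - 1):
        for j in range(n):
            cth[j] = 0.0
        for e in range(E):
            td = t - dsteps[e]
            if td < 0:
                td = 0
            cth[dst[e]] += math.sin(theta[src[e], td] - theta[dst[e], t])
        for j in range(n):
            dth = omegas[j] + pref[j] * cth[j]
            theta[j, t + 1] = theta[j, t] + dt * dth + noise_th[j, t]


@njit(cache=True)
def dpli_counts(theta, tol):
    """Pairwise time-mean of sign(wrap(θ_i − θ_j)); antisymmetric output.

    Differences within (−2π, 2π] are wrapped by a single branch (the
    common case: phases already in (−π, π] or nearby); larger unwrapped
    differences fall back to fmod.
    """
    n, T = theta.shape
    out = np.zeros((n, n))
    two_pi = 2.0 * math.pi
    for i in range(n):
        for j in range(i + 1, n):
            s = 0.0
            for t in range(T):
                w = theta[i, t] - theta[j, t]
                if w > two_pi or w < -two_pi:
                    w = w % two_pi
                if w > math.pi:
                    w -= two_pi
                elif w <= -math.pi:
                    w += two_pi
                if w > tol:
                    s += 1.0
                elif w < -tol:
                    s -= 1.0
            out[i, j] = s / T
            out[j, i] = -out[i, j]
    return out
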