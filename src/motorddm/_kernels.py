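"""Numba kernels: Wiener first-passage densities and the diffusion simulator.

The first-passage-time density of the two-boundary Wiener process is computed
with the classic dual series representation (small-time and large-time
expansions of the same density), switching per evaluation to whichever series
needs fewer terms for the requested truncation error.

Across-trial drift variability is integrated analytically: the density's
drift dependence factorises as exp(-a*z*v - v^2 t / 2), which is Gaussian in
v, so mixing over v ~ Normal(v, sv) has closed form.  Across-trial ranges of
non-decision time (st) and starting point (sz) are integrated by
Gauss-Legendre quadrature.

All densities are for unit diffusion coefficient (the scaling convention in
which v and a are identified).
"""

import math

import numpy as np
from numba import njit

SQRT_2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True, fastmath=True)
def wfpt_fnorm(tt, w, err):
    """Normalized lower-boundary density f(tt | v=0, a=1, z=w).

    ``tt`` is decision time in units of a^2; truncation error < ``err``.
    Term counts follow the standard small-/large-time bounds.
    """
    if tt <= 0.0:
        return 0.0
    # terms needed by the large-time (Fourier sine) series
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi * math.pi * tt))
        lo = 1.0 / (math.pi * math.sqrt(tt))
        if kl < lo:
            kl = lo
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    # terms needed by the small-time (image/reflection) series
    sq = 2.0 * math.sqrt(2.0 * math.pi * tt)
    if sq * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(sq * err))
        lo = math.sqrt(tt) + 1.0
        if ks < lo:
            ks = lo
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:
        K = int(math.ceil(ks))
        kmin = -((K - 1) // 2)
        kmax = K // 2
        for k in range(kmin, kmax + 1):
            wk = w + 2.0 * k
            p += wk * math.exp(-wk * wk / (2.0 * tt))
        p /= SQRT_2PI * tt * math.sqrt(tt)
    else:
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += (
                k
                * math.exp(-k * k * math.pi * math.pi * tt / 2.0)
                * math.sin(k * math.pi * w)
            )
        p *= math.pi
    if p < 0.0:  # truncation can leave a tiny negative residue
        p = 0.0
    return p


@njit(cache=True, fastmath=True)
def fptd_lower_sv(t, v, a, z, sv, err):
    """Lower-boundary first-passage density with drift mixed over N(v, sv).

    sv = 0 reduces to the plain Wiener first-passage density.
    """
    if t <= 0.0:
        return 0.0
    a2 = a * a
    g = wfpt_fnorm(t / a2, z, err)
    if g <= 0.0:
        return 0.0
    m = 1.0 / (1.0 + sv * sv * t)
    lg = (a2 * z * z * sv * sv - 2.0 * a * v * z - v * v * t) * 0.5 * m
    return g / a2 * math.sqrt(m) * math.exp(lg)


@njit(cache=True, fastmath=True)
def full_density_one(rt, upper, v, a, ter, z, sv, st, sz, xq, wq, err):
    """Defective density of (rt, boundary) with st/sz quadrature, sv analytic.

    ``upper`` selects the boundary; upper-boundary density equals the
    lower-boundary density under (v, z) -> (-v, 1-z).  Quadrature nodes
    ``xq``/``wq`` are Gauss-Legendre on [-1, 1]; dimensions with zero range
    are skipped exactly.
    """
    if upper:
        vv = -v
        zz = 1.0 - z
    else:
        vv = v
        zz = z
    nq = xq.shape[0]
    if st > 0.0:
        acc = 0.0
        if sz > 0.0:
            for j in range(nq):
                tj = rt - (ter + 0.5 * st * xq[j])
                s = 0.0
                for k in range(nq):
                    zk = zz + 0.5 * sz * xq[k]
                    s += wq[k] * fptd_lower_sv(tj, vv, a, zk, sv, err)
                acc += wq[j] * s * 0.5
            return acc * 0.5
        for j in range(nq):
            tj = rt - (ter + 0.5 * st * xq[j])
            acc += wq[j] * fptd_lower_sv(tj, vv, a, zz, sv, err)
        return acc * 0.5
    if sz > 0.0:
        acc = 0.0
        for k in range(nq):
            zk = zz + 0.5 * sz * xq[k]
            acc += wq[k] * fptd_lower_sv(rt - ter, vv, a, zk, sv, err)
        return acc * 0.5
    return fptd_lower_sv(rt - ter, vv, a, zz, sv, err)


@njit(cache=True, fastmath=True)
def full_density_batch(rt, upper, v, a, ter, z, sv, st, sz, xq, wq, err, out):
    """Vectorized full_density_one over trials (per-trial v, a, ter)."""
    for i in range(rt.shape[0]):
        out[i] = full_density_one(
            rt[i], upper[i], v[i], a[i], ter[i], z, sv, st, sz, xq, wq, err
        )
    return out


@njit(cache=True, fastmath=True)
def mixture_loglik_batch(rt, upper, v, a, ter, z, sv, st, sz,
                         p_outlier, u_dens, xq, wq, err, out):
    """Log of the contaminant mixture (1-p)*f + p*u per trial."""
    for i in range(rt.shape[0]):
        f = full_density_one(
            rt[i], upper[i], v[i], a[i], ter[i], z, sv, st, sz, xq, wq, err
        )
        mix = (1.0 - p_outlier) * f + p_outlier * u_dens
        if mix > 0.0:
            out[i] = math.log(mix)
        else:
            out[i] = -np.inf
    return out


@njit(cache=True)
def simulate_batch(seed, v, a, z0, ter, window, dt):
    """Euler-Maruyama diffusion paths with Brownian-bridge crossing detection.

    Per trial i the path starts at z0[i]*a[i] and runs with drift v[i] until
    a boundary is hit or the decision-time budget (window - ter[i]) runs out.
    Within each step the probability that the bridge between the two
    endpoints touched a boundary is applied, which removes almost all of the
    discretisation bias of naive Euler crossing checks.

    Returns (rt, boundary) arrays; boundary is 1 for upper, 0 for lower, -1
    (with rt = nan) for a missed response.
    """
    np.random.seed(seed)
    n = v.shape[0]
    rt = np.empty(n)
    bnd = np.empty(n, dtype=np.int8)
    sdt = math.sqrt(dt)
    for i in range(n):
        ai = a[i]
        x = z0[i] * ai
        tmax = window - ter[i]
        t = 0.0
        hit = -1
        thit = 0.0
        while t < tmax:
            xn = x + v[i] * dt + sdt * np.random.standard_normal()
            t += dt
            if xn >= ai:
                hit = 1
                thit = t
                break
            if xn <= 0.0:
                hit = 0
                thit = t
                break
            # bridge probability of an unobserved within-step touch
            pu = math.exp(-2.0 * (ai - x) * (ai - xn) / dt)
            if np.random.random() < pu:
                hit = 1
                thit = t - 0.5 * dt
                break
            pl = math.exp(-2.0 * x * xn / dt)
            if np.random.random() < pl:
                hit = 0
                thit = t - 0.5 * dt
                break
            x = xn
        if hit < 0:
            rt[i] = np.nan
            bnd[i] = -1
        else:
            rt[i] = thit + ter[i]
            bnd[i] = hit
    return rt, bnd
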