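"""Compiled kernel for the single-scatter validation mode.

The single-scatter-only, Compton-only configuration has a fixed control
flow (at most two free paths per history), which makes a scalar compiled
loop far faster than batched numpy for the deep-slab points where only one
history in 10^7 scores.  Physics and estimators are identical to the
generic engine; numba is optional and the vectorized kernel in
``transport`` is used when it is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f
        return wrap

_MEC2 = 0.51099895
_COS_FLOOR = 0.1


@njit(cache=False)
def _interp_loglog(x, lx, ly):
    """Scalar log-log interpolation on a *uniform* log-energy table."""
    z = math.log(x)
    step = (lx[-1] - lx[0]) / (lx.size - 1)
    p = (z - lx[0]) / step
    if p <= 0.0:
        return math.exp(ly[0])
    i = int(p)
    if i >= lx.size - 1:
        return math.exp(ly[-1])
    f = p - i
    return math.exp(ly[i] + f * (ly[i + 1] - ly[i]))


@njit(cache=False)
def single_scatter_kernel(nb, seed, beam_radius, t_slab, dws, radii, lateral,
                          e0, cutoff, lmu_e, lmu_v, lcv_e, lcv_v,
                          spec_lo, spec_bw, n_bins, ring_width, n_rings):
    """Analog single-scatter transport of ``nb`` photons; returns tallies.

    Outputs per detector plane: counts, sum/sum-of-squares of per-history
    fluence and kerma scores, fluence-energy sum and the binned fluence
    spectrum; plus the annular fluence profile at the first plane.
    """
    np.random.seed(seed)
    n_planes = dws.size
    counts = np.zeros(n_planes, np.int64)
    sum_f = np.zeros(n_planes)
    sum_f2 = np.zeros(n_planes)
    sum_k = np.zeros(n_planes)
    sum_k2 = np.zeros(n_planes)
    sum_we = np.zeros(n_planes)
    spec = np.zeros((n_planes, n_bins))
    ring_f = np.zeros(n_rings)
    ring_c = np.zeros(n_rings, np.int64)
    areas = np.pi * radii**2

    mu0 = _interp_loglog(e0, lmu_e, lmu_v)
    alpha0 = e0 / _MEC2
    eps_min = 1.0 / (1.0 + 2.0 * alpha0)
    w1 = -math.log(eps_min)
    w2 = 0.5 * (1.0 - eps_min * eps_min)
    p1 = w1 / (w1 + w2)

    for _ in range(nb):
        if beam_radius > 0.0:
            rr = beam_radius * math.sqrt(np.random.random())
            ph = 2.0 * math.pi * np.random.random()
            x = rr * math.cos(ph)
            y = rr * math.sin(ph)
        else:
            x = 0.0
            y = 0.0

        depth = -math.log(np.random.random()) / mu0
        if depth >= t_slab:
            sx = 0.0
            sy = 0.0
            cz = 1.0
            e_ph = e0
        else:
            # Klein-Nishina: composition-rejection in eps = E'/E
            eps = 1.0
            cos_t = 1.0
            for _it in range(1000):
                if np.random.random() < p1:
                    eps = eps_min ** (1.0 - np.random.random())
                else:
                    u = np.random.random()
                    eps = math.sqrt(eps_min * eps_min + u * (1.0 - eps_min * eps_min))
                cos_t = 1.0 - (1.0 / eps - 1.0) / alpha0
                sin2 = 1.0 - cos_t * cos_t
                if sin2 < 0.0:
                    sin2 = 0.0
                if np.random.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
                    break
            e2 = e0 * eps
            if cos_t <= 0.0 or e2 < cutoff:
                continue
            d_exit = (t_slab - depth) / cos_t
            mu2 = _interp_loglog(e2, lmu_e, lmu_v)
            if -math.log(np.random.random()) / mu2 < d_exit:
                continue  # second interaction: killed in single-scatter mode
            phi2 = 2.0 * math.pi * np.random.random()
            sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 0.0))
            sx = sin_t * math.cos(phi2)
            sy = sin_t * math.sin(phi2)
            x = x + d_exit * sx
            y = y + d_exit * sy
            if x * x + y * y >= lateral * lateral:
                continue
            cz = cos_t
            e_ph = e2

        conv = e_ph * _interp_loglog(e_ph, lcv_e, lcv_v)
        for k in range(n_planes):
            s = dws[k] / cz
            xk = x + sx * s
            yk = y + sy * s
            r2 = xk * xk + yk * yk
            if k == 0:
                ridx = int(math.sqrt(r2) / ring_width)
                if ridx < n_rings:
                    rw = 1.0 / (math.pi * ring_width * ring_width
                                * (2 * ridx + 1) * max(cz, _COS_FLOOR))
                    ring_f[ridx] += rw
                    ring_c[ridx] += 1
            if r2 <= radii[k] * radii[k]:
                w = 1.0 / (areas[k] * max(cz, _COS_FLOOR))
                counts[k] += 1
                sum_f[k] += w
                sum_f2[k] += w * w
                kw = w * conv
                sum_k[k] += kw
                sum_k2[k] += kw * kw
                sum_we[k] += w * e_ph
                b = int((e_ph - spec_lo) / spec_bw)
                if b < 0:
                    b = 0
                if b >= n_bins:
                    b = n_bins - 1
                spec[k, b] += w

    return counts, sum_f, sum_f2, sum_k, sum_k2, sum_we, spec, ring_f, ring_c
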