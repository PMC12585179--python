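"""Compiled fast path for simulation and slice-sampling.

The readable reference implementation of the latent cause model lives in
:mod:`latentcause.lcm`; fitting an animal evaluates the simulator around a
million times, so the trial loop, the error-likelihood objective and the
slice-sampling sweep are replicated here as numba kernels operating on plain
arrays.  Tests assert that the kernel and the reference simulator agree to
floating-point accuracy on random parameter sets.

Two exact shortcuts keep the chain fast without changing its distribution:

* slice sampling only ever compares the log target against the slice level
  ``y``, so the objective stops early once the running total plus the best
  possible contribution of the remaining trials is certainly below ``y``;
* the response threshold θ and response variance λ enter only the CR
  read-out, so their coordinate updates reuse the expected-shock trace of
  the (unchanged) latent dynamics instead of re-simulating them.

Parameter vectors follow :data:`latentcause.lcm.PARAM_NAMES` order:
[alpha, g, eta, max_em_iter, w0, sigma_r2, sigma_x2, theta, lam, K];
the two integer parameters are continuously relaxed and mapped back with a
ceiling inside the kernel.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "schedule_arrays",
    "simulate_er",
    "simulate_cr",
    "log_objective",
    "slice_chain",
]

_NEG_INF = -np.inf
_THETA_IDX = 7
_LAM_IDX = 8


def schedule_arrays(schedule):
    """Precompute per-schedule arrays consumed by the kernels.

    Returns (times, stimuli, us, delta_index, log_delta_unique): the pairwise
    time differences of the schedule take few distinct values, so the kernel
    evaluates the power-law temporal kernel once per unique Δτ per call.
    """
    times = np.ascontiguousarray(schedule.times, dtype=np.float64)
    stim = np.ascontiguousarray(schedule.stimuli, dtype=np.float64)
    us = np.ascontiguousarray(schedule.us, dtype=np.float64)
    n = times.shape[0]
    deltas = times[:, None] - times[None, :]
    lower = deltas[np.tril_indices(n, k=-1)]
    uniq = np.unique(lower)
    didx = np.zeros((n, n), dtype=np.int64)
    for t in range(1, n):
        didx[t, :t] = np.searchsorted(uniq, deltas[t, :t])
    return times, stim, us, didx, np.log(uniq)


@njit(cache=True, fastmath=True)
def simulate_er(p, times, stim, us, didx, logd_u):
    """Expected-shock trace E[r] per trial (the CR before thresholding)."""
    alpha = p[0]
    g = p[1]
    eta = p[2]
    em = int(math.ceil(p[3] - 1e-12))
    w0 = p[4]
    sr2 = p[5]
    sx2 = p[6]
    kmax = int(math.ceil(p[9] - 1e-12))

    n = times.shape[0]
    kern_u = np.exp(-g * logd_u)

    fsum = np.zeros((kmax, 2))
    fcnt = np.zeros(kmax)
    w = np.zeros((kmax, 2))
    assign = np.zeros(n, dtype=np.int64)
    er_out = np.zeros(n)

    inv2sx = 1.0 / (2.0 * sx2)
    log_norm_x = -math.log(2.0 * math.pi * sx2)  # 2-dim Gaussian normalizer (log)
    inv2sr = 1.0 / (2.0 * sr2)

    base = np.zeros(kmax + 1)  # log prior + log stimulus likelihood per slot
    post = np.zeros(kmax + 1)
    logm = np.zeros(kmax + 1)

    n_active = 0
    for t in range(n):
        x0 = stim[t, 0]
        x1 = stim[t, 1]
        r = us[t]
        has_new = n_active < kmax
        nslots = n_active + 1 if has_new else n_active

        # --- temporally discounted CRP prior ---------------------------------
        for j in range(nslots):
            post[j] = 0.0  # reuse as raw mass
        for tp in range(t):
            post[assign[tp]] += kern_u[didx[t, tp]]
        if has_new:
            post[n_active] = alpha

        # --- stimulus log likelihood per slot (fixed within the trial) -------
        for j in range(nslots):
            if j < n_active and fcnt[j] > 0.0:
                m0 = fsum[j, 0] / fcnt[j]
                m1 = fsum[j, 1] / fcnt[j]
            else:
                m0 = 0.0
                m1 = 0.0
            d0 = x0 - m0
            d1 = x1 - m1
            lp = math.log(post[j]) if post[j] > 0.0 else _NEG_INF
            base[j] = lp + log_norm_x - (d0 * d0 + d1 * d1) * inv2sx

        # --- anticipatory E[r] from the stimulus-only posterior --------------
        wn0 = w0  # prospective new cause's weights, learned within the trial
        wn1 = w0
        best = _NEG_INF
        for j in range(nslots):
            if base[j] > best:
                best = base[j]
        tot = 0.0
        for j in range(nslots):
            post[j] = math.exp(base[j] - best)
            tot += post[j]
        er = 0.0
        for j in range(nslots):
            post[j] /= tot
            if j < n_active:
                er += post[j] * (w[j, 0] * x0 + w[j, 1] * x1)
            else:
                er += post[j] * (wn0 * x0 + wn1 * x1)
        er_out[t] = er

        # --- EM loop: outcome likelihood in, posterior-weighted RW updates ---
        for _ in range(em):
            best = _NEG_INF
            for j in range(nslots):
                if j < n_active:
                    mu = w[j, 0] * x0 + w[j, 1] * x1
                else:
                    mu = wn0 * x0 + wn1 * x1
                d = r - mu
                logm[j] = base[j] - d * d * inv2sr
                if logm[j] > best:
                    best = logm[j]
            tot = 0.0
            for j in range(nslots):
                post[j] = math.exp(logm[j] - best)
                tot += post[j]
            for j in range(nslots):
                post[j] /= tot
            for j in range(n_active):
                err = r - (w[j, 0] * x0 + w[j, 1] * x1)
                step = eta * post[j] * err
                w[j, 0] += step * x0
                w[j, 1] += step * x1
            if has_new:
                err = r - (wn0 * x0 + wn1 * x1)
                step = eta * post[n_active] * err
                wn0 += step * x0
                wn1 += step * x1

        # --- MAP assignment (ties toward the lowest index) -------------------
        mp = 0
        for j in range(1, nslots):
            if post[j] > post[mp]:
                mp = j
        if has_new and mp == n_active:
            w[mp, 0] = wn0
            w[mp, 1] = wn1
            n_active += 1
        fsum[mp, 0] += x0
        fsum[mp, 1] += x1
        fcnt[mp] += 1.0
        assign[t] = mp
    return er_out


@njit(cache=True, fastmath=True)
def simulate_cr(p, times, stim, us, didx, logd_u):
    """Deterministic CR trace: Gaussian tail of E[r] above threshold θ."""
    er = simulate_er(p, times, stim, us, didx, logd_u)
    theta = p[_THETA_IDX]
    inv_sd = 1.0 / math.sqrt(2.0 * p[_LAM_IDX])
    cr = np.empty(er.shape[0])
    for t in range(er.shape[0]):
        cr[t] = 0.5 * (1.0 + math.erf((er[t] - theta) * inv_sd))
    return cr


@njit(cache=True, fastmath=True)
def _emission_obj(er, theta, lam, obs, const, inv2s2, y):
    """Half-normal error log likelihood of the read-out, with early exit.

    Returns the exact total when it ends up above ``y``; otherwise some
    value guaranteed to be <= the exact total's comparison side of ``y``.
    """
    n = er.shape[0]
    inv_sd = 1.0 / math.sqrt(2.0 * lam)
    total = 0.0
    for t in range(n):
        cr = 0.5 * (1.0 + math.erf((er[t] - theta) * inv_sd))
        d = cr - obs[t]
        e = d * d
        total += const - e * e * inv2s2
        # best possible remainder is `const` per remaining trial
        if total + (n - 1 - t) * const < y:
            return total + (n - 1 - t) * const
    return total


@njit(cache=True, fastmath=True)
def _obj_core(p, lob, hib, times, stim, us, didx, logd_u, obs, hn_sigma, y):
    for i in range(p.shape[0]):
        if p[i] < lob[i] or p[i] > hib[i]:
            return _NEG_INF
    const = math.log(math.sqrt(2.0 / math.pi) / hn_sigma)
    inv2s2 = 1.0 / (2.0 * hn_sigma * hn_sigma)
    er = simulate_er(p, times, stim, us, didx, logd_u)
    return _emission_obj(er, p[_THETA_IDX], p[_LAM_IDX], obs, const, inv2s2, y)


@njit(cache=True, fastmath=True)
def log_objective(p, lob, hib, times, stim, us, didx, logd_u, obs, hn_sigma):
    """Log target density: half-normal error likelihood inside the bound box.

    Per trial the squared CR error e_t = (sim_t - obs_t)^2 is scored on a
    half-normal density with scale ``hn_sigma``; outside the box the density
    is zero (uniform prior on the box).
    """
    return _obj_core(
        p, lob, hib, times, stim, us, didx, logd_u, obs, hn_sigma, _NEG_INF
    )


@njit(cache=True, fastmath=True)
def slice_chain(
    x0,
    n_steps,
    thin,
    lob,
    hib,
    widths,
    max_stepout,
    seed,
    times,
    stim,
    us,
    didx,
    logd_u,
    obs,
    hn_sigma,
):
    """Univariate-sweep slice sampler over the 10 parameters.

    Each step performs one stepping-out + shrinkage slice update per
    coordinate (Neal 2003); the total number of stepping-out expansions is
    capped at ``max_stepout`` and split at random between the two sides,
    which preserves the correct invariant distribution.  Brackets are
    clamped to the bound box.  Every ``thin``-th step is retained.

    Returns (samples, last_x, last_logp).
    """
    np.random.seed(seed)
    keep = n_steps // thin
    nd = x0.shape[0]
    out = np.empty((keep, nd))
    x = x0.copy()
    const = math.log(math.sqrt(2.0 / math.pi) / hn_sigma)
    inv2s2 = 1.0 / (2.0 * hn_sigma * hn_sigma)
    logp = log_objective(x, lob, hib, times, stim, us, didx, logd_u, obs, hn_sigma)
    if logp == _NEG_INF:
        raise ValueError("objective is -inf at the chain's starting point")
    er = simulate_er(x, times, stim, us, didx, logd_u)
    er_dirty = False
    kidx = 0
    for step in range(n_steps):
        for j in range(nd):
            # θ and λ leave the latent dynamics (hence `er`) untouched
            readout_only = j == _THETA_IDX or j == _LAM_IDX
            if readout_only and er_dirty:
                er = simulate_er(x, times, stim, us, didx, logd_u)
                er_dirty = False
            xj0 = x[j]
            y = logp + math.log(np.random.random())
            wj = widths[j]
            L = xj0 - wj * np.random.random()
            R = L + wj
            # stepping out with a randomly split cap on expansions
            nl = int(math.floor(max_stepout * np.random.random()))
            nr = max_stepout - 1 - nl
            if L < lob[j]:
                L = lob[j]
            else:
                while nl > 0:
                    x[j] = L
                    if readout_only:
                        f = _emission_obj(
                            er, x[_THETA_IDX], x[_LAM_IDX], obs, const, inv2s2, y
                        )
                    else:
                        f = _obj_core(
                            x, lob, hib, times, stim, us, didx, logd_u, obs,
                            hn_sigma, y,
                        )
                    if f <= y:
                        break
                    L -= wj
                    nl -= 1
                    if L < lob[j]:
                        L = lob[j]
                        break
            if R > hib[j]:
                R = hib[j]
            else:
                while nr > 0:
                    x[j] = R
                    if readout_only:
                        f = _emission_obj(
                            er, x[_THETA_IDX], x[_LAM_IDX], obs, const, inv2s2, y
                        )
                    else:
                        f = _obj_core(
                            x, lob, hib, times, stim, us, didx, logd_u, obs,
                            hn_sigma, y,
                        )
                    if f <= y:
                        break
                    R += wj
                    nr -= 1
                    if R > hib[j]:
                        R = hib[j]
                        break
            # shrinkage
            guard = 0
            while True:
                guard += 1
                xj = L + np.random.random() * (R - L)
                x[j] = xj
                if readout_only:
                    f = _emission_obj(
                        er, x[_THETA_IDX], x[_LAM_IDX], obs, const, inv2s2, y
                    )
                else:
                    f = _obj_core(
                        x, lob, hib, times, stim, us, didx, logd_u, obs, hn_sigma, y
                    )
                if f > y:
                    logp = f
                    if not readout_only:
                        er_dirty = True
                    break
                if guard > 1000:
                    x[j] = xj0
                    break
                if xj < xj0:
                    L = xj
                else:
                    R = xj
        if (step + 1) % thin == 0:
            out[kidx] = x
            kidx += 1
    return out, x, logp
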