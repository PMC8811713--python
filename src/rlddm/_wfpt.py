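"""Numba kernels: Wiener first-passage-time density and trial-loop likelihoods.

The density follows the series approximation of Navarro & Fuss (2009,
J. Math. Psych.): the standardized lower-boundary density is evaluated by
whichever of the small-time / large-time expansions needs fewer terms for a
requested absolute error, then rescaled to boundary separation ``a`` and
drift ``v``.  Between-trial drift variability ``sv`` uses the closed-form
Gaussian-mixture density; variability in non-decision time ``st`` and
starting point ``sz`` is handled by Gauss-Legendre quadrature over their
uniform supports.

Conventions (shared with the whole package):
  * diffusion coefficient fixed at 1
  * ``z`` is the relative starting point in (0, 1); response 1 = upper bound
  * all kernels return -inf log-likelihood for invalid parameter values so a
    rejection-style sampler can treat them as zero-probability states
"""

from __future__ import annotations

import numpy as np
from numba import njit

# 11-node Gauss-Legendre rule on [-1, 1]; weights sum to 2.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(11)
_GL_X.setflags(write=False)
_GL_W.setflags(write=False)

DEFAULT_ERR = 1e-4


@njit(cache=True)
def ftt01w(tt, w, err):
    """Standardized lower-bound first-passage density (a=1, v=0) at scaled
    time ``tt`` for relative start ``w``, to absolute error ``err``."""
    if tt <= 0.0:
        return 0.0
    # number of terms needed by the small-time expansion
    if 2.0 * np.sqrt(2.0 * np.pi * tt) * err < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tt * np.log(2.0 * err * np.sqrt(2.0 * np.pi * tt)))
        if ks < np.sqrt(tt) + 1.0:
            ks = np.sqrt(tt) + 1.0
    else:
        ks = 2.0
    # number of terms needed by the large-time expansion
    if np.pi * tt * err < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * tt * err) / (np.pi * np.pi * tt))
        if kl < 1.0 / (np.pi * np.sqrt(tt)):
            kl = 1.0 / (np.pi * np.sqrt(tt))
    else:
        kl = 1.0 / (np.pi * np.sqrt(tt))

    p = 0.0
    if ks < kl:  # small-time series
        K = int(np.ceil(ks))
        lower = -((K - 1) // 2)
        upper = (K - 1) // 2 + (K - 1) % 2
        for k in range(lower, upper + 1):
            wk = w + 2.0 * k
            p += wk * np.exp(-wk * wk / (2.0 * tt))
        p /= np.sqrt(2.0 * np.pi * tt * tt * tt)
    else:  # large-time series
        K = int(np.ceil(kl))
        for k in range(1, K + 1):
            p += k * np.exp(-k * k * np.pi * np.pi * tt / 2.0) * np.sin(k * np.pi * w)
        p *= np.pi
    if p < 0.0:
        p = 0.0  # truncation can undershoot slightly near the tails
    return p


@njit(cache=True)
def pdf_lower(u, v, a, w, sv, err):
    """Density of absorption at the LOWER boundary at decision time ``u``.

    ``w`` is the relative start measured from the lower boundary.  ``sv``
    integrates a Normal(v, sv^2) drift analytically.
    """
    if u <= 0.0:
        return 0.0
    tt = u / (a * a)
    p = ftt01w(tt, w, err)
    if p <= 0.0:
        return 0.0
    if sv > 0.0:
        den = 1.0 + sv * sv * u
        ex = (sv * sv * a * a * w * w - 2.0 * a * v * w - v * v * u) / (2.0 * den)
        return p / (a * a) * np.exp(ex) / np.sqrt(den)
    return p / (a * a) * np.exp(-v * a * w - v * v * u / 2.0)


@njit(cache=True)
def pdf_trial(rt, response, a, v, t, z, sv, st, sz, err, glx, glw):
    """Joint density of (boundary, rt) for one trial.

    ``response`` 1 means the upper boundary (evaluated by reflecting the
    lower-boundary density: v -> -v, z -> 1 - z).  Returns 0.0 outside the
    support and -1.0 for invalid parameters (caller maps that to -inf).
    """
    if a <= 0.0 or z <= 0.0 or z >= 1.0 or sv < 0.0 or st < 0.0 or sz < 0.0:
        return -1.0
    if t - st / 2.0 < 0.0:
        return -1.0
    if z - sz / 2.0 <= 0.0 or z + sz / 2.0 >= 1.0:
        return -1.0

    if response == 1:
        vv = -v
        ww = 1.0 - z
    else:
        vv = v
        ww = z

    if st <= 0.0 and sz <= 0.0:
        return pdf_lower(rt - t, vv, a, ww, sv, err)

    # average over uniform t and/or z perturbations by Gauss-Legendre
    total = 0.0
    if st > 0.0 and sz > 0.0:
        for i in range(glx.shape[0]):
            ti = t + 0.5 * st * glx[i]
            inner = 0.0
            for j in range(glx.shape[0]):
                wj = ww + 0.5 * sz * glx[j]
                inner += glw[j] * pdf_lower(rt - ti, vv, a, wj, sv, err)
            total += glw[i] * inner / 2.0
        return total / 2.0
    if st > 0.0:
        for i in range(glx.shape[0]):
            ti = t + 0.5 * st * glx[i]
            total += glw[i] * pdf_lower(rt - ti, vv, a, ww, sv, err)
        return total / 2.0
    for j in range(glx.shape[0]):
        wj = ww + 0.5 * sz * glx[j]
        total += glw[j] * pdf_lower(rt - t, vv, a, wj, sv, err)
    return total / 2.0


@njit(cache=True)
def q_trajectory_kernel(resp, fb, q0, alpha_pos, alpha_neg):
    """Delta-rule value trajectories for one subject x condition block.

    Returns the pre-choice expected values (q_upper, q_lower) per trial and
    the reward prediction error of the chosen option.  Only the chosen
    option is updated; a zero prediction error uses the positive-branch
    learning rate.
    """
    n = resp.shape[0]
    qu = np.empty(n)
    ql = np.empty(n)
    rpe = np.empty(n)
    qu_c = q0
    ql_c = q0
    for i in range(n):
        qu[i] = qu_c
        ql[i] = ql_c
        if resp[i] == 1:
            e = fb[i] - qu_c
            al = alpha_pos if e >= 0.0 else alpha_neg
            qu_c += al * e
        else:
            e = fb[i] - ql_c
            al = alpha_pos if e >= 0.0 else alpha_neg
            ql_c += al * e
        rpe[i] = e
    return qu, ql, rpe


@njit(cache=True)
def loglik_trials(rt, resp, a_arr, v_arr, t, z, sv, st, sz, err, glx, glw):
    """Sum of log wfpt densities with per-trial threshold and drift."""
    total = 0.0
    for i in range(rt.shape[0]):
        p = pdf_trial(rt[i], resp[i], a_arr[i], v_arr[i], t, z, sv, st, sz, err, glx, glw)
        if p <= 0.0:
            return -np.inf
        total += np.log(p)
    return total


@njit(cache=True)
def subject_loglik_basic(rt, resp, fb, bstart, qinit,
                         a_b, vs_b, t_b, z_b, ap_b, an_b,
                         sv, st, sz, err, glx, glw):
    """RLDDM log-likelihood for one subject without trial-wise regression.

    Per-block scalars are passed as arrays indexed by block so that
    condition-split parameters are supported.  ``bstart`` holds block
    boundaries into the concatenated trial arrays (length n_blocks + 1).
    """
    total = 0.0
    for b in range(bstart.shape[0] - 1):
        s = bstart[b]
        e = bstart[b + 1]
        ap = ap_b[b]
        an = an_b[b]
        if ap < 0.0 or ap > 1.0 or an < 0.0 or an > 1.0:
            return -np.inf
        qu, ql, _ = q_trajectory_kernel(resp[s:e], fb[s:e], qinit[b], ap, an)
        for i in range(e - s):
            v_i = (qu[i] - ql[i]) * vs_b[b]
            p = pdf_trial(rt[s + i], resp[s + i], a_b[b], v_i, t_b[b], z_b[b],
                          sv, st, sz, err, glx, glw)
            if p <= 0.0:
                return -np.inf
            total += np.log(p)
    return total


@njit(cache=True)
def softmax_loglik_kernel(resp, fb, bstart, qinit, beta_b, ap_b, an_b):
    """Softmax-RL (RT-free) log-likelihood for one subject."""
    total = 0.0
    for b in range(bstart.shape[0] - 1):
        s = bstart[b]
        e = bstart[b + 1]
        ap = ap_b[b]
        an = an_b[b]
        if ap < 0.0 or ap > 1.0 or an < 0.0 or an > 1.0:
            return -np.inf
        qu, ql, _ = q_trajectory_kernel(resp[s:e], fb[s:e], qinit[b], ap, an)
        beta = beta_b[b]
        for i in range(e - s):
            # overflow-safe log softmax of the observed response
            d = beta * (qu[i] - ql[i])
            if resp[s + i] == 1:
                x = -d
            else:
                x = d
            if x > 0.0:
                total += -(x + np.log1p(np.exp(-x)))
            else:
                total += -np.log1p(np.exp(x))
    return total


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


def seed_numba(seed: int) -> None:
    """Seed numba's internal RNG (independent of numpy's global state)."""
    _seed(np.uint32(seed % (2 ** 31)))


@njit(cache=True)
def em_first_passage(a, v, t, z, sv, st, sz, dt, horizon):
    """One Euler-Maruyama first-passage draw -> (response, rt).

    Between-trial variability perturbs v (normal), t and z (uniform) before
    the walk.  Each step applies the Brownian-bridge crossing correction
    (probability exp(-2 d0 d1 / dt) of an unobserved boundary hit between
    two interior endpoints), which removes the leading O(sqrt(dt))
    discretization bias.  Walks exceeding ``horizon`` seconds are redrawn.
    """
    while True:
        v_i = v + sv * np.random.randn() if sv > 0.0 else v
        t_i = t + st * (np.random.rand() - 0.5) if st > 0.0 else t
        z_i = z + sz * (np.random.rand() - 0.5) if sz > 0.0 else z
        x = z_i * a
        tt = 0.0
        sq = np.sqrt(dt)
        near = 5.0 * sq  # crossing prob < e^-50 beyond this; skip the exp
        while tt < horizon:
            x_new = x + v_i * dt + sq * np.random.randn()
            tt += dt
            if x_new >= a:
                return 1, t_i + tt
            if x_new <= 0.0:
                return 0, t_i + tt
            if a - x_new < near or a - x < near:
                if np.random.rand() < np.exp(-2.0 * (a - x) * (a - x_new) / dt):
                    return 1, t_i + tt
            elif x_new < near or x < near:
                if np.random.rand() < np.exp(-2.0 * x * x_new / dt):
                    return 0, t_i + tt
            x = x_new
        # horizon exceeded: redraw the whole trial


@njit(cache=True)
def em_sample_many(n, a, v, t, z, sv, st, sz, dt, horizon):
    resp = np.empty(n, dtype=np.int64)
    rt = np.empty(n)
    for i in range(n):
        r, x = em_first_passage(a, v, t, z, sv, st, sz, dt, horizon)
        resp[i] = r
        rt[i] = x
    return resp, rt


@njit(cache=True)
def sim_rl_block(n_trials, p_up, p_lo, q0, a, vs, t, z, ap, an,
                 sv, st, sz, dt, horizon):
    """Simulate one subject x condition block of the generative RLDDM.

    Feedback for the chosen option is Bernoulli with its scheduled
    probability; values update by the delta rule after each trial.
    """
    resp = np.empty(n_trials, dtype=np.int64)
    rt = np.empty(n_trials)
    fb = np.empty(n_trials)
    qu = q0
    ql = q0
    for i in range(n_trials):
        v_i = (qu - ql) * vs
        r, x = em_first_passage(a, v_i, t, z, sv, st, sz, dt, horizon)
        resp[i] = r
        rt[i] = x
        p_r = p_up if r == 1 else p_lo
        reward = 1.0 if np.random.rand() < p_r else 0.0
        fb[i] = reward
        if r == 1:
            e = reward - qu
            qu += (ap if e >= 0.0 else an) * e
        else:
            e = reward - ql
            ql += (ap if e >= 0.0 else an) * e
    return resp, rt, fb


@njit(cache=True)
def sim_rl_block_atrial(n_trials, p_up, p_lo, q0, a_arr, vs, t, z, ap, an,
                        sv, st, sz, dt, horizon):
    """As sim_rl_block but with a per-trial decision threshold array."""
    resp = np.empty(n_trials, dtype=np.int64)
    rt = np.empty(n_trials)
    fb = np.empty(n_trials)
    qu = q0
    ql = q0
    for i in range(n_trials):
        v_i = (qu - ql) * vs
        r, x = em_first_passage(a_arr[i], v_i, t, z, sv, st, sz, dt, horizon)
        resp[i] = r
        rt[i] = x
        p_r = p_up if r == 1 else p_lo
        reward = 1.0 if np.random.rand() < p_r else 0.0
        fb[i] = reward
        if r == 1:
            e = reward - qu
            qu += (ap if e >= 0.0 else an) * e
        else:
            e = reward - ql
            ql += (ap if e >= 0.0 else an) * e
    return resp, rt, fb
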