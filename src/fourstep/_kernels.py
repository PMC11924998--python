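"""Numba-jitted numerical kernels for the Two-Step learner.

The hot paths are the per-subject trial-sequence log likelihood and the
Metropolis-within-Gibbs sweeps of the hierarchical sampler; both run
millions of times during fitting and are kept free of Python objects.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT1_2 = 0.7071067811865476


@njit(cache=True)
def phi(x):
    """Standard normal CDF."""
    return 0.5 * (1.0 + math.erf(x * _SQRT1_2))


@njit(cache=True, fastmath=True)
def loglik_kernel(c1, s2, c2, rw, alpha, lam, bmf, bmb, bs2, p_rep,
                  n_skip, p_common):
    """Log likelihood of one subject's trial sequence under the hybrid
    SARSA(lambda) + model-based learner.

    Q-values evolve from trial 0; the summed log probability skips the
    first ``n_skip`` trials. ``s2`` is coded 1/2 for states A/B.
    """
    q00 = 0.0
    q01 = 0.0
    qa0 = 0.0
    qa1 = 0.0
    qb0 = 0.0
    qb1 = 0.0
    ll = 0.0
    prev = -1
    n = c1.shape[0]
    for t in range(n):
        a1 = c1[t]
        st = s2[t]
        a2 = c2[t]
        # model-based values via the one-step Bellman backup
        m1 = qa0 if qa0 > qa1 else qa1
        m2 = qb0 if qb0 > qb1 else qb1
        qmb0 = p_common * m1 + (1.0 - p_common) * m2
        qmb1 = (1.0 - p_common) * m1 + p_common * m2
        x0 = bmf * q00 + bmb * qmb0 + (p_rep if prev == 0 else 0.0)
        x1 = bmf * q01 + bmb * qmb1 + (p_rep if prev == 1 else 0.0)
        if st == 1:
            y0 = qa0
            y1 = qa1
        else:
            y0 = qb0
            y1 = qb1
        if t >= n_skip:
            d1 = x0 - x1 if a1 == 0 else x1 - x0
            d2 = bs2 * (y0 - y1) if a2 == 0 else bs2 * (y1 - y0)
            ll -= math.log1p(math.exp(-d1)) + math.log1p(math.exp(-d2))
        # within-trial SARSA updates: bootstrap, then reward, then trace
        qs2 = y0 if a2 == 0 else y1
        qs1 = q00 if a1 == 0 else q01
        d1u = qs2 - qs1
        qs1 += alpha * d1u
        d2u = rw[t] - qs2
        qs2 += alpha * d2u
        qs1 += alpha * lam * d2u
        if a1 == 0:
            q00 = qs1
        else:
            q01 = qs1
        if st == 1:
            if a2 == 0:
                qa0 = qs2
            else:
                qa1 = qs2
        else:
            if a2 == 0:
                qb0 = qs2
            else:
                qb1 = qs2
        prev = a1
    return ll


@njit(cache=True)
def _natural(raw, k):
    """Map a raw (probit-scale) value to the natural parameter scale:
    (0,1) for alpha/lambda, (0,10) for the betas, identity for p."""
    if k < 2:
        return phi(raw)
    if k < 5:
        return 10.0 * phi(raw)
    return raw


@njit(cache=True)
def _subject_ll(i, z, mu, ls, C1, S2, C2, RW, NT, n_skip, p_common):
    a = _natural(mu[0] + math.exp(ls[0]) * z[i, 0], 0)
    l = _natural(mu[1] + math.exp(ls[1]) * z[i, 1], 1)
    bf = _natural(mu[2] + math.exp(ls[2]) * z[i, 2], 2)
    bb = _natural(mu[3] + math.exp(ls[3]) * z[i, 3], 3)
    b2 = _natural(mu[4] + math.exp(ls[4]) * z[i, 4], 4)
    pr = _natural(mu[5] + math.exp(ls[5]) * z[i, 5], 5)
    n = NT[i]
    return loglik_kernel(C1[i, :n], S2[i, :n], C2[i, :n], RW[i, :n],
                         a, l, bf, bb, b2, pr, n_skip, p_common)


@njit(cache=True)
def run_chain(C1, S2, C2, RW, NT, seed, n_keep, n_warmup, n_scans,
              n_skip, p_common, mu_prior_sd, ls_prior_mu, ls_prior_sd):
    """One MCMC chain for the hierarchical model, with centered /
    non-centered interweaving.

    State: per-subject raw effects z[i,k] ~ N(0,1), group locations
    mu[k] and log-SDs ls[k] on the probit scale (subject parameter =
    transform(mu_k + exp(ls_k) * z_ik)). Each recorded iteration runs
    ``n_scans`` sweeps of:

    1. componentwise random-walk Metropolis on every z[i,k] given the
       group level (one likelihood evaluation per proposal) — the
       non-centered, data-informed move;
    2. a centered block that holds every subject's raw parameter values
       fixed while redrawing (mu_k, ls_k) from their conditional given
       those raws (exact conjugate normal for mu_k; a few 1-D Metropolis
       steps for ls_k), then back-solving z — this costs no likelihood
       evaluations and decorrelates the group level from the funnel.

    Proposal scales adapt toward ~44% acceptance during warmup only,
    then freeze, so the kept draws form a valid Markov chain. Returns
    (mu draws, sigma draws, natural-scale subject-parameter draws).
    """
    np.random.seed(seed)
    n_subj = NT.shape[0]
    z = 0.5 * np.random.standard_normal((n_subj, 6))
    mu = 0.3 * np.random.standard_normal(6)
    ls = ls_prior_mu + 0.3 * np.random.standard_normal(6)

    sz = np.full((n_subj, 6), 0.5)
    sls = 0.3

    ll = np.empty(n_subj)
    for i in range(n_subj):
        ll[i] = _subject_ll(i, z, mu, ls, C1, S2, C2, RW, NT, n_skip, p_common)

    out_mu = np.empty((n_keep, 6))
    out_sig = np.empty((n_keep, 6))
    out_th = np.empty((n_keep, n_subj, 6))
    adapt = 0.06
    mu_prec0 = 1.0 / (mu_prior_sd * mu_prior_sd)

    for it in range(n_warmup + n_keep):
        warm = it < n_warmup
        for _ in range(n_scans):
            # (1) non-centered subject-effect updates
            for i in range(n_subj):
                for k in range(6):
                    old = z[i, k]
                    prop = old + sz[i, k] * np.random.standard_normal()
                    z[i, k] = prop
                    new_ll = _subject_ll(i, z, mu, ls, C1, S2, C2, RW, NT,
                                         n_skip, p_common)
                    logr = new_ll - ll[i] - 0.5 * (prop * prop - old * old)
                    if math.log(np.random.random()) < logr:
                        ll[i] = new_ll
                        if warm:
                            sz[i, k] *= math.exp(adapt * 0.56)
                    else:
                        z[i, k] = old
                        if warm:
                            sz[i, k] *= math.exp(-adapt * 0.44)
            # (2) centered group updates holding subject raws fixed
            for k in range(6):
                sig = math.exp(ls[k])
                raw_sum = 0.0
                raw_sq = 0.0
                for i in range(n_subj):
                    r = mu[k] + sig * z[i, k]
                    z[i, k] = r  # temporarily store raw value
                    raw_sum += r
                # mu_k | sigma_k, raws: conjugate normal
                prec = n_subj / (sig * sig) + mu_prec0
                mean = (raw_sum / (sig * sig)) / prec
                mu[k] = mean + np.random.standard_normal() / math.sqrt(prec)
                for i in range(n_subj):
                    d = z[i, k] - mu[k]
                    raw_sq += d * d
                # ls_k | mu_k, raws: a few 1-D Metropolis steps
                for _rep in range(3):
                    old = ls[k]
                    prop = old + sls * np.random.standard_normal()
                    lp_old = (-n_subj * old
                              - 0.5 * raw_sq * math.exp(-2.0 * old)
                              - 0.5 * ((old - ls_prior_mu) / ls_prior_sd) ** 2)
                    lp_new = (-n_subj * prop
                              - 0.5 * raw_sq * math.exp(-2.0 * prop)
                              - 0.5 * ((prop - ls_prior_mu) / ls_prior_sd) ** 2)
                    if math.log(np.random.random()) < lp_new - lp_old:
                        ls[k] = prop
                # back-solve the non-centered effects
                sig = math.exp(ls[k])
                for i in range(n_subj):
                    z[i, k] = (z[i, k] - mu[k]) / sig
        if not warm:
            j = it - n_warmup
            for k in range(6):
                out_mu[j, k] = mu[k]
                out_sig[j, k] = math.exp(ls[k])
            for i in range(n_subj):
                for k in range(6):
                    out_th[j, i, k] = _natural(
                        mu[k] + math.exp(ls[k]) * z[i, k], k)
    return out_mu, out_sig, out_th
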