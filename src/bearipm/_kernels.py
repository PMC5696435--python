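"""Compiled inner loops for the Metropolis-within-Gibbs samplers.

The count-layer latent state is packed into one integer array ``lat`` of
shape (8, T, 2): rows are, in order,

    0 NC   before-harvest cubs
    1 NY   before-harvest yearlings
    2 AD   dependents surviving unweaned  (ND_BH = AD + BD)
    3 BD   yearlings surviving into dependence
    4 AS   subadults surviving without maturing  (NS_BH = AS + BS)
    5 BS   dependents weaning into subadulthood
    6 AA   adults surviving  (NA_BH = AA + BA)
    7 BA   subadults maturing into adulthood

Keeping the two binomial components of each class explicit (rather than only
their sum) makes every process term a plain Binomial or Poisson pmf, which
keeps the latent updates O(1) and exposes conjugate updates for most rates.
The marginal law of the sums is exactly the convolution-of-binomials process
model (validated against the exact likelihoods in the test suite).

Randomness inside compiled code uses numba's own ``np.random`` state, seeded
explicitly at each call, so sweeps are reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf

# latent row indices
NC, NY, AD, BD, AS, BS, AA, BA = 0, 1, 2, 3, 4, 5, 6, 7


@njit(cache=True)
def binom_lp(k, n, p):
    if n < 0 or k < 0 or k > n:
        return NEG_INF
    if p <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    if p >= 1.0:
        return 0.0 if k == n else NEG_INF
    return (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


@njit(cache=True)
def pois_lp(k, mu):
    if k < 0 or mu < 0.0:
        return NEG_INF
    if mu == 0.0:
        return 0.0 if k == 0 else NEG_INF
    return k * math.log(mu) - mu - math.lgamma(k + 1)


@njit(cache=True)
def _logaddexp(a, b):
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a > b:
        return a + math.log1p(math.exp(b - a))
    return b + math.log1p(math.exp(a - b))


@njit(cache=True)
def _nafter(lat, H, t, a, s):
    """Post-harvest abundance of age class a in year t (may be negative)."""
    if a == 0:
        v = lat[NC, t, s]
    elif a == 1:
        v = lat[NY, t, s]
    elif a == 2:
        v = lat[AD, t, s] + lat[BD, t, s]
    elif a == 3:
        v = lat[AS, t, s] + lat[BS, t, s]
    else:
        v = lat[AA, t, s] + lat[BA, t, s]
    return v - H[t, a, s]


@njit(cache=True)
def _cell_count_ll(counts, t, a, s, nafter, p):
    if nafter < 0:
        return NEG_INF
    ll = 0.0
    for k in range(counts.shape[1]):
        ll += binom_lp(counts[t, k, a, s], nafter, p)
        if ll == NEG_INF:
            return NEG_INF
    return ll


@njit(cache=True)
def _mu_cubs(lat, H, t, PhiA, P, L):
    """Poisson mean of the total cub crop appearing in year t (t >= 1)."""
    naf = _nafter(lat, H, t - 1, 4, 1)
    if naf < 0:
        return -1.0
    return naf * PhiA[t - 1, 1] * P[t - 1] * L[t - 1]


@njit(cache=True)
def latent_local_ll(
    i, t, s, lat, H, counts, PhiC, PhiY, PhiD, PhiS, PhiA,
    gamD, gamS, P, L, sr, p, ncap,
):
    """Sum of the joint-density terms that involve latent (i, t, s)."""
    T = lat.shape[1]
    v = lat[i, t, s]
    if v < 0 or v > ncap:
        return NEG_INF
    ll = 0.0

    if i == NC:
        na = v - H[t, 0, s]
        if t > 0:
            mu = _mu_cubs(lat, H, t, PhiA, P, L)
            if mu < 0.0:
                return NEG_INF
            share = sr[t - 1] if s == 0 else 1.0 - sr[t - 1]
            ll += pois_lp(v, mu * share)
        ll += _cell_count_ll(counts, t, 0, s, na, p)
        if t < T - 1:
            ll += binom_lp(lat[NY, t + 1, s], na, PhiC[t, s])

    elif i == NY:
        na = v - H[t, 1, s]
        if t > 0:
            ll += binom_lp(v, _nafter(lat, H, t - 1, 0, s), PhiC[t - 1, s])
        ll += _cell_count_ll(counts, t, 1, s, na, p)
        if t < T - 1:
            ll += binom_lp(lat[BD, t + 1, s], na, PhiY[t, s])

    elif i == AD or i == BD:
        na = lat[AD, t, s] + lat[BD, t, s] - H[t, 2, s]
        if t > 0:
            if i == AD:
                ll += binom_lp(
                    v,
                    _nafter(lat, H, t - 1, 2, s),
                    PhiD[t - 1, s] * (1.0 - gamD[t - 1, s]),
                )
            else:
                ll += binom_lp(v, _nafter(lat, H, t - 1, 1, s), PhiY[t - 1, s])
        ll += _cell_count_ll(counts, t, 2, s, na, p)
        if t < T - 1:
            ll += binom_lp(
                lat[AD, t + 1, s], na, PhiD[t, s] * (1.0 - gamD[t, s])
            )
            ll += binom_lp(lat[BS, t + 1, s], na, PhiD[t, s] * gamD[t, s])

    elif i == AS or i == BS:
        na = lat[AS, t, s] + lat[BS, t, s] - H[t, 3, s]
        if t > 0:
            if i == AS:
                ll += binom_lp(
                    v,
                    _nafter(lat, H, t - 1, 3, s),
                    PhiS[t - 1, s] * (1.0 - gamS[t - 1, s]),
                )
            else:
                ll += binom_lp(
                    v, _nafter(lat, H, t - 1, 2, s), PhiD[t - 1, s] * gamD[t - 1, s]
                )
        ll += _cell_count_ll(counts, t, 3, s, na, p)
        if t < T - 1:
            ll += binom_lp(
                lat[AS, t + 1, s], na, PhiS[t, s] * (1.0 - gamS[t, s])
            )
            ll += binom_lp(lat[BA, t + 1, s], na, PhiS[t, s] * gamS[t, s])

    else:  # AA or BA
        na = lat[AA, t, s] + lat[BA, t, s] - H[t, 4, s]
        if t > 0:
            if i == AA:
                ll += binom_lp(v, _nafter(lat, H, t - 1, 4, s), PhiA[t - 1, s])
            else:
                ll += binom_lp(
                    v, _nafter(lat, H, t - 1, 3, s), PhiS[t - 1, s] * gamS[t - 1, s]
                )
        ll += _cell_count_ll(counts, t, 4, s, na, p)
        if t < T - 1:
            ll += binom_lp(lat[AA, t + 1, s], na, PhiA[t, s])
            if s == 1:
                # adult females drive next year's cub crop, both sexes
                mu = _mu_cubs(lat, H, t + 1, PhiA, P, L)
                if mu < 0.0:
                    return NEG_INF
                ll += pois_lp(lat[NC, t + 1, 0], mu * sr[t])
                ll += pois_lp(lat[NC, t + 1, 1], mu * (1.0 - sr[t]))
    return ll


_PAIRS = ((AD, BD), (AS, BS), (AA, BA))


@njit(cache=True)
def count_latent_sweep(
    seed, lat, H, counts, PhiC, PhiY, PhiD, PhiS, PhiA,
    gamD, gamS, P, L, sr, p, ncap, scales,
):
    """One Metropolis sweep over every count-layer latent, in place.

    Each latent gets an integer random-walk proposal with a fixed per-site
    scale (symmetric, so no Hastings correction); each split pair also gets a
    sum-preserving exchange move whose shared terms cancel in the ratio.
    Returns the number of accepted moves.
    """
    np.random.seed(seed)
    T = lat.shape[1]
    accepted = 0
    for t in range(T):
        for s in range(2):
            for i in range(8):
                if t == 0 and (i == BD or i == BS or i == BA):
                    continue  # splits are undefined before the first transition
                old = lat[i, t, s]
                ll_old = latent_local_ll(
                    i, t, s, lat, H, counts, PhiC, PhiY, PhiD, PhiS, PhiA,
                    gamD, gamS, P, L, sr, p, ncap,
                )
                mag = 1 + int(np.random.random() * scales[i, t, s])
                if np.random.random() < 0.5:
                    mag = -mag
                lat[i, t, s] = old + mag
                ll_new = latent_local_ll(
                    i, t, s, lat, H, counts, PhiC, PhiY, PhiD, PhiS, PhiA,
                    gamD, gamS, P, L, sr, p, ncap,
                )
                if ll_new == NEG_INF or math.log(np.random.random() + 1e-300) >= (
                    ll_new - ll_old
                ):
                    lat[i, t, s] = old
                else:
                    accepted += 1
            if t > 0:
                for pair_idx in range(3):
                    ia = 2 + 2 * pair_idx
                    ib = ia + 1
                    olda = lat[ia, t, s]
                    oldb = lat[ib, t, s]
                    ll_old = latent_local_ll(
                        ia, t, s, lat, H, counts, PhiC, PhiY, PhiD, PhiS, PhiA,
                        gamD, gamS, P, L, sr, p, ncap,
                    ) + latent_local_ll(
                        ib, t, s, lat, H, counts, PhiC, PhiY, PhiD, PhiS, PhiA,
                        gamD, gamS, P, L, sr, p, ncap,
                    )
                    mag = 1 + int(np.random.random() * scales[ia, t, s])
                    if np.random.random() < 0.5:
                        mag = -mag
                    lat[ia, t, s] = olda + mag
                    lat[ib, t, s] = oldb - mag
                    ll_new = latent_local_ll(
                        ia, t, s, lat, H, counts, PhiC, PhiY, PhiD, PhiS, PhiA,
                        gamD, gamS, P, L, sr, p, ncap,
                    ) + latent_local_ll(
                        ib, t, s, lat, H, counts, PhiC, PhiY, PhiD, PhiS, PhiA,
                        gamD, gamS, P, L, sr, p, ncap,
                    )
                    if ll_new == NEG_INF or math.log(
                        np.random.random() + 1e-300
                    ) >= (ll_new - ll_old):
                        lat[ia, t, s] = olda
                        lat[ib, t, s] = oldb
                    else:
                        accepted += 1
    return accepted


@njit(cache=True)
def count_layer_logjoint(
    lat, H, counts, PhiC, PhiY, PhiD, PhiS, PhiA,
    gamD, gamS, P, L, sr, p, ncap,
):
    """Full count-layer log density: process priors + count observation terms.

    Initial-year latents carry a flat prior on {0, ..., ncap}, whose constant
    normalizer is omitted.
    """
    T = lat.shape[1]
    ll = 0.0
    for t in range(T):
        for s in range(2):
            for i in range(8):
                if lat[i, t, s] < 0 or lat[i, t, s] > ncap:
                    return NEG_INF
        # observation terms
        for s in range(2):
            for a in range(5):
                ll += _cell_count_ll(counts, t, a, s, _nafter(lat, H, t, a, s), p)
                if ll == NEG_INF:
                    return NEG_INF
        if t == 0:
            continue
        mu = _mu_cubs(lat, H, t, PhiA, P, L)
        if mu < 0.0:
            return NEG_INF
        ll += pois_lp(lat[NC, t, 0], mu * sr[t - 1])
        ll += pois_lp(lat[NC, t, 1], mu * (1.0 - sr[t - 1]))
        for s in range(2):
            ll += binom_lp(
                lat[NY, t, s], _nafter(lat, H, t - 1, 0, s), PhiC[t - 1, s]
            )
            ll += binom_lp(
                lat[AD, t, s],
                _nafter(lat, H, t - 1, 2, s),
                PhiD[t - 1, s] * (1.0 - gamD[t - 1, s]),
            )
            ll += binom_lp(
                lat[BD, t, s], _nafter(lat, H, t - 1, 1, s), PhiY[t - 1, s]
            )
            ll += binom_lp(
                lat[AS, t, s],
                _nafter(lat, H, t - 1, 3, s),
                PhiS[t - 1, s] * (1.0 - gamS[t - 1, s]),
            )
            ll += binom_lp(
                lat[BS, t, s], _nafter(lat, H, t - 1, 2, s),
                PhiD[t - 1, s] * gamD[t - 1, s],
            )
            ll += binom_lp(
                lat[AA, t, s], _nafter(lat, H, t - 1, 4, s), PhiA[t - 1, s]
            )
            ll += binom_lp(
                lat[BA, t, s], _nafter(lat, H, t - 1, 3, s),
                PhiS[t - 1, s] * gamS[t - 1, s],
            )
            if ll == NEG_INF:
                return NEG_INF
    return ll


@njit(cache=True)
def cmr_class_loglik(
    y, r, repro, length, weight, sex, adult_prev, elig, phi_S, phi_A,
    rho_scalar, p, p_prime, p_r,
):
    """Class-structured fast path of :func:`cmr_batch_loglik`.

    Survival is one of four values (subadult/adult x sex) selected by
    ``adult_prev`` and ``sex``; reproduction probability is a single scalar
    applied where ``elig`` (adult female years) is set.  ``weight`` counts
    how many identical histories each encoded row represents.  Same forward
    recursion as the general kernel.
    """
    n = y.shape[0]
    total = 0.0
    lp = math.log(p) if p > 0.0 else NEG_INF
    lq = math.log1p(-p) if p < 1.0 else NEG_INF
    lpp = math.log(p_prime) if p_prime > 0.0 else NEG_INF
    lqq = math.log1p(-p_prime) if p_prime < 1.0 else NEG_INF
    qr = rho_scalar * p_r
    lr1 = math.log(qr) if qr > 0.0 else NEG_INF
    lr0 = math.log1p(-qr) if qr < 1.0 else NEG_INF
    lphi = np.empty((2, 2))
    lqhi = np.empty((2, 2))
    for a in range(2):
        for s in range(2):
            ph = phi_A[s] if a == 1 else phi_S[s]
            lphi[a, s] = math.log(ph) if ph > 0.0 else NEG_INF
            lqhi[a, s] = math.log1p(-ph) if ph < 1.0 else NEG_INF
    for i in range(n):
        s = sex[i]
        la = 0.0
        ld = NEG_INF
        if repro[i, 0] >= 0 and elig[i, 0] == 1:
            la += lr1 if repro[i, 0] == 1 else lr0
        finished = False
        for j in range(1, length[i]):
            a = adult_prev[i, j]
            lph = lphi[a, s]
            lqh = lqhi[a, s]
            if r[i, j] == 1:
                total += weight[i] * (la + lqh + lpp)
                finished = True
                break
            if y[i, j] == 1:
                new_la = la + lph + lp
                new_ld = NEG_INF
            else:
                new_la = la + lph + lq
                new_ld = _logaddexp(la + lqh + lqq, ld)
            if repro[i, j] >= 0 and elig[i, j] == 1:
                if repro[i, j] == 1:
                    new_la += lr1
                    new_ld = NEG_INF
                else:
                    new_la += lr0
            la = new_la
            ld = new_ld
        if not finished:
            total += weight[i] * _logaddexp(la, ld)
    return total


@njit(cache=True)
def cmr_batch_loglik(y, r, repro, length, phi, rho, p, p_prime, p_r):
    """Total marginal CJS + dead-recovery + reproduction log-likelihood.

    ``y``, ``r`` are (n, Lmax) detection/recovery arrays; ``repro`` holds the
    reproduction record (-1 where none was collected, e.g. males or, in the
    detection-conditional mode, undetected years).  ``phi[i, j]`` is the
    survival probability of individual i over the interval ending at occasion
    j (column 0 unused); ``rho[i, j]`` the reproduction probability at
    occasion j (zero where ineligible).  Histories are conditioned on first
    capture; the forward recursion marginalizes the latent alive state over
    {alive, dead-unrecovered}, with dead recovery a terminal event.
    """
    n = y.shape[0]
    total = 0.0
    for i in range(n):
        la = 0.0
        ld = NEG_INF
        if repro[i, 0] >= 0:
            q = rho[i, 0] * p_r
            if repro[i, 0] == 1:
                la += math.log(q) if q > 0.0 else NEG_INF
            else:
                la += math.log1p(-q) if q < 1.0 else NEG_INF
        finished = False
        for j in range(1, length[i]):
            ph = phi[i, j]
            if r[i, j] == 1:
                contrib = la
                contrib += math.log(1.0 - ph) if ph < 1.0 else NEG_INF
                contrib += math.log(p_prime) if p_prime > 0.0 else NEG_INF
                total += contrib
                finished = True
                break
            if y[i, j] == 1:
                new_la = la + (math.log(ph) if ph > 0.0 else NEG_INF)
                new_la += math.log(p) if p > 0.0 else NEG_INF
                new_ld = NEG_INF
            else:
                new_la = la + (math.log(ph) if ph > 0.0 else NEG_INF)
                new_la += math.log1p(-p) if p < 1.0 else NEG_INF
                newly = la
                newly += math.log(1.0 - ph) if ph < 1.0 else NEG_INF
                newly += math.log1p(-p_prime) if p_prime < 1.0 else NEG_INF
                new_ld = _logaddexp(newly, ld)
            if repro[i, j] >= 0:
                q = rho[i, j] * p_r
                if repro[i, j] == 1:
                    new_la += math.log(q) if q > 0.0 else NEG_INF
                    new_ld = NEG_INF
                else:
                    new_la += math.log1p(-q) if q < 1.0 else NEG_INF
            la = new_la
            ld = new_ld
        if not finished:
            total += _logaddexp(la, ld)
    return total
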