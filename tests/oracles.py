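"""Shared enumeration oracles, independent of the library's kernels.

These recompute likelihoods by exhaustive summation over latent paths or
outcome spaces and are deliberately written from the model definitions
alone, so they can certify the forward-recursion and convolution kernels.
"""

import math

import numpy as np


def enumerate_cjs_loglik(y, r, phi, p, p_prime, repro=None, rho=None, p_r=None):
    """Brute-force marginal likelihood: sum over every latent alive path.

    A path is indexed by the occasion of death d (d = T means survived
    throughout).  Dead recovery happens only in the year of death, records
    y = r = 1, and ends the history; an unrecovered death leaves the bear
    unobservable ever after.
    """
    T = len(y)
    total = 0.0
    recovered = int(np.sum(r)) == 1
    for d in range(1, T + 1):
        prob = 1.0
        for j in range(1, min(d, T)):
            prob *= phi[j - 1]
        if d <= T - 1:
            prob *= 1.0 - phi[d - 1]
        ok = True
        for j in range(1, T):
            if j < d:  # alive at j
                prob *= p if y[j] == 1 else 1.0 - p
                if r[j] == 1:
                    ok = False
            elif j == d:  # newly dead at j
                if r[j] == 1:
                    if y[j] != 1 or j != T - 1:
                        ok = False
                    prob *= p_prime
                else:
                    if y[j] != 0:
                        ok = False
                    prob *= 1.0 - p_prime
            else:  # long dead: unobservable
                if y[j] != 0 or r[j] == 1:
                    ok = False
        if recovered and d != np.flatnonzero(np.asarray(r) == 1)[0]:
            ok = False
        if not recovered and d <= T - 1 and np.any(np.asarray(y)[d:] == 1):
            ok = False
        if ok and repro is not None:
            for j in range(T):
                q = rho * p_r
                if j < d:
                    prob *= q if repro[j] == 1 else 1.0 - q
                elif repro[j] == 1:
                    ok = False
        if ok:
            total += prob
    return math.log(total) if total > 0 else -math.inf


def all_histories(T):
    """Every coherent (y, r) history of length T (first capture at 0)."""
    import itertools

    out = []
    for ys in itertools.product([0, 1], repeat=T - 1):
        out.append((np.array((1,) + ys), np.zeros(T, dtype=int)))
    for tdead in range(1, T):
        for ys in itertools.product([0, 1], repeat=tdead - 1):
            y = np.array((1,) + ys + (1,))
            r = np.zeros(tdead + 1, dtype=int)
            r[tdead] = 1
            out.append((y, r))
    return out


def enumerate_litter_outcomes(l0, horizon):
    """All complete litter outcomes from initial size l0 up to `horizon`:
    extinction, weaning (certain from age 4), or right-censoring at the
    horizon after an unweaned assessment."""
    outs = []

    def rec(sizes, age):
        if sizes[-1] == 0:
            outs.append((tuple(sizes), None))
            return
        if age >= 2:
            if age >= 4:
                outs.append((tuple(sizes), age))
                return
            outs.append((tuple(sizes), age))  # weaned at this age
            if age == horizon:  # assessed unweaned, then study ends
                outs.append((tuple(sizes), None))
                return
        elif age == horizon:
            outs.append((tuple(sizes), None))
            return
        for nxt in range(sizes[-1] + 1):
            rec(sizes + [nxt], age + 1)

    for nxt in range(l0 + 1):
        rec([l0, nxt], 1)
    return outs
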