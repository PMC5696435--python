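"""Exact observation- and process-likelihood kernels.

These are the reference implementations used both by the samplers and by the
enumeration-oracle tests: a marginal Cormack-Jolly-Seber likelihood with dead
recovery (latent alive state integrated out by a forward recursion), the
litter size trajectory likelihood (zero-truncated Poisson initiation,
binomial attrition, piecewise weaning), the binomial repeated-count
observation term, and the year-to-year process likelihood with exact
convolution-of-binomials class transitions.

Dead-recovery coherence: a single recovery event drives both observation
vectors -- with probability p' a newly dead individual is recovered, which
records y = 1 AND r = 1 and ends the history; otherwise y = 0, r = 0 and the
individual is never observed again.  This preserves the three-outcome
structure of real recovery record-keeping and makes outcome probabilities sum
to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_model import (
    AgeClass,
    HarvestRecord,
    PopulationState,
    Sex,
    VitalRates,
    cub_recruitment_mean,
    weaning_probability,
)

__all__ = [
    "CMRHistory",
    "LitterRecord",
    "count_obs_loglik",
    "cjs_history_loglik",
    "repro_detection_loglik",
    "litter_loglik",
    "process_loglik",
    "binom_logpmf",
    "poisson_logpmf",
    "zt_poisson_logpmf",
    "binomial_sum_logpmf",
]

_NEG_INF = float("-inf")


def binom_logpmf(k: int, n: int, p: float) -> float:
    """Binomial log-pmf; -inf outside the support."""
    if n < 0 or k < 0 or k > n:
        return _NEG_INF
    if p <= 0.0:
        return 0.0 if k == 0 else _NEG_INF
    if p >= 1.0:
        return 0.0 if k == n else _NEG_INF
    return (
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )


def poisson_logpmf(k: int, mu: float) -> float:
    """Poisson log-pmf; handles the degenerate mu = 0 case exactly."""
    if k < 0 or mu < 0.0:
        return _NEG_INF
    if mu == 0.0:
        return 0.0 if k == 0 else _NEG_INF
    return k * math.log(mu) - mu - math.lgamma(k + 1)


def zt_poisson_logpmf(k: int, mu: float) -> float:
    """Zero-truncated Poisson log-pmf (support k >= 1)."""
    if k < 1 or mu <= 0.0:
        return _NEG_INF
    return poisson_logpmf(k, mu) - math.log(-math.expm1(-mu))


def binomial_sum_logpmf(n: int, n1: int, p1: float, n2: int, p2: float) -> float:
    """Log-pmf at ``n`` of the sum of two independent Binomials.

    Computed by exact convolution: logsumexp over Bin(j; n1, p1) *
    Bin(n - j; n2, p2).
    """
    if n < 0 or n > n1 + n2:
        return _NEG_INF
    lo = max(0, n - n2)
    hi = min(n, n1)
    if lo > hi:
        return _NEG_INF
    terms = [
        binom_logpmf(j, n1, p1) + binom_logpmf(n - j, n2, p2)
        for j in range(lo, hi + 1)
    ]
    m = max(terms)
    if m == _NEG_INF:
        return _NEG_INF
    return m + math.log(sum(math.exp(t - m) for t in terms))


@dataclass
class CMRHistory:
    """One marked individual's detection record, conditioned on first capture.

    Index 0 is the first-capture occasion (y[0] = 1 by construction and
    contributes no detection term).  ``y[j]`` is 1 when the individual was
    detected at occasion j, ``r[j]`` is 1 when it was recovered dead (which
    ends the history), and ``repro[j]`` (females only) is 1 when it was
    detected accompanied by new cubs.  ``z`` is the latent alive indicator --
    present only for simulated individuals, never in data.
    """

    individual_id: str
    entry_year: int
    y: np.ndarray
    r: np.ndarray
    sex: Sex
    age_at_entry: int
    repro: np.ndarray | None = None
    covariates: dict[str, np.ndarray] = field(default_factory=dict)
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.r = np.asarray(self.r, dtype=np.int8)
        if self.y.ndim != 1 or self.y.shape != self.r.shape:
            raise ValueError("y and r must be 1-d arrays of equal length")
        if self.repro is not None:
            self.repro = np.asarray(self.repro, dtype=np.int8)
            if self.repro.shape != self.y.shape:
                raise ValueError("repro must share the length of y and r")
            if self.sex is not Sex.FEMALE and np.any(self.repro == 1):
                raise ValueError(
                    f"individual {self.individual_id}: reproduction records "
                    "are only defined for females"
                )
        if self.y.size == 0:
            raise ValueError("history must include the first-capture occasion")
        recovered = np.flatnonzero(self.r == 1)
        if recovered.size > 1:
            raise ValueError(
                f"individual {self.individual_id}: multiple dead recoveries"
            )
        if recovered.size == 1:
            j = int(recovered[0])
            if j == 0:
                raise ValueError(
                    f"individual {self.individual_id}: recovered dead at entry"
                )
            if j != self.y.size - 1:
                raise ValueError(
                    f"individual {self.individual_id}: events recorded after "
                    "dead recovery"
                )
            if self.y[j] != 1:
                # a recovery is an observation: the coherence rule sets y = 1
                raise ValueError(
                    f"individual {self.individual_id}: dead recovery with y=0"
                )
            if self.repro is not None and self.repro[j] == 1:
                raise ValueError(
                    f"individual {self.individual_id}: reproduction detected "
                    "at the dead-recovery occasion"
                )

    @property
    def n_occasions(self) -> int:
        return int(self.y.size)

    @property
    def recovered_dead(self) -> bool:
        return bool(np.any(self.r == 1))

    def years(self) -> np.ndarray:
        return self.entry_year + np.arange(self.n_occasions)


@dataclass
class LitterRecord:
    """One litter's size trajectory from den exit to weaning or extinction.

    ``sizes[i]`` is the number of surviving young at litter age i (age 0 is
    the first assessment after den exit).  ``weaned_at`` is the litter age at
    which weaning was recorded, or None if the litter went extinct or the
    record is right-censored.
    """

    litter_id: str
    mother_id: str
    birth_year: int
    sizes: np.ndarray
    weaned_at: int | None = None
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.ndim != 1 or self.sizes.size == 0:
            raise ValueError("sizes must be a nonempty 1-d integer vector")
        if np.any(self.sizes < 0):
            raise ValueError("litter sizes must be nonnegative")
        if np.any(np.diff(self.sizes) > 0):
            raise ValueError(
                f"litter {self.litter_id}: sizes increase with age"
            )
        if self.weaned_at is not None:
            if self.weaned_at not in (2, 3, 4):
                raise ValueError(
                    f"litter {self.litter_id}: weaning age must be 2, 3 or 4"
                )
            if self.weaned_at != self.sizes.size - 1:
                raise ValueError(
                    f"litter {self.litter_id}: weaned_at must match the last "
                    "observed litter age"
                )

    @property
    def max_age(self) -> int:
        return int(self.sizes.size) - 1


def count_obs_loglik(count: int, n: int, p: float) -> float:
    """Binomial log-pmf of one replicated count around true abundance N.

    Counts larger than N are impossible under perfect classification and
    return -inf.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    return binom_logpmf(count, n, p)


def repro_detection_loglik(
    R: int, rho: float, p_r: float, alive_prob: float
) -> float:
    """Bernoulli log-pmf of a reproduction-status record.

    Success probability is rho * p_r * P(alive): a female must be alive,
    reproducing, and her cubs must be detected.  A dead female can never be
    seen with cubs, so R = 1 with alive_prob = 0 returns -inf.
    """
    q = rho * p_r * alive_prob
    if R == 1:
        return math.log(q) if q > 0.0 else _NEG_INF
    return math.log1p(-q) if q < 1.0 else _NEG_INF


def cjs_history_loglik(
    history: CMRHistory,
    phi: Sequence[float],
    p: float,
    p_prime: float,
    rho: Sequence[float] | float | None = None,
    p_r: float | None = None,
    repro_conditional_on_detection: bool = False,
) -> float:
    """Marginal log-likelihood of one CMR history with dead recovery.

    The latent alive chain is integrated out by a forward recursion over the
    states {alive, dead-unrecovered}; dead recovery is a terminal event (see
    module docstring for the coherence rule).  ``phi`` gives the survival
    probability for each interval (length n_occasions - 1).  When the history
    carries reproduction records, ``rho`` (scalar or per-occasion) and ``p_r``
    supply the reproduction and reproduction-detection probabilities; by
    default reproduction status is observable in every year the female is
    alive, with ``repro_conditional_on_detection`` restricting it to years
    with y = 1.

    Conditioning on first capture, the entry occasion contributes no term.
    Equals brute-force enumeration over all latent alive paths (tested).
    """
    T = history.n_occasions
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (T - 1,):
        raise ValueError(f"phi must have length {T - 1}, got {phi.shape}")
    has_repro = history.repro is not None
    if has_repro:
        if p_r is None or rho is None:
            raise ValueError("rho and p_r are required for reproduction records")
        rho_vec = np.broadcast_to(np.asarray(rho, dtype=float), (T,))

    log_alive = 0.0  # log P(alive at j, obs so far); conditioned on capture
    log_dead = _NEG_INF  # log P(dead-unrecovered at j, obs so far)

    if has_repro and not repro_conditional_on_detection:
        # entry occasion: alive with certainty, but the repro record is an
        # observation like any other year's
        log_alive += repro_detection_loglik(
            int(history.repro[0]), float(rho_vec[0]), p_r, 1.0
        )

    for j in range(1, T):
        yj = int(history.y[j])
        rj = int(history.r[j])
        ph = float(phi[j - 1])
        if rj == 1:
            # terminal: died in the interval and was recovered
            term = log_alive + _log(1.0 - ph) + _log(p_prime)
            return term
        # alive branch
        la = log_alive + _log(ph) + (_log(p) if yj == 1 else _log(1.0 - p))
        if has_repro:
            observe = (yj == 1) or not repro_conditional_on_detection
            if observe:
                la += repro_detection_loglik(
                    int(history.repro[j]), float(rho_vec[j]), p_r, 1.0
                )
        # dead branches emit y = 0 (and no reproduction record can be 1)
        if yj == 1:
            ld = _NEG_INF
        else:
            newly = log_alive + _log(1.0 - ph) + _log(1.0 - p_prime)
            ld = np.logaddexp(newly, log_dead)
            if has_repro and int(history.repro[j]) == 1:
                ld = _NEG_INF
        log_alive, log_dead = la, ld
    return float(np.logaddexp(log_alive, log_dead))


def _log(x: float) -> float:
    return math.log(x) if x > 0.0 else _NEG_INF


def litter_loglik(
    record: LitterRecord,
    lambda_k: float,
    phi_young: Sequence[float] | float,
    p_w: Sequence[float] | float,
    zero_truncated: bool = True,
) -> float:
    """Log-likelihood of one litter's size trajectory.

    Terms: zero-truncated Poisson(lambda_k) for the initial size (a recorded
    litter has at least one cub; ``zero_truncated=False`` exposes the plain
    Poisson for validation), a Binomial attrition term per year with young
    survival ``phi_young`` (scalar or per-interval, indexed by the age at the
    start of the interval), and weaning terms from the piecewise age rule:
    each age 2-3 at which the litter is observed alive contributes
    log(1 - p_w) if it continued unweaned, or log(p_w) if weaning was
    recorded (weaning at age 4 is certain and contributes 0).
    """
    sizes = record.sizes
    m = record.max_age
    phi_vec = np.broadcast_to(np.asarray(phi_young, dtype=float), (max(m, 1),))
    pw_vec = np.broadcast_to(np.asarray(p_w, dtype=float), (max(m + 1, 1),))

    if zero_truncated:
        ll = zt_poisson_logpmf(int(sizes[0]), lambda_k)
    else:
        ll = poisson_logpmf(int(sizes[0]), lambda_k)

    for i in range(1, m + 1):
        ll += binom_logpmf(int(sizes[i]), int(sizes[i - 1]), float(phi_vec[i - 1]))

    for age in range(2, m + 1):
        if sizes[age] == 0:
            continue  # extinct litters are never assessed for weaning
        w = weaning_probability(age, float(pw_vec[age]))
        if record.weaned_at is not None and age == record.weaned_at:
            ll += _log(w)
        elif age < m or record.weaned_at is None:
            # observed alive and unweaned at this age
            if age < m:
                ll += _log(1.0 - w)
            else:
                # right-censored final assessment: litter seen unweaned
                ll += _log(1.0 - w)
    return ll


def process_loglik(
    prev: PopulationState,
    curr: PopulationState,
    rates: VitalRates,
    harvest: HarvestRecord | None = None,
) -> float:
    """Joint log-probability of year-t before-harvest abundances given t-1.

    Terms, per the class-transition structure: a Poisson for the global cub
    crop with a Binomial sex split; a Binomial for yearlings (surviving cubs);
    and exact convolution-of-two-Binomials terms for dependents (surviving
    unweaned dependents + surviving yearlings), subadults (surviving
    non-maturing subadults + weaned dependents) and adults (surviving adults +
    maturing subadults).  All sample sizes are the previous year's
    post-harvest abundances.  Infeasible transitions return -inf.

    When ``harvest`` is given, conservation N = N_BH - H is validated for the
    current year.
    """
    if harvest is not None:
        expected = curr.n_before_harvest - harvest.h
        if np.any(expected != curr.n):
            raise ValueError(
                f"year {curr.year}: post-harvest abundances do not equal "
                "before-harvest minus harvest"
            )

    C, Y, D, S, A = (int(a) for a in AgeClass)
    M, F = int(Sex.MALE), int(Sex.FEMALE)
    n_prev = prev.n
    nbh = curr.n_before_harvest
    phi = rates.phi
    gam = rates.gamma  # rows: D->S, S->A

    ll = 0.0
    # cubs: global Poisson, then sex split
    mu = cub_recruitment_mean(
        int(n_prev[A, F]), float(phi[A, F]), rates.p_repro, rates.litter_size
    )
    total_cubs = int(nbh[C, M] + nbh[C, F])
    ll += poisson_logpmf(total_cubs, mu)
    ll += binom_logpmf(int(nbh[C, M]), total_cubs, rates.sex_ratio)

    for s in (M, F):
        ll += binom_logpmf(int(nbh[Y, s]), int(n_prev[C, s]), float(phi[C, s]))
        ll += binomial_sum_logpmf(
            int(nbh[D, s]),
            int(n_prev[D, s]),
            float(phi[D, s]) * (1.0 - float(gam[0, s])),
            int(n_prev[Y, s]),
            float(phi[Y, s]),
        )
        ll += binomial_sum_logpmf(
            int(nbh[S, s]),
            int(n_prev[S, s]),
            float(phi[S, s]) * (1.0 - float(gam[1, s])),
            int(n_prev[D, s]),
            float(phi[D, s]) * float(gam[0, s]),
        )
        ll += binomial_sum_logpmf(
            int(nbh[A, s]),
            int(n_prev[A, s]),
            float(phi[A, s]),
            int(n_prev[S, s]),
            float(phi[S, s]) * float(gam[1, s]),
        )
    return ll
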