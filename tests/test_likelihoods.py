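"""Observation/process likelihood kernels versus enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from bearipm.core_model import HarvestRecord, PopulationState, Sex, VitalRates
from bearipm.likelihoods import (
    CMRHistory,
    LitterRecord,
    binom_logpmf,
    binomial_sum_logpmf,
    cjs_history_loglik,
    count_obs_loglik,
    litter_loglik,
    poisson_logpmf,
    process_loglik,
    repro_detection_loglik,
    zt_poisson_logpmf,
)

from oracles import all_histories as _all_histories
from oracles import enumerate_cjs_loglik
from oracles import enumerate_litter_outcomes as _enumerate_litter_outcomes


@pytest.mark.parametrize("T", [2, 3, 4])
def test_cjs_matches_enumeration_all_histories(T):
    phi = [0.8, 0.6, 0.9][: T - 1]
    p, pp = 0.7, 0.85
    for y, r in _all_histories(T):
        h = CMRHistory("x", 0, y, r, Sex.MALE, 6)
        got = cjs_history_loglik(h, phi[: len(y) - 1], p, pp)
        want = enumerate_cjs_loglik(y, r, phi, p, pp)
        assert got == pytest.approx(want, abs=1e-10)


@pytest.mark.parametrize("T", [2, 3, 4])
def test_cjs_outcome_probabilities_sum_to_one(T):
    phi = [0.75, 0.55, 0.95][: T - 1]
    p, pp = 0.65, 0.8
    total = 0.0
    for y, r in _all_histories(T):
        h = CMRHistory("x", 0, y, r, Sex.MALE, 6)
        total += math.exp(cjs_history_loglik(h, phi[: len(y) - 1], p, pp))
    assert total == pytest.approx(1.0, abs=1e-10)


def test_cjs_with_reproduction_matches_enumeration():
    phi, p, pp, rho, p_r = [0.8, 0.7], 0.7, 0.9, 0.4, 0.8
    for y, r in _all_histories(3):
        T = len(y)
        for rep in itertools.product([0, 1], repeat=T):
            h_args = dict(
                individual_id="f", entry_year=0, y=y, r=r, sex=Sex.FEMALE,
                age_at_entry=7,
            )
            want = enumerate_cjs_loglik(
                y, r, phi, p, pp, repro=rep, rho=rho, p_r=p_r
            )
            try:
                h = CMRHistory(repro=np.array(rep), **h_args)
            except ValueError:
                assert want == -math.inf
                continue
            got = cjs_history_loglik(h, phi[: T - 1], p, pp, rho=rho, p_r=p_r)
            if want == -math.inf:
                assert got == -math.inf
            else:
                assert got == pytest.approx(want, abs=1e-10)


@pytest.mark.parametrize(
    "outcome, expected",
    [("seen", 0.8 * 0.7), ("recovered", 0.2 * 0.9), ("unseen", 0.8 * 0.3 + 0.2 * 0.1)],
)
def test_cjs_one_interval_outcomes(outcome, expected):
    y, r = {
        "seen": ([1, 1], [0, 0]),
        "recovered": ([1, 1], [0, 1]),
        "unseen": ([1, 0], [0, 0]),
    }[outcome]
    h = CMRHistory("x", 0, y, r, Sex.MALE, 6)
    assert math.exp(cjs_history_loglik(h, [0.8], 0.7, 0.9)) == pytest.approx(
        expected, abs=1e-12
    )


def test_cmr_history_validation():
    with pytest.raises(ValueError, match="after dead recovery"):
        CMRHistory("x", 0, [1, 1, 0], [0, 1, 0], Sex.MALE, 6)
    with pytest.raises(ValueError, match="multiple"):
        CMRHistory("x", 0, [1, 1, 1], [0, 1, 1], Sex.MALE, 6)
    with pytest.raises(ValueError, match="females"):
        CMRHistory("x", 0, [1, 1], [0, 0], Sex.MALE, 6, repro=[1, 0])


# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "count, n, p, expected",
    [
        (3, 5, 0.7, math.log(10 * 0.7**3 * 0.3**2)),
        (0, 0, 0.5, 0.0),
        (6, 5, 0.7, -math.inf),
    ],
)
def test_count_obs_loglik(count, n, p, expected):
    assert count_obs_loglik(count, n, p) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "R, rho, p_r, alive, expected",
    [
        (1, 1.0, 1.0, 1.0, 0.0),
        (1, 0.5, 0.8, 0.0, -math.inf),
        (0, 0.5, 0.8, 1.0, math.log(0.6)),
    ],
)
def test_repro_detection_loglik(R, rho, p_r, alive, expected):
    assert repro_detection_loglik(R, rho, p_r, alive) == pytest.approx(
        expected, abs=1e-12
    )


# ---------------------------------------------------------------------------
# litter likelihood


def test_litter_attrition_term():
    rec = LitterRecord("L1", "m1", 0, [2, 1])
    ll = litter_loglik(rec, 2.0, 0.5, 0.5)
    assert ll - zt_poisson_logpmf(2, 2.0) == pytest.approx(math.log(0.5), abs=1e-12)


def test_litter_initial_size_untruncated():
    rec = LitterRecord("L1", "m1", 0, [2])
    ll = litter_loglik(rec, 2.0, 0.5, 0.5, zero_truncated=False)
    assert ll == pytest.approx(math.log(math.exp(-2) * 4 / 2), abs=1e-10)


def test_litter_weaning_term_decomposition():
    rec = LitterRecord("L1", "m1", 0, [1, 1, 1], weaned_at=2)
    ll = litter_loglik(rec, 1.5, 1.0, 0.7)
    assert ll - zt_poisson_logpmf(1, 1.5) == pytest.approx(math.log(0.7), abs=1e-12)


@pytest.mark.parametrize("l0", [1, 2, 3])
def test_litter_outcomes_sum_to_one(l0):
    """Conditional on the initial size, the litter model's probabilities over
    every possible trajectory (attrition, weaning, censoring at a 3-year
    horizon) total one."""
    lam, phi, pw = 1.7, 0.8, 0.35
    base = zt_poisson_logpmf(l0, lam)
    total = 0.0
    for sizes, weaned_at in _enumerate_litter_outcomes(l0, horizon=3):
        rec = LitterRecord("L", "m", 0, list(sizes), weaned_at=weaned_at)
        ll = litter_loglik(rec, lam, phi, pw)
        prob = math.exp(ll - base)
        if weaned_at is not None:
            total += prob
        else:
            total += prob
    assert total == pytest.approx(1.0, abs=1e-10)


def test_litter_rejects_increasing_sizes():
    with pytest.raises(ValueError, match="increase"):
        LitterRecord("L1", "m1", 0, [2, 3])


# ---------------------------------------------------------------------------
# process likelihood


def test_binomial_sum_matches_bruteforce():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n1, n2 = rng.integers(0, 21, 2)
        p1, p2 = rng.uniform(0.05, 0.95, 2)
        for n in range(0, int(n1 + n2) + 2):
            direct = sum(
                math.exp(binom_logpmf(j, int(n1), p1))
                * math.exp(binom_logpmf(n - j, int(n2), p2))
                for j in range(0, n + 1)
            )
            got = binomial_sum_logpmf(n, int(n1), p1, int(n2), p2)
            if direct == 0:
                assert got == -math.inf
            else:
                assert got == pytest.approx(math.log(direct), abs=1e-10)


def _state(nbh, harvest=None):
    nbh = np.asarray(nbh, dtype=np.int64)
    h = np.zeros((5, 2), dtype=np.int64) if harvest is None else np.asarray(harvest)
    return PopulationState(0, nbh, nbh - h)


def test_process_degenerate_transitions_zero_loglik():
    # survival one, no transitions, no births: matching constant abundances
    # are certain apart from the (certain) cub terms
    nbh = np.array([[0, 0], [3, 4], [5, 6], [7, 8], [9, 10]])
    rates = VitalRates(
        phi=np.ones((5, 2)), gamma=np.zeros((2, 2)), p_repro=0.0,
        litter_size=0.0, sex_ratio=0.5,
    )
    prev = _state(nbh)
    nbh2 = nbh.copy()
    nbh2[1] = nbh[0]  # yearlings are last year's cubs under certain survival
    nbh2[2] = nbh[2] + nbh[1]
    curr = PopulationState(1, nbh2, nbh2)
    assert process_loglik(prev, curr, rates) == pytest.approx(0.0, abs=1e-12)


def test_process_dependent_convolution_value():
    # previous D=1, Y=1 with survival 0.5 each and no weaning:
    # P(D_t^BH = 1) = 0.5*0.5 + 0.5*0.5
    prev_nbh = np.zeros((5, 2), dtype=np.int64)
    prev_nbh[1, 1] = 1  # one female yearling
    prev_nbh[2, 1] = 1  # one female dependent
    prev = _state(prev_nbh)
    curr_nbh = np.zeros((5, 2), dtype=np.int64)
    curr_nbh[2, 1] = 1
    curr = PopulationState(1, curr_nbh, curr_nbh)
    phi = np.zeros((5, 2))
    phi[1, 1] = 0.5
    phi[2, 1] = 0.5
    rates = VitalRates(
        phi=phi, gamma=np.zeros((2, 2)), p_repro=0.0, litter_size=0.0,
        sex_ratio=0.5,
    )
    assert process_loglik(prev, curr, rates) == pytest.approx(
        math.log(0.5), abs=1e-12
    )


def test_process_infeasible_transition_is_impossible():
    prev = _state(np.zeros((5, 2), dtype=np.int64))
    curr_nbh = np.zeros((5, 2), dtype=np.int64)
    curr_nbh[1, 0] = 3  # yearlings cannot outnumber last year's (zero) cubs
    curr = PopulationState(1, curr_nbh, curr_nbh)
    rates = VitalRates(
        phi=np.full((5, 2), 0.5), gamma=np.full((2, 2), 0.5), p_repro=0.5,
        litter_size=2.0, sex_ratio=0.5,
    )
    assert process_loglik(prev, curr, rates) == -math.inf
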