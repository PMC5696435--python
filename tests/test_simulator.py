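"""Generative simulator: determinism, conservation, and analytic moments."""

import numpy as np
import pytest

from bearipm.core_model import AgeClass, Sex, VitalRates
from bearipm.simulator import (
    SimulationScenario,
    desk_scenario,
    deterministic_growth_rate,
    draw_vital_rates,
    simulate_cmr,
    simulate_counts,
    simulate_dataset,
    simulate_litters,
    simulate_trajectory,
    solve_zt_lambda,
    zt_mean,
)


def _fixed_rates(phi=0.8, gamma=0.5, p_repro=0.3, litter=2.2, sr=0.52):
    return VitalRates(
        phi=np.full((5, 2), phi), gamma=np.full((2, 2), gamma),
        p_repro=p_repro, litter_size=litter, sex_ratio=sr,
    )


def test_same_seed_gives_identical_datasets():
    sc = desk_scenario(n_years=6, n_cmr_individuals=40, n_litters=15, seed=9)
    a = simulate_dataset(sc)
    b = simulate_dataset(sc)
    assert np.array_equal(a.true_n(), b.true_n())
    assert np.array_equal(a.counts_array(), b.counts_array())
    assert all(
        np.array_equal(x.y, y.y) and np.array_equal(x.r, y.r)
        for x, y in zip(a.cmr, b.cmr)
    )
    assert all(
        np.array_equal(x.sizes, y.sizes) for x, y in zip(a.litters, b.litters)
    )


def test_frozen_dynamics_keep_classes_constant():
    # no births, certain survival, no transitions, no harvest, and empty cub
    # and yearling pools: the pipeline carries nothing, so D, S, A freeze
    init = np.array([[0, 0], [0, 0], [12, 14], [8, 9], [20, 25]])
    sc = SimulationScenario(
        n_years=6, initial_abundance=init,
        harvest_rates=np.zeros((5, 2)), seed=5,
    )
    rates = _fixed_rates(phi=1.0, gamma=0.0, p_repro=0.0)
    states, _, _ = simulate_trajectory(sc, rates=rates)
    for st in states:
        assert np.array_equal(st.n, init)


def test_trajectory_invariants_hold_on_random_scenario():
    sc = desk_scenario(n_years=10, seed=21)
    states, rates, harvests = simulate_trajectory(sc)
    for t in range(1, len(states)):
        prev, curr = states[t - 1], states[t]
        assert np.all(curr.n >= 0) and np.all(curr.n_before_harvest >= 0)
        # conservation: N_BH = N + H exactly
        assert np.array_equal(
            curr.n_before_harvest, curr.n + harvests[t].h
        )
        # cohort feasibility: yearlings cannot outnumber last year's cubs
        y = curr.n_before_harvest[AgeClass.YEARLING]
        assert np.all(y <= prev.n[AgeClass.CUB])


def test_immortal_population_never_shrinks():
    sc = SimulationScenario(
        n_years=8, harvest_rates=np.zeros((5, 2)), seed=4,
    )
    rates = _fixed_rates(phi=1.0, gamma=1.0, p_repro=0.3)
    states, _, _ = simulate_trajectory(sc, rates=rates)
    totals = [
        st.n[AgeClass.SUBADULT].sum() + st.n[AgeClass.ADULT].sum()
        for st in states
    ]
    assert all(b >= a for a, b in zip(totals, totals[1:]))


def test_yearling_mean_matches_binomial_expectation():
    # cohort mean over replicate trajectories vs the analytic binomial mean
    init = np.array([[40, 40], [0, 0], [10, 10], [10, 10], [30, 60]])
    sc = SimulationScenario(
        n_years=2, initial_abundance=init, harvest_rates=np.zeros((5, 2)),
    )
    rates = _fixed_rates(phi=0.7)
    rng = np.random.default_rng(17)
    n_rep = 400
    vals = np.empty(n_rep)
    for i in range(n_rep):
        states, _, _ = simulate_trajectory(sc, rates=rates, rng=rng)
        vals[i] = states[1].n[AgeClass.YEARLING].sum()
    mean_expected = 80 * 0.7
    se = np.sqrt(80 * 0.7 * 0.3 / n_rep)
    assert abs(vals.mean() - mean_expected) < 3 * se


@pytest.mark.parametrize("p, expect_equal", [(1.0, True), (0.0, False)])
def test_counts_at_detection_extremes(p, expect_equal, rng):
    sc = desk_scenario(n_years=4, seed=2)
    states, _, _ = simulate_trajectory(sc)
    counts = simulate_counts(states, p, 2, rng)
    if expect_equal:
        assert all(
            c.count == states[c.year].n[c.age_class, c.sex] for c in counts
        )
    else:
        assert all(c.count == 0 for c in counts)


def test_counts_binomial_mean(rng):
    from bearipm.core_model import HarvestRecord, PopulationState

    nbh = np.full((5, 2), 100, dtype=np.int64)
    state = PopulationState(0, nbh, nbh)
    counts = simulate_counts([state] * 1000, 0.7, 1, rng)
    vals = np.array([c.count for c in counts])
    se = np.sqrt(100 * 0.7 * 0.3 / vals.size)
    assert abs(vals.mean() - 70.0) < 3 * se


def test_cmr_one_interval_outcome_frequencies(rng):
    # survival .8, detection .7, recovery .9 -> (seen, recovered, unseen)
    # occur with probabilities (.56, .18, .26)
    sc = SimulationScenario(
        n_years=2, n_cmr_individuals=20000, detection_p=0.7,
        recovery_pprime=0.9, cmr_female_fraction=0.0,
    )
    rates = _fixed_rates(phi=0.8)
    hist = simulate_cmr(sc, rates, rng)
    seen = recovered = unseen = 0
    for h in hist:
        if h.recovered_dead:
            recovered += 1
        elif h.y[1] == 1:
            seen += 1
        else:
            unseen += 1
    n = len(hist)
    for frac, p_true in ((seen / n, 0.56), (recovered / n, 0.18), (unseen / n, 0.26)):
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(frac - p_true) < 4 * se


def test_litter_mean_sizes_in_literature_range(rng):
    sc = desk_scenario(n_litters=400, seed=6)
    rates = draw_vital_rates(sc, rng)
    litters = simulate_litters(sc, rates, rng)
    mean0 = np.mean([rec.sizes[0] for rec in litters])
    assert 1.0 <= mean0 <= 4.0


def test_litter_frozen_until_forced_weaning(rng):
    sc = SimulationScenario(n_years=12, n_litters=60)
    rates = _fixed_rates(phi=1.0, gamma=0.0)  # certain survival, p_w = 0
    litters = simulate_litters(sc, rates, rng)
    for rec in litters:
        assert np.all(rec.sizes == rec.sizes[0])
        if rec.weaned_at is not None:
            assert rec.weaned_at == 4


def test_untruncated_litter_initial_mean(rng):
    sc = SimulationScenario(n_years=3, n_litters=20000)
    rates = _fixed_rates(litter=zt_mean(2.0))
    litters = simulate_litters(sc, rates, rng, zero_truncated=False)
    sizes = np.array([rec.sizes[0] for rec in litters])
    se = np.sqrt(2.0 / sizes.size)
    assert abs(sizes.mean() - 2.0) < 3 * se


def test_zero_truncated_lambda_solver_roundtrip():
    for target in (1.3, 2.0, 3.5):
        lam = solve_zt_lambda(target)
        assert zt_mean(lam) == pytest.approx(target, abs=1e-9)


@pytest.mark.parametrize("trend, lo, hi", [
    ("stable", 0.999, 1.001), ("increasing", 1.01, 1.025),
    ("decreasing", 0.975, 0.99),
])
def test_trend_calibration(trend, lo, hi, rng):
    sc = desk_scenario(trend=trend)
    rates = draw_vital_rates(sc, rng)
    growth = deterministic_growth_rate(rates, sc.harvest_rates)
    assert lo <= growth <= hi
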