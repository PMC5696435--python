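"""Aggregation of individual-level rates into population-level rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bearipm.linking import (
    LinkedRates,
    aggregate_reproduction_and_litter,
    aggregate_survival,
)


def test_alive_weighted_class_mean():
    out = aggregate_survival([0.9, 0.7], [1, 1], ["A", "A"])
    assert out["A"] == pytest.approx(0.8)


def test_dead_individuals_do_not_enter_the_average():
    out = aggregate_survival([0.9, 0.7], [1, 0], ["A", "A"])
    assert out["A"] == pytest.approx(0.9)


def test_empty_class_uses_fallback_prior_value():
    out = aggregate_survival(
        [0.9, 0.7], [0, 0], ["A", "A"], fallback={"A": 0.42}
    )
    assert out["A"] == 0.42
    with pytest.raises(ValueError, match="no alive members"):
        aggregate_survival([0.9], [0], ["A"])


def test_reproduction_and_litter_aggregates():
    p_t, l_t = aggregate_reproduction_and_litter([0.4, 0.6], [1, 1], [2, 3, 1])
    assert p_t == pytest.approx(0.5)
    assert l_t == pytest.approx(2.0)


def test_no_litters_falls_back_to_prior_draw():
    _, l_t = aggregate_reproduction_and_litter([0.4], [1], [], litter_fallback=1.7)
    assert l_t == 1.7
    with pytest.raises(ValueError, match="no litters"):
        aggregate_reproduction_and_litter([0.4], [1], [])


@given(
    phi=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=20),
    seed=st.integers(0, 1000),
)
@settings(derandomize=True, max_examples=100)
def test_aggregates_bounded_by_inputs(phi, seed):
    rng = np.random.default_rng(seed)
    alive = rng.integers(0, 2, len(phi))
    if alive.sum() == 0:
        alive[0] = 1
    out = aggregate_survival(phi, alive, ["c"] * len(phi))
    assert min(phi) - 1e-12 <= out["c"] <= max(phi) + 1e-12


@given(c=st.floats(0.01, 0.99), n=st.integers(1, 30))
@settings(derandomize=True, max_examples=50)
def test_shared_rate_aggregates_exactly(c, n):
    out = aggregate_survival([c] * n, [1] * n, ["x"] * n)
    assert out["x"] == pytest.approx(c, abs=1e-12)


def test_linked_rates_validation():
    with pytest.raises(ValueError):
        LinkedRates(survival={"A": 1.2}, p_repro=0.3, litter_size=2.0)
    with pytest.raises(ValueError):
        LinkedRates(survival={"A": 0.9}, p_repro=0.3, litter_size=-1.0)
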