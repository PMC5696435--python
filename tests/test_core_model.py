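"""Kernels of the demographic algebra: linear predictors, harvest
accounting, the weaning rule and moment-matched Beta priors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bearipm.core_model import (
    ALL_CLASSES,
    DataInconsistencyError,
    InfeasibleMomentsError,
    LinearPredictorSpec,
    apply_harvest,
    beta_from_moments,
    cub_recruitment_mean,
    linear_predictor_prob,
    log_linear_mean,
    weaning_probability,
)


def test_class_structure_has_ten_combinations():
    assert len(ALL_CLASSES) == 10
    assert len({c.label for c in ALL_CLASSES}) == 10


@pytest.mark.parametrize(
    "spec, x, eps, expected",
    [
        (LinearPredictorSpec(0.0), (), 0.0, 0.5),
        (LinearPredictorSpec(0.0, (1.0,), ("x",)), (2.0,), 0.0, 0.8807970779778823),
        (LinearPredictorSpec(2.0, (-1.0, 3.0), ("a", "b")), (1.0, 0.0), -1.0, 0.5),
    ],
)
def test_linear_predictor_prob(spec, x, eps, expected):
    assert linear_predictor_prob(spec, x, eps) == pytest.approx(expected, abs=1e-12)


@given(
    beta=st.floats(-5, 5), slope=st.floats(0.01, 3),
    x1=st.floats(-3, 3), dx=st.floats(0.01, 3),
)
@settings(derandomize=True, max_examples=100)
def test_linear_predictor_in_unit_interval_and_monotone(beta, slope, x1, dx):
    # predictor kept within float-representable logit range
    spec = LinearPredictorSpec(beta, (slope,), ("x",))
    lo = linear_predictor_prob(spec, (x1,))
    hi = linear_predictor_prob(spec, (x1 + dx,))
    assert 0.0 < lo < 1.0 and 0.0 < hi < 1.0
    assert hi > lo  # positive slope: strictly increasing in the covariate


def test_linear_predictor_length_mismatch():
    spec = LinearPredictorSpec(0.0, (1.0,), ("x",))
    with pytest.raises(ValueError):
        linear_predictor_prob(spec, (1.0, 2.0))
    with pytest.raises(ValueError):
        LinearPredictorSpec(0.0, (1.0, 2.0), ("x",))


@pytest.mark.parametrize(
    "spec, x, expected",
    [
        (LinearPredictorSpec(0.0), (), 1.0),
        (LinearPredictorSpec(math.log(2.0), (1.0,), ("x",)), (math.log(1.5),), 3.0),
    ],
)
def test_log_linear_mean(spec, x, expected):
    assert log_linear_mean(spec, x) == pytest.approx(expected, rel=1e-12)


def test_log_linear_mean_positive_at_extreme_intercept():
    assert log_linear_mean(LinearPredictorSpec(-50.0)) > 0.0


@pytest.mark.parametrize(
    "args, expected",
    [((100, 0.9, 0.5, 2.0), 90.0), ((0, 0.9, 0.5, 2.0), 0.0),
     ((100, 1.0, 1.0, 1.0), 100.0)],
)
def test_cub_recruitment_mean(args, expected):
    assert cub_recruitment_mean(*args) == pytest.approx(expected)


def test_cub_recruitment_rejects_negative_input():
    with pytest.raises(ValueError):
        cub_recruitment_mean(-1, 0.9, 0.5, 2.0)


@pytest.mark.parametrize("nbh, h, expected", [(50, 5, 45), (7, 0, 7)])
def test_apply_harvest(nbh, h, expected):
    assert apply_harvest(nbh, h) == expected


def test_apply_harvest_infeasible_names_class_and_year():
    with pytest.raises(DataInconsistencyError, match=r"Cf.*1998"):
        apply_harvest(3, 4, class_label="Cf", year=1998)


@given(nbh=st.integers(0, 10_000), h=st.integers(0, 10_000))
@settings(derandomize=True, max_examples=100)
def test_apply_harvest_conserves_individuals(nbh, h):
    if h > nbh:
        with pytest.raises(DataInconsistencyError):
            apply_harvest(nbh, h)
    else:
        assert apply_harvest(nbh, h) + h == nbh


@pytest.mark.parametrize(
    "age, pw, expected", [(1, 0.7, 0.0), (4, 0.1, 1.0), (2, 0.7, 0.7), (3, 0.2, 0.2)]
)
def test_weaning_probability(age, pw, expected):
    assert weaning_probability(age, pw) == expected


@given(pw=st.floats(0.0, 1.0), ages=st.lists(st.integers(0, 8), min_size=2))
@settings(derandomize=True, max_examples=100)
def test_weaning_probability_monotone_in_age(pw, ages):
    vals = [weaning_probability(a, pw) for a in sorted(ages)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_weaning_probability_rejects_negative_age():
    with pytest.raises(ValueError):
        weaning_probability(-1, 0.5)


@pytest.mark.parametrize(
    "mean, var, expected",
    [(0.5, 1.0 / 12.0, (1.0, 1.0)), (0.5, 0.05, (2.0, 2.0))],
)
def test_beta_from_moments_closed_forms(mean, var, expected):
    a, b = beta_from_moments(mean, var)
    assert (a, b) == pytest.approx(expected, rel=1e-10)


def test_beta_from_moments_sex_ratio_roundtrip():
    # value pair used for the litter sex-ratio prior
    a, b = beta_from_moments(0.5238, 0.0771)
    assert a / (a + b) == pytest.approx(0.5238, abs=1e-10)
    assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(0.0771, abs=1e-10)


@given(
    mean=st.floats(0.01, 0.99),
    frac=st.floats(0.01, 0.99),
)
@settings(derandomize=True, max_examples=200)
def test_beta_from_moments_roundtrip_property(mean, frac):
    var = frac * mean * (1.0 - mean)
    a, b = beta_from_moments(mean, var)
    assert a > 0 and b > 0
    assert a / (a + b) == pytest.approx(mean, abs=1e-10)
    assert a * b / ((a + b) ** 2 * (a + b + 1)) == pytest.approx(var, abs=1e-10)


def test_beta_from_moments_infeasible_raises():
    with pytest.raises(InfeasibleMomentsError):
        beta_from_moments(0.5, 0.25)
    with pytest.raises(InfeasibleMomentsError):
        beta_from_moments(0.5, 0.4)
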