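"""Coverage scoring and the simulate-fit-score comparison harness."""

import numpy as np
import pytest

from bearipm.evaluation import (
    error_metrics,
    interval_coverage,
    run_comparison_study,
)
from bearipm.inference import McmcSettings, ModelConfig
from bearipm.simulator import desk_scenario


def test_interval_coverage_examples():
    assert interval_coverage([5], [(0, 10)]) == 1.0
    assert interval_coverage([5, 20], [(0, 10), (0, 10)]) == 0.5


def test_interval_coverage_input_errors():
    with pytest.raises(ValueError):
        interval_coverage([], [])
    with pytest.raises(ValueError, match="lower"):
        interval_coverage([5], [(10, 0)])


@pytest.mark.parametrize(
    "truths, ests, expected",
    [
        ([1, 2, 3], [1, 2, 3], (0.0, 0.0)),
        ([0, 0], [1, -1], (0.0, 1.0)),
        ([10], [13], (3.0, 3.0)),
    ],
)
def test_error_metrics(truths, ests, expected):
    bias, rmse = error_metrics(truths, ests)
    assert (bias, rmse) == pytest.approx(expected)


@pytest.fixture(scope="module")
def micro_report():
    scenario = desk_scenario(
        n_years=5, n_cmr_individuals=60, n_litters=20,
        n_reproducing_females=8, seed=31,
    )
    cfg = ModelConfig(
        mcmc=McmcSettings(n_chains=2, n_burnin=200, n_iter=200, seed=5)
    )
    return run_comparison_study([scenario], cfg), scenario


def test_comparison_report_bookkeeping(micro_report):
    report, scenario = micro_report
    # one row per scenario x variant x year x age class x sex
    assert len(report.rows) == 2 * scenario.n_years * 10
    assert set(report.rows.variant) == {"full_ipm", "counts_only"}
    for v in ("full_ipm", "counts_only"):
        assert 0.0 <= report.coverage(v) <= 1.0


def test_covered_flags_recomputable_from_bounds(micro_report):
    report, _ = micro_report
    rows = report.rows
    recomputed = (rows.true_n >= rows.lower) & (rows.true_n <= rows.upper)
    assert (recomputed == rows.covered).all()


def test_aggregates_include_pooled_and_convergence_flags(micro_report):
    report, _ = micro_report
    assert "pooled" in set(report.aggregates.scenario)
    assert set(report.convergence.columns) >= {"scenario", "variant", "max_rhat",
                                               "converged"}
    js = report.summary_json()
    assert "coverage" in js
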