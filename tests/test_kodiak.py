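"""Case-study pipeline: readers, model assembly, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from bearipm.fixtures import fixture_dir, load_fixture, regenerate
from bearipm.inference import McmcSettings, ModelConfig, run_mcmc, summarize
from bearipm.kodiak import (
    assemble_kodiak_model,
    generate_synthetic_kodiak,
    read_cmr_table,
    read_litter_table,
)
from bearipm.likelihoods import cjs_history_loglik


def test_fixture_roundtrip_matches_manifest():
    histories, litters, cov, manifest = load_fixture()
    assert manifest["synthetic"] is True
    assert len(histories) == manifest["n_individuals"]
    assert sum(h.n_occasions for h in histories) == manifest["n_cmr_rows"]
    assert len(litters) == manifest["n_litters"]
    assert sum(r.sizes.size for r in litters) == manifest["n_litter_years"]


def test_fixture_regeneration_is_deterministic(tmp_path):
    regenerate(tmp_path)
    for name in ("cmr.csv", "litters.csv", "salmon.csv", "manifest.json"):
        assert (tmp_path / name).read_bytes() == (
            fixture_dir() / name
        ).read_bytes()


def test_cmr_reader_rejects_rows_after_recovery(tmp_path):
    df = pd.DataFrame(
        dict(
            id=["b1"] * 3, year=[0, 1, 2], sex=["f"] * 3, age=[6, 7, 8],
            detected=[1, 1, 0], recovered_dead=[0, 1, 0],
            repro_status=[0, 0, 0], dependent_young_age=["", "", ""],
        )
    )
    path = tmp_path / "cmr.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="b1.*after dead recovery"):
        read_cmr_table(path)


def test_cmr_reader_rejects_unknown_sex_and_year_gaps(tmp_path):
    base = dict(
        detected=[1, 1], recovered_dead=[0, 0], repro_status=["", ""],
        dependent_young_age=["", ""],
    )
    bad_sex = pd.DataFrame(
        dict(id=["b"] * 2, year=[0, 1], sex=["x", "x"], age=[5, 6], **base)
    )
    bad_sex.to_csv(tmp_path / "s.csv", index=False)
    with pytest.raises(ValueError, match="sex"):
        read_cmr_table(tmp_path / "s.csv")
    gap = pd.DataFrame(
        dict(id=["b"] * 2, year=[0, 2], sex=["m", "m"], age=[5, 7], **base)
    )
    gap.to_csv(tmp_path / "g.csv", index=False)
    with pytest.raises(ValueError, match="line 3.*non-consecutive"):
        read_cmr_table(tmp_path / "g.csv")


def test_litter_reader_rejects_growing_litters(tmp_path):
    df = pd.DataFrame(
        dict(
            litter_id=["L1", "L1"], mother_id=["m", "m"], year=[0, 1],
            litter_age=[0, 1], size=[2, 3], weaned=[0, 0],
        )
    )
    df.to_csv(tmp_path / "l.csv", index=False)
    with pytest.raises(ValueError, match="L1.*increases"):
        read_litter_table(tmp_path / "l.csv")


def test_assemble_requires_salmon_covariate():
    histories, litters, cov, _ = load_fixture()
    with pytest.raises(ValueError, match="salmon"):
        assemble_kodiak_model(histories, litters, {"year0": 0})


def test_interceptonly_configuration_matches_reference_cjs():
    """With every slope and random effect zeroed the model's compiled CMR
    likelihood must equal the plain per-history CJS reference at the
    intercept probabilities -- the nested-model sanity check."""
    histories, litters, cov, _ = load_fixture()
    model = assemble_kodiak_model(histories, litters, cov)
    state = model.initial_state(np.random.default_rng(0))
    for key in ("beta_z", "beta_r", "beta_L", "beta_y", "beta_w"):
        state[key][1:] = 0.0
    phi0 = float(expit(state["beta_z"][0]))
    rho0 = float(expit(state["beta_r"][0]))
    fast = model._cmr_ll(state)
    slow = 0.0
    for h in histories:
        T = h.n_occasions
        slow += cjs_history_loglik(
            h, np.full(T - 1, phi0), state["p"], state["p_prime"],
            rho=rho0 if h.repro is not None else None,
            p_r=state["p_r"] if h.repro is not None else None,
        )
    assert fast == pytest.approx(slow, abs=1e-8)


def test_recovers_positive_sex_effect_on_survival(kodiak_recovery_fit):
    _, samples = kodiak_recovery_fit
    mean, lo, hi = summarize(samples, "surv:female")
    assert lo > 0.0  # credible interval excludes zero, correct sign


def test_dependent_young_suppress_reproduction(kodiak_recovery_fit):
    model, samples = kodiak_recovery_fit
    mean, lo, hi = summarize(samples, "repro:dep_young")
    assert hi < 0.0
    # effective reproduction probability with dependent young present ~ 0
    idx = {n: i for i, n in enumerate(samples.names)}
    b = samples.draws[:, :, [idx[f"repro:{t}"] for t in model.REPRO_TERMS]]
    eta = b[..., 0] + b[..., 4]  # intercept + dep-young effect
    assert float(expit(eta).mean()) < 0.01


def test_young_survival_increases_with_age(kodiak_recovery_fit):
    model, samples = kodiak_recovery_fit
    young = model.derived_young_survival(samples)
    assert young["cub"][0] < young["yearling"][0] < young["dependent"][0]


def test_annual_litter_size_within_observed_range(kodiak_recovery_fit):
    model, samples = kodiak_recovery_fit
    df = model.derived_annual_litter_size(samples)
    max_observed = float(model.lit_l0.max())
    assert (df.litter_size >= 0).all()
    assert (df.litter_size <= max_observed).all()
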