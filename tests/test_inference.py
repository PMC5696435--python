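"""Sampler machinery: diagnostics, conjugate checks, joint-density routes."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy.special import logsumexp

from bearipm import _kernels as K
from bearipm.inference import (
    McmcSettings,
    ModelConfig,
    ModelData,
    PosteriorSamples,
    SimpleBinomialModel,
    build_model,
    gelman_rubin,
    run_mcmc,
    summarize,
)
from bearipm.likelihoods import litter_loglik


# ---------------------------------------------------------------------------
# diagnostics


def test_gelman_rubin_identical_chains_hand_value():
    x = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    # B = 0, W = 1, n = 3 -> R-hat = sqrt((n-1)/n)
    assert gelman_rubin(x) == pytest.approx(math.sqrt(2.0 / 3.0), abs=1e-12)


def test_gelman_rubin_near_one_for_stationary_chains():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 20000))
    assert gelman_rubin(x) == pytest.approx(1.0, abs=0.01)


def test_gelman_rubin_zero_variance_sentinel():
    x = np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]])
    with pytest.warns(RuntimeWarning, match="undefined"):
        assert np.isnan(gelman_rubin(x))


def test_summarize_constant_and_quantiles():
    const = np.full((2, 50), 3.25)
    assert summarize(const) == (3.25, 3.25, 3.25)
    draws = np.arange(1.0, 101.0).reshape(1, 100)
    mean, lo, hi = summarize(draws)
    assert mean == pytest.approx(50.5)
    assert lo == pytest.approx(np.quantile(draws, 0.025))
    assert hi == pytest.approx(np.quantile(draws, 0.975))


def test_summarize_standard_normal_draws():
    rng = np.random.default_rng(1)
    mean, lo, hi = summarize(rng.normal(size=(2, 100000)))
    assert mean == pytest.approx(0.0, abs=0.02)
    assert lo == pytest.approx(-1.96, abs=0.03)
    assert hi == pytest.approx(1.96, abs=0.03)


# ---------------------------------------------------------------------------
# sampling machinery on closed-form posteriors


def _fit_simple(n, k, seed=0, iters=4000):
    model = SimpleBinomialModel(n, k)
    cfg = ModelConfig(
        variant="full_ipm",
        mcmc=McmcSettings(n_chains=2, n_burnin=500, n_iter=iters, seed=seed),
    )
    return run_mcmc(model, cfg)


def test_prior_only_detection_recovers_uniform_mean():
    s = _fit_simple(0, 0)
    mean, lo, hi = summarize(s, "p")
    assert mean == pytest.approx(0.5, abs=0.02)
    assert lo < 0.1 and hi > 0.9


def test_conjugate_binomial_posterior_mean():
    # Binomial(N=100, count=70), p ~ Uniform(0,1) -> Beta(71, 31)
    s = _fit_simple(100, 70)
    mean, _, _ = summarize(s, "p")
    beta_mean = 71.0 / 102.0
    mc_se = math.sqrt(beta_mean * (1 - beta_mean) / (2 * 4000)) * 5
    assert abs(mean - beta_mean) < max(mc_se, 0.01)
    assert gelman_rubin(s, "p") < 1.05


def test_same_seed_identical_draw_sequences(tiny_dataset):
    data = ModelData.from_dataset(tiny_dataset)
    cfg = ModelConfig(
        variant="full_ipm",
        mcmc=McmcSettings(n_chains=2, n_burnin=50, n_iter=50, seed=11),
    )
    a = run_mcmc(build_model(data, cfg), cfg)
    b = run_mcmc(build_model(data, cfg), cfg)
    assert np.array_equal(a.draws, b.draws)
    assert np.array_equal(a.latent_n, b.latent_n)


# ---------------------------------------------------------------------------
# model assembly


def test_separate_count_and_cmr_detection_when_not_shared(tiny_dataset):
    data = ModelData.from_dataset(tiny_dataset)
    cfg = ModelConfig(
        variant="full_ipm", share_detection=False,
        mcmc=McmcSettings(n_chains=2, n_burnin=60, n_iter=60, seed=4),
    )
    samples = run_mcmc(build_model(data, cfg), cfg)
    assert "p_cmr" in samples.names
    assert not np.allclose(samples.get("p"), samples.get("p_cmr"))


def test_build_model_reports_missing_tables(tiny_dataset):
    data = ModelData.from_dataset(tiny_dataset)
    with pytest.raises(ValueError, match="counts"):
        build_model(
            ModelData(cmr=data.cmr), ModelConfig(variant="counts_only")
        )
    with pytest.raises(ValueError, match="cmr"):
        build_model(
            ModelData(counts=data.counts, harvest=data.harvest),
            ModelConfig(variant="full_ipm"),
        )
    with pytest.raises(ValueError, match="salmon"):
        build_model(
            ModelData(cmr=data.cmr, litters=data.litters),
            ModelConfig(variant="kodiak_reduced"),
        )


def test_counts_only_finite_density_at_empty_population():
    T, Krep = 4, 3
    data = ModelData(
        counts=np.zeros((T, Krep, 5, 2), dtype=np.int64),
        harvest=np.zeros((T, 5, 2), dtype=np.int64),
    )
    model = build_model(data, ModelConfig(variant="counts_only"))
    state = model.initial_state(np.random.default_rng(0))
    state["lat"][:] = 0
    assert np.isfinite(model.log_joint(state))


def test_full_ipm_density_higher_at_truth_than_at_collapsed_survival(
    tiny_dataset,
):
    data = ModelData.from_dataset(tiny_dataset)
    model = build_model(data, ModelConfig(variant="full_ipm"))
    rng = np.random.default_rng(0)
    state = model.initial_state(rng)
    rates = tiny_dataset.rates
    sc = tiny_dataset.scenario
    state["phi_young"] = np.array(
        [rates.phi[0, 1], rates.phi[1, 1], rates.phi[2, 1]]
    )
    state["phi_S"] = rates.phi[3].copy()
    state["phi_A"] = rates.phi[4].copy()
    state["rho"] = rates.p_repro
    state["p"] = sc.detection_p
    state["p_prime"] = sc.recovery_pprime
    state["p_r"] = sc.repro_detect_pr
    at_truth = model.log_joint(state)
    assert np.isfinite(at_truth)
    worse = {k: (v.copy() if isinstance(v, np.ndarray) else v)
             for k, v in state.items()}
    worse["phi_S"] = np.array([0.02, 0.02])
    worse["phi_A"] = np.array([0.02, 0.02])
    assert model.log_joint(worse) < at_truth


# ---------------------------------------------------------------------------
# dual routes: compiled kernels vs the exact reference likelihoods


def test_litter_sufficient_statistics_match_per_record_likelihood(
    tiny_dataset,
):
    data = ModelData.from_dataset(tiny_dataset)
    model = build_model(data, ModelConfig(variant="full_ipm"))
    rng = np.random.default_rng(3)
    for _ in range(5):
        lam = rng.uniform(0.5, 4.0)
        phi_young = rng.uniform(0.3, 0.95, 3)
        p_w = rng.uniform(0.1, 0.9)
        fast = model._litter_ll(lam, phi_young, p_w)
        phi_by_age = [phi_young[0], phi_young[1], phi_young[2], phi_young[2]]
        slow = sum(
            litter_loglik(
                rec, lam, phi_by_age[: max(rec.max_age, 1)], p_w
            )
            for rec in tiny_dataset.litters
        )
        assert fast == pytest.approx(slow, abs=1e-8)


def test_augmented_count_state_marginalizes_to_exact_process_likelihood():
    """Summing the split-augmented joint over all split configurations must
    recover the exact convolution process likelihood plus observation
    terms."""
    from bearipm.core_model import PopulationState, VitalRates
    from bearipm.likelihoods import count_obs_loglik, process_loglik

    rng = np.random.default_rng(7)
    T, Krep, p = 2, 3, 0.7
    PhiC, PhiY, PhiD, PhiS, PhiA = (rng.uniform(0.4, 0.9, (T, 2)) for _ in range(5))
    gamD, gamS = (rng.uniform(0.2, 0.8, (T, 2)) for _ in range(2))
    P, L, sr = rng.uniform(0.2, 0.6, T), rng.uniform(1, 3, T), rng.uniform(0.4, 0.6, T)
    H = np.zeros((T, 5, 2), dtype=np.int64)
    lat = np.zeros((8, T, 2), dtype=np.int64)
    lat[K.NC, 0] = [5, 6]
    lat[K.NY, 0] = [4, 3]
    lat[K.AD, 0] = [3, 4]
    lat[K.AS, 0] = [3, 2]
    lat[K.AA, 0] = [5, 7]

    def naf(t, a, s):
        rows = {0: (K.NC,), 1: (K.NY,), 2: (K.AD, K.BD), 3: (K.AS, K.BS),
                4: (K.AA, K.BA)}[a]
        return int(sum(lat[rr, t, s] for rr in rows)) - int(H[t, a, s])

    mu = naf(0, 4, 1) * PhiA[0, 1] * P[0] * L[0]
    tot = rng.poisson(mu)
    lat[K.NC, 1, 0] = rng.binomial(tot, sr[0])
    lat[K.NC, 1, 1] = tot - lat[K.NC, 1, 0]
    for s in range(2):
        lat[K.NY, 1, s] = rng.binomial(naf(0, 0, s), PhiC[0, s])
        lat[K.AD, 1, s] = rng.binomial(naf(0, 2, s), PhiD[0, s] * (1 - gamD[0, s]))
        lat[K.BD, 1, s] = rng.binomial(naf(0, 1, s), PhiY[0, s])
        lat[K.AS, 1, s] = rng.binomial(naf(0, 3, s), PhiS[0, s] * (1 - gamS[0, s]))
        lat[K.BS, 1, s] = rng.binomial(naf(0, 2, s), PhiD[0, s] * gamD[0, s])
        lat[K.AA, 1, s] = rng.binomial(naf(0, 4, s), PhiA[0, s])
        lat[K.BA, 1, s] = rng.binomial(naf(0, 3, s), PhiS[0, s] * gamS[0, s])
    nafarr = np.array(
        [[[naf(t, a, s) for s in range(2)] for a in range(5)] for t in range(T)]
    )
    counts = rng.binomial(
        np.broadcast_to(nafarr[:, None], (T, Krep, 5, 2)), p
    ).astype(np.int64)

    states = []
    for t in range(T):
        nbh = np.array(
            [
                [int(sum(lat[rr, t, s] for rr in rows)) for s in range(2)]
                for rows in ((K.NC,), (K.NY,), (K.AD, K.BD), (K.AS, K.BS),
                             (K.AA, K.BA))
            ]
        )
        states.append(PopulationState(t, nbh, nbh - H[t]))
    ref = sum(
        count_obs_loglik(int(counts[t, k, a, s]), int(states[t].n[a, s]), p)
        for t in range(T)
        for k in range(Krep)
        for a in range(5)
        for s in range(2)
    )
    rates = VitalRates(
        phi=np.stack([PhiC[0], PhiY[0], PhiD[0], PhiS[0], PhiA[0]]),
        gamma=np.stack([gamD[0], gamS[0]]),
        p_repro=P[0], litter_size=L[0], sex_ratio=sr[0],
    )
    ref += process_loglik(states[0], states[1], rates)

    args = (PhiC, PhiY, PhiD, PhiS, PhiA, gamD, gamS, P, L, sr)
    pairs = [(row, 1, s) for row in (K.AD, K.AS, K.AA) for s in range(2)]
    sums = {k_: int(lat[k_[0], 1, k_[2]] + lat[k_[0] + 1, 1, k_[2]]) for k_ in pairs}
    lat2 = lat.copy()
    vals = []
    for combo in itertools.product(*[range(sums[k_] + 1) for k_ in pairs]):
        for k_, a_val in zip(pairs, combo):
            row, t, s = k_
            lat2[row, t, s] = a_val
            lat2[row + 1, t, s] = sums[k_] - a_val
        vals.append(
            K.count_layer_logjoint(lat2, H, counts, *args, p, 10**6)
        )
    assert logsumexp(vals) == pytest.approx(ref, abs=1e-9)


def test_cmr_class_kernel_matches_reference_history_likelihood(tiny_dataset):
    from bearipm.likelihoods import cjs_history_loglik

    data = ModelData.from_dataset(tiny_dataset)
    model = build_model(data, ModelConfig(variant="full_ipm"))
    phi_S = np.array([0.82, 0.86])
    phi_A = np.array([0.9, 0.94])
    p, pp, pr, rho = 0.7, 0.85, 0.8, 0.35
    state = model.initial_state(np.random.default_rng(0))
    state.update(
        phi_S=phi_S, phi_A=phi_A, p=p, p_prime=pp, p_r=pr, rho=rho
    )
    fast = model._cmr_ll(state)
    slow = 0.0
    for h in tiny_dataset.cmr:
        adult = np.asarray(h.covariates["is_adult"]) > 0.5
        s = int(h.sex)
        phi_vec = np.where(adult[:-1], phi_A[s], phi_S[s])
        rho_vec = rho * adult.astype(float) if h.repro is not None else None
        slow += cjs_history_loglik(
            h, phi_vec, p, pp,
            rho=rho_vec, p_r=pr if h.repro is not None else None,
        )
    assert fast == pytest.approx(slow, abs=1e-8)


def test_posterior_samples_validation():
    with pytest.raises(ValueError, match="finite"):
        PosteriorSamples(names=["a"], draws=np.full((2, 3, 1), np.nan))
    s = PosteriorSamples(names=["a", "b"], draws=np.zeros((2, 4, 2)))
    assert s.get("b").shape == (2, 4)
    df = s.to_dataframe()
    assert list(df.columns) == ["chain", "iteration", "a", "b"]
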