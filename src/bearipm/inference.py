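"""Posterior sampling for the three model variants.

``build_model`` assembles a joint log-density from the likelihood kernels,
the linking layer and the priors, for one of:

* ``counts_only`` -- the state-space count model alone, with independent
  Uniform(0,1) priors on every yearly rate where the linked rates would be;
* ``full_ipm`` -- counts + mark-recapture + litters, with class survival,
  reproduction probability and litter size informed by the individual-level
  layers through the linking equations;
* ``kodiak_reduced`` -- the covariate-rich CMR + litter case-study model
  (assembled in :mod:`bearipm.kodiak`).

``run_mcmc`` draws posterior samples with a Metropolis-within-Gibbs scheme:
compiled single-site integer random-walk (plus sum-preserving exchange)
updates for the discrete latent abundances, conjugate Gibbs draws where the
structure allows (binomial success probabilities, the sex ratio, detection in
the counts-only model), slice sampling for the remaining scalars, and a
joint detection/abundance rescaling move that traverses the N-vs-p ridge of
the repeated-count likelihood.  The latent alive state of marked individuals
is marginalized analytically (forward recursion), which is distributionally
equivalent to sampling it and mixes far better.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit
from scipy.stats import beta as beta_dist
from scipy.stats import gamma as gamma_dist

from . import _kernels as K
from ._slice import slice_sample
from .core_model import PriorSpec, beta_from_moments
from .likelihoods import CMRHistory, LitterRecord
from .simulator import SEX_RATIO_MEAN, SEX_RATIO_VAR, SimulatedDataset

__all__ = [
    "McmcSettings",
    "ModelConfig",
    "ModelData",
    "PosteriorSamples",
    "SimpleBinomialModel",
    "build_model",
    "run_mcmc",
    "gelman_rubin",
    "summarize",
    "MCMC_PRESETS",
]

logger = logging.getLogger(__name__)

#: Named MCMC protocols.  "desk" is the default interactive scale; "paper"
#: is the reference protocol (three chains, 50,000 burn-in, 50,000 sampling
#: iterations, thinning of 4).
MCMC_PRESETS = {
    "desk": dict(n_chains=2, n_burnin=5000, n_iter=5000, thin=1),
    "paper": dict(n_chains=3, n_burnin=50_000, n_iter=50_000, thin=4),
}


@dataclass
class McmcSettings:
    n_chains: int = 2
    n_burnin: int = 5000
    n_iter: int = 5000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least two chains are required for diagnostics")
        if self.n_iter < 1 or self.n_burnin < 0 or self.thin < 1:
            raise ValueError("invalid MCMC iteration settings")

    @classmethod
    def from_preset(cls, name: str, seed: int = 0) -> "McmcSettings":
        if name not in MCMC_PRESETS:
            raise ValueError(f"unknown MCMC preset {name!r}")
        return cls(seed=seed, **MCMC_PRESETS[name])


@dataclass
class ModelConfig:
    """Variant, priors and sampler settings for one model fit."""

    variant: str = "full_ipm"
    priors: dict[str, PriorSpec] = field(default_factory=dict)
    share_detection: bool = True
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    n_upper_bound: int | None = None
    litter_size_max: float = 4.0
    repro_conditional_on_detection: bool = False

    _VARIANTS = ("counts_only", "full_ipm", "kodiak_reduced")

    def __post_init__(self) -> None:
        if self.variant not in self._VARIANTS:
            raise ValueError(f"variant must be one of {self._VARIANTS}")

    def sex_ratio_prior_shapes(self) -> tuple[float, float]:
        spec = self.priors.get("sex_ratio")
        if spec is None:
            return beta_from_moments(SEX_RATIO_MEAN, SEX_RATIO_VAR)
        if spec.distribution == "uniform01":
            return 1.0, 1.0
        if spec.distribution == "beta":
            return spec.parameters
        raise ValueError("sex_ratio prior must be uniform01 or beta")


@dataclass
class ModelData:
    """Input tables for one fit; presence requirements depend on the variant."""

    counts: np.ndarray | None = None  # (T, K, 5, 2) nonnegative ints
    harvest: np.ndarray | None = None  # (T, 5, 2) nonnegative ints
    cmr: list[CMRHistory] | None = None
    litters: list[LitterRecord] | None = None
    covariates: dict[str, np.ndarray] | None = None  # e.g. yearly salmon biomass

    @classmethod
    def from_dataset(cls, ds: SimulatedDataset) -> "ModelData":
        return cls(
            counts=ds.counts_array(),
            harvest=ds.harvest_array(),
            cmr=ds.cmr,
            litters=ds.litters,
        )

    @property
    def n_years(self) -> int:
        if self.counts is not None:
            return int(self.counts.shape[0])
        raise ValueError("n_years undefined without count data")


@dataclass
class PosteriorSamples:
    """Labeled MCMC draws with chain structure.

    ``draws`` has shape (n_chains, n_draws, n_params); ``latent_n`` (when the
    model has a count layer) holds post-harvest abundance draws with shape
    (n_chains, n_draws, T, 5, 2).
    """

    names: list[str]
    draws: np.ndarray
    latent_n: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must have shape (chains, draws, params)")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite posterior draws")
        self._index = {n: i for i, n in enumerate(self.names)}

    def get(self, parameter: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_draws)."""
        return self.draws[:, :, self._index[parameter]]

    def to_dataframe(self):
        """One row per chain-iteration, one column per parameter."""
        import pandas as pd

        m, n, _ = self.draws.shape
        df = pd.DataFrame(
            self.draws.reshape(m * n, -1), columns=self.names
        )
        df.insert(0, "chain", np.repeat(np.arange(m), n))
        df.insert(1, "iteration", np.tile(np.arange(n), m))
        return df


def summarize(
    samples: PosteriorSamples | np.ndarray,
    parameter: str | None = None,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Posterior mean and equal-tailed credible interval, pooled over chains."""
    if isinstance(samples, PosteriorSamples):
        x = samples.get(parameter).ravel()
    else:
        x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no draws to summarize")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(x.mean()), float(lo), float(hi)


def gelman_rubin(
    samples: PosteriorSamples | np.ndarray, parameter: str | None = None
) -> float:
    """Potential scale reduction factor R-hat (classic two-part formula).

    Needs at least two chains of at least two draws.  When every chain has
    zero within-chain variance the statistic is undefined: a warning is
    emitted and NaN returned as a sentinel.
    """
    if isinstance(samples, PosteriorSamples):
        x = samples.get(parameter)
    else:
        x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    n = x.shape[1]
    chain_means = x.mean(axis=1)
    within = float(x.var(axis=1, ddof=1).mean())
    between_over_n = float(chain_means.var(ddof=1))  # B / n
    if within == 0.0:
        warnings.warn(
            "zero within-chain variance in all chains; R-hat undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    v_hat = (n - 1) / n * within + between_over_n
    return math.sqrt(v_hat / within)


# ---------------------------------------------------------------------------
# vectorized pmf helpers (clipped at the open-interval edges; samplers never
# visit p exactly 0 or 1 under the continuous priors)

_EPS = 1e-12


def _vbinom_sum(k: np.ndarray, n: np.ndarray, p) -> float:
    k = np.asarray(k)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    if np.any((n < 0) | (k < 0) | (k > n)):
        return -np.inf
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    lp = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(pc)
        + (n - k) * np.log1p(-pc)
    )
    return float(np.sum(lp))


def _vpois_sum(k: np.ndarray, mu: np.ndarray) -> float:
    k = np.asarray(k)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0) or np.any(k < 0):
        return -np.inf
    if np.any((mu == 0) & (k > 0)):
        return -np.inf
    muc = np.maximum(mu, 1e-300)
    lp = k * np.log(muc) - mu - gammaln(k + 1)
    return float(np.sum(lp))


def _trunc_gamma_draw(
    shape_: float, rate: float, upper: float, rng: np.random.Generator
) -> float:
    """Exact draw from Gamma(shape, rate) truncated to (0, upper]."""
    if rate <= 0.0 or shape_ <= 0.0:
        return float(rng.uniform(0.0, upper))
    scale = 1.0 / rate
    for _ in range(16):  # cheap rejection path covers the typical case
        x = rng.gamma(shape_, scale)
        if x <= upper:
            return max(float(x), 1e-12)
    cap = float(gamma_dist.cdf(upper, shape_, scale=scale))
    if cap <= 0.0:
        return upper * (1.0 - 1e-9)
    u = rng.random() * cap
    x = float(gamma_dist.ppf(u, shape_, scale=scale))
    return min(max(x, 1e-12), upper * (1.0 - 1e-12))


def _rounded_normal_logpmf(x: np.ndarray, c: np.ndarray, sd: np.ndarray):
    """Log-pmf of max(0, round(Normal(c, sd))) evaluated at integers x."""
    from scipy.special import ndtr

    hi = ndtr((x + 0.5 - c) / sd)
    lo = np.where(x > 0, ndtr((x - 0.5 - c) / sd), 0.0)
    return np.log(np.maximum(hi - lo, 1e-300))


# ---------------------------------------------------------------------------


class _CountLayerModel:
    """Shared machinery for variants with a repeated-count layer."""

    def __init__(self, data: ModelData, config: ModelConfig):
        if data.counts is None or data.harvest is None:
            missing = [
                name
                for name, v in (("counts", data.counts), ("harvest", data.harvest))
                if v is None
            ]
            raise ValueError(
                f"variant {config.variant!r} requires tables: {', '.join(missing)}"
            )
        self.config = config
        self.counts = np.ascontiguousarray(data.counts, dtype=np.int64)
        self.H = np.ascontiguousarray(data.harvest, dtype=np.int64)
        if self.counts.ndim != 4 or self.counts.shape[2:] != (5, 2):
            raise ValueError("counts must have shape (T, K, 5, 2)")
        if self.H.shape != (self.counts.shape[0], 5, 2):
            raise ValueError("harvest must have shape (T, 5, 2)")
        self.T = int(self.counts.shape[0])
        self.K = int(self.counts.shape[1])
        self.max_counts = self.counts.max(axis=1)  # (T, 5, 2)
        max_obs = int(self.max_counts.max())
        self.ncap = config.n_upper_bound or int(10 * max_obs + 200)
        if self.ncap <= max_obs:
            raise ValueError(
                f"n_upper_bound {self.ncap} must exceed max observed count {max_obs}"
            )
        a, b = config.sex_ratio_prior_shapes()
        self.sr_a, self.sr_b = float(a), float(b)
        self.Lmax = float(config.litter_size_max)

    # -- initialization ----------------------------------------------------

    def _init_latents(self, rng: np.random.Generator, inflate: float) -> np.ndarray:
        """Feasible latent start: counts scaled up by an assumed detection of
        0.5, then repaired backward so every binomial has enough trials."""
        T, H = self.T, self.H
        naf = np.ceil(self.max_counts / 0.5 * inflate).astype(np.int64) + 1
        lat = np.zeros((8, T, 2), dtype=np.int64)
        # backward repair of pool sizes, then forward assembly of splits
        for t in range(T - 1, 0, -1):
            for s in range(2):
                nbh_y = naf[t, 1, s] + H[t, 1, s]
                naf[t - 1, 0, s] = max(naf[t - 1, 0, s], nbh_y)
                nbh_d = naf[t, 2, s] + H[t, 2, s]
                bd = min(nbh_d, naf[t - 1, 1, s])
                naf[t - 1, 2, s] = max(naf[t - 1, 2, s], nbh_d - bd)
                nbh_s = naf[t, 3, s] + H[t, 3, s]
                bs = min(nbh_s, naf[t - 1, 2, s])
                naf[t - 1, 3, s] = max(naf[t - 1, 3, s], nbh_s - bs)
                nbh_a = naf[t, 4, s] + H[t, 4, s]
                ba = min(nbh_a, naf[t - 1, 3, s])
                naf[t - 1, 4, s] = max(naf[t - 1, 4, s], nbh_a - ba)
            if naf[t, 0, :].sum() + H[t, 0, :].sum() > 0:
                naf[t - 1, 4, 1] = max(naf[t - 1, 4, 1], 1)
        for t in range(T):
            for s in range(2):
                lat[K.NC, t, s] = naf[t, 0, s] + H[t, 0, s]
                lat[K.NY, t, s] = naf[t, 1, s] + H[t, 1, s]
                nbh_d = naf[t, 2, s] + H[t, 2, s]
                nbh_s = naf[t, 3, s] + H[t, 3, s]
                nbh_a = naf[t, 4, s] + H[t, 4, s]
                if t == 0:
                    lat[K.AD, t, s] = nbh_d
                    lat[K.AS, t, s] = nbh_s
                    lat[K.AA, t, s] = nbh_a
                else:
                    bd = min(nbh_d, naf[t - 1, 1, s])
                    lat[K.BD, t, s] = bd
                    lat[K.AD, t, s] = nbh_d - bd
                    bs = min(nbh_s, naf[t - 1, 2, s])
                    lat[K.BS, t, s] = bs
                    lat[K.AS, t, s] = nbh_s - bs
                    ba = min(nbh_a, naf[t - 1, 3, s])
                    lat[K.BA, t, s] = ba
                    lat[K.AA, t, s] = nbh_a - ba
        return lat

    def _proposal_scales(self, lat: np.ndarray) -> np.ndarray:
        return np.clip(np.sqrt(np.maximum(lat, 1)) / 2.0, 2, 12).astype(np.int64)

    # -- shared pieces -----------------------------------------------------

    def _nafter_arrays(self, lat: np.ndarray) -> np.ndarray:
        """Post-harvest abundances, shape (T, 5, 2)."""
        naf = np.empty((self.T, 5, 2), dtype=np.int64)
        naf[:, 0] = lat[K.NC] - self.H[:, 0]
        naf[:, 1] = lat[K.NY] - self.H[:, 1]
        naf[:, 2] = lat[K.AD] + lat[K.BD] - self.H[:, 2]
        naf[:, 3] = lat[K.AS] + lat[K.BS] - self.H[:, 3]
        naf[:, 4] = lat[K.AA] + lat[K.BA] - self.H[:, 4]
        return naf

    def latent_n(self, state: dict) -> np.ndarray:
        return self._nafter_arrays(state["lat"])

    def _count_logjoint(self, state: dict) -> float:
        arrs = self._expand(state)
        return float(
            K.count_layer_logjoint(
                state["lat"], self.H, self.counts, *arrs, self._get_p(state),
                self.ncap,
            )
        )

    def _latent_sweeps(self, state: dict, rng: np.random.Generator, n: int = 2):
        arrs = self._expand(state)
        for _ in range(n):
            seed = int(rng.integers(1, 1 << 31))
            K.count_latent_sweep(
                seed, state["lat"], self.H, self.counts, *arrs,
                self._get_p(state), self.ncap, state["scales"],
            )

    def _update_sex_ratio(self, state: dict, rng: np.random.Generator):
        lat = state["lat"]
        sr = state["sr"]
        ncm = lat[K.NC, 1:, 0]
        ncf = lat[K.NC, 1:, 1]
        sr[: self.T - 1] = rng.beta(self.sr_a + ncm, self.sr_b + ncf)
        sr[self.T - 1] = rng.beta(self.sr_a, self.sr_b)
        np.clip(sr, 1e-6, 1 - 1e-6, out=sr)

    #: detection-rescaling proposal: logit step and (constant) rounding noise.
    #: The noise must stay well under one individual, or the tightly coupled
    #: year-to-year binomials reject every joint proposal.
    _SCALE_ETA_SD = 0.08
    _SCALE_NOISE_SD = 0.15

    def _scale_move(self, state: dict, rng: np.random.Generator):
        """Joint move rescaling detection and every latent abundance.

        Proposes p' on the logit scale and every latent as a randomized
        rounding of N * p/p', which walks along the abundance-detection ridge
        of the repeated-count likelihood that single-site updates cross only
        very slowly.
        """
        p_old = self._get_p(state)
        eta = float(logit(p_old) + rng.normal(0.0, self._SCALE_ETA_SD))
        p_new = float(expit(eta))
        lat_old = state["lat"]
        free = np.ones_like(lat_old, dtype=bool)
        free[(K.BD, K.BS, K.BA), 0, :] = False
        sd = self._SCALE_NOISE_SD

        def propose(lat_src, factor):
            c = lat_src.astype(float) * factor
            prop = np.maximum(np.rint(rng.normal(c, sd)), 0).astype(np.int64)
            prop[~free] = lat_src[~free]
            lq = _rounded_normal_logpmf(prop, c, sd)[free].sum()
            return prop, float(lq)

        lat_new, lq_fwd = propose(lat_old, p_old / p_new)
        c_rev = lat_new.astype(float) * (p_new / p_old)
        lq_rev = float(_rounded_normal_logpmf(lat_old, c_rev, sd)[free].sum())

        ll_old = self._count_logjoint(state) + self._extra_p_loglik(state, p_old)
        state_new = dict(state)
        state_new["lat"] = lat_new
        self._set_p(state_new, p_new)
        ll_new = self._count_logjoint(state_new) + self._extra_p_loglik(
            state_new, p_new
        )
        log_acc = (
            ll_new
            - ll_old
            + lq_rev
            - lq_fwd
            + math.log(p_new * (1 - p_new))
            - math.log(p_old * (1 - p_old))
        )
        if np.isfinite(log_acc) and math.log(rng.random() + 1e-300) < log_acc:
            state["lat"] = lat_new
            self._set_p(state, p_new)

    def _extra_p_loglik(self, state: dict, p: float) -> float:
        """Non-count terms involving the detection probability (none here)."""
        return 0.0

    def _get_p(self, state: dict) -> float:
        return float(state["p"])

    def _set_p(self, state: dict, value: float):
        state["p"] = float(value)

    def _count_p_stats(self, lat: np.ndarray) -> tuple[float, float]:
        naf = self._nafter_arrays(lat)
        succ = float(self.counts.sum())
        trials = float(self.K * naf.sum())
        return succ, trials


class CountsOnlyModel(_CountLayerModel):
    """State-space count model with independent Uniform(0,1) yearly rates."""

    variant = "counts_only"

    def _expand(self, state: dict):
        return (
            state["PhiC"], state["PhiY"], state["PhiD"], state["PhiS"],
            state["PhiA"], state["gamD"], state["gamS"], state["P"],
            state["L"], state["sr"],
        )

    def param_names(self) -> list[str]:
        names = ["p"]
        for nm in ("PhiC", "PhiY", "PhiD", "PhiS", "PhiA", "gamD", "gamS"):
            names += [f"{nm}[{sc},{t}]" for sc in "mf" for t in range(self.T)]
        for nm in ("P", "L", "sex_ratio"):
            names += [f"{nm}[{t}]" for t in range(self.T)]
        return names

    def extract(self, state: dict) -> np.ndarray:
        parts = [np.array([state["p"]])]
        for nm in ("PhiC", "PhiY", "PhiD", "PhiS", "PhiA", "gamD", "gamS"):
            parts.append(state[nm].T.ravel())
        parts += [state["P"], state["L"], state["sr"]]
        return np.concatenate(parts)

    def initial_state(self, rng: np.random.Generator, inflate: float = 1.0) -> dict:
        T = self.T
        lat = self._init_latents(rng, inflate)
        state = {
            "lat": lat,
            "scales": self._proposal_scales(lat),
            "PhiC": np.full((T, 2), 0.6),
            "PhiY": np.full((T, 2), 0.6),
            "PhiD": np.full((T, 2), 0.6),
            "PhiS": np.full((T, 2), 0.6),
            "PhiA": np.full((T, 2), 0.7),
            "gamD": np.full((T, 2), 0.5),
            "gamS": np.full((T, 2), 0.5),
            "P": np.full(T, 0.3),
            "L": np.full(T, 2.0),
            "sr": np.full(T, self.sr_a / (self.sr_a + self.sr_b)),
            "p": 0.5,
        }
        return state

    def log_joint(self, state: dict) -> float:
        for nm in ("PhiC", "PhiY", "PhiD", "PhiS", "PhiA", "gamD", "gamS", "P"):
            if np.any((state[nm] <= 0) | (state[nm] >= 1)):
                return -np.inf
        if np.any((state["L"] <= 0) | (state["L"] > self.Lmax)):
            return -np.inf
        if not 0.0 < state["p"] < 1.0:
            return -np.inf
        if np.any((state["sr"] <= 0) | (state["sr"] >= 1)):
            return -np.inf
        lp = float(beta_dist.logpdf(state["sr"], self.sr_a, self.sr_b).sum())
        lp -= self.T * math.log(self.Lmax)  # uniform(0, Lmax) prior on L
        return lp + self._count_logjoint(state)

    # -- sweep -------------------------------------------------------------

    def sweep(self, state: dict, rng: np.random.Generator, iteration: int):
        self._latent_sweeps(state, rng, n=2)
        lat, H, T = state["lat"], self.H, self.T
        naf = self._nafter_arrays(lat)
        tt = slice(0, T - 1)

        def beta_update(arr, succ, trials, col):
            draws = rng.beta(1.0 + succ, 1.0 + (trials - succ))
            arr[tt, col] = np.clip(draws, 1e-9, 1 - 1e-9)
            arr[T - 1, col] = rng.uniform(1e-9, 1 - 1e-9)

        for s in range(2):
            beta_update(state["PhiC"], lat[K.NY, 1:, s], naf[tt, 0, s], s)
            beta_update(state["PhiY"], lat[K.BD, 1:, s], naf[tt, 1, s], s)
        beta_update(state["PhiA"], lat[K.AA, 1:, 0], naf[tt, 4, 0], 0)

        self._mh_phi_gamma(
            state, rng, "PhiD", "gamD", lat[K.AD, 1:], lat[K.BS, 1:], naf[tt, 2]
        )
        self._mh_phi_gamma(
            state, rng, "PhiS", "gamS", lat[K.AS, 1:], lat[K.BA, 1:], naf[tt, 3]
        )
        self._mh_phiA_female(state, rng, naf)
        self._gibbs_P_L(state, rng, naf)
        self._update_sex_ratio(state, rng)
        succ, trials = self._count_p_stats(lat)
        state["p"] = float(
            np.clip(rng.beta(1.0 + succ, 1.0 + trials - succ), 1e-9, 1 - 1e-9)
        )
        # detection is only weakly identified here, so cross the ridge twice
        self._scale_move(state, rng)
        self._scale_move(state, rng)

    def _mh_phi_gamma(self, state, rng, phi_key, gam_key, a_next, b_next, pool):
        """Joint elementwise MH on (survival, transition) pairs per class-year."""
        T = self.T
        phi, gam = state[phi_key], state[gam_key]
        for _ in range(2):
            cur_phi, cur_gam = phi[: T - 1], gam[: T - 1]
            prop_phi = expit(logit(cur_phi) + rng.normal(0, 0.35, cur_phi.shape))
            prop_gam = expit(logit(cur_gam) + rng.normal(0, 0.35, cur_gam.shape))

            def ll(ph, gm):
                with np.errstate(divide="ignore", invalid="ignore"):
                    la = (
                        a_next * np.log(np.clip(ph * (1 - gm), _EPS, None))
                        + (pool - a_next) * np.log1p(-np.clip(ph * (1 - gm), None, 1 - _EPS))
                    )
                    lb = (
                        b_next * np.log(np.clip(ph * gm, _EPS, None))
                        + (pool - b_next) * np.log1p(-np.clip(ph * gm, None, 1 - _EPS))
                    )
                return la + lb

            log_r = ll(prop_phi, prop_gam) - ll(cur_phi, cur_gam)
            # logit-normal random walk on a uniform(0,1) variable: the prior
            # times proposal asymmetry reduces to the Jacobian ratio
            for cur, prop in ((cur_phi, prop_phi), (cur_gam, prop_gam)):
                log_r += np.log(prop * (1 - prop)) - np.log(cur * (1 - cur))
            acc = np.log(rng.random(cur_phi.shape)) < log_r
            phi[: T - 1][acc] = prop_phi[acc]
            gam[: T - 1][acc] = prop_gam[acc]
        phi[T - 1] = rng.uniform(1e-9, 1 - 1e-9, 2)
        gam[T - 1] = rng.uniform(1e-9, 1 - 1e-9, 2)

    def _mh_phiA_female(self, state, rng, naf):
        T, lat = self.T, state["lat"]
        phi = state["PhiA"]
        pool = naf[: T - 1, 4, 1]
        succ = lat[K.AA, 1:, 1]
        tot_cubs = lat[K.NC, 1:, 0] + lat[K.NC, 1:, 1]
        base = naf[: T - 1, 4, 1] * state["P"][: T - 1] * state["L"][: T - 1]
        for _ in range(2):
            cur = phi[: T - 1, 1]
            prop = expit(logit(cur) + rng.normal(0, 0.3, cur.shape))

            def ll(ph):
                binom = succ * np.log(np.clip(ph, _EPS, None)) + (
                    pool - succ
                ) * np.log1p(-np.clip(ph, None, 1 - _EPS))
                mu = base * ph
                pois = np.where(
                    mu > 0, tot_cubs * np.log(np.maximum(mu, 1e-300)) - mu,
                    np.where(tot_cubs > 0, -np.inf, 0.0),
                )
                return binom + pois

            log_r = ll(prop) - ll(cur)
            log_r += np.log(prop * (1 - prop)) - np.log(cur * (1 - cur))
            acc = np.log(rng.random(cur.shape)) < log_r
            phi[: T - 1, 1][acc] = prop[acc]
        phi[T - 1, 1] = rng.uniform(1e-9, 1 - 1e-9)

    def _gibbs_P_L(self, state, rng, naf):
        """Exact truncated-Gamma draws for reproduction and litter size."""
        T, lat = self.T, state["lat"]
        tot_cubs = lat[K.NC, 1:, 0] + lat[K.NC, 1:, 1]
        for t in range(T - 1):
            shape_ = float(tot_cubs[t]) + 1.0
            c_common = float(naf[t, 4, 1]) * float(state["PhiA"][t, 1])
            state["P"][t] = _trunc_gamma_draw(
                shape_, c_common * state["L"][t], 1.0, rng
            )
            state["L"][t] = _trunc_gamma_draw(
                shape_, c_common * state["P"][t], self.Lmax, rng
            )
        state["P"][T - 1] = rng.uniform(1e-9, 1 - 1e-9)
        state["L"][T - 1] = rng.uniform(1e-9, self.Lmax)


class FullIPMModel(_CountLayerModel):
    """Joint model of counts, mark-recapture and litters with linked rates.

    Young survival (cubs, yearlings, dependents) is shared between the litter
    attrition process and the count transitions; subadult/adult survival and
    the reproduction probability are shared between the mark-recapture layer
    and the count transitions; cub recruitment runs on the litter model's
    population mean litter size (the zero-truncated mean of its initiation
    rate), so litter-sampling noise is propagated rather than plugged in.
    Detection is shared between counts and CMR when ``share_detection``.
    """

    variant = "full_ipm"

    def __init__(self, data: ModelData, config: ModelConfig):
        super().__init__(data, config)
        missing = [
            nm for nm, v in (("cmr", data.cmr), ("litters", data.litters)) if not v
        ]
        if missing:
            raise ValueError(
                f"variant 'full_ipm' requires tables: {', '.join(missing)}"
            )
        self._encode_cmr(data.cmr)
        self._litter_stats(data.litters)

    # -- data encodings ----------------------------------------------------

    def _encode_cmr(self, histories: list[CMRHistory]):
        n = len(histories)
        lmax = max(h.n_occasions for h in histories)
        y = np.zeros((n, lmax), dtype=np.int8)
        r = np.zeros((n, lmax), dtype=np.int8)
        repro = np.full((n, lmax), -1, dtype=np.int8)
        length = np.zeros(n, dtype=np.int64)
        sex = np.zeros(n, dtype=np.int64)
        adult = np.zeros((n, lmax), dtype=bool)
        for i, h in enumerate(histories):
            L = h.n_occasions
            length[i] = L
            y[i, :L] = h.y
            r[i, :L] = h.r
            sex[i] = int(h.sex)
            if "is_adult" in h.covariates:
                adult[i, :L] = np.asarray(h.covariates["is_adult"]) > 0.5
            else:
                ages = h.age_at_entry + np.arange(L)
                adult[i, :L] = ages >= 5
            if h.repro is not None:
                repro[i, :L] = h.repro
                if self.config.repro_conditional_on_detection:
                    repro[i, :L][h.y == 0] = -1
        # survival over interval ending at j uses the class held at j-1
        adult_prev = np.zeros((n, lmax), dtype=np.int8)
        adult_prev[:, 1:] = adult[:, :-1]
        # reproduction applies to adult females in the current year
        elig = (adult & (sex[:, None] == 1)).astype(np.int8)
        repro[(elig == 0) & (repro >= 0)] = -1
        # identical encoded histories collapse to one weighted row
        key = np.concatenate(
            [y, r, repro + 1, adult_prev, elig, sex[:, None].astype(np.int8),
             length[:, None].astype(np.int8)],
            axis=1,
        )
        _, first, counts_ = np.unique(
            key, axis=0, return_index=True, return_counts=True
        )
        self.cmr_y = np.ascontiguousarray(y[first])
        self.cmr_r = np.ascontiguousarray(r[first])
        self.cmr_repro = np.ascontiguousarray(repro[first])
        self.cmr_len = length[first]
        self.cmr_sex = sex[first]
        self.cmr_adult_prev = np.ascontiguousarray(adult_prev[first])
        self.cmr_repro_elig = np.ascontiguousarray(elig[first])
        self.cmr_weight = counts_.astype(np.float64)

    def _litter_stats(self, litters: list[LitterRecord]):
        self.n_litters = len(litters)
        self.sum_l0 = float(sum(int(r.sizes[0]) for r in litters))
        trials = np.zeros(3)
        succ = np.zeros(3)
        w_yes = 0
        w_no = 0
        lconst = 0.0
        L_obs = np.zeros(self.T)
        n_born = np.zeros(self.T, dtype=np.int64)
        for rec in litters:
            if 0 <= rec.birth_year < self.T:
                L_obs[rec.birth_year] += rec.sizes[0]
                n_born[rec.birth_year] += 1
            lconst -= gammaln(int(rec.sizes[0]) + 1)
            for i in range(1, rec.sizes.size):
                cls = min(i - 1, 2)  # interval start age -> cub/yrlg/dependent
                trials[cls] += rec.sizes[i - 1]
                succ[cls] += rec.sizes[i]
                lconst += (
                    gammaln(rec.sizes[i - 1] + 1)
                    - gammaln(rec.sizes[i] + 1)
                    - gammaln(rec.sizes[i - 1] - rec.sizes[i] + 1)
                )
            m = rec.max_age
            for age in range(2, m + 1):
                if rec.sizes[age] == 0 or age >= 4:
                    continue
                if rec.weaned_at == age:
                    w_yes += 1
                else:
                    w_no += 1
        self.att_trials = trials
        self.att_succ = succ
        self.w_yes, self.w_no = w_yes, w_no
        self.litter_const = float(lconst)
        self.has_litters = n_born > 0
        self.L_obs = np.where(n_born > 0, L_obs / np.maximum(n_born, 1), 0.0)

    # -- likelihood pieces --------------------------------------------------

    def _cmr_ll(self, state, p=None, p_prime=None, p_r=None, rho=None,
                phi_S=None, phi_A=None) -> float:
        p = self._cmr_p(state) if p is None else p
        p_prime = state["p_prime"] if p_prime is None else p_prime
        p_r = state["p_r"] if p_r is None else p_r
        rho = state["rho"] if rho is None else rho
        phi_S = state["phi_S"] if phi_S is None else phi_S
        phi_A = state["phi_A"] if phi_A is None else phi_A
        return float(
            K.cmr_class_loglik(
                self.cmr_y, self.cmr_r, self.cmr_repro, self.cmr_len,
                self.cmr_weight, self.cmr_sex, self.cmr_adult_prev,
                self.cmr_repro_elig,
                np.asarray(phi_S, dtype=float), np.asarray(phi_A, dtype=float),
                float(rho), float(p), float(p_prime), float(p_r),
            )
        )

    def _litter_ll(self, lam, phi_young, p_w) -> float:
        if lam <= 0 or not 0.0 < p_w < 1.0:
            return -np.inf
        n = self.n_litters
        ll = (
            self.sum_l0 * math.log(lam)
            - n * lam
            - n * math.log(-math.expm1(-lam))
            + self.litter_const
        )
        for c in range(3):
            phi = float(phi_young[c])
            if not 0.0 < phi < 1.0:
                return -np.inf
            ll += self.att_succ[c] * math.log(phi)
            ll += (self.att_trials[c] - self.att_succ[c]) * math.log1p(-phi)
        ll += self.w_yes * math.log(p_w) + self.w_no * math.log1p(-p_w)
        return ll

    def _cmr_p(self, state) -> float:
        return state["p"] if self.config.share_detection else state["p_cmr"]

    def _extra_p_loglik(self, state: dict, p: float) -> float:
        if self.config.share_detection:
            return self._cmr_ll(state, p=p)
        return 0.0

    # -- state <-> arrays ---------------------------------------------------

    def _L_vector(self, state) -> np.ndarray:
        # the count layer runs on the litter model's population mean litter
        # size (zero-truncated mean of lambda), not on per-year sample means
        # of a handful of litters: the plug-in sample mean carries sampling
        # noise the posterior would otherwise treat as exact, which
        # demonstrably miscalibrates the reproduction-side parameters at
        # small litter counts
        lam = float(state["lam"])
        return np.full(self.T, lam / -math.expm1(-lam))

    def _expand(self, state: dict):
        T = self.T
        py = state["phi_young"]
        arr = lambda v: np.full((T, 2), float(v))
        PhiS = np.repeat(state["phi_S"][None, :], T, axis=0)
        PhiA = np.repeat(state["phi_A"][None, :], T, axis=0)
        return (
            arr(py[0]), arr(py[1]), arr(py[2]), np.ascontiguousarray(PhiS),
            np.ascontiguousarray(PhiA), state["gamD"], state["gamS"],
            np.full(T, float(state["rho"])), self._L_vector(state), state["sr"],
        )

    def param_names(self) -> list[str]:
        names = [
            "p", "p_prime", "p_r", "rho",
            "phi_young_cub", "phi_young_yearling", "phi_young_dependent",
            "phi_subadult[m]", "phi_subadult[f]",
            "phi_adult[m]", "phi_adult[f]",
            "p_w", "litter_lambda",
        ]
        if not self.config.share_detection:
            names.insert(1, "p_cmr")
        names.append("mean_litter_size")
        for nm in ("gamD", "gamS"):
            names += [f"{nm}[{sc},{t}]" for sc in "mf" for t in range(self.T)]
        names += [f"sex_ratio[{t}]" for t in range(self.T)]
        return names

    def extract(self, state: dict) -> np.ndarray:
        head = [state["p"]]
        if not self.config.share_detection:
            head.append(state["p_cmr"])
        head += [
            state["p_prime"], state["p_r"], state["rho"],
            *state["phi_young"], *state["phi_S"], *state["phi_A"],
            state["p_w"], state["lam"], float(self._L_vector(state)[0]),
        ]
        parts = [np.asarray(head, dtype=float)]
        for nm in ("gamD", "gamS"):
            parts.append(state[nm].T.ravel())
        parts.append(state["sr"])
        return np.concatenate(parts)

    def initial_state(self, rng: np.random.Generator, inflate: float = 1.0) -> dict:
        T = self.T
        lat = self._init_latents(rng, inflate)
        state = {
            "lat": lat,
            "scales": self._proposal_scales(lat),
            "phi_young": np.array([0.65, 0.8, 0.85]),
            "phi_S": np.array([0.85, 0.85]),
            "phi_A": np.array([0.9, 0.93]),
            "rho": 0.3,
            "gamD": np.full((T, 2), 0.5),
            "gamS": np.full((T, 2), 0.5),
            "sr": np.full(T, self.sr_a / (self.sr_a + self.sr_b)),
            "p": 0.6,
            "p_prime": 0.8,
            "p_r": 0.8,
            "p_w": 0.5,
            "lam": 2.0,
        }
        if not self.config.share_detection:
            state["p_cmr"] = 0.6
        return state

    def log_joint(self, state: dict) -> float:
        scalars = [
            state["p"], state["p_prime"], state["p_r"], state["rho"],
            state["p_w"], *state["phi_young"], *state["phi_S"], *state["phi_A"],
        ]
        if not self.config.share_detection:
            scalars.append(state["p_cmr"])
        if any(not 0.0 < v < 1.0 for v in scalars) or state["lam"] <= 0:
            return -np.inf
        if np.any((state["gamD"] <= 0) | (state["gamD"] >= 1)):
            return -np.inf
        if np.any((state["gamS"] <= 0) | (state["gamS"] >= 1)):
            return -np.inf
        if np.any((state["sr"] <= 0) | (state["sr"] >= 1)):
            return -np.inf
        lp = float(beta_dist.logpdf(state["sr"], self.sr_a, self.sr_b).sum())
        lp += self._count_logjoint(state)
        lp += self._cmr_ll(state)
        lp += self._litter_ll(state["lam"], state["phi_young"], state["p_w"])
        return lp

    # -- sweep -------------------------------------------------------------

    def sweep(self, state: dict, rng: np.random.Generator, iteration: int):
        self._latent_sweeps(state, rng, n=2)
        lat, T = state["lat"], self.T
        naf = self._nafter_arrays(lat)
        self._mh_gamma(state, rng, naf)
        self._update_sex_ratio(state, rng)
        self._slice_survival(state, rng, naf)
        self._slice_observation(state, rng, naf)
        # weaning probability: litter data only, conjugate
        state["p_w"] = float(
            np.clip(
                rng.beta(1.0 + self.w_yes, 1.0 + self.w_no), 1e-9, 1 - 1e-9
            )
        )
        self._scale_move(state, rng)

    def _mh_gamma(self, state, rng, naf):
        """Elementwise MH for yearly transition rates given fixed survival."""
        lat, T = state["lat"], self.T
        specs = (
            ("gamD", float(state["phi_young"][2]), lat[K.AD, 1:], lat[K.BS, 1:],
             naf[: T - 1, 2]),
            ("gamS", None, lat[K.AS, 1:], lat[K.BA, 1:], naf[: T - 1, 3]),
        )
        for key, phi_scalar, a_next, b_next, pool in specs:
            gam = state[key]
            phi = (
                np.full(2, phi_scalar)
                if phi_scalar is not None
                else state["phi_S"]
            )[None, :]
            for _ in range(2):
                cur = gam[: T - 1]
                prop = expit(logit(cur) + rng.normal(0, 0.35, cur.shape))

                def ll(gm):
                    pa = np.clip(phi * (1 - gm), _EPS, 1 - _EPS)
                    pb = np.clip(phi * gm, _EPS, 1 - _EPS)
                    return (
                        a_next * np.log(pa)
                        + (pool - a_next) * np.log1p(-pa)
                        + b_next * np.log(pb)
                        + (pool - b_next) * np.log1p(-pb)
                    )

                log_r = ll(prop) - ll(cur)
                log_r += np.log(prop * (1 - prop)) - np.log(cur * (1 - cur))
                acc = np.log(rng.random(cur.shape)) < log_r
                gam[: T - 1][acc] = prop[acc]
            gam[T - 1] = rng.uniform(1e-9, 1 - 1e-9, 2)

    def _slice_survival(self, state, rng, naf):
        """Slice updates for the linked survival/reproduction scalars.

        Each conditional is reduced to sufficient statistics of the fixed
        latent state (binomial success/failure totals, Poisson totals), so a
        slice evaluation costs one CMR kernel call plus O(1) arithmetic.
        """
        lat, T = state["lat"], self.T
        tt = slice(0, T - 1)
        gamD, gamS = state["gamD"][tt], state["gamS"][tt]
        L_vec = self._L_vector(state)
        tot_cubs = float(np.sum(lat[K.NC, 1:]))

        # young survival: litter attrition + count transitions
        py = state["phi_young"]
        stats = {
            0: (float(lat[K.NY, 1:].sum()), float((naf[tt, 0] - lat[K.NY, 1:]).sum())),
            1: (float(lat[K.BD, 1:].sum()), float((naf[tt, 1] - lat[K.BD, 1:]).sum())),
        }
        kAD, kBS = lat[K.AD, 1:], lat[K.BS, 1:]
        nD = naf[tt, 2]

        def logf_young(idx):
            if idx < 2:
                succ, fail = stats[idx]

                def f(x):
                    trial = py.copy()
                    trial[idx] = x
                    return (
                        self._litter_ll(state["lam"], trial, state["p_w"])
                        + succ * math.log(x)
                        + fail * math.log1p(-x)
                    )
            else:

                def f(x):
                    trial = py.copy()
                    trial[2] = x
                    pa = x * (1 - gamD)
                    pb = x * gamD
                    proc = float(
                        np.sum(kAD * np.log(pa) + (nD - kAD) * np.log1p(-pa))
                        + np.sum(kBS * np.log(pb) + (nD - kBS) * np.log1p(-pb))
                    )
                    return self._litter_ll(state["lam"], trial, state["p_w"]) + proc

            return f

        for idx in range(3):
            py[idx] = slice_sample(
                float(py[idx]), logf_young(idx), rng, w=0.1, lower=1e-9,
                upper=1 - 1e-9,
            )

        # subadult survival: CMR + count transitions
        for s in range(2):
            kAS, kBA = lat[K.AS, 1:, s], lat[K.BA, 1:, s]
            nS = naf[tt, 3, s]
            gS = gamS[:, s]

            def logf_S(x, s=s, kAS=kAS, kBA=kBA, nS=nS, gS=gS):
                phi_S = state["phi_S"].copy()
                phi_S[s] = x
                pa = x * (1 - gS)
                pb = x * gS
                proc = float(
                    np.sum(kAS * np.log(pa) + (nS - kAS) * np.log1p(-pa))
                    + np.sum(kBA * np.log(pb) + (nS - kBA) * np.log1p(-pb))
                )
                return self._cmr_ll(state, phi_S=phi_S) + proc

            state["phi_S"][s] = slice_sample(
                float(state["phi_S"][s]), logf_S, rng, w=0.1, lower=1e-9,
                upper=1 - 1e-9,
            )

        # adult survival: CMR + count transitions (+ cub recruitment, females)
        for s in range(2):
            succ = float(lat[K.AA, 1:, s].sum())
            fail = float((naf[tt, 4, s] - lat[K.AA, 1:, s]).sum())
            if s == 1:
                c1 = float(
                    np.sum(naf[tt, 4, 1] * state["rho"] * L_vec[tt])
                )
            else:
                c1 = 0.0
            pois_k = tot_cubs if s == 1 else 0.0

            def logf_A(x, s=s, succ=succ, fail=fail, c1=c1, pois_k=pois_k):
                phi_A = state["phi_A"].copy()
                phi_A[s] = x
                ll = self._cmr_ll(state, phi_A=phi_A)
                ll += succ * math.log(x) + fail * math.log1p(-x)
                if s == 1:
                    if c1 <= 0.0 and pois_k > 0:
                        return -np.inf
                    ll += pois_k * math.log(x) - x * c1
                return ll

            state["phi_A"][s] = slice_sample(
                float(state["phi_A"][s]), logf_A, rng, w=0.08, lower=1e-9,
                upper=1 - 1e-9,
            )

        # reproduction probability: CMR reproduction records + cub recruitment
        c2 = float(np.sum(naf[tt, 4, 1] * state["phi_A"][1] * L_vec[tt]))

        def logf_rho(x):
            ll = self._cmr_ll(state, rho=x)
            if c2 <= 0.0 and tot_cubs > 0:
                return -np.inf
            return ll + tot_cubs * math.log(x) - x * c2

        state["rho"] = slice_sample(
            float(state["rho"]), logf_rho, rng, w=0.1, lower=1e-9, upper=1 - 1e-9
        )

        # litter initiation rate: litter data plus cub recruitment, which
        # runs on the population mean litter size zt-mean(lambda)
        c3 = float(np.sum(naf[tt, 4, 1] * state["phi_A"][1] * state["rho"]))

        def logf_lam(x):
            ll = self._litter_ll(x, py, state["p_w"])
            if tot_cubs > 0 and c3 <= 0.0:
                return -np.inf
            L = x / -math.expm1(-x)
            return ll + tot_cubs * math.log(L) - L * c3

        state["lam"] = slice_sample(
            float(state["lam"]), logf_lam, rng, w=0.3, lower=1e-6, upper=30.0
        )

    def _slice_observation(self, state, rng, naf):
        succ, trials = self._count_p_stats(state["lat"])

        def logf_p(x):
            ll = succ * math.log(x) + (trials - succ) * math.log1p(-x)
            if self.config.share_detection:
                ll += self._cmr_ll(state, p=x)
            return ll

        state["p"] = slice_sample(
            float(state["p"]), logf_p, rng, w=0.05, lower=1e-9, upper=1 - 1e-9
        )
        if not self.config.share_detection:
            state["p_cmr"] = slice_sample(
                float(state["p_cmr"]),
                lambda x: self._cmr_ll(state, p=x),
                rng, w=0.05, lower=1e-9, upper=1 - 1e-9,
            )
        state["p_prime"] = slice_sample(
            float(state["p_prime"]),
            lambda x: self._cmr_ll(state, p_prime=x),
            rng, w=0.08, lower=1e-9, upper=1 - 1e-9,
        )
        state["p_r"] = slice_sample(
            float(state["p_r"]),
            lambda x: self._cmr_ll(state, p_r=x),
            rng, w=0.08, lower=1e-9, upper=1 - 1e-9,
        )


class SimpleBinomialModel:
    """Minimal model -- Binomial(n, p) with known n and a Uniform(0,1) prior.

    Used to validate the sampling machinery against the closed-form
    Beta(1 + k, 1 + n - k) posterior; with n = 0 it reduces to prior-only
    sampling.
    """

    variant = "simple_binomial"

    def __init__(self, n_trials: int, successes: int):
        if not 0 <= successes <= n_trials:
            raise ValueError("successes must lie in [0, n_trials]")
        self.n = int(n_trials)
        self.k = int(successes)

    def param_names(self) -> list[str]:
        return ["p"]

    def extract(self, state: dict) -> np.ndarray:
        return np.array([state["p"]])

    def latent_n(self, state: dict):
        return None

    def initial_state(self, rng: np.random.Generator, inflate: float = 1.0):
        return {"p": 0.5}

    def log_joint(self, state: dict) -> float:
        p = state["p"]
        if not 0.0 < p < 1.0:
            return -np.inf
        return self.k * math.log(p) + (self.n - self.k) * math.log1p(-p)

    def sweep(self, state: dict, rng: np.random.Generator, iteration: int):
        state["p"] = slice_sample(
            state["p"],
            lambda x: self.k * math.log(x) + (self.n - self.k) * math.log1p(-x),
            rng, w=0.2, lower=1e-12, upper=1 - 1e-12,
        )


def build_model(data: ModelData, config: ModelConfig):
    """Assemble the joint model for the configured variant.

    Raises a configuration error listing the missing tables when the data
    bundle does not match the variant's requirements.
    """
    if config.variant == "counts_only":
        return CountsOnlyModel(data, config)
    if config.variant == "full_ipm":
        return FullIPMModel(data, config)
    from .kodiak import assemble_kodiak_model  # deferred: optional layer

    if data.cmr is None or data.litters is None or data.covariates is None:
        missing = [
            nm
            for nm, v in (
                ("cmr", data.cmr),
                ("litters", data.litters),
                ("covariates (salmon)", data.covariates),
            )
            if not v
        ]
        raise ValueError(
            f"variant 'kodiak_reduced' requires tables: {', '.join(missing)}"
        )
    return assemble_kodiak_model(data.cmr, data.litters, data.covariates, config)


def run_mcmc(model, config: ModelConfig) -> PosteriorSamples:
    """Metropolis-within-Gibbs sampling of the model's posterior.

    Runs ``config.mcmc.n_chains`` independent chains (seeded reproducibly
    from ``config.mcmc.seed``), discards the burn-in, thins, and returns the
    labeled draws.  Chains that cannot find a finite-density initial state
    are re-initialized with progressively inflated latent abundances a
    bounded number of times before failing loudly.
    """
    mc = config.mcmc
    names = model.param_names()
    n_draws = mc.n_iter // mc.thin
    all_draws = np.empty((mc.n_chains, n_draws, len(names)))
    latent_store = None
    for chain in range(mc.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([mc.seed, chain]))
        state = None
        for attempt in range(8):
            cand = model.initial_state(rng, inflate=1.0 + 0.5 * attempt)
            if np.isfinite(model.log_joint(cand)):
                state = cand
                break
            logger.warning(
                "chain %d: non-finite initial density (attempt %d); "
                "re-initializing", chain, attempt + 1,
            )
        if state is None:
            raise RuntimeError(
                f"chain {chain}: could not find a finite-density initial state"
            )
        stored = 0
        for it in range(mc.n_burnin + mc.n_iter):
            model.sweep(state, rng, it)
            k = it - mc.n_burnin
            if k >= 0 and (k + 1) % mc.thin == 0 and stored < n_draws:
                all_draws[chain, stored] = model.extract(state)
                ln = model.latent_n(state)
                if ln is not None:
                    if latent_store is None:
                        latent_store = np.empty(
                            (mc.n_chains, n_draws) + ln.shape, dtype=np.int32
                        )
                    latent_store[chain, stored] = ln
                stored += 1
    return PosteriorSamples(names=names, draws=all_draws, latent_n=latent_store)
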