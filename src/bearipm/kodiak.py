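"""Reduced case-study pipeline: mark-recapture + litter data, no counts.

This variant mirrors the situation of long-term monitoring programmes where
yearly repeated counts are unavailable: individual detection histories with
dead recovery and reproduction status, plus litter follow-ups, are modeled
jointly with a shared covariate structure --

* adult/subadult survival ~ age + age^2 + sex + salmon biomass + subadult
  flag + yearly random effect;
* reproduction probability ~ age + salmon + age at first reproduction +
  dependent-young-present flag + yearly random effect;
* initial litter size (log link) ~ mother's age + age at first reproduction
  + salmon + yearly random effect;
* young survival ~ litter age + litter age^2 + litter size + mother's age +
  salmon + yearly random effect;
* weaning probability ~ litter age + yearly random effect.

Continuous covariates are z-scored before entering the linear predictors
(this stabilizes the sampler and makes slopes comparable); coefficients get
Normal(0, 10) priors, random-effect scales half-Normal(1), observation
probabilities Uniform(0, 1).  Sex of dependent young is not modeled.

The deposited case-study tables are expected as tidy CSV (schemas below);
the packaged fixtures and the test suite use synthetic stand-ins produced by
:func:`generate_synthetic_kodiak`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _kernels as K
from ._slice import slice_sample
from .core_model import Sex
from .likelihoods import CMRHistory, LitterRecord

__all__ = [
    "CovariateSet",
    "read_cmr_table",
    "read_litter_table",
    "assemble_kodiak_model",
    "KodiakModel",
    "generate_synthetic_kodiak",
]

logger = logging.getLogger(__name__)

_SEX_CODES = {"m": Sex.MALE, "f": Sex.FEMALE}


@dataclass
class CovariateSet:
    """Per-year environmental covariates for the case-study model.

    ``salmon`` is annual salmon biomass indexed from ``year0``; it is
    z-scored at assembly if not already standardized.
    """

    salmon: np.ndarray
    year0: int = 0

    def __post_init__(self) -> None:
        self.salmon = np.asarray(self.salmon, dtype=float)
        if self.salmon.ndim != 1 or self.salmon.size == 0:
            raise ValueError("salmon must be a nonempty 1-d array")

    def standardized(self) -> "CovariateSet":
        s = self.salmon
        sd = s.std()
        if sd == 0:
            raise ValueError("salmon biomass has zero variance")
        if abs(s.mean()) < 1e-8 and abs(sd - 1.0) < 1e-6:
            return self
        return CovariateSet(salmon=(s - s.mean()) / sd, year0=self.year0)


def read_cmr_table(path) -> list[CMRHistory]:
    """Read a tidy CMR table into validated histories.

    Expected columns: id, year, sex (m/f), age, detected (0/1),
    recovered_dead (0/1), repro_status (0/1 or blank), dependent_young_age
    (integer or blank).  Rows per individual must be consecutive years;
    nothing may follow a dead recovery.  Errors carry CSV line numbers
    (header = line 1).
    """
    df = pd.read_csv(path)
    required = {
        "id", "year", "sex", "age", "detected", "recovered_dead", "repro_status",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CMR table missing columns: {sorted(missing)}")
    df["_line"] = np.arange(2, len(df) + 2)
    histories: list[CMRHistory] = []
    n_detections = 0
    for ind, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("year")
        years = grp.year.to_numpy()
        lines = grp._line.to_numpy()
        if np.any(np.diff(years) != 1):
            bad = lines[1:][np.diff(years) != 1][0]
            raise ValueError(
                f"line {bad}: individual {ind!r} has non-consecutive years"
            )
        sexes = set(grp.sex)
        if len(sexes) != 1 or not sexes <= set(_SEX_CODES):
            raise ValueError(
                f"line {lines[0]}: individual {ind!r} has unknown or "
                f"inconsistent sex codes {sorted(sexes)}"
            )
        sex = _SEX_CODES[grp.sex.iloc[0]]
        rec = grp.recovered_dead.to_numpy().astype(int)
        if rec.sum() > 1 or (rec.sum() == 1 and rec[-1] != 1):
            after = lines[np.flatnonzero(rec == 1)[0] + 1]
            raise ValueError(
                f"line {after}: individual {ind!r} has records after dead "
                "recovery"
            )
        y = grp.detected.to_numpy().astype(int)
        if rec.sum() == 1:
            y[-1] = 1  # a recovery is an observation event
        n_detections += int(y.sum())
        repro = None
        if sex is Sex.FEMALE:
            raw = grp.repro_status.to_numpy()
            repro = np.array(
                [0 if (pd.isna(v) or v == "") else int(float(v)) for v in raw],
                dtype=np.int8,
            )
        dep_raw = (
            grp.dependent_young_age.to_numpy()
            if "dependent_young_age" in grp
            else np.full(len(grp), np.nan)
        )
        dep = np.array(
            [0.0 if (pd.isna(v) or v == "") else 1.0 for v in dep_raw]
        )
        ages = grp.age.to_numpy().astype(float)
        histories.append(
            CMRHistory(
                individual_id=str(ind),
                entry_year=int(years[0]),
                y=y,
                r=rec,
                sex=sex,
                age_at_entry=int(ages[0]),
                repro=repro,
                covariates={
                    "age": ages,
                    "dep_young": dep,
                    "is_adult": (ages >= 5).astype(float),
                },
            )
        )
    logger.info(
        "read %d individuals, %d detections from CMR table",
        len(histories), n_detections,
    )
    return histories


def read_litter_table(path) -> list[LitterRecord]:
    """Read a tidy litter table into validated records.

    Expected columns: litter_id, mother_id, year, litter_age, size, weaned
    (0/1).  Sizes must not increase with age; ages must be consecutive from
    the first observation.
    """
    df = pd.read_csv(path)
    required = {"litter_id", "mother_id", "year", "litter_age", "size", "weaned"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"litter table missing columns: {sorted(missing)}")
    df["_line"] = np.arange(2, len(df) + 2)
    records: list[LitterRecord] = []
    litter_years = 0
    for lid, grp in df.groupby("litter_id", sort=False):
        grp = grp.sort_values("litter_age")
        ages = grp.litter_age.to_numpy().astype(int)
        lines = grp._line.to_numpy()
        if np.any(np.diff(ages) != 1):
            raise ValueError(
                f"line {lines[0]}: litter {lid!r} has non-consecutive ages"
            )
        sizes = grp["size"].to_numpy().astype(int)
        if np.any(np.diff(sizes) > 0):
            bad = lines[1:][np.diff(sizes) > 0][0]
            raise ValueError(
                f"line {bad}: litter {lid!r} size increases with age"
            )
        weaned = grp.weaned.to_numpy().astype(int)
        weaned_at = int(ages[-1]) if weaned[-1] == 1 else None
        litter_years += len(grp)
        records.append(
            LitterRecord(
                litter_id=str(lid),
                mother_id=str(grp.mother_id.iloc[0]),
                birth_year=int(grp.year.iloc[0]) - int(ages[0]),
                sizes=sizes,
                weaned_at=weaned_at,
            )
        )
    logger.info(
        "read %d litters, %d litter-years from litter table",
        len(records), litter_years,
    )
    return records


# ---------------------------------------------------------------------------


class _Standardizer:
    def __init__(self, values):
        v = np.asarray(values, dtype=float)
        self.mean = float(v.mean()) if v.size else 0.0
        self.sd = float(v.std()) if v.size else 1.0
        if self.sd == 0:
            self.sd = 1.0

    def __call__(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd


class KodiakModel:
    """Joint CMR + litter model with the case-study covariate structure."""

    variant = "kodiak_reduced"

    SURV_TERMS = ("intercept", "age", "age2", "female", "salmon", "subadult")
    REPRO_TERMS = ("intercept", "age", "salmon", "age_first_repro", "dep_young")
    LSIZE_TERMS = ("intercept", "mother_age", "age_first_repro", "salmon")
    YOUNG_TERMS = (
        "intercept", "litter_age", "litter_age2", "litter_size", "mother_age",
        "salmon",
    )
    WEAN_TERMS = ("intercept", "litter_age")

    def __init__(self, histories, litters, covariates, config=None):
        from .inference import ModelConfig

        self.config = config or ModelConfig(variant="kodiak_reduced")
        if isinstance(covariates, dict):
            covariates = CovariateSet(**covariates)
        cov = covariates.standardized()
        years = [h.entry_year + j for h in histories for j in range(h.n_occasions)]
        years += [r.birth_year + a for r in litters for a in range(r.sizes.size)]
        self.year0 = min(min(years), cov.year0)
        self.n_years = max(years) - self.year0 + 1
        salmon_full = np.zeros(self.n_years)
        off = cov.year0 - self.year0
        end = min(off + cov.salmon.size, self.n_years)
        salmon_full[off:end] = cov.salmon[: end - off]
        self.salmon = salmon_full

        self._encode_cmr(histories)
        self._encode_litters(litters, histories)

    # -- encodings ---------------------------------------------------------

    def _encode_cmr(self, histories):
        n = len(histories)
        lmax = max(h.n_occasions for h in histories)
        self.y = np.zeros((n, lmax), dtype=np.int8)
        self.r = np.zeros((n, lmax), dtype=np.int8)
        self.repro = np.full((n, lmax), -1, dtype=np.int8)
        self.length = np.zeros(n, dtype=np.int64)
        valid = np.zeros((n, lmax), dtype=bool)
        ages = np.zeros((n, lmax))
        female = np.zeros(n)
        dep = np.zeros((n, lmax))
        yeari = np.zeros((n, lmax), dtype=np.int64)
        afr = np.full(n, np.nan)
        for i, h in enumerate(histories):
            L = h.n_occasions
            self.length[i] = L
            self.y[i, :L] = h.y
            self.r[i, :L] = h.r
            valid[i, :L] = True
            female[i] = 1.0 if h.sex is Sex.FEMALE else 0.0
            a = h.covariates.get("age")
            ages[i, :L] = (
                np.asarray(a)[:L] if a is not None
                else h.age_at_entry + np.arange(L)
            )
            d = h.covariates.get("dep_young")
            if d is not None:
                dep[i, :L] = np.asarray(d)[:L]
            yeari[i, :L] = h.entry_year - self.year0 + np.arange(L)
            if h.repro is not None:
                self.repro[i, :L] = h.repro
                first = np.flatnonzero(h.repro == 1)
                if first.size:
                    afr[i] = ages[i, first[0]]
        afr_obs = afr[~np.isnan(afr)]
        afr_fill = float(np.median(afr_obs)) if afr_obs.size else 6.0
        afr = np.where(np.isnan(afr), afr_fill, afr)

        self._age_std = _Standardizer(ages[valid])
        self._afr_std = _Standardizer(afr)
        age_z = np.where(valid, self._age_std(ages), 0.0)
        sal = self.salmon[np.clip(yeari, 0, self.n_years - 1)]
        subadult = ((ages >= 3) & (ages < 5)).astype(float)
        # survival design applies to the interval ending at occasion j: use
        # the state at the interval's start (j-1)
        def lag(mat):
            out = np.zeros_like(mat)
            out[:, 1:] = mat[:, :-1]
            return out

        self.X_surv = np.stack(
            [
                np.ones_like(age_z), lag(age_z), lag(age_z) ** 2,
                np.broadcast_to(female[:, None], age_z.shape).copy(),
                lag(sal), lag(subadult),
            ],
            axis=-1,
        )
        self.surv_year = lag(yeari.astype(float)).astype(np.int64)
        self.X_rho = np.stack(
            [
                np.ones_like(age_z), age_z,
                sal,
                np.broadcast_to(self._afr_std(afr)[:, None], age_z.shape).copy(),
                dep,
            ],
            axis=-1,
        )
        self.rho_year = yeari
        self.weight = np.ones(len(histories), dtype=np.float64)
        self.sex_idx = (female > 0.5).astype(np.int64)
        # mother lookup for litter covariates
        self._mother_info = {
            h.individual_id: (h.entry_year, h.age_at_entry)
            for h in histories
        }

    def _encode_litters(self, litters, histories):
        init_rows = []  # (l0, year_idx, mage, afr)
        att_rows = []  # (prev, next, litter_age, l0, mage, year_idx)
        wean_rows = []  # (outcome, litter_age, year_idx)
        mage_fill = []
        for rec in litters:
            info = self._mother_info.get(rec.mother_id)
            if info is not None:
                entry_year, age_at_entry = info
                mage = age_at_entry + (rec.birth_year - entry_year)
                mage_fill.append(mage)
        fill = float(np.median(mage_fill)) if mage_fill else 10.0
        for rec in litters:
            info = self._mother_info.get(rec.mother_id)
            if info is not None:
                mage = info[1] + (rec.birth_year - info[0])
            else:
                mage = fill
            yi = rec.birth_year - self.year0
            init_rows.append((int(rec.sizes[0]), yi, mage, np.nan))
            for a in range(1, rec.sizes.size):
                att_rows.append(
                    (
                        int(rec.sizes[a - 1]), int(rec.sizes[a]), a - 1,
                        int(rec.sizes[0]), mage, yi + a,
                    )
                )
            for age in range(2, rec.max_age + 1):
                if rec.sizes[age] == 0 or age >= 4:
                    continue
                wean_rows.append(
                    (1 if rec.weaned_at == age else 0, age, yi + age)
                )
        l0 = np.array([r[0] for r in init_rows], dtype=float)
        self.lit_l0 = l0
        self.lit_year = np.array([r[1] for r in init_rows], dtype=np.int64)
        mages = np.array([r[2] for r in init_rows])
        self._mage_std = _Standardizer(mages)
        afr_z = np.zeros(len(init_rows))  # age at first repro of the mother
        self.X_lsize = np.stack(
            [
                np.ones(len(init_rows)), self._mage_std(mages), afr_z,
                self.salmon[np.clip(self.lit_year, 0, self.n_years - 1)],
            ],
            axis=-1,
        )
        if att_rows:
            prev = np.array([r[0] for r in att_rows], dtype=float)
            nxt = np.array([r[1] for r in att_rows], dtype=float)
            lage = np.array([r[2] for r in att_rows], dtype=float)
            al0 = np.array([r[3] for r in att_rows], dtype=float)
            amage = np.array([r[4] for r in att_rows])
            self.att_year = np.clip(
                np.array([r[5] for r in att_rows], dtype=np.int64),
                0, self.n_years - 1,
            )
            self._lage_std = _Standardizer(lage)
            self._l0_std = _Standardizer(al0)
            lage_z = self._lage_std(lage)
            self.X_young = np.stack(
                [
                    np.ones_like(prev), lage_z, lage_z**2, self._l0_std(al0),
                    self._mage_std(amage), self.salmon[self.att_year],
                ],
                axis=-1,
            )
            self.att_prev = prev
            self.att_next = nxt
            from scipy.special import gammaln

            self.att_const = float(
                np.sum(
                    gammaln(prev + 1) - gammaln(nxt + 1) - gammaln(prev - nxt + 1)
                )
            )
        else:
            self.att_prev = np.zeros(0)
            self.att_next = np.zeros(0)
            self.X_young = np.zeros((0, len(self.YOUNG_TERMS)))
            self.att_year = np.zeros(0, dtype=np.int64)
            self.att_const = 0.0
            self._lage_std = _Standardizer([0.0, 1.0])
            self._l0_std = _Standardizer([1.0, 2.0])
        if wean_rows:
            self.wean_out = np.array([r[0] for r in wean_rows], dtype=float)
            wage = np.array([r[1] for r in wean_rows], dtype=float)
            self.wean_age_z = wage - 2.5  # centered within the 2-3 window
            self.wean_year = np.clip(
                np.array([r[2] for r in wean_rows], dtype=np.int64),
                0, self.n_years - 1,
            )
        else:
            self.wean_out = np.zeros(0)
            self.wean_age_z = np.zeros(0)
            self.wean_year = np.zeros(0, dtype=np.int64)
        from scipy.special import gammaln

        self.lsize_const = -float(np.sum(gammaln(l0 + 1)))

    # -- likelihoods -------------------------------------------------------

    def _phi_mat(self, state, eta_base=None):
        eta = (
            self.X_surv @ state["beta_z"] if eta_base is None else eta_base
        ) + state["eps_z"][self.surv_year]
        return expit(eta)

    def _rho_mat(self, state, eta_base=None):
        eta = (
            self.X_rho @ state["beta_r"] if eta_base is None else eta_base
        ) + state["eps_r"][self.rho_year]
        return expit(eta)

    def _cmr_ll_mats(self, state, phi, rho) -> float:
        return float(
            K.cmr_batch_loglik(
                self.y, self.r, self.repro, self.length, phi, rho,
                float(state["p"]), float(state["p_prime"]), float(state["p_r"]),
            )
        )

    def _cmr_ll(self, state) -> float:
        return self._cmr_ll_mats(state, self._phi_mat(state), self._rho_mat(state))

    def _lsize_ll(self, state) -> float:
        lam = np.exp(
            np.clip(
                self.X_lsize @ state["beta_L"] + state["eps_L"][self.lit_year],
                -20, 10,
            )
        )
        ll = np.sum(
            self.lit_l0 * np.log(lam) - lam - np.log(-np.expm1(-lam))
        )
        return float(ll) + self.lsize_const

    def _young_ll(self, state) -> float:
        if self.att_prev.size == 0:
            return 0.0
        phi = expit(self.X_young @ state["beta_y"] + state["eps_y"][self.att_year])
        phi = np.clip(phi, 1e-12, 1 - 1e-12)
        ll = np.sum(
            self.att_next * np.log(phi)
            + (self.att_prev - self.att_next) * np.log1p(-phi)
        )
        return float(ll) + self.att_const

    def _wean_ll(self, state) -> float:
        if self.wean_out.size == 0:
            return 0.0
        eta = (
            state["beta_w"][0]
            + state["beta_w"][1] * self.wean_age_z
            + state["eps_w"][self.wean_year]
        )
        pw = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        return float(
            np.sum(self.wean_out * np.log(pw) + (1 - self.wean_out) * np.log1p(-pw))
        )

    _BLOCKS = (
        ("beta_z", "eps_z", "sigma_z", "_cmr_ll"),
        ("beta_r", "eps_r", "sigma_r", "_cmr_ll"),
        ("beta_L", "eps_L", "sigma_L", "_lsize_ll"),
        ("beta_y", "eps_y", "sigma_y", "_young_ll"),
        ("beta_w", "eps_w", "sigma_w", "_wean_ll"),
    )

    def _priors(self, state) -> float:
        lp = 0.0
        for bkey, ekey, skey, _ in self._BLOCKS:
            beta = state[bkey]
            lp += float(np.sum(-0.5 * (beta / 10.0) ** 2))
            sig = state[skey]
            if sig <= 0:
                return -np.inf
            lp += -0.5 * sig**2  # half-Normal(1)
            eps = state[ekey]
            lp += float(
                np.sum(-0.5 * (eps / sig) ** 2) - eps.size * math.log(sig)
            )
        for pkey in ("p", "p_prime", "p_r"):
            if not 0.0 < state[pkey] < 1.0:
                return -np.inf
        return lp

    def log_joint(self, state) -> float:
        lp = self._priors(state)
        if not np.isfinite(lp):
            return lp
        return (
            lp
            + self._cmr_ll(state)
            + self._lsize_ll(state)
            + self._young_ll(state)
            + self._wean_ll(state)
        )

    # -- sampler interface ---------------------------------------------------

    def param_names(self) -> list[str]:
        names = []
        for terms, bkey in (
            (self.SURV_TERMS, "surv"), (self.REPRO_TERMS, "repro"),
            (self.LSIZE_TERMS, "lsize"), (self.YOUNG_TERMS, "young"),
            (self.WEAN_TERMS, "wean"),
        ):
            names += [f"{bkey}:{t}" for t in terms]
        names += ["sigma_z", "sigma_r", "sigma_L", "sigma_y", "sigma_w"]
        names += ["p", "p_prime", "p_r"]
        return names

    def extract(self, state) -> np.ndarray:
        return np.concatenate(
            [
                state["beta_z"], state["beta_r"], state["beta_L"],
                state["beta_y"], state["beta_w"],
                [state["sigma_z"], state["sigma_r"], state["sigma_L"],
                 state["sigma_y"], state["sigma_w"]],
                [state["p"], state["p_prime"], state["p_r"]],
            ]
        )

    def latent_n(self, state):
        return None

    def initial_state(self, rng, inflate: float = 1.0) -> dict:
        T = self.n_years
        st = {
            "beta_z": np.array([1.5, 0, 0, 0.5, 0, 0], dtype=float),
            "beta_r": np.array([-0.5, 0, 0, 0, 0], dtype=float),
            "beta_L": np.array([0.5, 0, 0, 0], dtype=float),
            "beta_y": np.array([1.5, 0, 0, 0, 0, 0], dtype=float),
            "beta_w": np.array([0.0, 0.0], dtype=float),
            "p": 0.6, "p_prime": 0.7, "p_r": 0.7,
        }
        for k in ("z", "r", "L", "y", "w"):
            st[f"eps_{k}"] = np.zeros(T)
            st[f"sigma_{k}"] = 0.3
        return st

    def _sweep_linear_block(
        self, state, rng, bkey, ekey, skey, X, yearidx, ll_of_eta
    ):
        """Slice-update one linear predictor block (coefficients, yearly
        random effects, scale), maintaining the running eta to avoid
        re-multiplying the design matrix per evaluation."""
        beta = state[bkey]
        eps = state[ekey]
        eta = X @ beta

        for j in range(beta.size):
            xcol = X[..., j]

            def logf(x, j=j):
                return (
                    ll_of_eta(eta + (x - beta[j]) * xcol + eps[yearidx])
                    - 0.5 * (x / 10.0) ** 2
                )

            new = slice_sample(
                float(beta[j]), logf, rng, w=0.4, lower=-300.0, upper=300.0
            )
            eta += (new - beta[j]) * xcol
            beta[j] = new

        sig = state[skey]
        used_years = np.unique(yearidx)
        for t in range(eps.size):
            if t not in used_years:
                eps[t] = sig * rng.standard_normal()  # prior-only year
                continue

            def logf_e(x, t=t):
                trial = eps.copy()
                trial[t] = x
                return ll_of_eta(eta + trial[yearidx]) - 0.5 * (x / sig) ** 2

            eps[t] = slice_sample(
                float(eps[t]), logf_e, rng, w=0.3, lower=-20.0, upper=20.0
            )

        def logf_s(x):
            return (
                -0.5 * x**2
                - eps.size * math.log(x)
                - 0.5 * float(np.sum((eps / x) ** 2))
            )

        state[skey] = slice_sample(
            float(sig), logf_s, rng, w=0.2, lower=1e-3, upper=10.0
        )

    def sweep(self, state, rng, iteration):
        # survival: reproduction side of the CMR likelihood is unchanged
        rho = self._rho_mat(state)
        self._sweep_linear_block(
            state, rng, "beta_z", "eps_z", "sigma_z", self.X_surv,
            self.surv_year,
            lambda eta: self._cmr_ll_mats(state, expit(eta), rho),
        )
        phi = self._phi_mat(state)
        self._sweep_linear_block(
            state, rng, "beta_r", "eps_r", "sigma_r", self.X_rho,
            self.rho_year,
            lambda eta: self._cmr_ll_mats(state, phi, expit(eta)),
        )

        def lsize_ll_eta(eta):
            lam = np.exp(np.clip(eta, -20, 10))
            return float(
                np.sum(self.lit_l0 * np.log(lam) - lam - np.log(-np.expm1(-lam)))
            )

        self._sweep_linear_block(
            state, rng, "beta_L", "eps_L", "sigma_L", self.X_lsize,
            self.lit_year, lsize_ll_eta,
        )

        def young_ll_eta(eta):
            ph = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            return float(
                np.sum(
                    self.att_next * np.log(ph)
                    + (self.att_prev - self.att_next) * np.log1p(-ph)
                )
            )

        if self.att_prev.size:
            self._sweep_linear_block(
                state, rng, "beta_y", "eps_y", "sigma_y", self.X_young,
                self.att_year, young_ll_eta,
            )

        def wean_ll_eta(eta):
            pw = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            return float(
                np.sum(
                    self.wean_out * np.log(pw)
                    + (1 - self.wean_out) * np.log1p(-pw)
                )
            )

        if self.wean_out.size:
            X_w = np.stack([np.ones_like(self.wean_age_z), self.wean_age_z], -1)
            self._sweep_linear_block(
                state, rng, "beta_w", "eps_w", "sigma_w", X_w, self.wean_year,
                wean_ll_eta,
            )

        phi = self._phi_mat(state)
        rho = self._rho_mat(state)
        for pkey in ("p", "p_prime", "p_r"):
            def logf_p(x, pkey=pkey):
                old = state[pkey]
                state[pkey] = x
                v = self._cmr_ll_mats(state, phi, rho)
                state[pkey] = old
                return v

            state[pkey] = slice_sample(
                float(state[pkey]), logf_p, rng, w=0.08, lower=1e-9,
                upper=1 - 1e-9,
            )

    # -- derived quantities --------------------------------------------------

    def derived_young_survival(self, samples) -> dict[str, tuple[float, float, float]]:
        """Posterior summaries of young survival for cubs, yearlings and
        dependents >= 2, at mean covariates and zero random effect."""
        from .inference import summarize

        idx = {n: i for i, n in enumerate(samples.names)}
        beta = samples.draws[:, :, [idx[f"young:{t}"] for t in self.YOUNG_TERMS]]
        out = {}
        for label, age in (("cub", 0.0), ("yearling", 1.0), ("dependent", 2.5)):
            z = float(self._lage_std(age))
            eta = beta[..., 0] + beta[..., 1] * z + beta[..., 2] * z**2
            out[label] = summarize(expit(eta).reshape(1, -1, order="C"))
        return out

    def derived_annual_litter_size(self, samples) -> pd.DataFrame:
        """Posterior mean and CrI of expected initial litter size per year.

        Computed at mean mother covariates with that year's salmon value and
        litter-size year effect; reported on the zero-truncated scale."""
        from .inference import summarize

        idx = {n: i for i, n in enumerate(samples.names)}
        b0 = samples.draws[:, :, idx["lsize:intercept"]]
        bsal = samples.draws[:, :, idx["lsize:salmon"]]
        rows = []
        for t in range(self.n_years):
            lam = np.exp(np.clip(b0 + bsal * self.salmon[t], -20, 10))
            lt = lam / -np.expm1(-lam)
            mean, lo, hi = summarize(lt.reshape(1, -1))
            rows.append(
                dict(year=self.year0 + t, litter_size=mean, lower=lo, upper=hi)
            )
        return pd.DataFrame(rows)


def assemble_kodiak_model(histories, litters, covariates, config=None) -> KodiakModel:
    """Build the reduced case-study model from validated inputs.

    Raises a configuration error when the salmon covariate is missing, since
    food availability enters four of the five linear predictors.
    """
    if covariates is None or (
        isinstance(covariates, dict) and "salmon" not in covariates
    ):
        raise ValueError(
            "kodiak_reduced requires the salmon biomass covariate "
            "(covariates['salmon'])"
        )
    if not histories:
        raise ValueError("kodiak_reduced requires CMR histories")
    if not litters:
        raise ValueError("kodiak_reduced requires litter records")
    return KodiakModel(histories, litters, covariates, config)


# ---------------------------------------------------------------------------


def generate_synthetic_kodiak(
    n_individuals: int = 120,
    n_years: int = 16,
    seed: int = 0,
    surv_coefs: dict[str, float] | None = None,
    repro_coefs: dict[str, float] | None = None,
    lsize_coefs: dict[str, float] | None = None,
    young_coefs: dict[str, float] | None = None,
    p: float = 0.85,
    p_prime: float = 0.7,
    p_r: float = 0.8,
):
    """Synthetic stand-in for the deposited case-study tables.

    Generates radio-collared-style histories (female-biased, staggered
    entry), reproduction records, dependent-young flags and litter
    follow-ups from known logit-linear effect structures, so that parameter
    recovery can be tested end to end.  Returns (histories, litters,
    covariates) in the exact form :func:`assemble_kodiak_model` consumes.
    Coefficient dicts are on the z-scored covariate scale used by the model.
    """
    rng = np.random.default_rng(seed)
    sc = dict(intercept=2.2, age=0.5, age2=-0.4, female=1.5, salmon=0.6,
              subadult=0.2)
    if surv_coefs:
        sc.update(surv_coefs)
    rc = dict(intercept=-0.4, age=-0.3, salmon=0.0, age_first_repro=-0.2,
              dep_young=-8.0)
    if repro_coefs:
        rc.update(repro_coefs)
    lc = dict(intercept=0.6, mother_age=0.15, age_first_repro=-0.1, salmon=0.2)
    if lsize_coefs:
        lc.update(lsize_coefs)
    yc = dict(intercept=2.0, litter_age=0.8, litter_age2=0.0, litter_size=-0.5,
              mother_age=0.2, salmon=0.4)
    if young_coefs:
        yc.update(young_coefs)

    salmon = rng.normal(0.0, 1.0, n_years)
    salmon = (salmon - salmon.mean()) / salmon.std()
    age_mu, age_sd = 9.0, 4.0  # approximate standardizer of collared ages
    lage_mu, lage_sd = 1.0, 1.0
    l0_mu, l0_sd = 2.0, 0.8

    histories: list[CMRHistory] = []
    litters: list[LitterRecord] = []
    lit_counter = 0
    for i in range(n_individuals):
        female = rng.random() < 0.75
        sex = Sex.FEMALE if female else Sex.MALE
        entry = int(rng.integers(0, n_years - 2))
        age0 = int(rng.integers(3, 18))
        afr = int(rng.integers(5, 9))
        afr_z = (afr - 6.5) / 1.0
        L = n_years - entry
        y = np.zeros(L, dtype=np.int8)
        r = np.zeros(L, dtype=np.int8)
        repro = np.zeros(L, dtype=np.int8) if female else None
        ages = age0 + np.arange(L, dtype=float)
        dep = np.zeros(L)
        alive = True
        end = L
        active_litter = None  # (sizes list, birth offset)
        y[0] = 1
        for j in range(L):
            year = entry + j
            age = ages[j]
            if j > 0:
                az = (ages[j - 1] - age_mu) / age_sd
                eta = (
                    sc["intercept"] + sc["age"] * az + sc["age2"] * az**2
                    + sc["female"] * female + sc["salmon"] * salmon[year - 1]
                    + sc["subadult"] * (3 <= ages[j - 1] < 5)
                )
                if alive and rng.random() >= expit(eta):
                    alive = False
                    if rng.random() < p_prime:
                        y[j] = 1
                        r[j] = 1
                        end = j + 1
                        break
                if alive:
                    y[j] = 1 if rng.random() < p else 0
            if not alive:
                continue
            # litter dynamics for females
            if female and active_litter is not None:
                sizes, born = active_litter
                lage = year - born
                if lage >= 1:
                    prev = sizes[-1]
                    lz = (lage - 1 - lage_mu) / lage_sd
                    eta_y = (
                        yc["intercept"] + yc["litter_age"] * lz
                        + yc["litter_age2"] * lz**2
                        + yc["litter_size"] * (sizes[0] - l0_mu) / l0_sd
                        + yc["mother_age"] * (age - age_mu) / age_sd
                        + yc["salmon"] * salmon[year - 1]
                    )
                    nxt = int(rng.binomial(prev, expit(eta_y)))
                    sizes.append(nxt)
                    done = nxt == 0
                    weaned_at = None
                    if not done and lage >= 2:
                        pw = (
                            1.0 if lage >= 4
                            else expit(0.2 + 0.8 * (lage - 2.5))
                        )
                        if rng.random() < pw:
                            weaned_at = lage
                            done = True
                    if done or year == n_years - 1:
                        litters.append(
                            LitterRecord(
                                litter_id=f"SL{lit_counter:04d}",
                                mother_id=f"k{i:04d}",
                                birth_year=born,
                                sizes=np.array(sizes),
                                weaned_at=weaned_at,
                            )
                        )
                        lit_counter += 1
                        active_litter = None
            # the dependent-young flag records young carried into this year,
            # before any new reproduction
            dep_now = 1.0 if active_litter is not None else 0.0
            dep[j] = dep_now
            if female and age >= 5:
                az = (age - age_mu) / age_sd
                eta_r = (
                    rc["intercept"] + rc["age"] * az + rc["salmon"] * salmon[year]
                    + rc["age_first_repro"] * afr_z
                    + rc["dep_young"] * dep_now
                )
                reproduced = rng.random() < expit(eta_r)
                if reproduced and active_litter is None:
                    eta_L = (
                        lc["intercept"] + lc["mother_age"] * az
                        + lc["age_first_repro"] * afr_z
                        + lc["salmon"] * salmon[year]
                    )
                    lam = math.exp(eta_L)
                    size = max(1, int(rng.poisson(lam)))
                    active_litter = ([size], year)
                repro[j] = 1 if (reproduced and rng.random() < p_r) else 0
        sl = slice(0, end)
        histories.append(
            CMRHistory(
                individual_id=f"k{i:04d}",
                entry_year=entry,
                y=y[sl], r=r[sl], sex=sex, age_at_entry=age0,
                repro=repro[sl] if female else None,
                covariates={
                    "age": ages[sl], "dep_young": dep[sl],
                    "is_adult": (ages[sl] >= 5).astype(float),
                },
            )
        )
    return histories, litters, {"salmon": salmon, "year0": 0}
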