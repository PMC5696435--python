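"""Demographic algebra shared by every layer of the integrated population model.

The population is structured into five age classes -- cub (C, age 0), yearling
(Y, age 1), dependent young (D, age 2-3 still accompanying their mother),
subadult (S, independent but immature) and adult (A) -- each split by sex,
giving ten age-sex classes.  Age brackets for D and S overlap in calendar age;
classes are keyed on independence status first and age second, which matches
the weaning window (ages 2-3) used by the litter model.

This module holds the pure kernels: logit/log linear predictors, the cub
recruitment mean, harvest accounting, the piecewise weaning rule and
moment-matched Beta priors.  It performs no I/O and holds no random state.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "AgeClass",
    "Sex",
    "AgeSexClass",
    "ALL_CLASSES",
    "N_AGE_CLASSES",
    "N_SEXES",
    "PopulationState",
    "HarvestRecord",
    "VitalRates",
    "LinearPredictorSpec",
    "PriorSpec",
    "DataInconsistencyError",
    "InfeasibleMomentsError",
    "linear_predictor_prob",
    "log_linear_mean",
    "cub_recruitment_mean",
    "apply_harvest",
    "weaning_probability",
    "beta_from_moments",
    "inv_logit",
]


class AgeClass(enum.IntEnum):
    """Age classes; integer values index the first axis of state arrays."""

    CUB = 0
    YEARLING = 1
    DEPENDENT = 2
    SUBADULT = 3
    ADULT = 4

    @property
    def code(self) -> str:
        return "CYDSA"[int(self)]


class Sex(enum.IntEnum):
    """Sexes; integer values index the second axis of state arrays."""

    MALE = 0
    FEMALE = 1

    @property
    def code(self) -> str:
        return "mf"[int(self)]


class AgeSexClass(NamedTuple):
    age_class: AgeClass
    sex: Sex

    @property
    def label(self) -> str:
        return f"{self.age_class.code}{self.sex.code}"


#: The ten age-sex classes, in array order (age-major, male before female).
ALL_CLASSES: tuple[AgeSexClass, ...] = tuple(
    AgeSexClass(a, s) for a in AgeClass for s in Sex
)

N_AGE_CLASSES = len(AgeClass)
N_SEXES = len(Sex)

_CLASS_SHAPE = (N_AGE_CLASSES, N_SEXES)


class DataInconsistencyError(ValueError):
    """Observed data contradict the model's hard constraints (e.g. H > N)."""


class InfeasibleMomentsError(ValueError):
    """Requested mean/variance pair is outside the Beta family's range."""


def _check_class_array(name: str, arr: np.ndarray, integer: bool = True) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.shape != _CLASS_SHAPE:
        raise ValueError(f"{name} must have shape {_CLASS_SHAPE}, got {arr.shape}")
    if integer:
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError(f"{name} must be integer-valued")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError(f"{name} must be nonnegative")
    return arr


@dataclass
class PopulationState:
    """True abundance by age-sex class in one year, before and after harvest.

    ``n_before_harvest[a, s]`` is the latent abundance after births, survival
    and class transitions but before subtracting that year's harvest;
    ``n[a, s]`` is the post-harvest abundance that repeated counts are drawn
    around.  Conservation holds exactly: ``n = n_before_harvest - H >= 0``.
    """

    year: int
    n_before_harvest: np.ndarray  # (5, 2) nonnegative ints
    n: np.ndarray  # (5, 2) nonnegative ints

    def __post_init__(self) -> None:
        self.n_before_harvest = _check_class_array(
            "n_before_harvest", self.n_before_harvest
        )
        self.n = _check_class_array("n", self.n)

    @classmethod
    def from_harvest(
        cls, year: int, n_before_harvest: np.ndarray, harvest: "HarvestRecord"
    ) -> "PopulationState":
        nbh = _check_class_array("n_before_harvest", n_before_harvest)
        n = np.empty_like(nbh)
        for a in AgeClass:
            for s in Sex:
                n[a, s] = apply_harvest(
                    int(nbh[a, s]),
                    int(harvest.h[a, s]),
                    class_label=AgeSexClass(a, s).label,
                    year=year,
                )
        return cls(year=year, n_before_harvest=nbh, n=n)

    def of(self, cls_: AgeSexClass, before_harvest: bool = False) -> int:
        arr = self.n_before_harvest if before_harvest else self.n
        return int(arr[cls_.age_class, cls_.sex])


@dataclass
class HarvestRecord:
    """Per-class harvest tally for one year; assumed observed without error."""

    year: int
    h: np.ndarray  # (5, 2) nonnegative ints

    def __post_init__(self) -> None:
        self.h = _check_class_array("h", self.h)


@dataclass
class VitalRates:
    """Demographic rates driving one year-to-year transition.

    phi
        Survival probability per age-sex class, shape (5, 2).
    gamma
        Transition probabilities, shape (2, 2): row 0 is dependent-young ->
        subadult (weaning), row 1 is subadult -> adult (maturation); columns
        are male, female.
    p_repro
        Probability an adult female reproduces (is accompanied by new cubs).
    litter_size
        Mean size of litters produced (litters have at least one cub).
    sex_ratio
        Proportion of cubs that are male.
    """

    phi: np.ndarray
    gamma: np.ndarray
    p_repro: float
    litter_size: float
    sex_ratio: float

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.phi.shape != _CLASS_SHAPE:
            raise ValueError(f"phi must have shape {_CLASS_SHAPE}")
        if self.gamma.shape != (2, 2):
            raise ValueError("gamma must have shape (2, 2): rows D->S, S->A")
        for name, val in (("phi", self.phi), ("gamma", self.gamma)):
            if np.any((val < 0) | (val > 1)):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        for name in ("p_repro", "sex_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.litter_size < 0:
            raise ValueError("litter_size must be nonnegative")

    def phi_of(self, cls_: AgeSexClass) -> float:
        return float(self.phi[cls_.age_class, cls_.sex])


@dataclass
class LinearPredictorSpec:
    """A logit- or log-scale linear predictor: intercept + slopes . x (+ eps).

    ``random_effect_sd`` is the scale of an optional zero-mean Normal random
    effect; ``None`` means the predictor has no random effect term.
    """

    intercept: float
    slopes: tuple[float, ...] = ()
    covariate_names: tuple[str, ...] = ()
    random_effect_sd: float | None = None

    def __post_init__(self) -> None:
        self.slopes = tuple(float(s) for s in self.slopes)
        self.covariate_names = tuple(self.covariate_names)
        if len(self.slopes) != len(self.covariate_names):
            raise ValueError(
                "slopes and covariate_names must have equal length "
                f"({len(self.slopes)} != {len(self.covariate_names)})"
            )
        if self.random_effect_sd is not None and self.random_effect_sd < 0:
            raise ValueError("random_effect_sd must be nonnegative")

    def eta(self, covariates: Sequence[float], random_effect: float = 0.0) -> float:
        x = np.asarray(covariates, dtype=float)
        if x.shape != (len(self.slopes),):
            raise ValueError(
                f"expected {len(self.slopes)} covariates, got {x.shape}"
            )
        return float(self.intercept + np.dot(self.slopes, x) + random_effect)


@dataclass
class PriorSpec:
    """A named prior distribution: uniform01, beta, normal or half_normal."""

    distribution: str
    parameters: tuple[float, ...] = ()

    _ARITY = {"uniform01": 0, "beta": 2, "normal": 2, "half_normal": 1}

    def __post_init__(self) -> None:
        if self.distribution not in self._ARITY:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        self.parameters = tuple(float(p) for p in self.parameters)
        if len(self.parameters) != self._ARITY[self.distribution]:
            raise ValueError(
                f"{self.distribution} takes {self._ARITY[self.distribution]} "
                f"parameters, got {len(self.parameters)}"
            )
        if self.distribution == "beta" and any(p <= 0 for p in self.parameters):
            raise ValueError("beta shapes must be positive")
        if self.distribution == "half_normal" and self.parameters[0] <= 0:
            raise ValueError("half_normal scale must be positive")


def inv_logit(eta: float) -> float:
    """Numerically stable inverse logit, strictly inside (0, 1) for finite eta."""
    if eta >= 0:
        return 1.0 / (1.0 + math.exp(-eta))
    e = math.exp(eta)
    return e / (1.0 + e)


def linear_predictor_prob(
    spec: LinearPredictorSpec,
    covariates: Sequence[float] = (),
    random_effect: float = 0.0,
) -> float:
    """Probability from a logit-scale linear predictor.

    Returns ``logit^-1(intercept + slopes . covariates + random_effect)``,
    strictly in (0, 1) for finite inputs.
    """
    return inv_logit(spec.eta(covariates, random_effect))


def log_linear_mean(
    spec: LinearPredictorSpec,
    covariates: Sequence[float] = (),
    random_effect: float = 0.0,
) -> float:
    """Positive mean from a log-scale linear predictor: exp(eta) > 0."""
    return math.exp(spec.eta(covariates, random_effect))


def cub_recruitment_mean(
    n_adult_female: int, phi_adult_female: float, p_repro: float, litter_size: float
) -> float:
    """Poisson mean for before-harvest cub abundance.

    The product N * Phi * P * L: adult females last year that survive and
    reproduce, times the mean litter size -- cubs born over the year that
    survive to den exit.
    """
    if n_adult_female < 0:
        raise ValueError("n_adult_female must be nonnegative")
    for name, v, hi in (
        ("phi_adult_female", phi_adult_female, 1.0),
        ("p_repro", p_repro, 1.0),
        ("litter_size", litter_size, math.inf),
    ):
        if not 0.0 <= v <= hi:
            raise ValueError(f"{name} out of range: {v}")
    return float(n_adult_female) * phi_adult_female * p_repro * litter_size


def apply_harvest(
    n_before_harvest: int,
    harvest: int,
    class_label: str | None = None,
    year: int | None = None,
) -> int:
    """Post-harvest abundance N = N_BH - H; harvest is observed without error.

    Raises :class:`DataInconsistencyError` (naming the class and year when
    given) if the recorded harvest exceeds the before-harvest abundance.
    """
    if n_before_harvest < 0 or harvest < 0:
        raise ValueError("abundance and harvest must be nonnegative")
    if harvest > n_before_harvest:
        where = ""
        if class_label is not None or year is not None:
            where = f" (class {class_label!r}, year {year})"
        raise DataInconsistencyError(
            f"harvest {harvest} exceeds before-harvest abundance "
            f"{n_before_harvest}{where}"
        )
    return int(n_before_harvest) - int(harvest)


def weaning_probability(litter_age: int, p_w: float) -> float:
    """Piecewise weaning rule conditional on litter age.

    Young under 2 never wean; litters aged 2-3 wean with probability ``p_w``;
    litters 4 years old or greater have weaned with certainty.
    """
    if litter_age < 0:
        raise ValueError("litter_age must be nonnegative")
    if not 0.0 <= p_w <= 1.0:
        raise ValueError("p_w must lie in [0, 1]")
    if litter_age < 2:
        return 0.0
    if litter_age >= 4:
        return 1.0
    return p_w


def beta_from_moments(mean: float, variance: float) -> tuple[float, float]:
    """Beta shape parameters (a, b) with the requested mean and variance.

    Inverts the Beta moment equations: a = mu * (mu(1-mu)/var - 1),
    b = a (1-mu)/mu.  Feasibility requires 0 < var < mu(1-mu); infeasible
    moments raise :class:`InfeasibleMomentsError` rather than being clipped,
    because silent clipping would corrupt an informative prior.
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleMomentsError(f"mean must be in (0, 1), got {mean}")
    if variance <= 0.0:
        raise InfeasibleMomentsError(f"variance must be positive, got {variance}")
    bound = mean * (1.0 - mean)
    if variance >= bound:
        raise InfeasibleMomentsError(
            f"variance {variance} must be below mean(1-mean) = {bound:.6g} "
            "for a Beta distribution"
        )
    a = mean * (bound / variance - 1.0)
    b = a * (1.0 - mean) / mean
    return a, b
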