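"""Information-sharing layer between individual-level data and the count model.

Individual survival and reproduction probabilities estimated from
mark-recapture, and litter sizes, are aggregated into the population-level
rates that drive the count process: class-averaged survival for subadults and
adults (from CMR), for cubs/yearlings/dependent young (from litters), the
mean reproduction probability of adult females alive in each year, and the
mean size of litters born in each year.  Averages weight individuals by their
alive indicator (or its posterior probability when the alive state is
marginalized); both satisfy the population-average definition in
expectation.

The aggregation assumes marked individuals are a representative sample of
the population -- an assumption that cannot be tested from these data alone
and is documented rather than enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["LinkedRates", "aggregate_survival", "aggregate_reproduction_and_litter"]


@dataclass
class LinkedRates:
    """Per-year class-averaged rates with the sample sizes behind each."""

    survival: dict[str, float]
    p_repro: float
    litter_size: float
    denominators: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.survival.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"averaged survival {name} outside [0, 1]: {v}")
        if not 0.0 <= self.p_repro <= 1.0:
            raise ValueError(f"p_repro outside [0, 1]: {self.p_repro}")
        if self.litter_size < 0:
            raise ValueError("litter_size must be nonnegative")


def aggregate_survival(
    phi: Sequence[float],
    alive: Sequence[float],
    class_membership: Sequence[str],
    fallback: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Alive-weighted mean survival per class.

    ``phi`` and ``alive`` are aligned per-individual vectors; ``alive`` may be
    the 0/1 latent indicator or its posterior probability.  For each class
    label the average of phi over (probably-)alive members is returned.  A
    class with no alive members carries no information from the marked
    sample; its entry falls back to ``fallback[class]`` -- in the full model
    an independent draw from the rate's prior -- rather than fabricating a
    value from dead individuals.
    """
    phi = np.asarray(phi, dtype=float)
    alive = np.asarray(alive, dtype=float)
    labels = np.asarray(class_membership)
    if not (phi.shape == alive.shape == labels.shape):
        raise ValueError("phi, alive and class_membership must be aligned")
    out: dict[str, float] = {}
    for cls in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        mask = labels == cls
        w = alive[mask]
        denom = float(w.sum())
        if denom > 0:
            out[cls] = float(np.dot(phi[mask], w) / denom)
        elif fallback is not None and cls in fallback:
            out[cls] = float(fallback[cls])
        else:
            raise ValueError(
                f"class {cls!r} has no alive members and no fallback value"
            )
    return out


def aggregate_reproduction_and_litter(
    rho: Sequence[float],
    alive: Sequence[float],
    litter_sizes_born: Sequence[int],
    litter_fallback: float | None = None,
) -> tuple[float, float]:
    """Population reproduction probability and mean newborn litter size.

    ``P_t`` is the alive-weighted mean of adult-female reproduction
    probabilities; ``L_t`` is the plain mean of the initial sizes of litters
    born in year t, falling back to ``litter_fallback`` (a prior draw in the
    full model) when no litter was born that year.
    """
    rho = np.asarray(rho, dtype=float)
    alive = np.asarray(alive, dtype=float)
    if rho.shape != alive.shape:
        raise ValueError("rho and alive must be aligned")
    denom = float(alive.sum())
    if denom > 0:
        p_t = float(np.dot(rho, alive) / denom)
    else:
        p_t = float("nan")
    sizes = np.asarray(litter_sizes_born, dtype=float)
    if sizes.size > 0:
        l_t = float(sizes.mean())
    elif litter_fallback is not None:
        l_t = float(litter_fallback)
    else:
        raise ValueError("no litters born and no fallback value")
    return p_t, l_t
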