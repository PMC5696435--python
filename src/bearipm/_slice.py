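"""Scalar slice sampler (stepping-out and shrinkage, Neal 2003).

Used for the non-conjugate scalar parameters; robust to poorly scaled
conditionals and needs no tuning beyond an initial width.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["slice_sample"]


def slice_sample(
    x0: float,
    logf,
    rng: np.random.Generator,
    w: float = 0.25,
    lower: float = -math.inf,
    upper: float = math.inf,
    max_steps: int = 30,
) -> float:
    """Draw one slice-sampling update of a scalar from density exp(logf).

    ``w`` is the initial bracket width; ``lower``/``upper`` truncate the
    support.  Returns the new value (equal to ``x0`` only in pathological
    shrinkage failure).
    """
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise ValueError(f"slice_sample started at zero-density point x0={x0}")
    log_y = f0 + math.log(rng.random() + 1e-300)

    u = rng.random()
    left = x0 - u * w
    right = left + w
    j = int(rng.random() * max_steps)
    k = max_steps - 1 - j
    while j > 0 and left > lower and logf(max(left, lower)) > log_y:
        left -= w
        j -= 1
    while k > 0 and right < upper and logf(min(right, upper)) > log_y:
        right += w
        k -= 1
    left = max(left, lower)
    right = min(right, upper)

    for _ in range(100):
        x1 = left + rng.random() * (right - left)
        if logf(x1) > log_y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0
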