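"""A-priori sample size for estimating a mean utility to a target precision.

The default criterion is iterative and t-based: the smallest n ≥ 2 such that
t(1 − α/2, n − 1) · sd / √n does not exceed the margin of error. With margin
0.05, sd 0.15 and 95% confidence this gives n = 38. The cruder z-based
formula ⌈(z·sd/margin)²⌉ is available behind ``method="z"``; it ignores the
uncertainty in the variance estimate and yields 35 for the same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SampleSizeSpec:
    """Target precision for a mean-utility estimate."""

    margin: float
    sd: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError(f"margin must be > 0, got {self.margin}")
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError(f"confidence must lie in (0, 1), got {self.confidence}")


def achieved_margin(n: int, sd: float, confidence: float = 0.95) -> float:
    """Half-width t(·, n−1)·sd/√n of the CI for a mean at sample size *n*."""
    if n < 2:
        raise ValueError(f"achieved_margin requires n >= 2, got {n}")
    q = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    return q * sd / float(np.sqrt(n))


def min_sample_size(spec: SampleSizeSpec, method: str = "t") -> int:
    """Smallest n meeting the precision target.

    method="t" iterates the exact t-based half-width criterion; method="z"
    uses the closed-form normal approximation.
    """
    if method == "z":
        z = float(stats.norm.ppf(0.5 + spec.confidence / 2.0))
        return max(2, int(np.ceil((z * spec.sd / spec.margin) ** 2)))
    if method != "t":
        raise ValueError(f"method must be 't' or 'z', got {method!r}")
    n = 2
    # t-quantile decreases and √n grows, so the half-width is eventually
    # monotone decreasing; iterate until it first drops below the margin
    while achieved_margin(n, spec.sd, spec.confidence) > spec.margin:
        n += 1
        if n > 10_000_000:
            raise RuntimeError("sample-size iteration failed to terminate")
    return n
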