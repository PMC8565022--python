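"""Quality-adjusted life years from a sequence of health-state intervals.

A survival trajectory is split into segments, each spent in one state with
duration Ti (years) and utility coefficient UCi in [0, 1]; QALYs are the
weighted sum Σ Ti·UCi. Optional continuous discounting at rate r replaces
each segment's contribution with its discounted integral
UCi·(e^(−r·a) − e^(−r·(a+Ti)))/r, where a is the time already elapsed; the
default rate 0 recovers the plain weighted sum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class QALYSegment:
    duration: float  # years
    utility: float
    state_id: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.duration) and self.duration >= 0):
            raise ValueError(f"segment duration must be >= 0, got {self.duration}")
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError(f"segment utility must lie in [0, 1], got {self.utility}")


@dataclass
class QALYProfile:
    segments: list[QALYSegment] = field(default_factory=list)
    discount_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError(f"discount_rate must be >= 0, got {self.discount_rate}")
        self.segments = [
            s if isinstance(s, QALYSegment) else QALYSegment(**s) for s in self.segments
        ]

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @classmethod
    def from_json(cls, path: str | Path) -> "QALYProfile":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            segments=[QALYSegment(**s) for s in raw["segments"]],
            discount_rate=raw.get("discount_rate", 0.0),
        )


def compute_qalys(profile: QALYProfile) -> float:
    """QALYs of a profile: Σ Ti·UCi, discounted continuously if requested."""
    r = profile.discount_rate
    if r == 0.0:
        return sum(s.duration * s.utility for s in profile.segments)
    total = 0.0
    elapsed = 0.0
    for s in profile.segments:
        total += s.utility * (math.exp(-r * elapsed) - math.exp(-r * (elapsed + s.duration))) / r
        elapsed += s.duration
    return total


def qaly_difference(profile_a: QALYProfile, profile_b: QALYProfile) -> float:
    """Incremental QALYs of *profile_a* over *profile_b*."""
    return compute_qalys(profile_a) - compute_qalys(profile_b)
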