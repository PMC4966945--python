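"""Circular statistics for period-matching.

Response times are wrapped onto the unit circle with one circle length
equal to one stimulus IBI (beat-level trials) or two IBIs (two-beat
trials). Period-matched responses cluster around a preferred direction —
anywhere on the circle, since phase is not scored — and the Rayleigh
test against circular uniformity decides, per trial segment, whether
synchronization succeeded. Circular variance V = 1 - R measures angular
dispersion of the whole, un-segmented trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AngleSeries",
    "RayleighResult",
    "BimodalityResult",
    "TooFewResponsesError",
    "events_to_angles",
    "resultant_length",
    "circular_variance",
    "rayleigh_test",
    "rayleigh_p",
    "segment_angles",
    "detect_bimodality",
]


class TooFewResponsesError(ValueError):
    """Not enough responses for the requested circular statistic."""


@dataclass(frozen=True)
class AngleSeries:
    """Response angles on the unit circle for one trial.

    circle_span_ms is the circle length in milliseconds (L x IBI).
    """

    angles: np.ndarray
    circle_span_ms: float
    source: str = ""

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if angles.size and (angles.min() < 0.0 or angles.max() >= 2 * np.pi):
            raise ValueError("angles must lie in [0, 2*pi)")
        if not self.circle_span_ms > 0:
            raise ValueError("circle_span_ms must be positive")

    def __len__(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class RayleighResult:
    """Rayleigh test outcome: n, resultant length R, z = n*R^2, p-value."""

    n: int
    R: float
    z: float
    p: float

    @property
    def significant(self) -> bool:  # at the conventional 0.05
        return self.p < 0.05


@dataclass(frozen=True)
class BimodalityResult:
    """Axial-doubling bimodality diagnostic.

    bimodal is None when n is too small to decide (undetermined).
    """

    bimodal: Optional[bool]
    R: float
    R_doubled: float
    p_doubled: Optional[float]


def events_to_angles(
    event_times_s: np.ndarray | Sequence[float],
    ibi_ms: float,
    level_multiplier: int = 1,
    source: str = "",
) -> AngleSeries:
    """Wrap event times onto the circle: theta = 2*pi * (t mod L*IBI) / (L*IBI).

    Uses the unrounded IBI in milliseconds. One IBI spans the circle for
    beat-level trials (L=1), two IBIs for two-beat trials (L=2).
    """
    times = np.asarray(event_times_s, dtype=float)
    if times.size == 0:
        raise TooFewResponsesError("no events to convert to angles")
    if not ibi_ms > 0:
        raise ValueError("ibi_ms must be positive")
    if level_multiplier not in (1, 2, 4):
        raise ValueError("level_multiplier must be 1, 2 or 4")
    span = level_multiplier * ibi_ms
    angles = 2 * np.pi * np.mod(times * 1000.0, span) / span
    angles = np.mod(angles, 2 * np.pi)  # guard the half-open interval
    return AngleSeries(angles=angles, circle_span_ms=span, source=source)


def _as_angles(angles) -> np.ndarray:
    if isinstance(angles, AngleSeries):
        return angles.angles
    return np.asarray(angles, dtype=float)


def resultant_length(angles) -> float:
    """Length of the mean unit vector, in [0, 1]."""
    theta = _as_angles(angles)
    if theta.size == 0:
        raise TooFewResponsesError("resultant length of an empty angle set")
    return float(np.abs(np.mean(np.exp(1j * theta))))


def circular_variance(angles) -> float:
    """Circular variance V = 1 - R, clamped into [0, 1] against roundoff."""
    return float(np.clip(1.0 - resultant_length(angles), 0.0, 1.0))


def rayleigh_p(n: int | np.ndarray, R: float | np.ndarray) -> np.ndarray | float:
    """Rayleigh p-value via the small-sample exponential approximation.

    p = exp( sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n) ), capped into (0, 1].
    Vectorized over n and R.
    """
    n = np.asarray(n, dtype=float)
    Rn = n * np.asarray(R, dtype=float)
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - Rn**2)) - (1.0 + 2.0 * n))
    p = np.minimum(p, 1.0)
    p = np.maximum(p, np.finfo(float).tiny)
    return p if p.ndim else float(p)


def rayleigh_test(angles, min_n: int = 4) -> RayleighResult:
    """Rayleigh test of circular uniformity.

    Requires n >= `min_n` (the approximation is unreliable below 4);
    smaller samples raise TooFewResponsesError and mark the segment
    unusable.
    """
    theta = _as_angles(angles)
    n = theta.size
    if n < min_n:
        raise TooFewResponsesError(
            f"Rayleigh test needs at least {min_n} responses, got {n}"
        )
    R = resultant_length(theta)
    z = n * R**2
    return RayleighResult(n=n, R=R, z=z, p=float(rayleigh_p(n, R)))


def segment_angles(angles: AngleSeries, level_multiplier: int, min_segment_n: int = 4) -> list[AngleSeries]:
    """Split a trial into consecutive, equal-count segments.

    Beat-level trials (L=1) get four segments, two-beat trials (L=2) two,
    so each segment holds the same number of responses; a remainder r
    puts one extra response into each of the first r segments. The
    segmentation catches trials where the beat was lost partway, or
    found only late.
    """
    if level_multiplier == 1:
        k = 4
    elif level_multiplier == 2:
        k = 2
    else:
        raise ValueError("segmentation is defined for level multipliers 1 and 2")
    n = len(angles)
    if n < k * min_segment_n:
        raise TooFewResponsesError(
            f"{n} responses cannot fill {k} segments of at least {min_segment_n}"
        )
    base, r = divmod(n, k)
    sizes = [base + 1] * r + [base] * (k - r)
    out, start = [], 0
    for size in sizes:
        out.append(
            AngleSeries(
                angles=angles.angles[start : start + size],
                circle_span_ms=angles.circle_span_ms,
                source=angles.source,
            )
        )
        start += size
    return out


def detect_bimodality(
    angles,
    alpha: float = 0.05,
    margin: float = 0.2,
    min_n: int = 8,
) -> BimodalityResult:
    """Flag trials whose responses cluster around two preferred directions.

    Axial statistic: with doubled angles 2*theta, two antipodal lobes
    collapse onto one. The trial is flagged bimodal when the Rayleigh
    test on 2*theta is significant at `alpha` AND R(2*theta) exceeds
    R(theta) by at least `margin` — i.e. two lobes dominate a single one.
    Fewer than `min_n` responses leave the flag undetermined (None).
    """
    theta = _as_angles(angles)
    if theta.size < min_n:
        return BimodalityResult(None, float("nan"), float("nan"), None)
    R = resultant_length(theta)
    doubled = np.mod(2.0 * theta, 2 * np.pi)
    R2 = resultant_length(doubled)
    p2 = float(rayleigh_p(theta.size, R2))
    flag = (p2 < alpha) and (R2 - R >= margin)
    return BimodalityResult(bool(flag), R, R2, p2)
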