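"""Self-paced (unpaced) motor production.

Without a pacing stimulus, the produced rate reflects the participant's
referent period. Tempo is the mean inter-response interval of the first
30 events; regularity is the coefficient of variation (CV = SD of the
IRIs / mean IRI) over the same window, log-normalized because the CV
distribution is log-normal. Normative cut-offs are mean +/- 2 SD of the
normal-synchronizer reference group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .events import ResponseSeries, TooFewEventsError

__all__ = [
    "SelfPacedStats",
    "self_paced_stats",
    "normative_cutoffs",
    "flag_outliers",
]


@dataclass(frozen=True)
class SelfPacedStats:
    """Produced tempo and regularity of one self-paced trial.

    normalized_cv = -log10(cv) (floored): higher means more regular.
    raw SD of the IRIs is kept as an optional secondary measure.
    """

    mean_iri_ms: float
    cv: float
    normalized_cv: float
    n_events_used: int
    sd_iri_ms: float


def self_paced_stats(
    series: ResponseSeries, n_events: int = 30, cv_floor: float = 1e-6
) -> SelfPacedStats:
    """Tempo and regularity from the first `n_events` events (29 IRIs at 30).

    The event count, not the interval count, is truncated: 30 events
    yield 29 IRIs. With fewer events than requested, the statistics are
    computed on what exists (with a warning) and the count recorded.
    CV uses the sample (n-1) standard deviation.
    """
    if len(series) < 2:
        raise TooFewEventsError("self-paced statistics need at least 2 events")
    if len(series) < n_events:
        warnings.warn(
            f"only {len(series)} events available (requested {n_events}); "
            "statistics computed on the shorter series",
            RuntimeWarning,
            stacklevel=2,
        )
    used = series.event_times[:n_events]
    iris = np.diff(used) * 1000.0
    mean_iri = float(np.mean(iris))
    sd_iri = float(np.std(iris, ddof=1)) if iris.size > 1 else 0.0
    cv = sd_iri / mean_iri
    return SelfPacedStats(
        mean_iri_ms=mean_iri,
        cv=cv,
        normalized_cv=-math.log10(max(cv, cv_floor)),
        n_events_used=int(used.size),
        sd_iri_ms=sd_iri,
    )


def normative_cutoffs(
    reference: Iterable[float],
    direction: str,
    integer: bool = False,
) -> float:
    """Mean +/- 2 SD cut-off from a normal-synchronizer reference group.

    direction='upper' gives mean + 2 SD (e.g. abnormally slow tempo);
    direction='lower' gives mean - 2 SD (e.g. abnormally low
    regularity). For integer-scored tests the cut-off is rounded to the
    nearest integer (e.g. mean 27.4, SD 3.65 -> lower cut-off 20).
    """
    values = np.asarray(list(reference), dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 reference values for a normative cut-off")
    if direction not in ("upper", "lower"):
        raise ValueError("direction must be 'upper' or 'lower'")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "degenerate reference (SD = 0); cut-off equals the mean",
            RuntimeWarning,
            stacklevel=2,
        )
    cutoff = mean + 2.0 * sd if direction == "upper" else mean - 2.0 * sd
    return float(round(cutoff)) if integer else cutoff


def flag_outliers(
    values: Mapping[str, float], cutoff: float, direction: str
) -> list[str]:
    """IDs whose value violates the cut-off in the stated direction.

    direction='upper': values above the cut-off are flagged;
    direction='lower': values below it.
    """
    if direction == "upper":
        return [k for k, v in values.items() if v > cutoff]
    if direction == "lower":
        return [k for k, v in values.items() if v < cutoff]
    raise ValueError("direction must be 'upper' or 'lower'")
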