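"""Metrical level of the produced movement, from the trace's power spectrum.

Participants move at the beat level (every beat), the two-beat level
(every second beat, half the beat frequency) or — rarely — the four-beat
level. The level is read off the dominant peak of the Fourier power
spectrum of the acceleration signal; trials whose produced frequency
matches no level within tolerance are off-tempo, and trials whose level
changes between the two halves of the analysis window are unstable.
Off-tempo and unstable trials are excluded from the level table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .events import vertical_axis
from .stimuli import StimulusSpec
from .trace import AccelTrace

__all__ = [
    "MetricalLevelResult",
    "dominant_frequency",
    "classify_level",
    "check_level_stability",
    "LEVEL_MULTIPLIERS",
]

#: level name -> movements-per-beat divisor
LEVEL_MULTIPLIERS = {"beat": 1, "two_beat": 2, "four_beat": 4}
_LEVEL_BY_MULT = {v: k for k, v in LEVEL_MULTIPLIERS.items()}


@dataclass(frozen=True)
class MetricalLevelResult:
    """Outcome of level determination for one trial.

    level: beat | two_beat | four_beat | off_tempo | unstable | indeterminate.
    level_multiplier: 1, 2 or 4 when a level was assigned, else None.
    relative_deviation: |f - f_target| / f_target for the assigned level.
    """

    level: str
    level_multiplier: Optional[int]
    dominant_freq_hz: Optional[float]
    beat_freq_hz: float
    relative_deviation: Optional[float] = None

    @property
    def determinable(self) -> bool:
        return self.level in LEVEL_MULTIPLIERS


def dominant_frequency(
    trace: AccelTrace,
    band_hz: Optional[tuple[float, float]] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    axis: Optional[int] = None,
) -> Optional[float]:
    """Frequency of the maximal power-spectrum peak in the movement band.

    The spectrum is taken from the mean-removed movement-axis signal with
    a rectangular window; at 105 s the native resolution (~0.0095 Hz) is
    sufficient without padding. Returns None when no peak rises above
    ``spectrum_peak_ratio`` times the in-band median power (an
    indeterminate, noise-like spectrum).
    """
    band = config.spectrum_band_hz if band_hz is None else band_hz
    if trace.duration_s < 30.0:
        raise ValueError(
            f"analysis window of {trace.duration_s:.1f} s is too short for "
            "frequency resolution; at least 30 s required"
        )
    ax = vertical_axis(trace, config) if axis is None else axis
    x = trace.data[:, ax]
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / trace.sample_rate_hz)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(in_band):
        raise ValueError("no spectral bins inside the search band")
    band_power = power[in_band]
    floor = float(np.median(band_power))
    peak_idx = int(np.argmax(band_power))
    if floor > 0 and band_power[peak_idx] < config.spectrum_peak_ratio * floor:
        return None
    if band_power[peak_idx] == 0.0:
        return None
    return float(freqs[in_band][peak_idx])


def classify_level(
    dominant_freq_hz: Optional[float],
    stimulus: StimulusSpec,
    tolerance: Optional[float] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> MetricalLevelResult:
    """Assign a metrical level to a produced movement frequency.

    For L in (1, 2, 4) the target frequency is beat_freq / L; the
    smallest L whose relative deviation is within tolerance wins. A
    frequency matching no level is off-tempo; a missing frequency is
    indeterminate.
    """
    tol = config.level_tolerance if tolerance is None else tolerance
    f_beat = stimulus.beat_freq_hz
    if dominant_freq_hz is None:
        return MetricalLevelResult("indeterminate", None, None, f_beat)
    for mult in (1, 2, 4):
        target = f_beat / mult
        deviation = abs(dominant_freq_hz - target) / target
        if deviation <= tol:
            return MetricalLevelResult(
                _LEVEL_BY_MULT[mult], mult, dominant_freq_hz, f_beat, deviation
            )
    return MetricalLevelResult("off_tempo", None, dominant_freq_hz, f_beat)


def check_level_stability(
    trace: AccelTrace,
    stimulus: StimulusSpec,
    config: AnalysisConfig = DEFAULT_CONFIG,
    axis: Optional[int] = None,
) -> MetricalLevelResult:
    """Level determination with a two-half constancy check.

    The analysis window is split in half and the level determined in
    each; halves that disagree mark the trial unstable (the chosen level
    was not constant throughout the trial). Requires >= 60 s of data so
    each half supports the spectral resolution.
    """
    if trace.duration_s < 60.0:
        raise ValueError("level stability check needs at least 60 s of data")
    ax = vertical_axis(trace, config) if axis is None else axis
    mid = trace.t0 + trace.duration_s / 2.0
    halves = [trace.slice_time(trace.t0, mid), trace.slice_time(mid)]
    results = [
        classify_level(
            dominant_frequency(h, config=config, axis=ax), stimulus, config=config
        )
        for h in halves
    ]
    if results[0].level != results[1].level:
        full = dominant_frequency(trace, config=config, axis=ax)
        return MetricalLevelResult("unstable", None, full, stimulus.beat_freq_hz)
    # consistent halves: report the full-window spectrum for best resolution
    full = dominant_frequency(trace, config=config, axis=ax)
    result = classify_level(full, stimulus, config=config)
    if result.level != results[0].level:
        # full-window estimate straddles the boundary the halves agreed on
        return results[0]
    return result
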