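"""Movement-event extraction from acceleration traces.

Responses are the timing of maximal knee flexion (bouncing) or hand
impact (clapping). Bounce events are acceleration minima of the vertical
axis after band-pass filtering; clap events are threshold-crossing peaks
of the high-passed, rectified resultant magnitude. The interval between
two successive responses is the inter-response interval (IRI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

from .config import DEFAULT_CONFIG, AnalysisConfig
from .trace import AccelTrace

__all__ = [
    "ResponseSeries",
    "FlatTraceError",
    "TooFewEventsError",
    "discard_lead",
    "extract_events",
    "compute_iris",
    "vertical_axis",
]


class FlatTraceError(ValueError):
    """The trace carries no movement signal."""


class TooFewEventsError(ValueError):
    """Fewer events than required for a usable trial."""


@dataclass(frozen=True)
class ResponseSeries:
    """Ordered movement-event times for one trial.

    event_times are in seconds and strictly increasing; IRIs (ms) derive
    from them as successive differences.
    """

    event_times: np.ndarray
    movement_type: str = "bounce"
    source: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", times)
        if times.ndim != 1:
            raise ValueError("event_times must be one-dimensional")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("event_times must be strictly increasing")

    def __len__(self) -> int:
        return self.event_times.size

    @property
    def iris_ms(self) -> np.ndarray:
        """Inter-response intervals in milliseconds (length n - 1)."""
        return np.diff(self.event_times) * 1000.0

    def after(self, t_min_s: float) -> "ResponseSeries":
        """Events at or after `t_min_s` (the analysis window)."""
        return replace(self, event_times=self.event_times[self.event_times >= t_min_s])


def discard_lead(trace: AccelTrace, lead_s: float = 10.0) -> AccelTrace:
    """Drop the first `lead_s` seconds of a trace; timestamps preserved.

    The study discarded the first 10 s of every 115-s trial, leaving
    105 s for analysis.
    """
    if lead_s < 0:
        raise ValueError("lead_s must be non-negative")
    if lead_s == 0:
        return trace
    if trace.t0 + trace.duration_s <= lead_s:
        raise ValueError(
            f"trace ends at {trace.t0 + trace.duration_s:.1f} s, "
            f"cannot discard a {lead_s:.1f} s lead"
        )
    return trace.slice_time(lead_s)


def vertical_axis(trace: AccelTrace, config: AnalysisConfig = DEFAULT_CONFIG) -> int:
    """Index of the movement (vertical) axis.

    Auto-detected as the axis with maximal variance in the movement band;
    override by passing an explicit axis to the callers that accept one.
    """
    lo, hi = config.bounce_band_hz
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=trace.sample_rate_hz, output="sos")
    var = [float(np.var(sps.sosfiltfilt(sos, trace.data[:, i]))) for i in range(3)]
    return int(np.argmax(var))


def _robust_sd(x: np.ndarray) -> float:
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def _clap_event_times(trace: AccelTrace, config: AnalysisConfig) -> np.ndarray:
    """Detect impact transients by matched filtering the high-passed axes.

    Each mean-removed axis is high-passed above ``clap_highpass_hz``,
    correlated with a unit-norm template of the high-passed impact
    transient (biexponential, ``clap_rise_s`` / ``clap_decay_s``), and
    the per-axis scores combined into a resultant detection score. Peaks
    exceeding ``clap_threshold_sds`` robust noise SDs above the score
    median (with a relative floor of ``clap_peak_floor_frac`` of the
    maximal score against spurious sub-transient wiggles on noiseless
    recordings), separated by the refractory window, mark the impacts.
    """
    fs = trace.sample_rate_hz
    sos = sps.butter(4, config.clap_highpass_hz, btype="highpass", fs=fs, output="sos")
    hp = sps.sosfiltfilt(sos, trace.data - trace.data.mean(axis=0), axis=0)

    k_t = np.arange(0.0, 6 * config.clap_decay_s, 1.0 / fs)
    kern = np.exp(-k_t / config.clap_decay_s) - np.exp(-k_t / config.clap_rise_s)
    if kern.max() <= 0:
        raise ValueError("degenerate clap template; check rise/decay constants")
    pad = int(round(0.3 * fs))
    tpl_full = sps.sosfiltfilt(
        sos, np.concatenate([np.zeros(pad), kern / kern.max(), np.zeros(pad)])
    )
    core = np.nonzero(np.abs(tpl_full) > 0.05 * np.abs(tpl_full).max())[0]
    tpl = tpl_full[core[0] : core[-1] + 1]
    norm = np.linalg.norm(tpl)
    if norm == 0.0:
        raise ValueError("degenerate clap template after filtering")
    tpl = tpl / norm
    event_in_tpl = pad + int(np.argmax(kern)) - core[0]

    scores = np.stack([sps.correlate(hp[:, i], tpl, mode="full") for i in range(3)])
    score = np.sqrt((scores**2).sum(axis=0))
    med = float(np.median(score))
    noise_sd = _robust_sd(score)
    if noise_sd == 0.0 and score.max() == 0.0:
        raise FlatTraceError("no clap transients in trace")
    threshold = max(
        med + config.clap_threshold_sds * noise_sd,
        config.clap_peak_floor_frac * float(score.max()),
    )
    distance = max(1, int(round(config.clap_refractory_s * fs)))
    peaks, _ = sps.find_peaks(score, height=threshold, distance=distance)
    if peaks.size == 0:
        raise FlatTraceError("no clap transients above the detection threshold")
    idx = peaks - (tpl.size - 1) + event_in_tpl
    idx = idx[(idx >= 0) & (idx < hp.shape[0])]
    return trace.times[idx]


def extract_events(
    trace: AccelTrace,
    expected_period_s: Optional[float] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    min_events: Optional[int] = None,
    axis: Optional[int] = None,
) -> ResponseSeries:
    """Extract movement-event times from a trace.

    Bounce: band-pass the vertical axis to the movement band, then find
    local minima separated by at least ``bounce_min_sep_frac`` of the
    expected period with prominence at least ``bounce_prominence_frac``
    of the filtered-signal SD. When no expected period is given, the
    dominant spectral period of the trace is used.

    Clap: high-pass the resultant magnitude above ``clap_highpass_hz``,
    rectify, and take peaks exceeding ``clap_threshold_sds`` robust noise
    SDs, with a refractory window of ``clap_refractory_s`` between
    impacts.
    """
    if expected_period_s is not None and not expected_period_s > 0:
        raise ValueError("expected_period_s must be positive")
    min_events = config.min_events if min_events is None else min_events
    fs = trace.sample_rate_hz
    if float(np.ptp(trace.data)) == 0.0:
        raise FlatTraceError("trace is constant; no events to extract")

    if trace.movement_type == "bounce":
        ax = vertical_axis(trace, config) if axis is None else axis
        lo, hi = config.bounce_band_hz
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        filt = sps.sosfiltfilt(sos, trace.data[:, ax])
        sd = float(np.std(filt))
        if sd == 0.0:
            raise FlatTraceError("filtered trace is flat; no bounce oscillation")
        if expected_period_s is None:
            from .level import dominant_frequency  # deferred: avoids module cycle

            f0 = dominant_frequency(trace, config=config)
            if f0 is None:
                raise FlatTraceError("no dominant movement frequency in trace")
            expected_period_s = 1.0 / f0
        distance = max(1, int(round(config.bounce_min_sep_frac * expected_period_s * fs)))
        peaks, _ = sps.find_peaks(
            -filt, distance=distance, prominence=config.bounce_prominence_frac * sd
        )
        times = trace.times[peaks]
    else:
        times = _clap_event_times(trace, config)

    if times.size < min_events:
        raise TooFewEventsError(
            f"only {times.size} events detected (minimum {min_events}); trial unusable"
        )
    return ResponseSeries(
        event_times=times, movement_type=trace.movement_type, source=trace.participant_id
    )


def compute_iris(series: ResponseSeries) -> np.ndarray:
    """Inter-response intervals in milliseconds (successive differences)."""
    if len(series) < 2:
        raise TooFewEventsError("at least 2 events are needed to compute IRIs")
    return series.iris_ms
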