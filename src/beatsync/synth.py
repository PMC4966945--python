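"""Synthetic accelerometer cohorts with known ground truth.

The study's raw recordings are not deposited, so every downstream stage
is exercised on simulated data. The generator produces:

* event-time series on a (possibly mistuned, drifting, jittered) beat
  grid — the timing model behind both movement types;
* rendered 3-axis traces: a smooth raised-cosine oscillation whose
  acceleration minima mark maximal knee flexion (bouncing), or sharp
  biexponential impact transients (clapping), plus Gaussian sensor noise;
* whole labeled cohorts mixing normal synchronizers with the four
  poor-synchronizer archetypes observed behaviourally (global failure,
  music-only failure, graded bounce<clap & music<metronome failure,
  bounce-only failure).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .stimuli import StimulusSpec, default_stimulus_set
from .trace import AccelTrace

__all__ = [
    "SimParams",
    "simulate_event_times",
    "render_trace",
    "simulate_trial",
    "CohortTrial",
    "Cohort",
    "simulate_cohort",
    "POOR_ARCHETYPES",
]

#: Biexponential clap transient time constants (seconds): fast rise,
#: slower decay — a broadband spike clearly distinct from the bounce
#: oscillation.
CLAP_RISE_S = 0.001
CLAP_DECAY_S = 0.030

#: forearm-swing amplitude as a fraction of the impact amplitude; the
#: smooth swing carries the movement fundamental in the power spectrum
CLAP_SWING_FRAC = 0.3


@dataclass(frozen=True)
class SimParams:
    """Timing and rendering parameters for one simulated trial.

    level_multiplier L in {1, 2, 4}: movements every L-th beat, i.e. the
    produced period is L * IBI * (1 + tempo_mismatch).
    phase_noise_sd_ms: independent per-event timing jitter.
    drift_sd_ms: SD of the random-walk increments of the produced period.
    bimodal_offset_rad / bimodal_mix: with probability `bimodal_mix` an
    event is displaced by offset/(2*pi) of a circle length — a mixture of
    two preferred phases.
    """

    movement_type: str = "bounce"
    level_multiplier: int = 1
    tempo_mismatch: float = 0.0
    phase_noise_sd_ms: float = 0.0
    drift_sd_ms: float = 0.0
    bimodal_offset_rad: Optional[float] = None
    bimodal_mix: float = 0.0
    amplitude: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.movement_type not in ("bounce", "clap"):
            raise ValueError(f"unknown movement_type {self.movement_type!r}")
        if self.level_multiplier not in (1, 2, 4):
            raise ValueError("level_multiplier must be 1, 2 or 4")
        if not 0.0 <= self.bimodal_mix <= 1.0:
            raise ValueError("bimodal_mix must lie in [0, 1]")
        if self.phase_noise_sd_ms < 0 or self.drift_sd_ms < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.noise_sd < 0 or self.amplitude < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")


def simulate_event_times(
    params: SimParams,
    stimulus: Optional[StimulusSpec] = None,
    referent_period_s: Optional[float] = None,
    duration_s: Optional[float] = None,
    offset_s: Optional[float] = None,
) -> np.ndarray:
    """Simulate movement-event times for one trial, in seconds.

    Either a stimulus (paced trial: base period = L * IBI) or a referent
    period (self-paced trial) must be given. The produced period is
    ``base * (1 + tempo_mismatch)`` and then follows a random walk with
    increment SD ``drift_sd_ms``; each event additionally receives
    independent Gaussian jitter of SD ``phase_noise_sd_ms``, and with
    probability ``bimodal_mix`` a displacement of
    ``bimodal_offset_rad / (2*pi)`` circle lengths. Times are clipped to
    [0, duration] and returned sorted.
    """
    if stimulus is not None:
        base_period = params.level_multiplier * stimulus.ibi_ms_exact / 1000.0
        duration = stimulus.duration_s if duration_s is None else duration_s
    elif referent_period_s is not None:
        if not referent_period_s > 0:
            raise ValueError("referent_period_s must be positive")
        base_period = referent_period_s
        duration = 120.0 if duration_s is None else duration_s
    else:
        raise ValueError("either a stimulus or a referent period is required")

    period = base_period * (1.0 + params.tempo_mismatch)
    if not period > 0:
        raise ValueError("produced period must be positive")

    rng = np.random.default_rng(params.seed)
    offset = float(rng.uniform(0, period)) if offset_s is None else float(offset_s)

    n_max = int(np.ceil((duration - offset) / period)) + 3
    n_max = max(n_max, 1)
    increments = rng.normal(0.0, params.drift_sd_ms / 1000.0, size=n_max)
    periods = period + np.cumsum(increments)
    if np.any(periods <= 0):
        raise ValueError("drift produced a non-positive period; lower drift_sd_ms")
    grid = offset + np.concatenate(([0.0], np.cumsum(periods)))

    jitter = rng.normal(0.0, params.phase_noise_sd_ms / 1000.0, size=grid.size)
    events = grid + jitter
    if params.bimodal_mix > 0 and params.bimodal_offset_rad is not None:
        circle_span = base_period  # L * IBI (or the referent period)
        mask = rng.random(grid.size) < params.bimodal_mix
        events = events + mask * (params.bimodal_offset_rad / (2 * np.pi)) * circle_span

    events = events[(events >= 0.0) & (events <= duration)]
    if np.any(np.diff(events) <= 0):
        warnings.warn(
            "event jitter exceeded half the period; events re-sorted",
            RuntimeWarning,
            stacklevel=2,
        )
        events = np.sort(events)
    return events


def _bounce_waveform(t: np.ndarray, events: np.ndarray, amplitude: float) -> np.ndarray:
    """Raised-cosine acceleration with minima (maximal flexion) at events."""
    if events.size < 2:
        raise ValueError("bounce rendering needs at least two events")
    idx = np.arange(events.size, dtype=float)
    phase = np.interp(t, events, idx)
    # np.interp clamps outside the event range; extrapolate with the edge periods
    p_first = events[1] - events[0]
    p_last = events[-1] - events[-2]
    before = t < events[0]
    after = t > events[-1]
    phase[before] = (t[before] - events[0]) / p_first
    phase[after] = (events.size - 1) + (t[after] - events[-1]) / p_last
    return -amplitude * np.cos(2 * np.pi * phase)


def _clap_waveform(
    t: np.ndarray, events: np.ndarray, amplitude: float, fs: float
) -> np.ndarray:
    """Sum of biexponential impact transients, peak aligned to each event."""
    # peak time of exp(-t/d) - exp(-t/r) after onset
    t_peak = CLAP_RISE_S * CLAP_DECAY_S / (CLAP_DECAY_S - CLAP_RISE_S) * np.log(
        CLAP_DECAY_S / CLAP_RISE_S
    )
    k_t = np.arange(0.0, 6 * CLAP_DECAY_S, 1.0 / fs)
    kernel = np.exp(-k_t / CLAP_DECAY_S) - np.exp(-k_t / CLAP_RISE_S)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("degenerate clap kernel")
    kernel *= amplitude / peak
    out = np.zeros_like(t)
    for e in events:
        start = int(round((e - t_peak - t[0]) * fs))
        lo, hi = max(start, 0), min(start + kernel.size, out.size)
        if hi > lo:
            out[lo:hi] += kernel[lo - start : hi - start]
    return out


def render_trace(
    events: np.ndarray,
    params: SimParams,
    sample_rate_hz: float = 100.0,
    duration_s: float = 115.0,
    participant_id: str = "",
    stimulus: Optional[StimulusSpec] = None,
) -> AccelTrace:
    """Render an event series into a 3-axis acceleration trace.

    The movement signal is carried on the third (vertical) axis; the
    other axes carry sensor noise only. Bouncing yields a continuous
    raised-cosine oscillation with acceleration minima at event times;
    clapping yields a biexponential transient whose peak sample falls at
    each event time (within one sample). Gaussian noise of SD
    ``params.noise_sd`` is added to all axes.
    """
    events = np.asarray(events, dtype=float)
    if params.movement_type == "clap" and sample_rate_hz < 50:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz too low to resolve clap transients"
        )
    n = int(round(sample_rate_hz * duration_s))
    t = np.arange(n) / sample_rate_hz
    signal = np.zeros(n)
    if params.amplitude > 0 and events.size > 0:
        if params.movement_type == "bounce":
            signal = _bounce_waveform(t, events, params.amplitude)
        else:
            signal = _clap_waveform(t, events, params.amplitude, sample_rate_hz)
            if events.size >= 2:
                # the forearm swings between impacts: a smooth periodic
                # component at the movement frequency underlies the spikes
                signal += _bounce_waveform(t, events, CLAP_SWING_FRAC * params.amplitude)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5EED]))
    data = rng.normal(0.0, params.noise_sd, size=(n, 3)) if params.noise_sd > 0 else np.zeros((n, 3))
    data[:, 2] += signal
    return AccelTrace(
        data=data,
        sample_rate_hz=sample_rate_hz,
        participant_id=participant_id,
        movement_type=params.movement_type,
        stimulus=stimulus,
    )


def simulate_trial(
    params: SimParams,
    stimulus: Optional[StimulusSpec] = None,
    referent_period_s: Optional[float] = None,
    duration_s: Optional[float] = None,
    sample_rate_hz: float = 100.0,
    participant_id: str = "",
    offset_s: Optional[float] = None,
) -> tuple[np.ndarray, AccelTrace]:
    """Simulate event times and render the corresponding trace."""
    events = simulate_event_times(
        params,
        stimulus=stimulus,
        referent_period_s=referent_period_s,
        duration_s=duration_s,
        offset_s=offset_s,
    )
    if duration_s is None:
        duration_s = stimulus.duration_s if stimulus is not None else 120.0
    trace = render_trace(
        events,
        params,
        sample_rate_hz=sample_rate_hz,
        duration_s=duration_s,
        participant_id=participant_id,
        stimulus=stimulus,
    )
    return events, trace


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Poor-synchronizer archetypes: number of failing trials per condition
#: (bounce-music of 6, clap-music of 6, bounce-metronome of 2,
#: clap-metronome of 2), mirroring the four observed behavioural profiles.
POOR_ARCHETYPES: dict[str, tuple[int, int, int, int]] = {
    "global_failure": (6, 6, 2, 2),
    "music_only_failure": (5, 4, 0, 0),
    "graded_failure": (4, 1, 0, 0),
    "bounce_only_failure": (5, 0, 1, 0),
}

# Timing parameters by trial role. Normal trials keep phase jitter at
# ~2% of the circle length with essentially no tempo mismatch; failing
# trials carry a 5-9% tempo mismatch, which keeps the produced frequency
# within the metrical-level tolerance but sweeps the relative phase
# around the circle, defeating the Rayleigh criterion.
_NORMAL_PHASE_NOISE_FRAC = 0.02
_FAIL_MISMATCH_RANGE = (0.05, 0.09)
_FAIL_PHASE_NOISE_FRAC = 0.08


@dataclass(frozen=True)
class CohortTrial:
    """One simulated trial plus its generating ground truth."""

    participant_id: str
    profile: str  # "normal" or a POOR_ARCHETYPES key
    movement_type: str
    stimulus: StimulusSpec
    params: SimParams
    truth_fails: bool  # generated with synchronization-defeating timing


@dataclass
class Cohort:
    """A simulated cohort: trial specs plus participant-level truth."""

    trials: list[CohortTrial]
    seed: int
    sample_rate_hz: float = 100.0

    @property
    def participants(self) -> dict[str, str]:
        """participant_id -> generating profile name."""
        return {t.participant_id: t.profile for t in self.trials}

    @property
    def truth_groups(self) -> dict[str, str]:
        """participant_id -> 'normal' | 'poor' ground truth."""
        return {
            pid: ("normal" if prof == "normal" else "poor")
            for pid, prof in self.participants.items()
        }

    def iter_traces(self) -> Iterator[tuple[CohortTrial, np.ndarray, AccelTrace]]:
        """Render each trial lazily: yields (spec, true events, trace)."""
        for trial in self.trials:
            events, trace = simulate_trial(
                trial.params,
                stimulus=trial.stimulus,
                sample_rate_hz=self.sample_rate_hz,
                participant_id=trial.participant_id,
            )
            yield trial, events, trace


def _trial_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0])


def _failing_conditions(
    archetype: str, stimuli: Sequence[StimulusSpec]
) -> set[tuple[str, str]]:
    """(movement, stimulus-name) pairs that fail for a poor archetype.

    Within music, the lowest-saliency stimuli fail first (beat saliency
    aids synchronization); metronome failures take the slower metronome
    first.
    """
    n_bm, n_cm, n_bn, n_cn = POOR_ARCHETYPES[archetype]
    music = sorted(
        (s for s in stimuli if not s.is_metronome), key=lambda s: s.beat_saliency_z
    )
    metro = sorted((s for s in stimuli if s.is_metronome), key=lambda s: s.tempo_bpm)
    fails: set[tuple[str, str]] = set()
    fails |= {("bounce", s.name) for s in music[:n_bm]}
    fails |= {("clap", s.name) for s in music[:n_cm]}
    fails |= {("bounce", s.name) for s in metro[:n_bn]}
    fails |= {("clap", s.name) for s in metro[:n_cn]}
    return fails


def simulate_cohort(
    n_normal: int,
    n_poor: int,
    stimuli: Optional[Sequence[StimulusSpec]] = None,
    seed: int = 0,
    sample_rate_hz: float = 100.0,
) -> Cohort:
    """Simulate a labeled cohort: 2 movement types x the stimulus set each.

    Normal synchronizers get near-zero tempo mismatch and small phase
    noise; poor synchronizers cycle through the four archetypes, with
    their failing trials generated under a 5-9% tempo mismatch. Bounce
    trials pick the two-beat level more often than clap trials, matching
    the tendency to bounce every other beat but clap every beat.
    """
    if n_normal + n_poor <= 0:
        raise ValueError("cohort must contain at least one participant")
    if n_normal < 0 or n_poor < 0:
        raise ValueError("participant counts must be non-negative")
    stimuli = list(default_stimulus_set() if stimuli is None else stimuli)

    rng = np.random.default_rng(seed)
    archetypes = list(POOR_ARCHETYPES)
    trials: list[CohortTrial] = []
    index = 0
    for p in range(n_normal + n_poor):
        pid = f"P{p + 1:03d}"
        if p < n_normal:
            profile = "normal"
            fails: set[tuple[str, str]] = set()
        else:
            profile = archetypes[(p - n_normal) % len(archetypes)]
            fails = _failing_conditions(profile, stimuli)
        for movement in ("bounce", "clap"):
            p_two_beat = 0.45 if movement == "bounce" else 0.12
            for stim in stimuli:
                level = 2 if rng.random() < p_two_beat else 1
                circle_ms = level * stim.ibi_ms_exact
                failing = (movement, stim.name) in fails
                if failing:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    mismatch = sign * rng.uniform(*_FAIL_MISMATCH_RANGE)
                    phase_noise = _FAIL_PHASE_NOISE_FRAC * circle_ms
                else:
                    mismatch = float(np.clip(rng.normal(0.0, 0.002), -0.005, 0.005))
                    phase_noise = _NORMAL_PHASE_NOISE_FRAC * circle_ms
                params = SimParams(
                    movement_type=movement,
                    level_multiplier=level,
                    tempo_mismatch=mismatch,
                    phase_noise_sd_ms=phase_noise,
                    amplitude=2.0 if movement == "bounce" else 8.0,
                    noise_sd=0.1,
                    seed=_trial_seed(seed, index),
                )
                trials.append(
                    CohortTrial(
                        participant_id=pid,
                        profile=profile,
                        movement_type=movement,
                        stimulus=stim,
                        params=params,
                        truth_fails=failing,
                    )
                )
                index += 1
    return Cohort(trials=trials, seed=seed, sample_rate_hz=sample_rate_hz)
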