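"""End-to-end trial and cohort analysis.

Per trial: trim the 10-s lead, determine the produced metrical level
with the two-half stability check, extract movement events, wrap them
onto the circle at the produced level, run the segmented Rayleigh tests
and the bimodality diagnostic, and classify the trial. Per cohort:
collect tidy trial tables and apply the participant rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .circular import (
    TooFewResponsesError,
    circular_variance,
    detect_bimodality,
    events_to_angles,
    rayleigh_test,
    segment_angles,
)
from .classify import (
    TrialClass,
    TrialRecord,
    classify_participant,
    classify_trial,
    synchronization_regularity,
)
from .config import DEFAULT_CONFIG, AnalysisConfig
from .events import (
    FlatTraceError,
    TooFewEventsError,
    discard_lead,
    extract_events,
)
from .level import MetricalLevelResult, check_level_stability
from .stimuli import StimulusSpec
from .synth import Cohort
from .trace import AccelTrace

__all__ = ["TrialAnalysis", "analyze_trial", "analyze_cohort", "classify_cohort"]


@dataclass
class TrialAnalysis:
    """Full outcome of one trial's analysis."""

    participant_id: str
    movement_type: str
    stimulus_name: str
    is_metronome: bool
    level: str
    level_multiplier: Optional[int]
    dominant_freq_hz: Optional[float]
    trial_class: str
    n_responses: int = 0
    segment_ps: tuple = ()
    bimodal: Optional[bool] = None
    circular_variance: Optional[float] = None
    sr: Optional[float] = None
    four_beat_matched: Optional[bool] = None

    def to_row(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "movement_type": self.movement_type,
            "stimulus_name": self.stimulus_name,
            "is_metronome": self.is_metronome,
            "level": self.level,
            "level_multiplier": self.level_multiplier,
            "dominant_freq_hz": self.dominant_freq_hz,
            "trial_class": self.trial_class,
            "n_responses": self.n_responses,
            "segment_ps": self.segment_ps,
            "bimodal": self.bimodal,
            "circular_variance": self.circular_variance,
            "sr": self.sr,
            "four_beat_matched": self.four_beat_matched,
        }

    def to_record(self) -> TrialRecord:
        return TrialRecord(
            movement_type=self.movement_type,
            stimulus_name=self.stimulus_name,
            is_metronome=self.is_metronome,
            trial_class=self.trial_class,
            four_beat_matched=self.four_beat_matched,
        )


def analyze_trial(
    trace: AccelTrace,
    stimulus: Optional[StimulusSpec] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> TrialAnalysis:
    """Analyze one paced trial from the raw trace.

    Events are detected on the full trace; only events inside the
    analysis window (t >= lead) are scored. Four-beat-level trials are
    not segmented — they get a whole-trial Rayleigh test on a 4*IBI
    circle whose outcome feeds the participant-level exclusion.
    """
    if stimulus is None:
        stimulus = trace.stimulus
    if stimulus is None:
        raise ValueError("paced-trial analysis requires a stimulus")

    base = TrialAnalysis(
        participant_id=trace.participant_id,
        movement_type=trace.movement_type,
        stimulus_name=stimulus.name,
        is_metronome=stimulus.is_metronome,
        level="indeterminate",
        level_multiplier=None,
        dominant_freq_hz=None,
        trial_class=TrialClass.UNUSABLE,
    )

    window = discard_lead(trace, config.discard_lead_s)
    try:
        level: MetricalLevelResult = check_level_stability(window, stimulus, config)
    except ValueError:
        return base
    base.level = level.level
    base.level_multiplier = level.level_multiplier
    base.dominant_freq_hz = level.dominant_freq_hz

    if level.level == "off_tempo":
        base.trial_class = TrialClass.OFF_TEMPO
        return base
    if level.level == "unstable":
        base.trial_class = TrialClass.UNSTABLE
        return base
    if level.level == "indeterminate":
        base.trial_class = TrialClass.UNUSABLE
        return base

    L = level.level_multiplier
    expected_period = L * stimulus.ibi_ms_exact / 1000.0
    try:
        events = extract_events(trace, expected_period_s=expected_period, config=config)
    except (FlatTraceError, TooFewEventsError):
        return base
    responses = events.after(config.discard_lead_s)
    base.n_responses = len(responses)
    if len(responses) < config.min_events:
        return base

    if level.level == "four_beat":
        angles = events_to_angles(
            responses.event_times, stimulus.ibi_ms_exact, 4, source=trace.participant_id
        )
        try:
            whole = rayleigh_test(angles, min_n=config.min_segment_n)
        except TooFewResponsesError:
            return base
        base.trial_class = TrialClass.FOUR_BEAT
        base.four_beat_matched = whole.p < config.alpha
        base.circular_variance = 1.0 - whole.R
        return base

    angles = events_to_angles(
        responses.event_times, stimulus.ibi_ms_exact, L, source=trace.participant_id
    )
    bimod = detect_bimodality(
        angles, alpha=config.bimodal_alpha, margin=config.bimodal_margin
    )
    base.bimodal = bimod.bimodal
    try:
        segments = [
            rayleigh_test(seg, min_n=config.min_segment_n)
            for seg in segment_angles(angles, L, min_segment_n=config.min_segment_n)
        ]
    except TooFewResponsesError:
        return base
    base.segment_ps = tuple(seg.p for seg in segments)
    base.trial_class = classify_trial(segments, bimodal=bimod.bimodal, alpha=config.alpha)
    V = circular_variance(angles)
    base.circular_variance = V
    if base.trial_class == TrialClass.NORMAL:
        base.sr = synchronization_regularity(V, floor=config.sr_floor)
    return base


def analyze_cohort(
    cohort: Cohort, config: AnalysisConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Run the full trial analysis over a simulated cohort (tidy table)."""
    rows = []
    for trial, _events, trace in cohort.iter_traces():
        result = analyze_trial(trace, stimulus=trial.stimulus, config=config)
        row = result.to_row()
        row["truth_profile"] = trial.profile
        row["truth_fails"] = trial.truth_fails
        rows.append(row)
    return pd.DataFrame(rows)


def classify_cohort(trials: pd.DataFrame) -> pd.DataFrame:
    """Participant classification from a tidy trial table."""
    rows = []
    for pid, grp in trials.groupby("participant_id"):
        records = [
            TrialRecord(
                movement_type=r.movement_type,
                stimulus_name=r.stimulus_name,
                is_metronome=bool(r.is_metronome),
                trial_class=r.trial_class,
                four_beat_matched=r.four_beat_matched,
            )
            for r in grp.itertuples()
        ]
        group, reason = classify_participant(records)
        n_poor = {
            m: int(
                sum(
                    1
                    for t in records
                    if t.movement_type == m
                    and not t.is_metronome
                    and t.trial_class in TrialClass.POOR_LIKE
                )
            )
            for m in ("bounce", "clap")
        }
        n_bimodal = {
            m: int(
                sum(
                    1
                    for t in records
                    if t.movement_type == m and t.trial_class == TrialClass.BIMODAL
                )
            )
            for m in ("bounce", "clap")
        }
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "exclusion_reason": reason,
                "n_poor_music_bounce": n_poor["bounce"],
                "n_poor_music_clap": n_poor["clap"],
                "n_bimodal_bounce": n_bimodal["bounce"],
                "n_bimodal_clap": n_bimodal["clap"],
            }
        )
    return pd.DataFrame(rows).set_index("participant_id").sort_index()
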