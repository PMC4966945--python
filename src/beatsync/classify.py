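"""Trial- and participant-level synchronization classification.

A trial is 'poor synchronization' when the Rayleigh test is
non-significant in any one of its segments, 'normal' when significant in
all of them; bimodal trials are excluded from scoring. A participant is
a Poor Synchronizer when at least 3 of the 6 music trials fail in at
least one movement type; participants with 3+ bimodal trials of 8 in a
movement type, or who period-match at the four-beat level throughout,
are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .circular import RayleighResult

__all__ = [
    "TrialClass",
    "TrialRecord",
    "ParticipantProfile",
    "classify_trial",
    "classify_participant",
    "synchronization_regularity",
    "trial_accounting",
    "accounting_from_counts",
]


class TrialClass:
    """String constants for trial outcomes."""

    NORMAL = "normal"
    POOR = "poor"
    BIMODAL = "bimodal"
    FOUR_BEAT = "four_beat"
    OFF_TEMPO = "off_tempo"
    UNSTABLE = "unstable"
    UNUSABLE = "unusable"

    #: classes counting as failed synchronization for the participant rule
    POOR_LIKE = (POOR, OFF_TEMPO, UNSTABLE)


@dataclass(frozen=True)
class TrialRecord:
    """Minimal per-trial information needed for participant classification."""

    movement_type: str
    stimulus_name: str
    is_metronome: bool
    trial_class: str
    four_beat_matched: Optional[bool] = None


@dataclass
class ParticipantProfile:
    """Participant-level outcome."""

    participant_id: str
    group: str  # normal_synchronizer | poor_synchronizer | excluded
    exclusion_reason: str = "none"  # four_beat_mover | bimodal_overload | none
    n_poor_music: dict = field(default_factory=dict)  # movement -> count
    n_bimodal: dict = field(default_factory=dict)  # movement -> count


def classify_trial(
    segments: Sequence[RayleighResult],
    bimodal: Optional[bool] = False,
    alpha: float = 0.05,
) -> str:
    """Classify one trial from its segment-wise Rayleigh tests.

    Bimodal trials are excluded outright; otherwise the trial is normal
    iff every segment's Rayleigh test is significant at `alpha`, and poor
    if any one segment is not.
    """
    if bimodal:
        return TrialClass.BIMODAL
    if not segments:
        raise ValueError("no segments to classify")
    if all(seg.p < alpha for seg in segments):
        return TrialClass.NORMAL
    return TrialClass.POOR


def classify_participant(
    trials: Sequence[TrialRecord],
    n_music_threshold: int = 3,
    n_bimodal_threshold: int = 3,
) -> tuple[str, str]:
    """Apply the participant-level decision rules.

    In order of precedence:

    1. four_beat_mover — the participant's determinable trials are
       predominantly at the four-beat level and mostly period-matched
       there: their behaviour is not comparable to the group and they
       are excluded.
    2. bimodal_overload — at least `n_bimodal_threshold` of the 8 trials
       in either movement type are bimodal: too much missing data.
    3. poor_synchronizer — at least `n_music_threshold` of the 6 music
       trials in either movement type failed (poor, off-tempo or
       unstable trials all count as failures here).
    4. normal_synchronizer otherwise.

    Returns (group, exclusion_reason).
    """
    movements = {t.movement_type for t in trials}
    if movements != {"bounce", "clap"}:
        raise ValueError(
            f"incomplete profile: need both movement types, got {sorted(movements)}"
        )

    four_beat = [t for t in trials if t.trial_class == TrialClass.FOUR_BEAT]
    determinable = [
        t
        for t in trials
        if t.trial_class
        in (TrialClass.NORMAL, TrialClass.POOR, TrialClass.FOUR_BEAT)
    ]
    if determinable and len(four_beat) > len(determinable) / 2:
        matched = [t for t in four_beat if t.four_beat_matched]
        if len(matched) > len(four_beat) / 2:
            return "excluded", "four_beat_mover"

    for movement in ("bounce", "clap"):
        n_bimodal = sum(
            1
            for t in trials
            if t.movement_type == movement and t.trial_class == TrialClass.BIMODAL
        )
        if n_bimodal >= n_bimodal_threshold:
            return "excluded", "bimodal_overload"

    for movement in ("bounce", "clap"):
        n_poor_music = sum(
            1
            for t in trials
            if t.movement_type == movement
            and not t.is_metronome
            and t.trial_class in TrialClass.POOR_LIKE
        )
        if n_poor_music >= n_music_threshold:
            return "poor_synchronizer", "none"

    return "normal_synchronizer", "none"


def synchronization_regularity(V: float, floor: float = 1e-6) -> float:
    """Synchronization regularity SR = -log10(max(V, floor)).

    The circular variance of normal trials is log-normally distributed;
    the sign-flipped log makes higher values mean more regular. The
    floor caps SR at 6 for (numerically) perfect trials.
    """
    if not 0.0 <= V <= 1.0:
        raise ValueError(f"circular variance must lie in [0, 1], got {V}")
    return -math.log10(max(V, floor))


def accounting_from_counts(
    total: int, level_excluded: int, bimodal: int, poor: int
) -> dict:
    """Poor-trial accounting for one movement type.

    The poor percentage is taken over classifiable trials only:
    poor / (total - level_excluded - bimodal) * 100, to one decimal.
    """
    denom = total - level_excluded - bimodal
    if denom <= 0:
        raise ValueError("no classifiable trials")
    normal = denom - poor
    return {
        "total": total,
        "level_excluded": level_excluded,
        "bimodal": bimodal,
        "poor": poor,
        "normal": normal,
        "poor_pct": round(100.0 * poor / denom, 1),
    }


def trial_accounting(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-movement-type trial accounting from a tidy trial table.

    Expects columns ``movement_type`` and ``trial_class``. Off-tempo,
    unstable and unusable trials count as level-excluded here (they never
    reached circular scoring); the poor percentage is over classifiable
    trials only.
    """
    rows = []
    for movement, grp in trials.groupby("movement_type"):
        cls = grp["trial_class"]
        level_excluded = int(
            cls.isin(
                [
                    TrialClass.FOUR_BEAT,
                    TrialClass.OFF_TEMPO,
                    TrialClass.UNSTABLE,
                    TrialClass.UNUSABLE,
                ]
            ).sum()
        )
        rows.append(
            {
                "movement_type": movement,
                **accounting_from_counts(
                    total=len(grp),
                    level_excluded=level_excluded,
                    bimodal=int((cls == TrialClass.BIMODAL).sum()),
                    poor=int((cls == TrialClass.POOR).sum()),
                ),
            }
        )
    return pd.DataFrame(rows).set_index("movement_type")
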