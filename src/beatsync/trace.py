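"""The 3-axis acceleration trace container and its plain-text file format.

Traces model a trunk- or forearm-mounted accelerometer sampled at a
nominal 100 Hz. Acceleration is simulated and analyzed about a zero
baseline (gravity removed): the pipeline only needs relative dynamics.

File format: a ``#``-prefixed key-value header block followed by a
whitespace-delimited table ``time_s ax ay az``, one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .stimuli import StimulusSpec

__all__ = ["AccelTrace", "write_trace", "read_trace"]


@dataclass
class AccelTrace:
    """A sampled 3-axis acceleration recording for one trial.

    Attributes
    ----------
    data : ndarray, shape (n_samples, 3)
        Acceleration (ax, ay, az) in m/s^2, gravity-removed.
    sample_rate_hz : float
        Sampling rate; the study's capture ran at 100 frames/s.
    participant_id, movement_type : str
        Trial metadata; movement_type is ``"bounce"`` or ``"clap"``.
    stimulus : StimulusSpec or None
        The pacing stimulus, or None for self-paced production.
    t0 : float
        Time of the first sample in seconds. Stays 0 for raw traces and
        becomes the lead length after discarding the lead-in, so
        timestamps are preserved rather than re-zeroed.
    """

    data: np.ndarray
    sample_rate_hz: float = 100.0
    participant_id: str = ""
    movement_type: str = "bounce"
    stimulus: Optional[StimulusSpec] = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError(f"data must have shape (n, 3), got {self.data.shape}")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trace contains non-finite values")
        if self.movement_type not in ("bounce", "clap"):
            raise ValueError(f"unknown movement_type {self.movement_type!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate_hz

    def slice_time(self, start_s: float, stop_s: Optional[float] = None) -> "AccelTrace":
        """Restrict the trace to t in [start_s, stop_s), keeping timestamps."""
        t = self.times
        mask = t >= start_s if stop_s is None else (t >= start_s) & (t < stop_s)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError("time slice retains no samples")
        return replace(self, data=self.data[idx], t0=float(t[idx[0]]))


def write_trace(trace: AccelTrace, path) -> None:
    """Write a trace to the columnar text format with a metadata header."""
    path = Path(path)
    stim = trace.stimulus.name if trace.stimulus is not None else "self-paced"
    header = (
        f"# participant: {trace.participant_id}\n"
        f"# movement: {trace.movement_type}\n"
        f"# stimulus: {stim}\n"
        f"# sample_rate_hz: {trace.sample_rate_hz:g}\n"
        f"# t0_s: {trace.t0:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("time_s ax ay az\n")
        t = trace.times
        for i in range(trace.n_samples):
            ax, ay, az = trace.data[i]
            fh.write(f"{t[i]:.3f} {ax:.6f} {ay:.6f} {az:.6f}\n")


def read_trace(path, stimuli: Optional[dict[str, StimulusSpec]] = None) -> AccelTrace:
    """Read a trace file; resolve its stimulus name against `stimuli` if given."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("#").partition(":")
                meta[key.strip()] = value.strip()
            elif line.startswith("time_s"):
                continue
            else:
                rows.append([float(x) for x in line.split()])
    arr = np.asarray(rows, dtype=float)
    stim_name = meta.get("stimulus", "self-paced")
    stimulus = None
    if stim_name != "self-paced" and stimuli is not None:
        stimulus = stimuli.get(stim_name)
    return AccelTrace(
        data=arr[:, 1:4],
        sample_rate_hz=float(meta.get("sample_rate_hz", 100.0)),
        participant_id=meta.get("participant", ""),
        movement_type=meta.get("movement", "bounce"),
        stimulus=stimulus,
        t0=float(meta.get("t0_s", arr[0, 0] if arr.size else 0.0)),
    )
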