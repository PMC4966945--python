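"""Analysis configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

__all__ = ["AnalysisConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and filter constants used across the pipeline.

    alpha : significance level of the segment-wise Rayleigh tests.
    discard_lead_s : lead-in seconds dropped before scoring (stimulus
        onset transient; 115 s trials leave 105 s of data).
    level_tolerance : maximal relative deviation of the produced
        frequency from a candidate metrical level's target frequency.
    bimodal_alpha / bimodal_margin : the axial-doubling bimodality rule —
        flag when the Rayleigh test on doubled angles is significant and
        the doubled-angle resultant exceeds the plain one by the margin.
    sr_floor : floor applied to circular variance before the log in the
        synchronization-regularity score (caps SR at 6).
    min_events : fewer detected events than this makes a trial unusable.
    min_segment_n : minimum responses per segment for a Rayleigh test.
    bounce_band_hz : band-pass for bounce event detection.
    bounce_min_sep_frac : minimum peak separation as a fraction of the
        expected movement period.
    bounce_prominence_frac : peak prominence threshold as a fraction of
        the filtered-signal SD.
    clap_highpass_hz / clap_threshold_sds / clap_refractory_s : clap
        transient detection — high-pass corner, threshold in robust noise
        SDs, and refractory window between impacts.
    spectrum_band_hz : search band for the dominant movement frequency.
    spectrum_peak_ratio : dominant peak must exceed this multiple of the
        in-band median power, else the spectrum is indeterminate.
    """

    alpha: float = 0.05
    discard_lead_s: float = 10.0
    level_tolerance: float = 0.10
    bimodal_alpha: float = 0.05
    bimodal_margin: float = 0.2
    sr_floor: float = 1e-6
    min_events: int = 8
    min_segment_n: int = 4
    bounce_band_hz: tuple[float, float] = (0.3, 5.0)
    bounce_min_sep_frac: float = 0.4
    bounce_prominence_frac: float = 0.5
    clap_highpass_hz: float = 10.0
    clap_threshold_sds: float = 4.0
    clap_refractory_s: float = 0.150
    clap_rise_s: float = 0.001
    clap_decay_s: float = 0.030
    clap_peak_floor_frac: float = 0.2
    spectrum_band_hz: tuple[float, float] = (0.2, 4.0)
    # raw-periodogram bins are exponentially distributed: the in-band
    # maximum of pure noise sits near ln(n_bins)/ln(2) ~ 9-14 times the
    # median, so the indeterminate threshold must clear that
    spectrum_peak_ratio: float = 20.0

    def to_file(self, path) -> None:
        """Write the configuration as flat ``key = value`` lines."""
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, tuple):
                value = ",".join(f"{v:g}" for v in value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if "," in value:
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif key in ("min_events", "min_segment_n"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


DEFAULT_CONFIG = AnalysisConfig()
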