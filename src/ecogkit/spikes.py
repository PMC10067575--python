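"""Interictal spike detection and per-block spike-rate statistics.

Detection runs on the 0.5-60 Hz band-passed ECoG of one analysis block.
The threshold is a multiple (4-5, default 4.5) of the block's standard
deviation.  An event opens at the first sample whose absolute value
exceeds the threshold; its window spans from 50 ms before the crossing
to 250 ms total.  Crossings inside an open window belong to the same
event (biphasic transients count once), and a new event may open only
after the window closes, so event windows never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SizeError

__all__ = ["SpikeEvent", "SpikeStats", "detect_spikes", "spike_change"]

MAX_EVENT_DURATION_S = 0.25
PRETRIGGER_S = 0.05


@dataclass(frozen=True)
class SpikeEvent:
    """One detected transient.

    time_s
        Trigger time (first threshold crossing), in seconds from the
        start of the analysed trace.  Triggers lead peaks: that is what
        the 50 ms pretrigger is for.
    peak_time_s
        Time of the extremum within the event window.
    peak_amplitude
        Signed extremum within the event window, uV.
    duration_s
        Span from window start to the last supra-threshold sample,
        capped at the 250 ms window.
    """

    time_s: float
    peak_time_s: float
    peak_amplitude: float
    duration_s: float


@dataclass
class SpikeStats:
    """Event count and rate for one analysis block."""

    n_events: int
    block_duration_s: float
    threshold_used: float
    threshold_multiplier: float

    @property
    def rate_per_min(self) -> float:
        return 60.0 * self.n_events / self.block_duration_s

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "block_duration_s": self.block_duration_s,
            "rate_per_min": self.rate_per_min,
            "threshold_used": self.threshold_used,
            "threshold_multiplier": self.threshold_multiplier,
        }


def events_to_frame(events: list[SpikeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.time_s, e.peak_time_s, e.peak_amplitude, e.duration_s) for e in events],
        columns=["time_s", "peak_time_s", "peak_amplitude_uv", "duration_s"],
    )


def detect_spikes(x, sample_rate_hz: float, threshold_multiplier: float = 4.5,
                  pretrigger_s: float = PRETRIGGER_S,
                  max_duration_s: float = MAX_EVENT_DURATION_S,
                  polarity: str = "both",
                  exclude_times_s: list[float] | None = None,
                  ) -> tuple[list[SpikeEvent], SpikeStats]:
    """Threshold detector on a band-passed block trace.

    ``x`` must already be 0.5-60 Hz band-passed (see
    ``preprocess.SPIKE_BANDPASS``).  ``threshold_multiplier`` must lie in
    the accepted 4-5 range.  ``polarity`` is ``"both"`` (|x| crossings,
    default — interictal spikes are biphasic), ``"positive"`` or
    ``"negative"``.  ``exclude_times_s`` stands in for manual artifact
    rejection: events whose trigger falls within one window length of a
    listed time are dropped before counting.
    """
    x = np.asarray(x, dtype=float)
    if not 4.0 <= threshold_multiplier <= 5.0:
        raise ValueError("threshold_multiplier must lie in [4, 5]")
    window_n = int(round(max_duration_s * sample_rate_hz))
    pre_n = int(round(pretrigger_s * sample_rate_hz))
    if x.size < window_n:
        raise SizeError(f"block of {x.size} samples shorter than one {max_duration_s} s window")

    sd = float(np.std(x))
    threshold = threshold_multiplier * sd

    if polarity == "both":
        drive = np.abs(x)
    elif polarity == "positive":
        drive = x
    elif polarity == "negative":
        drive = -x
    else:
        raise ValueError(f"unknown polarity {polarity!r}")

    crossings = np.flatnonzero(drive > threshold) if threshold > 0 else np.array([], int)

    events: list[SpikeEvent] = []
    window_close = -1
    for i in crossings:
        if i < window_close:
            continue  # belongs to the open event
        start = i - pre_n
        end = start + window_n  # exclusive
        lo, hi = max(start, 0), min(end, x.size)
        seg = x[lo:hi]
        peak_idx = int(np.argmax(np.abs(seg)))
        peak = float(seg[peak_idx])
        supra = np.flatnonzero(drive[lo:hi] > threshold)
        duration = (supra[-1] + 1) / sample_rate_hz if supra.size else 0.0
        duration = min(duration + (lo - start) / sample_rate_hz, max_duration_s)
        events.append(SpikeEvent(time_s=i / sample_rate_hz,
                                 peak_time_s=(lo + peak_idx) / sample_rate_hz,
                                 peak_amplitude=peak,
                                 duration_s=duration))
        window_close = end

    if exclude_times_s:
        excl = np.asarray(exclude_times_s, dtype=float)
        events = [e for e in events
                  if np.min(np.abs(excl - e.time_s)) > max_duration_s]

    stats = SpikeStats(
        n_events=len(events),
        block_duration_s=x.size / sample_rate_hz,
        threshold_used=threshold,
        threshold_multiplier=threshold_multiplier,
    )
    return events, stats


def spike_change(pre_stats: SpikeStats, post_stats: SpikeStats) -> float:
    """Post/pre spike-rate ratio; undefined (error) when the pre rate is zero."""
    if pre_stats.rate_per_min <= 0:
        raise DegenerateInputError(
            "pre-drug spike rate is zero; change ratio undefined "
            "(subject excluded from ratio analyses)"
        )
    return post_stats.rate_per_min / pre_stats.rate_per_min
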