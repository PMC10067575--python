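"""EMG enveloping and the filters feeding epoch selection and spike detection.

Movement epochs are rejected from spectral analysis using the enveloped
electromyogram.  The envelope is built from the Teager-Kaiser Energy
Operator (TKEO),

    psi[n] = x[n]^2 - x[n-1] * x[n+1],

an instantaneous-energy estimate that responds to both amplitude and
frequency of muscle activity, then rectified and smoothed with a 3 Hz
zero-phase low-pass.  ECoG channels destined for spike detection pass
through a 0.5-60 Hz band-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import FilterError, SizeError

__all__ = ["FilterSpec", "EnvelopeTrace", "tkeo", "envelope_emg", "apply_filter"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description, representable in the pipeline config.

    kind
        ``"lowpass"`` (one cutoff) or ``"bandpass"`` (two cutoffs, low < high).
    cutoffs_hz
        Corner frequencies in Hz; validated against Nyquist at apply time.
    order
        Filter order (per pass; zero-phase application doubles the
        effective order).
    zero_phase
        Forward-backward application (no group delay) when True.
    """

    kind: str
    cutoffs_hz: tuple[float, ...]
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if self.kind not in ("lowpass", "bandpass"):
            raise FilterError(f"unknown filter kind {self.kind!r}")
        cut = tuple(float(c) for c in self.cutoffs_hz)
        object.__setattr__(self, "cutoffs_hz", cut)
        n_expected = 1 if self.kind == "lowpass" else 2
        if len(cut) != n_expected:
            raise FilterError(
                f"{self.kind} filter needs {n_expected} cutoff(s), got {len(cut)}"
            )
        if any(c <= 0 for c in cut):
            raise FilterError("cutoff frequencies must be positive")
        if self.kind == "bandpass" and not cut[0] < cut[1]:
            raise FilterError("bandpass requires low < high cutoff")
        if self.order < 1:
            raise FilterError("filter order must be >= 1")

    def sos(self, sample_rate_hz: float) -> np.ndarray:
        nyq = sample_rate_hz / 2.0
        if max(self.cutoffs_hz) >= nyq:
            raise FilterError(
                f"cutoff {max(self.cutoffs_hz)} Hz >= Nyquist {nyq} Hz"
            )
        btype = "low" if self.kind == "lowpass" else "bandpass"
        wn = self.cutoffs_hz[0] if self.kind == "lowpass" else self.cutoffs_hz
        return signal.butter(self.order, wn, btype=btype, fs=sample_rate_hz, output="sos")


#: 0.5-60 Hz band-pass applied to ECoG before spike detection.
SPIKE_BANDPASS = FilterSpec(kind="bandpass", cutoffs_hz=(0.5, 60.0))


@dataclass
class EnvelopeTrace:
    """Rectified-and-smoothed TKEO output; arbitrary energy units, >= 0."""

    samples: np.ndarray
    sample_rate_hz: float
    source_label: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("envelope values must be nonnegative")


def tkeo(x) -> np.ndarray:
    """Teager-Kaiser energy psi[n] = x[n]^2 - x[n-1]*x[n+1].

    The first and last samples, undefined by the formula, replicate their
    nearest interior value so the output aligns sample-for-sample with the
    input.  Exactly quadratic: ``tkeo(c*x) == c**2 * tkeo(x)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise SizeError(f"tkeo needs >= 3 samples, got {x.size}")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def envelope_emg(x, sample_rate_hz: float, cutoff_hz: float = 3.0,
                 source_label: str = "emg") -> EnvelopeTrace:
    """EMG envelope: |TKEO(x)| smoothed by a zero-phase low-pass.

    The TKEO output is rectified (absolute value -- TKEO can go negative on
    noise) and smoothed with a 4th-order Butterworth low-pass at
    ``cutoff_hz`` applied forward-backward.  Filter ringing below zero is
    floored at 0 so the trace remains a valid energy envelope.
    """
    if cutoff_hz >= sample_rate_hz / 2.0:
        raise FilterError(f"cutoff {cutoff_hz} Hz >= Nyquist {sample_rate_hz / 2.0} Hz")
    rectified = np.abs(tkeo(x))
    spec = FilterSpec(kind="lowpass", cutoffs_hz=(cutoff_hz,))
    # even padding: odd reflection undershoots below zero at the edges of a
    # strictly positive trace, which would poison the harmonic mean later
    smoothed = signal.sosfiltfilt(spec.sos(sample_rate_hz), rectified, padtype="even")
    return EnvelopeTrace(np.maximum(smoothed, 0.0), sample_rate_hz, source_label)


def apply_filter(x, spec: FilterSpec, sample_rate_hz: float) -> np.ndarray:
    """Apply ``spec`` to ``x``; zero-phase (sosfiltfilt) when requested.

    Output length always equals input length.
    """
    x = np.asarray(x, dtype=float)
    sos = spec.sos(sample_rate_hz)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)
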