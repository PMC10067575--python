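"""Epoching, Welch power spectral density, band powers, coherence.

The analysis grid divides each 1.5-h block into 5-s epochs advanced by
2.5 s (50% epoch overlap).  Per-epoch PSDs use Welch's method with
Hann-windowed, 50%-overlapping segments; the default segment length is
1024 samples at 1 kHz, giving a 0.9766 Hz bin so the canonical rodent
band edges (0.9-3.9, 4.8-7.8, 8.7-11.7, 12.6-29.2, 30.2-99.6 Hz) fall on
bin centers.  Interhemispheric coupling is the magnitude-squared
coherence

    C(f) = |<P_LR>|^2 / (<P_LL> <P_RR>),

with cross- and auto-spectra pooled over every Welch segment of every
supplied epoch before the ratio is formed (per-epoch single-segment
coherence is identically 1 and carries no information).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, SizeError
from .io_signals import AnalysisBlock, Recording

__all__ = [
    "BandScheme",
    "EpochGrid",
    "PSDResult",
    "BandPowers",
    "CoherenceSpectrum",
    "default_nperseg",
    "make_epochs",
    "epoch_matrix",
    "welch_psd",
    "band_powers",
    "coherence_spectrum",
]

log = logging.getLogger(__name__)

EPOCH_LEN_S = 5.0
EPOCH_STEP_S = 2.5

_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands with inclusive edges in Hz.

    A PSD bin belongs to a band iff its center frequency lies inside the
    inclusive edges; the narrow gaps between adjacent default bands
    (3.9->4.8 Hz etc.) therefore belong to no band and are excluded from
    "total power".
    """

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        prev_high = 0.0
        for name, low, high in self.bands:
            if not (0 < low < high):
                raise ValueError(f"band {name!r}: need 0 < low < high")
            if low < prev_high:
                raise ValueError(f"band {name!r} overlaps its predecessor")
            prev_high = high

    @classmethod
    def default(cls) -> "BandScheme":
        return cls(bands=(
            ("delta", 0.9, 3.9),
            ("theta", 4.8, 7.8),
            ("alpha", 8.7, 11.7),
            ("beta", 12.6, 29.2),
            ("gamma", 30.2, 99.6),
        ))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        for n, low, high in self.bands:
            if n == name:
                return low, high
        raise KeyError(name)

    def mask(self, frequencies_hz: np.ndarray, name: str) -> np.ndarray:
        low, high = self.edges(name)
        return (frequencies_hz >= low - _EDGE_EPS) & (frequencies_hz <= high + _EDGE_EPS)

    def check_alignment(self, bin_width_hz: float, tol_fraction: float = 0.2) -> None:
        """Warn when any band edge misses the PSD bin grid by > tol * bin."""
        for name, low, high in self.bands:
            for edge in (low, high):
                offset = abs(edge / bin_width_hz - round(edge / bin_width_hz))
                if offset > tol_fraction:
                    log.warning(
                        "band %s edge %.4g Hz is %.0f%% of a bin off the %.4g Hz grid",
                        name, edge, 100 * offset, bin_width_hz,
                    )


def default_nperseg(sample_rate_hz: float) -> int:
    """Segment length giving the 0.9766 Hz bin grid (1024 samples at 1 kHz)."""
    return max(8, int(round(sample_rate_hz * 1024.0 / 1000.0)))


@dataclass(frozen=True)
class EpochGrid:
    """Starts of the 5-s analysis epochs inside one block (absolute seconds)."""

    starts_s: np.ndarray
    block: AnalysisBlock
    epoch_len_s: float = EPOCH_LEN_S
    step_s: float = EPOCH_STEP_S

    @property
    def n_epochs(self) -> int:
        return len(self.starts_s)


def make_epochs(block: AnalysisBlock, recording: Recording | None = None,
                epoch_len_s: float = EPOCH_LEN_S, step_s: float = EPOCH_STEP_S) -> EpochGrid:
    """Lay the sliding-epoch grid over a block.

    Epochs start at ``block.start_s``, advance by ``step_s``, and the last
    epoch must fit entirely inside the block.
    """
    span = block.duration_s
    if span + 1e-9 < epoch_len_s:
        raise SizeError(f"block of {span} s cannot hold a {epoch_len_s} s epoch")
    if recording is not None and block.end_s > recording.duration_s + 1e-9:
        raise SizeError("block extends past the recording end")
    n = int(np.floor((span - epoch_len_s) / step_s + 1e-9)) + 1
    starts = block.start_s + step_s * np.arange(n)
    return EpochGrid(starts_s=starts, block=block, epoch_len_s=epoch_len_s, step_s=step_s)


def epoch_matrix(x: np.ndarray, grid: EpochGrid, sample_rate_hz: float) -> np.ndarray:
    """Stack the grid's epochs of signal ``x`` into an (n_epochs, n_samples) array.

    ``x`` is the full-recording trace; epoch starts are absolute times.
    """
    n_ep = int(round(grid.epoch_len_s * sample_rate_hz))
    starts = np.round(grid.starts_s * sample_rate_hz).astype(int)
    idx = starts[:, None] + np.arange(n_ep)[None, :]
    if idx.max() > x.size:
        raise SizeError("epoch grid extends past the end of the signal")
    return x[idx]


@dataclass
class PSDResult:
    """One-sided Welch PSD in uV^2/Hz on the segment-transform frequency grid."""

    frequencies_hz: np.ndarray
    density: np.ndarray
    n_segments: int
    segment_len_samples: int

    @property
    def bin_width_hz(self) -> float:
        return float(self.frequencies_hz[1] - self.frequencies_hz[0])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"frequency_hz": self.frequencies_hz, "psd_uv2_per_hz": self.density})


def _segment_count(n_samples: int, nperseg: int, overlap_fraction: float) -> int:
    step = nperseg - int(nperseg * overlap_fraction)
    return (n_samples - nperseg) // step + 1


def welch_psd(epoch_samples, sample_rate_hz: float, segment_len_samples: int | None = None,
              overlap_fraction: float = 0.5) -> PSDResult:
    """Welch PSD of one epoch (Hann window, 50% overlap by default).

    The one-sided density is normalized so its integral over frequency
    equals the signal's mean squared amplitude (no detrending).  Accepts a
    1-D epoch or a 2-D (n_epochs, n_samples) stack, in which case the
    density is the arithmetic mean across epochs.
    """
    x = np.asarray(epoch_samples, dtype=float)
    if segment_len_samples is None:
        segment_len_samples = default_nperseg(sample_rate_hz)
    if x.shape[-1] < segment_len_samples:
        raise SizeError(
            f"epoch of {x.shape[-1]} samples shorter than segment {segment_len_samples}"
        )
    noverlap = int(segment_len_samples * overlap_fraction)
    freqs, pxx = signal.welch(
        x, fs=sample_rate_hz, window="hann", nperseg=segment_len_samples,
        noverlap=noverlap, detrend=False, scaling="density", axis=-1,
    )
    n_seg = _segment_count(x.shape[-1], segment_len_samples, overlap_fraction)
    if x.ndim == 2:
        pxx = pxx.mean(axis=0)
        n_seg *= x.shape[0]
    return PSDResult(frequencies_hz=freqs, density=pxx, n_segments=n_seg,
                     segment_len_samples=segment_len_samples)


@dataclass
class BandPowers:
    """Absolute (uV^2) and relative (%) power per band.

    ``total`` sums the five bands only; inter-band gap power is excluded.
    Relative powers always sum to 100.
    """

    absolute: dict[str, float]
    total: float
    relative: dict[str, float]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "band": list(self.absolute),
            "absolute_uv2": list(self.absolute.values()),
            "relative_pct": list(self.relative.values()),
        })


def band_powers(psd: PSDResult, scheme: BandScheme | None = None) -> BandPowers:
    """Integrate the PSD over each band (bin-center membership, inclusive edges)."""
    scheme = scheme or BandScheme.default()
    df = psd.bin_width_hz
    absolute = {}
    for name in scheme.names:
        m = scheme.mask(psd.frequencies_hz, name)
        absolute[name] = float(psd.density[m].sum() * df)
    total = float(sum(absolute.values()))
    if total <= 0:
        raise DegenerateInputError("total band power is zero; relative powers undefined")
    relative = {name: 100.0 * p / total for name, p in absolute.items()}
    return BandPowers(absolute=absolute, total=total, relative=relative)


@dataclass
class CoherenceSpectrum:
    """Frequency-resolved interhemispheric coherence in [0, 1]."""

    frequencies_hz: np.ndarray
    coherence: np.ndarray
    band_means: dict[str, float]
    n_segments: int
    kind: str = "msc"

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"frequency_hz": self.frequencies_hz, "coherence": self.coherence})


def coherence_spectrum(left, right, sample_rate_hz: float,
                       segment_len_samples: int | None = None,
                       overlap_fraction: float = 0.5,
                       scheme: BandScheme | None = None,
                       kind: str = "msc",
                       force_single_segment: bool = False) -> CoherenceSpectrum:
    """Coherence between two channels from matched epoch stacks.

    ``left`` and ``right`` are time-aligned (n_epochs, n_samples) arrays
    (a single 1-D epoch is also accepted).  Cross- and auto-spectra are
    averaged over all Welch segments of all epochs, then
    C(f) = |<P_LR>|^2 / (<P_LL><P_RR>).  ``kind="magnitude"`` returns the
    square root (non-squared coherence).  A single total segment makes the
    estimate identically 1; that degenerate case raises unless
    ``force_single_segment``.
    """
    scheme = scheme or BandScheme.default()
    L = np.atleast_2d(np.asarray(left, dtype=float))
    R = np.atleast_2d(np.asarray(right, dtype=float))
    if L.shape != R.shape:
        raise SizeError(f"left {L.shape} and right {R.shape} epoch stacks differ")
    if segment_len_samples is None:
        segment_len_samples = default_nperseg(sample_rate_hz)
    if L.shape[-1] < segment_len_samples:
        raise SizeError("epochs shorter than one Welch segment")
    noverlap = int(segment_len_samples * overlap_fraction)
    per_epoch = _segment_count(L.shape[-1], segment_len_samples, overlap_fraction)
    n_total = per_epoch * L.shape[0]
    if n_total < 2 and not force_single_segment:
        raise DegenerateInputError(
            "coherence from a single Welch segment is identically 1; "
            "supply more/longer epochs or pass force_single_segment=True"
        )

    kw = dict(fs=sample_rate_hz, window="hann", nperseg=segment_len_samples,
              noverlap=noverlap, detrend=False, scaling="density", axis=-1)
    freqs, pxy = signal.csd(L, R, **kw)
    _, pxx = signal.welch(L, **kw)
    _, pyy = signal.welch(R, **kw)
    pxy_m = pxy.mean(axis=0)
    pxx_m = pxx.mean(axis=0)
    pyy_m = pyy.mean(axis=0)

    denom = pxx_m * pyy_m
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.abs(pxy_m) ** 2 / denom
    msc = np.where(denom > 0, msc, 0.0)
    msc = np.clip(msc, 0.0, 1.0)
    if kind == "magnitude":
        coh = np.sqrt(msc)
    elif kind == "msc":
        coh = msc
    else:
        raise ValueError(f"unknown coherence kind {kind!r}")

    band_means = {}
    for name in scheme.names:
        m = scheme.mask(freqs, name)
        band_means[name] = float(coh[m].mean()) if m.any() else float("nan")
    return CoherenceSpectrum(frequencies_hz=freqs, coherence=coh,
                             band_means=band_means, n_segments=n_total, kind=kind)
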