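"""Selection of artifact-free awake-immobile epochs.

Three conditions, all evaluated against thresholds computed over the
whole 1.5-h block, must hold simultaneously (strict inequalities):

i)   the epoch's delta power is below the median delta power,
ii)  its theta/delta ratio is below the 75th percentile of ratios,
iii) the enveloped EMG stays below twice the block-wide harmonic mean of
     the envelope throughout the entire epoch.

Condition i removes slow-wave-sleep epochs, ii removes exploratory
theta-dominated epochs, iii removes movement; what remains is quiet
wakefulness.  A block is usable only when at least 100 epochs survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SizeError
from .preprocess import EnvelopeTrace
from .spectral import BandScheme, EpochGrid, epoch_matrix

__all__ = [
    "EpochFeatures",
    "SelectionResult",
    "harmonic_mean",
    "effective_envelope_floor",
    "compute_epoch_features",
    "select_epochs",
    "epoch_qc",
    "ENVELOPE_FLOOR",
]

#: absolute floor applied to envelope samples before the harmonic mean,
#: which is undefined at zero; far below any physical EMG energy level.
ENVELOPE_FLOOR = 1e-12

#: relative floor: zero-clipped low-pass ringing (isolated samples at 0
#: next to movement bursts) would otherwise dominate sum(1/x) and collapse
#: the harmonic mean; 1% of the block median leaves the limit essentially
#: unchanged while keeping the statistic meaningful
ENVELOPE_FLOOR_MEDIAN_FRACTION = 0.01

QC_MIN_EPOCHS = 100


def effective_envelope_floor(envelope_samples) -> float:
    """Floor used for the block harmonic mean: max of the absolute floor
    and 1% of the block's median envelope."""
    med = float(np.median(envelope_samples))
    return max(ENVELOPE_FLOOR, ENVELOPE_FLOOR_MEDIAN_FRACTION * med)


@dataclass(frozen=True)
class EpochFeatures:
    """Per-epoch quantities entering the three selection conditions."""

    epoch_index: int
    delta_power: float            # uV^2
    theta_delta_ratio: float      # dimensionless
    emg_envelope_max_ratio: float  # epoch max envelope / block harmonic mean


@dataclass
class SelectionResult:
    """Accepted epoch indices, the thresholds applied, and QC status."""

    accepted: set[int]
    thresholds: dict[str, float]
    rejections: dict[str, int]     # per-condition rejection counts
    n_epochs: int
    qc_min: int = QC_MIN_EPOCHS

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    @property
    def qc_pass(self) -> bool:
        return self.n_accepted >= self.qc_min

    def to_frame(self) -> pd.DataFrame:
        rows = [{"epoch_index": i, "accepted": i in self.accepted}
                for i in range(self.n_epochs)]
        return pd.DataFrame(rows)


def harmonic_mean(x, floor: float | None = None) -> float:
    """n / sum(1/x_i); values below ``floor`` (if given) are raised to it."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise SizeError("harmonic mean of an empty sequence")
    if floor is not None:
        x = np.maximum(x, floor)
    if np.any(x <= 0):
        raise ValueError("harmonic mean requires strictly positive values")
    return float(x.size / np.sum(1.0 / x))


def _envelope_epoch_max(envelope: EnvelopeTrace, grid: EpochGrid) -> np.ndarray:
    """Max envelope value inside each epoch's half-open [start, start+5 s)."""
    fs = envelope.sample_rate_hz
    block_start = grid.block.start_s
    n_ep = int(round(grid.epoch_len_s * fs))
    out = np.empty(grid.n_epochs)
    for k, t0 in enumerate(grid.starts_s):
        i0 = int(round((t0 - block_start) * fs))
        seg = envelope.samples[i0:i0 + n_ep]
        if seg.size == 0:
            raise SizeError("envelope does not cover the epoch grid")
        out[k] = seg.max()
    return out


def compute_epoch_features(ecog: np.ndarray, envelope: EnvelopeTrace, grid: EpochGrid,
                           sample_rate_hz: float, scheme: BandScheme | None = None,
                           segment_len_samples: int | None = None) -> list[EpochFeatures]:
    """Delta power, theta/delta ratio and EMG ratio for every epoch of a block.

    ``ecog`` is the full-recording trace of the channel used for state
    scoring; ``envelope`` covers exactly the block (its sample 0 is the
    block start).
    """
    from scipy import signal as _sig

    from .spectral import default_nperseg

    scheme = scheme or BandScheme.default()
    mat = epoch_matrix(np.asarray(ecog, dtype=float), grid, sample_rate_hz)
    hm = harmonic_mean(envelope.samples, floor=effective_envelope_floor(envelope.samples))
    env_max = _envelope_epoch_max(envelope, grid)

    nperseg = segment_len_samples or default_nperseg(sample_rate_hz)
    # one vectorized Welch over all epochs (rows) at once
    freqs, pxx = _sig.welch(mat, fs=sample_rate_hz, window="hann", nperseg=nperseg,
                            noverlap=nperseg // 2, detrend=False,
                            scaling="density", axis=-1)
    df = float(freqs[1] - freqs[0])
    delta = pxx[:, scheme.mask(freqs, "delta")].sum(axis=1) * df
    theta = pxx[:, scheme.mask(freqs, "theta")].sum(axis=1) * df
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta > 0, theta / delta, np.inf)

    return [
        EpochFeatures(
            epoch_index=k,
            delta_power=float(delta[k]),
            theta_delta_ratio=float(ratio[k]),
            emg_envelope_max_ratio=float(env_max[k] / hm),
        )
        for k in range(grid.n_epochs)
    ]


def select_epochs(features: list[EpochFeatures], envelope: EnvelopeTrace,
                  grid: EpochGrid, qc_min: int = QC_MIN_EPOCHS,
                  exclude: set[int] | None = None) -> SelectionResult:
    """Apply the three-condition filter with block-wide thresholds.

    Thresholds are computed over ALL epochs of the block: the median delta
    power, the 75th percentile (linear-interpolation quantile) of
    theta/delta ratios, and twice the harmonic mean of the envelope over
    the whole block.  An epoch passes only if it beats all three strictly.
    ``exclude`` stands in for manual inspection: indices listed there are
    rejected regardless.
    """
    if not features:
        raise SizeError("select_epochs needs at least one epoch")
    if len(features) != grid.n_epochs:
        raise SizeError(
            f"{len(features)} feature rows for a grid of {grid.n_epochs} epochs"
        )
    exclude = exclude or set()

    delta = np.array([f.delta_power for f in features])
    ratio = np.array([f.theta_delta_ratio for f in features])
    delta_median = float(np.median(delta))
    ratio_q75 = float(np.quantile(ratio, 0.75))  # type-7 linear interpolation
    env_limit = 2.0 * harmonic_mean(envelope.samples,
                                    floor=effective_envelope_floor(envelope.samples))
    env_max = _envelope_epoch_max(envelope, grid)

    pass_i = delta < delta_median
    pass_ii = ratio < ratio_q75
    pass_iii = env_max < env_limit

    accepted = {
        f.epoch_index
        for f, a, b, c in zip(features, pass_i, pass_ii, pass_iii)
        if a and b and c and f.epoch_index not in exclude
    }
    rejections = {
        "delta_ge_median": int(np.sum(~pass_i)),
        "ratio_ge_q75": int(np.sum(~pass_ii)),
        "emg_ge_limit": int(np.sum(~pass_iii)),
        "manual_exclusion": len(exclude & {f.epoch_index for f in features}),
    }
    return SelectionResult(
        accepted=accepted,
        thresholds={
            "delta_median": delta_median,
            "theta_delta_q75": ratio_q75,
            "envelope_limit": env_limit,
        },
        rejections=rejections,
        n_epochs=len(features),
        qc_min=qc_min,
    )


def epoch_qc(result: SelectionResult, minimum: int = QC_MIN_EPOCHS) -> tuple[bool, dict]:
    """QC gate: at least ``minimum`` accepted epochs.

    Returns (pass, report); the report carries the accepted count, the
    thresholds, and per-condition rejection counts.
    """
    ok = result.n_accepted >= minimum
    report = {
        "qc_pass": ok,
        "n_accepted": result.n_accepted,
        "n_epochs": result.n_epochs,
        "minimum": minimum,
        "thresholds": dict(result.thresholds),
        "rejections": dict(result.rejections),
        "all_rejected": result.n_accepted == 0,
    }
    return ok, report
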