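"""Synthetic two-channel ECoG + EMG sessions with known ground truth.

Background activity is built in the frequency domain: a 1/f^a backbone
with band-limited components whose variances are scaled so the relative
power of each canonical band matches the requested shares exactly on the
fine FFT grid (Welch estimates then recover them up to leakage).
Interhemispheric coupling uses a shared-source mixing model

    L = sqrt(a)*s + sqrt(1-a)*n1,   R = sqrt(a)*s + sqrt(1-a)*n2,

with s, n1, n2 independent and identically distributed, so the
magnitude-squared coherence is a^2 at every frequency (a is the shared
variance fraction).  Interictal spikes are biphasic difference-of-
Gaussian templates at Poisson times thinned to >= 300 ms separation; the
EMG is white noise with scheduled movement bursts.  A "drug" acts
multiplicatively on total power, band shares, spike rate, and the shared
fraction between the two halves of a session.

Everything is deterministic under a fixed seed, at the session and the
cohort level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_signals import Recording, SignalChannel

__all__ = [
    "BackgroundSpec",
    "SpikeSpec",
    "DrugEffectSpec",
    "CohortSpec",
    "gen_background",
    "gen_spikes",
    "gen_emg",
    "gen_session",
    "gen_cohort",
    "spike_template",
]

DEFAULT_BAND_SHARES = {
    "delta": 40.0, "theta": 20.0, "alpha": 10.0, "beta": 20.0, "gamma": 10.0,
}
_BAND_EDGES = {
    "delta": (0.9, 3.9), "theta": (4.8, 7.8), "alpha": (8.7, 11.7),
    "beta": (12.6, 29.2), "gamma": (30.2, 99.6),
}
#: variance placed in the inter-band gaps (fraction of the in-band total);
#: keeps spectra hole-free without entering band-power ground truth.
GAP_FRACTION = 0.05

MIN_SPIKE_SEPARATION_S = 0.3


@dataclass(frozen=True)
class BackgroundSpec:
    """Spectral recipe for one analysis half (pre or post).

    ``duration_s`` is the length of one half of a session; band_amplitudes
    are target relative powers (percent, summing to 100) over the five
    canonical bands; ``shared_fraction`` is the variance fraction common
    to both hemispheres (MSC = shared_fraction**2); ``total_rms`` the
    per-channel RMS amplitude in microvolts.
    """

    duration_s: float = 7200.0
    sample_rate_hz: float = 1000.0
    one_over_f_exponent: float = 2.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_SHARES))
    shared_fraction: float = 0.5
    total_rms: float = 50.0

    def __post_init__(self):
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ConfigError("duration_s and sample_rate_hz must be positive")
        if self.one_over_f_exponent < 0:
            raise ConfigError("one_over_f_exponent must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigError("shared_fraction must lie in [0, 1]")
        if self.total_rms <= 0:
            raise ConfigError("total_rms must be positive")
        if set(self.band_amplitudes) != set(_BAND_EDGES):
            raise ConfigError(f"band_amplitudes must cover {sorted(_BAND_EDGES)}")
        s = sum(self.band_amplitudes.values())
        if abs(s - 100.0) > 1e-6:
            raise ConfigError(f"band_amplitudes must sum to 100, got {s}")
        if any(v < 0 for v in self.band_amplitudes.values()):
            raise ConfigError("band_amplitudes must be nonnegative")


@dataclass(frozen=True)
class SpikeSpec:
    """Interictal-spike injection recipe.

    ``peak_amplitude`` is a multiple of the background channel SD;
    ``biphasic_width_ms`` the approximate total template width and
    ``decay_ms`` the width/lag of the slower opposite-polarity phase.
    """

    rate_per_min: float = 6.0
    peak_amplitude: float = 8.0
    biphasic_width_ms: float = 40.0
    decay_ms: float = 12.0

    def __post_init__(self):
        if self.rate_per_min <= 0 or self.peak_amplitude < 0:
            raise ConfigError("rate and amplitude must be positive")
        # thinning to >=300 ms separation fails to track the target rate
        # once the raw Poisson rate approaches 1/separation
        if self.rate_per_min / 60.0 * MIN_SPIKE_SEPARATION_S > 0.5:
            raise ConfigError(
                f"rate {self.rate_per_min}/min too high for the "
                f"{MIN_SPIKE_SEPARATION_S} s separation constraint"
            )


@dataclass(frozen=True)
class DrugEffectSpec:
    """Multiplicative ground-truth drug effect applied to the post half."""

    power_scale: float = 1.0
    band_redistribution: dict[str, float] | None = None
    spike_rate_multiplier: float = 1.0
    coherence_shift: float = 0.0

    def __post_init__(self):
        if self.power_scale <= 0 or self.spike_rate_multiplier <= 0:
            raise ConfigError("power_scale and spike_rate_multiplier must be positive")
        if self.band_redistribution is not None:
            if any(v <= 0 for v in self.band_redistribution.values()):
                raise ConfigError("band_redistribution tilts must be positive")

    def apply_to(self, spec: BackgroundSpec) -> BackgroundSpec:
        shares = dict(spec.band_amplitudes)
        if self.band_redistribution:
            shares = {b: shares[b] * self.band_redistribution.get(b, 1.0) for b in shares}
            s = sum(shares.values())
            shares = {b: 100.0 * v / s for b, v in shares.items()}
        return replace(
            spec,
            total_rms=spec.total_rms * math.sqrt(self.power_scale),
            band_amplitudes=shares,
            shared_fraction=min(1.0, max(0.0, spec.shared_fraction + self.coherence_shift)),
        )


# ---------------------------------------------------------------------------
# background

def _realized_band_var(Y: np.ndarray, mask: np.ndarray, n: int) -> float:
    """Variance contributed by the masked rfft bins of coefficient array Y."""
    w = np.full(Y.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    return float(np.sum(w[mask] * np.abs(Y[mask]) ** 2) / n ** 2)


def _one_source(n: int, fs: float, spec: BackgroundSpec, rng: np.random.Generator) -> np.ndarray:
    """Unit-band-variance source: 1/f-shaped in-band spectrum, exact shares."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    W = np.fft.rfft(rng.standard_normal(n))
    shape = np.where(freqs >= 0.5, np.maximum(freqs, 0.5) ** (-spec.one_over_f_exponent / 2.0),
                     0.5 ** (-spec.one_over_f_exponent / 2.0))
    shape[0] = 0.0  # no DC
    Y = W * shape

    band_masks = {}
    in_band = np.zeros(freqs.size, dtype=bool)
    for band, (lo, hi) in _BAND_EDGES.items():
        m = (freqs >= lo) & (freqs <= hi)
        band_masks[band] = m
        in_band |= m

    # scale each band to its exact variance share (unit total in-band variance)
    for band, m in band_masks.items():
        target = spec.band_amplitudes[band] / 100.0
        have = _realized_band_var(Y, m, n)
        if have > 0 and target > 0:
            Y[m] *= math.sqrt(target / have)
        elif target == 0:
            Y[m] = 0.0
    # gaps: keep the 1/f trend at a small total variance, excluded from shares
    gap = ~in_band
    gap_have = _realized_band_var(Y, gap, n)
    if gap_have > 0:
        Y[gap] *= math.sqrt(GAP_FRACTION / gap_have)
    return np.fft.irfft(Y, n=n)


def gen_background(spec: BackgroundSpec, seed) -> tuple[np.ndarray, np.ndarray]:
    """Two ECoG channels with the requested spectrum and shared fraction.

    Returns (left, right), each of RMS ``spec.total_rms`` microvolts.
    Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    if n < 16:
        raise ConfigError("background too short")
    a = spec.shared_fraction
    shared = _one_source(n, spec.sample_rate_hz, spec, rng)
    noise_l = _one_source(n, spec.sample_rate_hz, spec, rng)
    noise_r = _one_source(n, spec.sample_rate_hz, spec, rng)
    left = math.sqrt(a) * shared + math.sqrt(1.0 - a) * noise_l
    right = math.sqrt(a) * shared + math.sqrt(1.0 - a) * noise_r
    # common gain so coherence is untouched
    rms = math.sqrt((np.var(left) + np.var(right)) / 2.0)
    gain = spec.total_rms / rms
    return left * gain, right * gain


# ---------------------------------------------------------------------------
# spikes

def spike_template(sample_rate_hz: float, biphasic_width_ms: float = 40.0,
                   decay_ms: float = 12.0) -> tuple[np.ndarray, int]:
    """Difference-of-Gaussians biphasic spike, peak normalized to 1.

    Returns (template, peak_index); the sharp positive phase peaks at
    ``peak_index`` and the slower opposite phase follows ``decay_ms``
    later.
    """
    fs = sample_rate_hz
    # proportions keep the extremum on the sharp phase even after the
    # 0.5-60 Hz detection band-pass (which attenuates it more than the
    # slow phase)
    sigma1 = biphasic_width_ms / 10.0 / 1000.0   # 4 ms at the 40 ms default
    sigma2 = decay_ms * 0.7 / 1000.0
    lag = decay_ms / 1000.0
    t_max = lag + 4 * sigma2
    t = np.arange(-4 * sigma1, t_max, 1.0 / fs)
    wave = np.exp(-t ** 2 / (2 * sigma1 ** 2)) - 0.5 * np.exp(-(t - lag) ** 2 / (2 * sigma2 ** 2))
    wave /= np.max(np.abs(wave))
    return wave, int(np.argmax(wave))


def _poisson_times(rate_per_s: float, duration_s: float, rng: np.random.Generator,
                   min_separation_s: float = MIN_SPIKE_SEPARATION_S) -> np.ndarray:
    """Homogeneous Poisson times thinned to the minimum separation."""
    n_raw = rng.poisson(rate_per_s * duration_s * 1.5) + 1
    gaps = rng.exponential(1.0 / rate_per_s, size=int(n_raw * 1.5) + 10)
    raw = np.cumsum(gaps)
    raw = raw[raw < duration_s]
    kept = []
    last = -np.inf
    for t in raw:
        if t - last >= min_separation_s:
            kept.append(t)
            last = t
    return np.asarray(kept)


def gen_spikes(background: np.ndarray, spec: SpikeSpec, seed,
               sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Add biphasic transients to a channel; returns (signal, peak times).

    Template amplitude is ``spec.peak_amplitude`` times the SD of the
    background trace; the log records the exact peak times in seconds.
    """
    rng = np.random.default_rng(seed)
    x = np.array(background, dtype=float)
    fs = sample_rate_hz
    wave, peak_idx = spike_template(fs, spec.biphasic_width_ms, spec.decay_ms)
    margin_s = len(wave) / fs
    duration_s = x.size / fs
    if duration_s <= 2 * margin_s:
        raise ConfigError("recording too short for spike injection")
    times = _poisson_times(spec.rate_per_min / 60.0, duration_s - 2 * margin_s, rng) + margin_s
    amp = spec.peak_amplitude * float(np.std(x))
    if amp == 0:
        return x, times
    for t in times:
        i0 = int(round(t * fs)) - peak_idx
        x[i0:i0 + wave.size] += amp * wave
    return x, times


# ---------------------------------------------------------------------------
# EMG

def gen_emg(duration_s: float, sample_rate_hz: float,
            burst_schedule: list[tuple[float, float, float]] | None,
            seed, baseline_sigma: float = 10.0) -> tuple[np.ndarray, list]:
    """White-noise EMG with scheduled movement bursts.

    Each (start_s, end_s, gain) burst multiplies the baseline amplitude by
    ``gain`` (> 1); bursts must lie inside the recording and not overlap.
    Returns (samples, schedule) so the schedule can serve as a selection
    oracle.
    """
    burst_schedule = sorted(burst_schedule or [])
    n = int(round(duration_s * sample_rate_hz))
    prev_end = -math.inf
    for start, end, gain in burst_schedule:
        if not 0 <= start < end <= duration_s:
            raise ConfigError(f"burst [{start}, {end}) outside recording")
        if gain <= 1:
            raise ConfigError("burst gain must exceed 1")
        if start < prev_end:
            raise ConfigError("bursts overlap")
        prev_end = end
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n) * baseline_sigma
    for start, end, gain in burst_schedule:
        i0, i1 = int(round(start * sample_rate_hz)), int(round(end * sample_rate_hz))
        x[i0:i1] *= gain
    return x, burst_schedule


# ---------------------------------------------------------------------------
# sessions and cohorts

def gen_session(background_spec: BackgroundSpec | None = None,
                spike_spec: SpikeSpec | None = None,
                emg_bursts: list[tuple[float, float, float]] | None = None,
                drug_spec: DrugEffectSpec | None = None,
                seed=0, subject: dict | None = None) -> tuple[Recording, dict]:
    """One pre/post session: two halves of ``background_spec.duration_s`` each.

    The pre half follows the base specs; the post half follows the specs
    transformed by ``drug_spec``; drug administration sits exactly at the
    midpoint.  Spikes are injected at the same times into both ECoG
    channels (bilateral discharges).  Returns the Recording and a
    ground-truth manifest with all generating parameters and spike times.
    """
    background_spec = background_spec or BackgroundSpec()
    spike_spec = spike_spec or SpikeSpec()
    drug_spec = drug_spec or DrugEffectSpec()
    fs = background_spec.sample_rate_hz
    post_spec = drug_spec.apply_to(background_spec)
    post_spike = replace(spike_spec,
                         rate_per_min=spike_spec.rate_per_min * drug_spec.spike_rate_multiplier)

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]

    halves = []
    spike_times = []
    for half_i, (bspec, sspec) in enumerate(((background_spec, spike_spec),
                                             (post_spec, post_spike))):
        left, right = gen_background(bspec, seeds[2 * half_i])
        offset = half_i * background_spec.duration_s
        # identical event times on both channels; each scaled to its own SD
        left, times = gen_spikes(left, sspec, seeds[2 * half_i + 1], fs)
        right = _inject_at(right, times, sspec, fs)
        halves.append((left, right))
        spike_times.extend((times + offset).tolist())

    left = np.concatenate([h[0] for h in halves])
    right = np.concatenate([h[1] for h in halves])
    total_s = 2 * background_spec.duration_s
    emg, schedule = gen_emg(total_s, fs, emg_bursts, seeds[4])

    rec = Recording(
        channels=[
            SignalChannel("ECoG-L", "ecog_left", left),
            SignalChannel("ECoG-R", "ecog_right", right),
            SignalChannel("EMG", "emg", emg),
        ],
        sample_rate_hz=fs,
        drug_time_s=background_spec.duration_s,
        subject=subject or {"subject_id": "synthetic"},
    )
    manifest = {
        "seed": seed,
        "sample_rate_hz": fs,
        "half_duration_s": background_spec.duration_s,
        "drug_time_s": background_spec.duration_s,
        "pre": _spec_dict(background_spec, spike_spec),
        "post": _spec_dict(post_spec, post_spike),
        "drug_effect": {
            "power_scale": drug_spec.power_scale,
            "spike_rate_multiplier": drug_spec.spike_rate_multiplier,
            "coherence_shift": drug_spec.coherence_shift,
            "band_redistribution": drug_spec.band_redistribution or {},
        },
        "spike_times_s": spike_times,
        "emg_bursts": [list(b) for b in schedule],
        "subject": rec.subject,
    }
    return rec, manifest


def _inject_at(x: np.ndarray, times: np.ndarray, spec: SpikeSpec, fs: float) -> np.ndarray:
    x = np.array(x, dtype=float)
    wave, peak_idx = spike_template(fs, spec.biphasic_width_ms, spec.decay_ms)
    amp = spec.peak_amplitude * float(np.std(x))
    for t in times:
        i0 = int(round(t * fs)) - peak_idx
        x[i0:i0 + wave.size] += amp * wave
    return x


def _spec_dict(bspec: BackgroundSpec, sspec: SpikeSpec) -> dict:
    return {
        "total_rms": bspec.total_rms,
        "band_amplitudes": dict(bspec.band_amplitudes),
        "shared_fraction": bspec.shared_fraction,
        "msc_expected": bspec.shared_fraction ** 2,
        "one_over_f_exponent": bspec.one_over_f_exponent,
        "spike_rate_per_min": sspec.rate_per_min,
        "spike_peak_amplitude_sd": sspec.peak_amplitude,
    }


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of sessions with subject-level drug-effect variability.

    Spike-rate multipliers and power scales are log-normal across
    subjects; their rank dependence is planted through a Gaussian copula
    with Spearman correlation ``planted_correlation``.  Session-scale
    parameters default to 240-s analysis blocks (5-s acclimations,
    500 Hz) so whole-cohort studies stay cheap while each block still
    holds ~60 spikes at the default rate; the recovered quantities are
    ratios, which are duration-invariant in expectation.
    """

    n_subjects: int = 20
    planted_correlation: float = 0.9
    spike_mult_median: float = 0.6
    spike_mult_sigma_log: float = 0.5
    power_scale_median: float = 0.8
    power_scale_sigma_log: float = 0.35
    coherence_shift_sd: float = 0.0
    master_seed: int = 0
    background: BackgroundSpec = field(default_factory=lambda: BackgroundSpec(
        duration_s=245.0, sample_rate_hz=500.0))
    spikes: SpikeSpec = field(default_factory=lambda: SpikeSpec(rate_per_min=15.0))

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ConfigError("cohort needs n_subjects >= 3")
        if not -1.0 <= self.planted_correlation <= 1.0:
            raise ConfigError("planted_correlation must lie in [-1, 1]")
        for v in (self.spike_mult_median, self.power_scale_median):
            if v <= 0:
                raise ConfigError("multiplier medians must be positive")


def gen_cohort(spec: CohortSpec) -> tuple[list[tuple[Recording, dict]], pd.DataFrame]:
    """Generate a cohort; returns (sessions, ground-truth table).

    The table has one row per subject with the drawn multipliers; the
    same master seed reproduces it exactly.
    """
    rng = np.random.default_rng(spec.master_seed)
    # Gaussian copula: Pearson rho of the latent normals that induces the
    # requested Spearman rho
    rho_s = spec.planted_correlation
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    cov = np.array([[1.0, rho_p], [rho_p, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=spec.n_subjects)
    spike_mult = spec.spike_mult_median * np.exp(spec.spike_mult_sigma_log * z[:, 0])
    power_scale = spec.power_scale_median * np.exp(spec.power_scale_sigma_log * z[:, 1])
    coh_shift = (rng.normal(0.0, spec.coherence_shift_sd, spec.n_subjects)
                 if spec.coherence_shift_sd > 0 else np.zeros(spec.n_subjects))

    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in np.random.SeedSequence(spec.master_seed).spawn(spec.n_subjects)]

    sessions = []
    rows = []
    for i in range(spec.n_subjects):
        sid = f"subj{i:03d}"
        drug = DrugEffectSpec(power_scale=float(power_scale[i]),
                              spike_rate_multiplier=float(spike_mult[i]),
                              coherence_shift=float(coh_shift[i]))
        rec, manifest = gen_session(spec.background, spec.spikes, None, drug,
                                    seed=child_seeds[i],
                                    subject={"subject_id": sid, "drug": "synthetic"})
        sessions.append((rec, manifest))
        rows.append({"subject_id": sid, "seed": child_seeds[i],
                     "spike_rate_multiplier": float(spike_mult[i]),
                     "power_scale": float(power_scale[i]),
                     "coherence_shift": float(coh_shift[i])})
    return sessions, pd.DataFrame(rows)
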