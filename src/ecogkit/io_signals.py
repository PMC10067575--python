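"""Recordings, analysis blocks, and file I/O.

A session is a continuous multi-channel recording — two ECoG channels
(left and right somatosensory cortex) plus one EMG channel — with a drug
administration time annotated.  The session splits into a pre-drug and a
post-drug analysis block after discarding 30-minute acclimation spans.

Supported on-disk forms: EDF/EDF+ (read via MNE, written by a built-in
16-bit EDF writer) and delimited text with explicit sampling-rate
metadata.  All amplitudes are microvolts.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import BlockError, ConfigError, ParseError

__all__ = [
    "ROLES",
    "SignalChannel",
    "Recording",
    "AnalysisBlock",
    "read_edf",
    "write_edf",
    "read_delimited",
    "read_annotation",
    "write_annotation",
    "segment_blocks",
    "write_results",
    "read_results",
    "DEFAULT_LABEL_MAP",
]

log = logging.getLogger(__name__)

ROLES = ("ecog_left", "ecog_right", "emg")

#: label-pattern -> role, tried in order, case-insensitive regex search.
DEFAULT_LABEL_MAP: tuple[tuple[str, str], ...] = (
    (r"emg", "emg"),
    (r"(ecog|eeg).*l|l.*(ecog|eeg)|left", "ecog_left"),
    (r"(ecog|eeg).*r|r.*(ecog|eeg)|right", "ecog_right"),
)


@dataclass
class SignalChannel:
    """One recorded channel: a label, a role, and samples in microvolts."""

    label: str
    role: str
    samples: np.ndarray

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigError(f"unknown channel role {self.role!r}; expected one of {ROLES}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("channel samples must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.label!r} contains non-finite samples")


@dataclass
class Recording:
    """Equal-length channels at one sampling rate, plus session annotations.

    ``drug_time_s`` is the administration time in seconds from recording
    start (None for drug-free sessions).  ``subject`` is free-form metadata
    (id, genotype, drug, dose ...).
    """

    channels: list[SignalChannel]
    sample_rate_hz: float
    drug_time_s: float | None = None
    subject: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        lengths = {c.samples.size for c in self.channels}
        if len(lengths) > 1:
            raise ValueError(f"channels differ in length: {sorted(lengths)}")
        roles = [c.role for c in self.channels]
        if len(set(roles)) != len(roles):
            raise ConfigError(f"duplicate channel roles: {roles}")
        if self.drug_time_s is not None and self.drug_time_s < 0:
            raise ValueError("drug_time_s must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.channels[0].samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, role: str) -> SignalChannel:
        for c in self.channels:
            if c.role == role:
                return c
        raise ConfigError(f"recording has no channel with role {role!r}")

    def has_role(self, role: str) -> bool:
        return any(c.role == role for c in self.channels)


@dataclass(frozen=True)
class AnalysisBlock:
    """Half-open time span [start_s, end_s) labelled 'pre' or 'post'."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.label not in ("pre", "post"):
            raise ValueError("block label must be 'pre' or 'post'")
        if not (0 <= self.start_s < self.end_s):
            raise ValueError("need 0 <= start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def slice_samples(self, x: np.ndarray, sample_rate_hz: float) -> np.ndarray:
        i0 = int(round(self.start_s * sample_rate_hz))
        i1 = int(round(self.end_s * sample_rate_hz))
        return x[i0:i1]


# ---------------------------------------------------------------------------
# channel-role mapping

def map_roles(labels: list[str], label_map=DEFAULT_LABEL_MAP) -> dict[str, str]:
    """Map channel labels to roles by first-match regex; one label per role."""
    assignment: dict[str, str] = {}
    for label in labels:
        for pattern, role in label_map:
            if role not in assignment.values() and re.search(pattern, label, re.IGNORECASE):
                assignment[label] = role
                break
    return assignment


def _require_roles(rec: Recording, required=("ecog_left", "ecog_right")):
    missing = [r for r in required if not rec.has_role(r)]
    if missing:
        raise ConfigError(f"recording is missing required channel role(s): {missing}")


# ---------------------------------------------------------------------------
# EDF

_EDF_DIGITAL_MAX = 32767


def write_edf(recording: Recording, path) -> None:
    """Write the recording as a plain EDF file (16-bit, 1-s records).

    Physical min/max per channel are set symmetrically from the data range,
    so the round-trip quantization error is at most |x|_max / 32767.  The
    sampling rate must be a positive integer and the duration a whole
    number of seconds (true of all synthetic sessions).
    """
    fs = recording.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n = recording.n_samples
    if n % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds of data")
    n_records = n // fs
    chans = recording.channels
    ns = len(chans)

    header = bytearray()

    def put(text, width):
        b = str(text).encode("ascii")[:width]
        header.extend(b.ljust(width))

    put("0", 8)
    put(recording.subject.get("subject_id", "X"), 80)
    put("Startdate 01-JAN-2000", 80)
    put("01.01.00", 8)
    put("00.00.00", 8)
    put(256 * (1 + ns), 8)
    put("", 44)
    put(n_records, 8)
    put(1, 8)  # record duration, seconds
    put(ns, 4)

    phys_ranges = []
    for c in chans:
        amp = float(np.max(np.abs(c.samples)))
        phys_ranges.append(amp if amp > 0 else 1.0)

    for c in chans:
        put(c.label, 16)
    for _ in chans:
        put("AgAgCl wire", 80)
    for _ in chans:
        put("uV", 8)
    for amp in phys_ranges:
        put(f"{-amp:.6g}"[:8], 8)
    for amp in phys_ranges:
        put(f"{amp:.6g}"[:8], 8)
    for _ in chans:
        put(-_EDF_DIGITAL_MAX, 8)
    for _ in chans:
        put(_EDF_DIGITAL_MAX, 8)
    for _ in chans:
        put("", 80)
    for _ in chans:
        put(fs, 8)
    for _ in chans:
        put("", 32)

    # digital samples, record-major then channel-major within a record
    digital = []
    for c, amp in zip(chans, phys_ranges):
        # re-parse the 8-char ascii physical max so read scaling inverts exactly
        amp_stored = float(f"{amp:.6g}"[:8])
        d = np.clip(np.round(c.samples / amp_stored * _EDF_DIGITAL_MAX),
                    -_EDF_DIGITAL_MAX, _EDF_DIGITAL_MAX).astype("<i2")
        digital.append(d.reshape(n_records, fs))
    body = np.concatenate(digital, axis=1)  # (n_records, ns*fs), channel blocks in order

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(body.tobytes())


def read_edf(path, label_map=DEFAULT_LABEL_MAP, drug_time_s: float | None = None,
             subject: dict | None = None, require=("ecog_left", "ecog_right")) -> Recording:
    """Read an EDF/EDF+ file into a Recording (amplitudes in microvolts).

    Channel labels map to roles via ``label_map`` (first regex match wins);
    channels that map to no role are dropped with a log message.  Channels
    recorded at different rates are polyphase-resampled to the highest rate
    so coherence has a common time base.
    """
    import mne  # deferred: mne import is slow

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_v = raw.get_data()  # SI units (volts)
    labels = list(raw.ch_names)
    assignment = map_roles(labels, label_map)
    if not assignment:
        raise ConfigError(f"no channel label in {labels} maps to a known role")

    channels = []
    for label, role in assignment.items():
        i = labels.index(label)
        channels.append(SignalChannel(label=label, role=role,
                                      samples=data_v[i] * 1e6))
    dropped = [l for l in labels if l not in assignment]
    if dropped:
        log.info("dropping unmapped channels: %s", dropped)

    rec = Recording(channels=channels, sample_rate_hz=float(raw.info["sfreq"]),
                    drug_time_s=drug_time_s, subject=subject or {})
    _require_roles(rec, require)
    return rec


# ---------------------------------------------------------------------------
# delimited text

def read_delimited(path, sample_rate_hz: float, column_roles: dict[str, str],
                   drug_time_s: float | None = None, subject: dict | None = None) -> Recording:
    """Read a delimited text file, one column per channel.

    ``column_roles`` maps column names (or stringified 0-based indices for
    headerless files) to roles.  Any non-numeric or missing cell raises
    :class:`ParseError` with the offending row index.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    df = pd.read_csv(path, sep=None, engine="python")
    # headerless file: first row parsed as header will be numeric-looking
    if all(_is_number(c) for c in df.columns):
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        df.columns = [str(c) for c in df.columns]

    channels = []
    for col, role in column_roles.items():
        if col not in df.columns:
            raise ConfigError(f"declared column {col!r} not found in {list(df.columns)}")
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ParseError(
                f"non-numeric or missing value in column {col!r} at data row {bad[0]}",
                row=int(bad[0]),
            )
        channels.append(SignalChannel(label=col, role=role, samples=values))
    if not channels:
        raise ConfigError("column_roles mapped no columns")
    return Recording(channels=channels, sample_rate_hz=float(sample_rate_hz),
                     drug_time_s=drug_time_s, subject=subject or {})


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# annotations

def read_annotation(path) -> dict:
    """Read the key-value session annotation (YAML mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"annotation file {path} is not a key-value mapping")
    return data


def write_annotation(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# analysis blocks

def segment_blocks(recording: Recording, acclimation_s: float = 1800.0,
                   block_len_s: float = 5400.0) -> tuple[AnalysisBlock, AnalysisBlock]:
    """Split a session into the pre- and post-drug analysis blocks.

    The first ``acclimation_s`` of the recording and of the post-drug
    period are discarded as acclimation.  Pre spans
    [acclimation_s, drug_time_s); post spans
    [drug_time_s + acclimation_s, drug_time_s + acclimation_s + block_len_s).
    With the default 4-h protocol (drug at 2 h, 30-min acclimations) both
    blocks last 1.5 h.  A recording too short for the post block is an
    error, never a silent clip.
    """
    if recording.drug_time_s is None:
        raise BlockError("segment_blocks requires a drug_time_s annotation")
    t_drug = recording.drug_time_s
    if acclimation_s <= 0 or block_len_s <= 0:
        raise ValueError("acclimation_s and block_len_s must be positive")
    if t_drug <= acclimation_s:
        raise BlockError(
            f"drug_time_s={t_drug} leaves no pre block after {acclimation_s} s acclimation"
        )
    post_end = t_drug + acclimation_s + block_len_s
    dur = recording.duration_s
    if post_end > dur + 1e-9:
        raise BlockError(
            f"recording lasts {dur:.1f} s but the post block ends at {post_end:.1f} s "
            f"(short by {post_end - dur:.1f} s)"
        )
    pre = AnalysisBlock("pre", acclimation_s, t_drug)
    post = AnalysisBlock("post", t_drug + acclimation_s, post_end)
    return pre, post


# ---------------------------------------------------------------------------
# results

def write_results(results, path) -> None:
    """Write a pipeline product to disk.

    DataFrames (and result objects exposing ``to_frame()``) become CSV;
    dicts (and objects exposing ``to_dict()``) become YAML.  Floats are
    written with full repr precision, so a read-back is lossless at double
    precision.
    """
    path = Path(path)
    if hasattr(results, "to_frame") and not isinstance(results, pd.DataFrame):
        results = results.to_frame()
    if isinstance(results, pd.DataFrame):
        # %.17g round-trips IEEE doubles exactly
        results.to_csv(path, index=False, float_format="%.17g")
        return
    if hasattr(results, "to_dict") and not isinstance(results, dict):
        results = results.to_dict()
    if isinstance(results, dict):
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(results), fh, sort_keys=False)
        return
    raise TypeError(f"unsupported result type {type(results).__name__}")


def read_results(path) -> pd.DataFrame | dict:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as fh:
            return yaml.safe_load(fh)
    return pd.read_csv(path, float_precision="round_trip")


def _plain(obj):
    """Recursively convert numpy scalars/arrays so YAML stays readable."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
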