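"""Pipeline configuration: one YAML document, validated, unknown keys rejected."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import ConfigError
from .pipeline import AnalysisParams
from .spectral import BandScheme
from .synthetic import BackgroundSpec, CohortSpec, DrugEffectSpec, SpikeSpec

__all__ = ["PipelineConfig", "load_config"]


def _build(cls, data: dict, where: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SimulateConfig:
    """Synthetic-session / cohort parameters (see the synthetic module)."""

    half_duration_s: float = 7200.0
    sample_rate_hz: float = 1000.0
    one_over_f_exponent: float = 2.0
    band_amplitudes: dict | None = None
    shared_fraction: float = 0.5
    total_rms: float = 50.0
    spike_rate_per_min: float = 6.0
    spike_peak_amplitude: float = 8.0
    power_scale: float = 1.0
    spike_rate_multiplier: float = 1.0
    coherence_shift: float = 0.0
    band_redistribution: dict | None = None
    emg_bursts: list | None = None
    cohort_n: int | None = None
    planted_correlation: float = 0.9

    def background_spec(self) -> BackgroundSpec:
        kw = dict(duration_s=self.half_duration_s, sample_rate_hz=self.sample_rate_hz,
                  one_over_f_exponent=self.one_over_f_exponent,
                  shared_fraction=self.shared_fraction, total_rms=self.total_rms)
        if self.band_amplitudes is not None:
            kw["band_amplitudes"] = dict(self.band_amplitudes)
        return BackgroundSpec(**kw)

    def spike_spec(self) -> SpikeSpec:
        return SpikeSpec(rate_per_min=self.spike_rate_per_min,
                         peak_amplitude=self.spike_peak_amplitude)

    def drug_spec(self) -> DrugEffectSpec:
        return DrugEffectSpec(power_scale=self.power_scale,
                              spike_rate_multiplier=self.spike_rate_multiplier,
                              coherence_shift=self.coherence_shift,
                              band_redistribution=self.band_redistribution)

    def cohort_spec(self, seed: int) -> CohortSpec:
        return CohortSpec(n_subjects=self.cohort_n or 20,
                          planted_correlation=self.planted_correlation,
                          master_seed=seed,
                          background=self.background_spec(),
                          spikes=self.spike_spec())


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs besides file paths.

    ``bands`` is a list of [name, low_hz, high_hz]; None means the
    canonical five-band scheme.
    """

    bands: list | None = None
    segment_len_samples: int | None = None
    acclimation_s: float = 1800.0
    block_len_s: float = 5400.0
    selection_channel: str = "ecog_left"
    qc_min_epochs: int = 100
    spike_threshold_multiplier: float = 4.5
    spike_channel: str = "ecog_left"
    coherence_kind: str = "msc"
    emg_cutoff_hz: float = 3.0
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def scheme(self) -> BandScheme:
        if self.bands is None:
            return BandScheme.default()
        return BandScheme(bands=tuple((str(n), float(a), float(b)) for n, a, b in self.bands))

    def analysis_params(self) -> AnalysisParams:
        return AnalysisParams(
            scheme=self.scheme(),
            segment_len_samples=self.segment_len_samples,
            acclimation_s=self.acclimation_s,
            block_len_s=self.block_len_s,
            selection_channel=self.selection_channel,
            qc_min_epochs=self.qc_min_epochs,
            spike_threshold_multiplier=self.spike_threshold_multiplier,
            spike_channel=self.spike_channel,
            coherence_kind=self.coherence_kind,
            emg_cutoff_hz=self.emg_cutoff_hz,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load the YAML config (or defaults), applying CLI overrides last."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a mapping")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    sim = data.pop("simulate", {})
    if not isinstance(sim, dict):
        raise ConfigError("'simulate' section must be a mapping")
    cfg = _build(PipelineConfig, {**data, "simulate": _build(SimulateConfig, sim, "simulate")},
                 "config")
    return cfg
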