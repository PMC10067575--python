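"""End-to-end session analysis: blocks -> epochs -> selection -> metrics.

``analyze_block`` runs one analysis block through epoching, EMG-based
epoch selection, band-resolved PSD averaging over the selected epochs,
interhemispheric coherence, and interictal spike detection.
``analyze_session`` applies it to the pre and post blocks and returns a
subject summary ready for the drug-effect statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import drug_effects, epoch_select, spectral, spikes
from .errors import DegenerateInputError
from .io_signals import AnalysisBlock, Recording, segment_blocks
from .preprocess import SPIKE_BANDPASS, apply_filter, envelope_emg
from .spectral import BandScheme

__all__ = ["AnalysisParams", "BlockResult", "SessionResult",
           "analyze_block", "analyze_session", "compare_cohort"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable pipeline parameters with the protocol defaults.

    ``segment_len_samples=None`` picks the length that puts the band edges
    on the PSD bin grid (1024 samples at 1 kHz).  ``selection_channel`` is
    the ECoG channel used for the state-scoring features (the spectral
    outputs themselves average both hemispheres' metrics per channel
    role).  ``qc_min_epochs`` follows the >= 100 selected-epochs rule;
    scaled-down studies may lower it explicitly.
    """

    scheme: BandScheme = field(default_factory=BandScheme.default)
    segment_len_samples: int | None = None
    acclimation_s: float = 1800.0
    block_len_s: float = 5400.0
    selection_channel: str = "ecog_left"
    qc_min_epochs: int = 100
    spike_threshold_multiplier: float = 4.5
    spike_channel: str = "ecog_left"
    coherence_kind: str = "msc"
    emg_cutoff_hz: float = 3.0
    compute_coherence: bool = True


@dataclass
class BlockResult:
    """All products of one analysis block."""

    block: AnalysisBlock
    selection: epoch_select.SelectionResult
    qc_report: dict
    psd: spectral.PSDResult | None
    band_powers: spectral.BandPowers | None
    coherence: spectral.CoherenceSpectrum | None
    spike_events: list[spikes.SpikeEvent]
    spike_stats: spikes.SpikeStats
    spike_stats_by_channel: dict[str, spikes.SpikeStats]

    def metrics(self) -> drug_effects.BlockMetrics:
        if self.band_powers is None:
            raise DegenerateInputError(
                f"block {self.block.label!r}: no epochs selected, band powers undefined")
        coh = (self.coherence.band_means if self.coherence is not None
               else {b: float("nan") for b in self.band_powers.relative})
        return drug_effects.BlockMetrics(
            band_powers=self.band_powers,
            coherence_band_means=coh,
            spike_stats=self.spike_stats,
            qc_pass=self.qc_report["qc_pass"],
        )


@dataclass
class SessionResult:
    pre: BlockResult
    post: BlockResult
    summary: drug_effects.SubjectSummary


def analyze_block(recording: Recording, block: AnalysisBlock,
                  params: AnalysisParams | None = None) -> BlockResult:
    """Run the full single-block pipeline.

    Epoch selection uses the EMG when present; without an EMG channel the
    selection falls back to conditions i-ii only (logged loudly).  Spike
    detection runs on the whole block (not just selected epochs) of the
    0.5-60 Hz band-passed ECoG, per channel; the headline stats come from
    ``params.spike_channel``.
    """
    params = params or AnalysisParams()
    fs = recording.sample_rate_hz
    grid = spectral.make_epochs(block, recording)

    sel_trace = recording.channel(params.selection_channel).samples
    if recording.has_role("emg"):
        emg_block = block.slice_samples(recording.channel("emg").samples, fs)
        envelope = envelope_emg(emg_block, fs, cutoff_hz=params.emg_cutoff_hz)
    else:
        log.warning("no EMG channel: selection condition iii (movement) is skipped")
        envelope = envelope_emg(np.ones(int(block.duration_s * fs)) * 1e-6, fs,
                                cutoff_hz=params.emg_cutoff_hz)

    features = epoch_select.compute_epoch_features(
        sel_trace, envelope, grid, fs, params.scheme, params.segment_len_samples)
    selection = epoch_select.select_epochs(features, envelope, grid,
                                           qc_min=params.qc_min_epochs)
    qc_pass, qc_report = epoch_select.epoch_qc(selection, params.qc_min_epochs)
    log.info("block %s: %d/%d epochs selected (thresholds %s)", block.label,
             selection.n_accepted, selection.n_epochs, selection.thresholds)

    accepted = sorted(selection.accepted)
    psd = bp = coherence = None
    if accepted:
        sub = grid.starts_s[accepted]
        sel_grid = spectral.EpochGrid(starts_s=sub, block=grid.block,
                                      epoch_len_s=grid.epoch_len_s, step_s=grid.step_s)
        left = spectral.epoch_matrix(recording.channel("ecog_left").samples, sel_grid, fs)
        psd = spectral.welch_psd(left, fs, params.segment_len_samples)
        bp = spectral.band_powers(psd, params.scheme)
        if params.compute_coherence and recording.has_role("ecog_right"):
            right = spectral.epoch_matrix(recording.channel("ecog_right").samples, sel_grid, fs)
            coherence = spectral.coherence_spectrum(
                left, right, fs, params.segment_len_samples,
                scheme=params.scheme, kind=params.coherence_kind)

    by_channel: dict[str, spikes.SpikeStats] = {}
    events_main: list[spikes.SpikeEvent] = []
    for role in ("ecog_left", "ecog_right"):
        if not recording.has_role(role):
            continue
        trace = block.slice_samples(recording.channel(role).samples, fs)
        filtered = apply_filter(trace, SPIKE_BANDPASS, fs)
        ev, st = spikes.detect_spikes(filtered, fs,
                                      threshold_multiplier=params.spike_threshold_multiplier)
        by_channel[role] = st
        if role == params.spike_channel:
            events_main = ev
    stats = by_channel[params.spike_channel]
    log.info("block %s: %d spikes on %s (threshold %.3g uV)", block.label,
             stats.n_events, params.spike_channel, stats.threshold_used)

    return BlockResult(block=block, selection=selection, qc_report=qc_report,
                       psd=psd, band_powers=bp, coherence=coherence,
                       spike_events=events_main, spike_stats=stats,
                       spike_stats_by_channel=by_channel)


def analyze_session(recording: Recording, params: AnalysisParams | None = None) -> SessionResult:
    """Analyze both blocks of an annotated session and summarize the subject."""
    params = params or AnalysisParams()
    pre_block, post_block = segment_blocks(recording, params.acclimation_s,
                                           params.block_len_s)
    pre = analyze_block(recording, pre_block, params)
    post = analyze_block(recording, post_block, params)
    summary = drug_effects.summarize_subject(
        str(recording.subject.get("subject_id", "?")), pre.metrics(), post.metrics(),
        drug=str(recording.subject.get("drug", "")))
    return SessionResult(pre=pre, post=post, summary=summary)


def compare_cohort(results: list[SessionResult],
                   bins: drug_effects.ResponderBins | None = None,
                   metrics=drug_effects.DEFAULT_METRICS):
    """Drug-effect rows and the Spearman surface for a cohort of sessions."""
    bins = bins or drug_effects.ResponderBins()
    effects = [drug_effects.compute_drug_effect(r.summary, bins)
               for r in results if not r.summary.excluded]
    matrix = drug_effects.spearman_matrix(effects, metrics) if len(effects) >= 3 else None
    return effects, matrix
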