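import numpy as np
import pytest

from ecogkit.errors import ConfigError
from ecogkit.io_signals import AnalysisBlock
from ecogkit.preprocess import SPIKE_BANDPASS, apply_filter, envelope_emg
from ecogkit.spectral import band_powers, coherence_spectrum, epoch_matrix, make_epochs, welch_psd
from ecogkit.spikes import detect_spikes
from ecogkit.synthetic import (BackgroundSpec, CohortSpec, DrugEffectSpec, SpikeSpec,
                               _poisson_times, gen_background, gen_cohort, gen_emg,
                               gen_session, gen_spikes)

FS = 1000.0
SHARES = {"delta": 40.0, "theta": 20.0, "alpha": 10.0, "beta": 20.0, "gamma": 10.0}


def _estimated_shares(x, fs, duration_s):
    grid = make_epochs(AnalysisBlock("pre", 0.0, duration_s))
    psd = welch_psd(epoch_matrix(x, grid, fs), fs)
    return band_powers(psd).relative


class TestBackground:
    def test_band_share_recovery_within_3pp(self):
        spec = BackgroundSpec(duration_s=600.0, sample_rate_hz=FS,
                              band_amplitudes=dict(SHARES))
        left, right = gen_background(spec, seed=5)
        rel = _estimated_shares(left, FS, 600.0)
        for band, target in SHARES.items():
            assert rel[band] == pytest.approx(target, abs=3.0)

    def test_rms_matches_spec(self):
        spec = BackgroundSpec(duration_s=120.0, sample_rate_hz=FS, total_rms=50.0)
        left, right = gen_background(spec, seed=1)
        assert np.std(left) == pytest.approx(50.0, rel=0.05)
        assert np.std(right) == pytest.approx(50.0, rel=0.05)

    def test_full_sharing_gives_unit_coherence(self):
        spec = BackgroundSpec(duration_s=60.0, sample_rate_hz=FS, shared_fraction=1.0)
        left, right = gen_background(spec, seed=2)
        assert np.allclose(left, right)

    def test_zero_sharing_coherence_at_bias_level(self):
        spec = BackgroundSpec(duration_s=600.0, sample_rate_hz=FS, shared_fraction=0.0)
        left, right = gen_background(spec, seed=3)
        grid = make_epochs(AnalysisBlock("pre", 0.0, 600.0))
        coh = coherence_spectrum(epoch_matrix(left, grid, FS),
                                 epoch_matrix(right, grid, FS), FS)
        # sliding epochs and overlapped segments correlate the averages, so
        # allow twice the nominal 1/K bias
        assert float(coh.coherence.mean()) < 2 * (1.0 / coh.n_segments) * 2

    def test_deterministic_under_seed(self):
        spec = BackgroundSpec(duration_s=30.0, sample_rate_hz=FS)
        a = gen_background(spec, seed=9)
        b = gen_background(spec, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_invalid_shares_rejected(self):
        with pytest.raises(ConfigError):
            BackgroundSpec(band_amplitudes={**SHARES, "delta": 50.0})


class TestSpikes:
    def test_poisson_mean_count(self):
        # rate 1/min over 600 s -> mean 10 events; check across 100 seeds
        counts = [len(_poisson_times(1.0 / 60.0, 600.0, np.random.default_rng(s)))
                  for s in range(100)]
        mean = np.mean(counts)
        se = np.std(counts) / 10.0
        assert abs(mean - 10.0) <= 2 * se + 0.5

    def test_zero_amplitude_leaves_signal_unchanged(self):
        spec = BackgroundSpec(duration_s=60.0, sample_rate_hz=FS)
        left, _ = gen_background(spec, seed=4)
        out, times = gen_spikes(left, SpikeSpec(rate_per_min=6.0, peak_amplitude=0.0),
                                seed=1, sample_rate_hz=FS)
        assert np.array_equal(out, left)
        assert len(times) > 0

    def test_detection_recovers_injected_events(self):
        spec = BackgroundSpec(duration_s=600.0, sample_rate_hz=FS)
        hits = total = 0
        for seed in range(3):
            left, _ = gen_background(spec, seed=40 + seed)
            x, times = gen_spikes(left, SpikeSpec(rate_per_min=1.0, peak_amplitude=8.0),
                                  seed=50 + seed, sample_rate_hz=FS)
            filtered = apply_filter(x, SPIKE_BANDPASS, FS)
            ev, _ = detect_spikes(filtered, FS)
            peaks = np.array([e.peak_time_s for e in ev])
            hits += sum(1 for t in times if peaks.size and np.min(np.abs(peaks - t)) < 0.05)
            total += len(times)
        assert total > 0 and hits / total >= 0.95

    def test_minimum_separation_enforced(self):
        times = _poisson_times(0.5, 600.0, np.random.default_rng(0))
        assert np.all(np.diff(times) >= 0.3)

    def test_unattainable_rate_rejected(self):
        with pytest.raises(ConfigError):
            SpikeSpec(rate_per_min=200.0)


class TestEmg:
    def test_quiet_emg_passes_condition_iii(self):
        # without bursts the envelope stays below twice its harmonic mean
        from ecogkit.epoch_select import effective_envelope_floor, harmonic_mean
        x, _ = gen_emg(600.0, FS, None, seed=3)
        env = envelope_emg(x, FS).samples
        hm = harmonic_mean(env, floor=effective_envelope_floor(env))
        grid = make_epochs(AnalysisBlock("pre", 0.0, 600.0))
        n_ep = int(5.0 * FS)
        fails = sum(env[int(t0 * FS):int(t0 * FS) + n_ep].max() >= 2 * hm
                    for t0 in grid.starts_s)
        assert fails / grid.n_epochs <= 0.01

    def test_burst_epoch_fails_condition_iii(self):
        from ecogkit.epoch_select import effective_envelope_floor, harmonic_mean
        x, _ = gen_emg(120.0, FS, [(50.0, 60.0, 10.0)], seed=4)
        env = envelope_emg(x, FS).samples
        hm = harmonic_mean(env, floor=effective_envelope_floor(env))
        burst_max = env[int(52 * FS):int(58 * FS)].max()
        assert burst_max >= 2 * hm  # TKEO scales with gain^2 = 100 >> 2

    def test_deterministic_and_validated(self):
        a, _ = gen_emg(10.0, FS, None, seed=7)
        b, _ = gen_emg(10.0, FS, None, seed=7)
        assert np.array_equal(a, b)
        with pytest.raises(ConfigError):
            gen_emg(10.0, FS, [(2.0, 5.0, 3.0), (4.0, 6.0, 3.0)], seed=1)
        with pytest.raises(ConfigError):
            gen_emg(10.0, FS, [(2.0, 12.0, 3.0)], seed=1)


class TestSession:
    def test_null_effect_ratios_near_one(self, scaled_params):
        from ecogkit.drug_effects import compute_drug_effect
        from ecogkit.pipeline import analyze_session
        rec, _ = gen_session(BackgroundSpec(duration_s=125.0, sample_rate_hz=500.0),
                             SpikeSpec(rate_per_min=15.0), None, DrugEffectSpec(), seed=21)
        eff = compute_drug_effect(analyze_session(rec, scaled_params).summary)
        assert eff.ratios["total_power"] == pytest.approx(1.0, abs=0.1)
        assert eff.ratios["rel_delta"] == pytest.approx(1.0, abs=0.15)

    def test_manifest_describes_halves(self, scaled_session):
        rec, manifest = scaled_session
        assert manifest["drug_time_s"] == 125.0
        assert manifest["post"]["spike_rate_per_min"] == pytest.approx(15.0 * 0.4)
        assert manifest["pre"]["total_rms"] == pytest.approx(50.0)
        assert manifest["post"]["total_rms"] == pytest.approx(50.0 * np.sqrt(0.5))
        assert rec.duration_s == 250.0

    def test_same_seed_identical_session(self):
        spec = BackgroundSpec(duration_s=30.0, sample_rate_hz=500.0)
        a, ma = gen_session(spec, SpikeSpec(rate_per_min=10.0), None, None, seed=3)
        b, mb = gen_session(spec, SpikeSpec(rate_per_min=10.0), None, None, seed=3)
        assert np.array_equal(a.channel("ecog_left").samples,
                              b.channel("ecog_left").samples)
        assert ma["spike_times_s"] == mb["spike_times_s"]

    def test_band_redistribution_renormalizes(self):
        drug = DrugEffectSpec(band_redistribution={"beta": 2.0})
        post = drug.apply_to(BackgroundSpec())
        assert sum(post.band_amplitudes.values()) == pytest.approx(100.0)
        assert post.band_amplitudes["beta"] > BackgroundSpec().band_amplitudes["beta"]


class TestCohort:
    def test_ground_truth_deterministic(self):
        spec = CohortSpec(n_subjects=4, master_seed=5,
                          background=BackgroundSpec(duration_s=30.0, sample_rate_hz=500.0))
        _, t1 = gen_cohort(spec)
        _, t2 = gen_cohort(spec)
        assert t1.equals(t2)

    def test_planted_rank_correlation_in_multipliers(self):
        spec = CohortSpec(n_subjects=200, master_seed=8,
                          background=BackgroundSpec(duration_s=30.0, sample_rate_hz=500.0))
        _, truth = gen_cohort(spec)
        from scipy.stats import spearmanr
        rho = spearmanr(truth["spike_rate_multiplier"], truth["power_scale"]).statistic
        assert rho == pytest.approx(0.9, abs=0.08)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ConfigError):
            CohortSpec(n_subjects=2)
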