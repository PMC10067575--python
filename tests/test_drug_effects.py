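import itertools
import math

import numpy as np
import pytest

from ecogkit.drug_effects import (BlockMetrics, DrugEffect, ResponderBins,
                                  category_table_test, compute_drug_effect,
                                  fisher_exact_2x2, spearman_matrix, spearman_pair,
                                  summarize_subject)
from ecogkit.errors import SizeError
from ecogkit.spectral import BandPowers
from ecogkit.spikes import SpikeStats


def _bp(delta=30, theta=20, alpha=10, beta=10, gamma=30, total=1000.0):
    rel = {"delta": delta, "theta": theta, "alpha": alpha, "beta": beta, "gamma": gamma}
    absolute = {k: total * v / 100 for k, v in rel.items()}
    return BandPowers(absolute=absolute, total=total, relative=rel)


def _metrics(spike_rate=10.0, total=1000.0, coh=0.25, qc=True, **rel):
    stats = SpikeStats(n_events=int(spike_rate * 90), block_duration_s=5400.0,
                       threshold_used=100.0, threshold_multiplier=4.5)
    return BlockMetrics(band_powers=_bp(total=total, **rel),
                        coherence_band_means={b: coh for b in
                                              ("delta", "theta", "alpha", "beta", "gamma")},
                        spike_stats=stats, qc_pass=qc)


class TestSubjectSummary:
    def test_theta_beta_ratio(self):
        m = _metrics(theta=20, beta=10)
        assert m.theta_beta_ratio == pytest.approx(2.0)

    def test_theta_beta_gamma_ratio(self):
        m = _metrics(theta=20, beta=10, gamma=30)
        assert m.theta_beta_gamma_ratio == pytest.approx(0.5)

    def test_zero_denominator_flagged(self):
        m = _metrics(theta=40, beta=0, gamma=0, delta=40, alpha=20)
        assert math.isnan(m.theta_beta_gamma_ratio)

    def test_qc_failure_excludes_subject(self):
        s = summarize_subject("m1", _metrics(qc=False), _metrics())
        assert s.excluded and "pre" in s.exclusion_reason


class TestDrugEffect:
    def test_ratios_and_category(self):
        s = summarize_subject("m1", _metrics(spike_rate=10, total=1000),
                              _metrics(spike_rate=4, total=500))
        eff = compute_drug_effect(s)
        assert eff.ratios["spike_rate"] == pytest.approx(0.4)
        assert eff.ratios["total_power"] == pytest.approx(0.5)
        assert eff.responder_category == "reduction >50%"

    def test_identity_effect(self):
        s = summarize_subject("m1", _metrics(), _metrics())
        eff = compute_drug_effect(s)
        assert all(r == pytest.approx(1.0) for r in eff.ratios.values())
        assert eff.responder_category == "no change/small"

    def test_increase_category(self):
        s = summarize_subject("m1", _metrics(spike_rate=5), _metrics(spike_rate=10))
        assert compute_drug_effect(s).responder_category == "increase"

    def test_zero_pre_value_flags_only_that_metric(self):
        s = summarize_subject("m1", _metrics(spike_rate=0), _metrics(spike_rate=3))
        eff = compute_drug_effect(s)
        assert math.isnan(eff.ratios["spike_rate"]) and "spike_rate" in eff.undefined
        assert eff.ratios["total_power"] == pytest.approx(1.0)
        assert eff.responder_category is None

    def test_rate_equivariance(self):
        # common rescaling of both blocks' rates leaves ratio and category
        a = summarize_subject("m", _metrics(spike_rate=10), _metrics(spike_rate=4))
        b = summarize_subject("m", _metrics(spike_rate=30), _metrics(spike_rate=12))
        ea, eb = compute_drug_effect(a), compute_drug_effect(b)
        assert ea.ratios["spike_rate"] == pytest.approx(eb.ratios["spike_rate"])
        assert ea.responder_category == eb.responder_category


class TestResponderBins:
    @pytest.mark.parametrize("ratio,category", [
        (0.3, "reduction >50%"), (0.5, "reduction 20-50%"), (0.79, "reduction 20-50%"),
        (0.85, "reduction 10-20%"), (0.9, "no change/small"), (1.1, "no change/small"),
        (1.2, "increase"), (5.0, "increase"),
    ])
    def test_bin_lookup(self, ratio, category):
        assert ResponderBins().categorize(ratio) == category

    def test_bins_partition_positive_reals(self, rng):
        bins = ResponderBins()
        for r in rng.random(100) * 4 + 1e-6:
            assert sum(a <= r < b for _, a, b in bins.categories) == 1


def _effect(sid, **ratios):
    return DrugEffect(subject_id=sid, drug="", ratios=ratios,
                      undefined=set(), responder_category=None)


class TestSpearman:
    def test_monotone_increasing_rho_one(self):
        rho, p, n = spearman_pair([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert rho == pytest.approx(1.0) and n == 5

    def test_monotone_decreasing_rho_minus_one(self):
        rho, _, _ = spearman_pair([1, 2, 3, 4, 5], [5, 3, 2, 1, 0])
        assert rho == pytest.approx(-1.0)

    def test_worked_five_point_example(self):
        # rank formula: rho = 1 - 6*sum(d^2)/(n(n^2-1)); d = (-2,1,1,-1,1)
        x = [1, 2, 3, 4, 5]
        y = [3, 1, 2, 5, 4]
        d2 = sum((xi - yi) ** 2 for xi, yi in zip(x, y))
        oracle = 1 - 6 * d2 / (5 * (5 ** 2 - 1))
        rho, p, _ = spearman_pair(x, y)
        assert rho == pytest.approx(oracle) == pytest.approx(0.6)

    def test_exact_permutation_p_against_enumeration(self):
        # independent oracle: enumerate all orderings with the rank formula
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 1.0, 2.0, 5.0, 4.0]

        def rho_of(perm):
            d2 = sum((xi - yi) ** 2 for xi, yi in zip(x, perm))
            return 1 - 6 * d2 / (5 * 24)

        r_obs = rho_of(y)
        count = sum(abs(rho_of(p)) >= abs(r_obs) - 1e-12
                    for p in itertools.permutations(y))
        oracle_p = count / math.factorial(5)
        _, p, _ = spearman_pair(x, y)
        assert p == pytest.approx(oracle_p)

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(12)
        y = rng.random(12)
        r1, _, _ = spearman_pair(x, y)
        r2, _, _ = spearman_pair(np.exp(3 * x), y ** 3 - 5)
        assert r1 == pytest.approx(r2)

    def test_matrix_symmetry_diagonal_and_bounds(self, rng):
        effects = [_effect(f"s{i}", a=float(rng.random()), b=float(rng.random()),
                           c=float(rng.random())) for i in range(8)]
        m = spearman_matrix(effects, metrics=("a", "b", "c"))
        rho = m.rho.to_numpy()
        assert np.allclose(rho, rho.T)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.all(np.abs(rho[np.isfinite(rho)]) <= 1 + 1e-12)

    def test_pairwise_complete_and_insufficient_n(self):
        effects = [_effect("s1", a=1.0, b=math.nan), _effect("s2", a=2.0, b=math.nan),
                   _effect("s3", a=3.0, b=math.nan), _effect("s4", a=4.0, b=1.0)]
        m = spearman_matrix(effects, metrics=("a", "b"))
        assert math.isnan(m.rho.loc["a", "b"])
        assert m.n.loc["a", "b"] == 1

    def test_too_few_subjects_raise(self):
        with pytest.raises(SizeError):
            spearman_matrix([_effect("s1", a=1.0)], metrics=("a",))


def _fisher_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration with math.comb."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    @pytest.mark.parametrize("table", [
        [[5, 5], [5, 5]],
        [[10, 0], [0, 10]],
        [[2, 1], [1, 2]],
        [[8, 2], [3, 7]],
        [[1, 9], [4, 6]],
    ])
    def test_against_enumeration_oracle(self, table):
        assert fisher_exact_2x2(table) == pytest.approx(_fisher_oracle(table), rel=1e-9)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_separation(self):
        # p = 2 / C(20, 10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / math.comb(20, 10))

    def test_category_collapse(self):
        a = ["reduction >50%"] * 5 + ["increase"] * 5
        b = ["reduction 20-50%"] * 5 + ["no change/small"] * 5
        # collapsed table [[5,5],[5,5]] -> p = 1
        assert category_table_test(a, b) == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(SizeError):
            category_table_test([], ["increase"])
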