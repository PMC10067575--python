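"""Cohort-level drug-effect statistics with a planted correlation.

Generates a 12-subject cohort whose spike-rate multipliers and power
scales share a Spearman-0.9 rank dependence, analyzes every session, and
prints the responder breakdown and the recovered correlation between the
spike-rate change and the total-power change.
"""

from collections import Counter

from ecogkit.pipeline import AnalysisParams, analyze_session, compare_cohort
from ecogkit.synthetic import CohortSpec, gen_cohort

spec = CohortSpec(n_subjects=12, planted_correlation=0.9, master_seed=4)
sessions, truth = gen_cohort(spec)

params = AnalysisParams(acclimation_s=5.0, block_len_s=240.0, qc_min_epochs=10)
results = [analyze_session(rec, params) for rec, _ in sessions]
effects, matrix = compare_cohort(results)

print("responder categories:")
for cat, n in Counter(e.responder_category for e in effects).most_common():
    print(f"  {cat}: {n}/{len(effects)} subjects")

rho = matrix.rho.loc["spike_rate", "total_power"]
p = matrix.p.loc["spike_rate", "total_power"]
print(f"\nSpearman(spike-rate change, total-power change): "
      f"rho = {rho:.2f} (planted 0.9), p = {p:.4f}, n = {len(effects)}")
# rho near the planted value means the pipeline's per-subject change
# ratios preserve the cohort's rank structure
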