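"""Awake-immobile epoch selection on a block with scheduled movement.

Builds a 120 s block whose EMG contains two movement bursts, computes the
per-epoch features (delta power, theta/delta ratio, EMG envelope ratio)
and shows which epochs the three-condition filter keeps.  Epochs that
overlap a burst must fail condition iii (the TKEO envelope scales with
the squared burst gain).
"""

import numpy as np

from ecogkit.epoch_select import compute_epoch_features, epoch_qc, select_epochs
from ecogkit.io_signals import AnalysisBlock
from ecogkit.preprocess import envelope_emg
from ecogkit.spectral import make_epochs
from ecogkit.synthetic import BackgroundSpec, gen_background, gen_emg

FS = 500.0
bursts = [(30.0, 40.0, 8.0), (80.0, 90.0, 8.0)]

ecog, _ = gen_background(BackgroundSpec(duration_s=120.0, sample_rate_hz=FS), seed=2)
emg, _ = gen_emg(120.0, FS, bursts, seed=3)

block = AnalysisBlock("pre", 0.0, 120.0)
grid = make_epochs(block)
envelope = envelope_emg(emg, FS)
features = compute_epoch_features(ecog, envelope, grid, FS)
result = select_epochs(features, envelope, grid, qc_min=10)
ok, report = epoch_qc(result, minimum=10)

print(f"epochs: {result.n_epochs}, accepted: {sorted(result.accepted)}")
print("thresholds:", {k: round(v, 3) for k, v in result.thresholds.items()})
print("rejections per condition:", result.rejections)
print(f"QC (>=10 epochs): {'PASS' if ok else 'FAIL'}")

burst_epochs = {k for k, t0 in enumerate(grid.starts_s)
                if any(s < t0 + 5 and e > t0 for s, e, _ in bursts)}
print(f"epochs overlapping a burst: {sorted(burst_epochs)} "
      f"(none accepted: {not (burst_epochs & result.accepted)})")
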