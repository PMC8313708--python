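"""Resting-state connectivity from ROI-correlated CBV fluctuations.

Simulates low-frequency CBV noise with a two-block correlation structure
(ρ=0.7 within blocks), extracts ROI signals, low-pass filters at 0.1 Hz and
prints the recovered Pearson connectivity matrix.
"""

import numpy as np

from bps.functional import StimulusPattern, connectivity_matrix, lowpass
from bps.phantom import simulate_functional_timeseries

rho = 0.7
corr = np.eye(4)
corr[0, 1] = corr[1, 0] = rho
corr[2, 3] = corr[3, 2] = rho
labels = np.arange(1, 5).reshape(2, 2).repeat(4, axis=0).repeat(4, axis=1)
stim = StimulusPattern(600, 0, 0, 0)  # 600 s resting-state block, no stimulus
series = simulate_functional_timeseries(labels, stim, {}, noise_sd=0.05,
                                        rate_hz=2.5, corr=corr, seed=0)
roi = np.array([series[labels == k][0] for k in range(1, 5)])
cm = connectivity_matrix(lowpass(roi, cutoff_hz=0.1, rate_hz=2.5),
                         roi_ids=["L1", "L2", "R1", "R2"])
print("connectivity matrix (0.1 Hz low-passed, 600 s at 2.5 Hz):")
with np.printoptions(precision=2, suppress=True):
    print(cm.r)
print(f"-> within-block correlations recover ρ≈{rho}; across-block stay near 0.")
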