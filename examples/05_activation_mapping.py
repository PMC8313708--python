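"""Task-evoked activation mapping on a stimulus-locked phantom.

Simulates CBV time series over a labelled field with a 5% response confined
to one region under the 30 s baseline + 3×(30 ON / 30 OFF) protocol, fits
the GLM and reports Bonferroni-significant voxels.
"""

import numpy as np

from bps.functional import StimulusPattern, activation_map, build_design
from bps.phantom import simulate_functional_timeseries

stim = StimulusPattern(baseline_s=30, n_trials=3, on_s=30, off_s=30)
labels = np.zeros((24, 24), int)
labels[4:10, 4:10] = 1    # responding region
labels[14:20, 12:20] = 2  # silent region
series = simulate_functional_timeseries(labels, stim, {1: 0.05}, noise_sd=0.05,
                                        rate_hz=2.5, seed=0)
X = build_design(stim, rate_hz=2.5)
amap = activation_map(series, X, alpha=0.05)
sig = amap.significant
inside = sig[labels == 1].sum()
print(f"protocol: {stim.total_s:.0f} s, {X.shape[0]} Doppler frames at 2.5 Hz")
print(f"per-voxel threshold p < {amap.p_threshold:.1e} (Bonferroni over {sig.size} voxels)")
print(f"significant voxels: {sig.sum()} total, {inside} inside the stimulated region")
print(f"peak z-score: {np.nanmax(amap.z):.1f}")
print("-> activation localizes to the region carrying the simulated response.")
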