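"""Clutter filtering and Power Doppler from a simulated frame stack.

Builds a rank-structured tissue+blood ensemble (200 compounded frames at
500 Hz, the standard imaging block), removes the tissue clutter with the SVD
filter and prints the block arithmetic and the blood/background contrast of
the resulting Power Doppler image.
"""

import numpy as np

from bps.doppler import compound_frame_rate, doppler_frame_rate, power_doppler, svd_clutter_filter
from bps.phantom import simulate_frame_stack

rate = compound_frame_rate(prf_hz=5500, n_angles=11)
doppler_hz, block_s = doppler_frame_rate(block_frames=200, compound_rate_hz=rate)
print(f"compound frame rate : {rate:.0f} Hz (5500 Hz PRF / 11 plane waves)")
print(f"Doppler frame rate  : {doppler_hz:.1f} Hz ({block_s*1e3:.0f} ms blocks)")

mask = np.zeros((48, 48), bool)
mask[10:38, 22:26] = True  # a vertical vessel
stack = simulate_frame_stack(200, grid=(48, 48), tissue_rank=4, blood_mask=mask,
                             blood_power=1.0, tissue_power=400.0,
                             noise_power=0.01, seed=0)
pd_raw = power_doppler(stack)
pd = power_doppler(svd_clutter_filter(stack, cutoff_rank=4))
contrast_raw = pd_raw[mask].mean() / pd_raw[~mask].mean()
contrast = pd[mask].mean() / pd[~mask].mean()
print(f"vessel/background contrast before filtering: {contrast_raw:5.1f}")
print(f"vessel/background contrast after  filtering: {contrast:5.1f}")
print("-> the SVD filter strips the dominant tissue components so the "
      "Power Doppler image is blood-weighted.")
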