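"""Super-resolution bubble tracking and misalignment quantification.

Simulates a microbubble movie on a vascular tree, runs detection → Hungarian
linking → map rendering, scores track recovery against the exact ground
truth, then measures a constructed 40 µm offset between two map renderings
with the demons displacement field.
"""

import numpy as np

from bps.phantom import generate_vessel_tree, simulate_bubble_movie
from bps.ulm import (demons_displacement, detect_bubbles, link_tracks,
                     mean_misalignment, render_ulm_maps, track_recovery_stats)

tree = generate_vessel_tree(2)
stack, truth = simulate_bubble_movie(tree, n_bubbles=12, seed=2, n_frames=60)
px = stack.pixel_size_mm
dets = [detect_bubbles(stack.data[:, :, f], threshold=0.3, psf_radius=3,
                       pixel_size_mm=px, frame_index=f)
        for f in range(stack.n_frames)]
found = link_tracks(dets, max_link_dist=0.05, min_track_length=4,
                    frame_rate_hz=stack.compound_rate_hz)
frac, loc_err = track_recovery_stats(truth, found, match_tol_mm=px[0])
print(f"recovered {100*frac:.0f}% of ground-truth tracks, "
      f"localization error {loc_err/px[0]:.2f} px ({loc_err*1000:.1f} um)")

maps_a = render_ulm_maps(found, pixel_size_mm=0.005)
shift_mm = 0.040
shifted = [type(t)(t.frames, t.positions_mm + [shift_mm, 0.0]) for t in found.tracks]
maps_b = render_ulm_maps(type(found)(shifted, found.frame_rate_hz),
                         pixel_size_mm=0.005,
                         extent_mm=(maps_a.density.shape[0] * 0.005,
                                    maps_a.density.shape[1] * 0.005))
field = demons_displacement(maps_a.density, maps_b.density)
res = mean_misalignment(field, maps_a.density > 0, maps_b.density > 0, 0.005)
print(f"constructed offset 40 um; demons-recovered "
      f"({res.mean_shift_um[0]:.1f}, {res.mean_shift_um[1]:.1f}) um")
print("-> 5 um map pixels resolve misalignments far below the 100 um "
      "Doppler voxel.")
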