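"""Atlas overlay and probe-plane targeting on a synthetic session.

Propagates mini-atlas labels into a subject volume through a composed
subject→reference→atlas transform, defines an oblique imaging plane through
two atlas markers (one per hemisphere, as for a V1↔S1 targeting) and solves
the 4-DOF stage pose that reaches it.
"""

import numpy as np

from bps.geometry import AffineTransform3D
from bps.navigation import (compose_transforms, make_synthetic_atlas,
                            plane_from_markers, propagate_labels,
                            solve_stage_pose)
from bps.registration import GridSpec

atlas = make_synthetic_atlas()
subject_to_ref = AffineTransform3D.from_translation((0.2, -0.1, 0.05))
ref_to_atlas = AffineTransform3D.identity()
subject_to_atlas = compose_transforms(ref_to_atlas, subject_to_ref)

grid = GridSpec(atlas.labels.shape, atlas.spacing_mm, atlas.origin_mm)
labels = propagate_labels(atlas, subject_to_atlas, grid)
n = len(np.unique(labels)) - 1
print(f"propagated {n} atlas regions into the subject grid")

m1 = (1.2, 2.8, 1.5)   # marker in one hemisphere
m2 = (5.0, 1.6, 1.5)   # marker in the other
plane = plane_from_markers(m1, m2)
pose = solve_stage_pose(plane)
print(f"oblique plane through markers: yaw {pose.yaw_deg:.1f} deg, "
      f"centre ({pose.x_mm:.2f}, {pose.y_mm:.2f}, {pose.z_mm:.2f}) mm")
print("-> the motors move to this pose so the probe images both targets "
      "in a single oblique slice.")
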