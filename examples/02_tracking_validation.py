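"""Validate the block-matching tracker against phantom ground truth.

Builds a speckle phantom with synchronous pulsatile motion, tracks the four
annotated interfaces, and compares the trajectories with the exact material
paths of the warp.
"""

import numpy as np

import plaquesync as ps

model = ps.MotionModel(seed=1)
seq, truth, contours = ps.generate_image_sequence(model, ps.PhantomGeometry())
trajectories = ps.track_rois(seq, contours)

for name in ("AWL", "PWL", "PTS", "PBS"):
    sl = slice(25, -25) if name in ("PTS", "PBS") else slice(None)
    err = np.sqrt(
        np.mean(
            (trajectories[name].rows[sl] - truth[name].rows[sl]) ** 2
            + (trajectories[name].cols[sl] - truth[name].cols[sl]) ** 2
        )
    )
    print(f"{name}: RMS trajectory error {err:.2f} px")
# Errors well below one pixel mean the tracker follows the speckle pattern
# at sub-pixel accuracy (plaque surfaces evaluated after 25-px edge trim).
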