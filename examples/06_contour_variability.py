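"""Test robustness of the phase shifts to annotation variability.

Different observers outline the same tissue within about 2 px of each
other.  All contours are displaced radially by sub-pixel to 2-px offsets,
the pipeline is re-run, and the per-pair phase-shift distributions are
compared with the original annotation by rank-sum test.
"""

import plaquesync as ps

model = ps.MotionModel(top_bottom_delay=0.3, seed=1)
seq, _, contours = ps.generate_image_sequence(model, ps.PhantomGeometry())

table = ps.variability_experiment(seq, contours, offsets=(0.5, 1.0, 2.0))
print(table.round(3))
# p-values above 0.05 for every offset and correlation type mean the
# measured phase shifts are insensitive to plausible annotation differences.
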