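"""Grayscale-normalise a phantom and compute the plaque GSM label.

Reference regions are picked inside the lumen (blood) and below the
posterior wall (adventitia); after normalisation their medians anchor at 0
and 190, and the plaque grayscale median decides echolucent vs echogenic.
"""

import numpy as np

import plaquesync as ps

geom = ps.PhantomGeometry()
seq, truth, _ = ps.generate_image_sequence(ps.MotionModel(seed=3), geom)

rr, cc = np.mgrid[int(geom.awl_row) + 4 : int(geom.awl_row) + 13, 30:45]
blood = np.stack([rr.ravel(), cc.ravel()], axis=1)
rr, cc = np.mgrid[int(geom.pwl_row) + 4 : int(geom.pwl_row) + 13, 30:45]
adventitia = np.stack([rr.ravel(), cc.ravel()], axis=1)
refs = ps.ReferenceRegions(blood=blood, adventitia=adventitia)

normalised = ps.normalise_grayscale(seq.frames[0], refs)
mb, ma = refs.medians(normalised)
print(f"normalised reference medians: blood {mb:.1f}, adventitia {ma:.1f}")

result = ps.plaque_gsm(seq, truth["PTS"], truth["PBS"], refs)
print(f"plaque GSM = {result.gsm:.1f} -> {result.label}")
# GSM < 25 marks a dark (echolucent, lipid-rich appearing) plaque; the
# phantom's plaque reflectivity of 60 yields an echogenic label.
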