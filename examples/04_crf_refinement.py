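"""Dense 3D CRF refinement: energies, and removal of isolated regions.

A fully connected CRF couples every voxel pair through a spatial
smoothness kernel and an intensity-aware appearance kernel (Potts
compatibility: only disagreeing labels pay).  Mean-field inference
lowers the energy of the labeling; a classic effect is that small
isolated low-confidence regions are absorbed by their surroundings.
"""

import numpy as np

from mpsseg import CRFParams, crf_energy, mean_field_refine

shape = (7, 7, 7)
p = np.zeros((4,) + shape)
p[0] = 0.95                      # confident background everywhere ...
p[1:] = 0.05 / 3
p[:, 3, 3, 3] = [0.45, 0.0, 0.0, 0.55]  # ... except one weak "tumor" voxel
feats = np.zeros((4,) + shape)   # homogeneous intensities

params = CRFParams()  # grid-searched defaults: w1=2.5, w2=4.0, 5 iterations
before = p.argmax(axis=0)
refined, labels = mean_field_refine(p, feats, params, mode="dense")

e_before = crf_energy(before, p, feats, params)
e_after = crf_energy(labels.to_class_indices(), p, feats, params)
print(f"isolated foreground voxels before refinement: {(before > 0).sum()}")
print(f"after 5 mean-field iterations               : {(labels.labels > 0).sum()}")
print(f"CRF energy: {e_before:.2f} -> {e_after:.2f} (lower is better)")
print("the lone weak voxel is relabeled to background: the pairwise "
      "potentials outweigh its 0.55 unary preference")
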