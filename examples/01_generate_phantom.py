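"""Generate a synthetic multi-modal brain-tumor phantom and inspect it.

The phantom emulates the layout the segmentation model assumes: four MR
sequences (T1, T1C, T2, FLAIR) over a zero-intensity background, a
healthy-brain ellipsoid, and a nested tumor — necrotic core (label 1)
inside an enhancing shell (label 4) inside edema (label 2).
"""

import numpy as np

from mpsseg import PhantomConfig, generate_phantom, merge_regions

cfg = PhantomConfig(seed=42)
vol, lab = generate_phantom(cfg)

print(f"volume shape {vol.shape}, channels T1/T1C/T2/FLAIR")
for raw, name in [(0, "background+healthy"), (2, "edema"), (4, "enhancing"), (1, "necrotic")]:
    n = int((lab.labels == raw).sum())
    print(f"  label {raw} ({name:>18}): {n:7d} voxels "
          f"({100 * n / lab.labels.size:.2f}%)")

masks = merge_regions(lab)
print("nested evaluation regions:",
      {r: int(m.mask.sum()) for r, m in masks.items()})
print("nesting ET <= TC <= WT holds:",
      bool(np.all(masks["ET"].mask <= masks["TC"].mask)
           and np.all(masks["TC"].mask <= masks["WT"].mask)))

# contrast sanity: each tumor compartment is conspicuous in one sequence
flair, t1ce = vol.channel("flair"), vol.channel("t1ce")
healthy = (lab.labels == 0) & (flair != 0)
print(f"FLAIR mean, edema vs healthy: {flair[lab.labels == 2].mean():.0f} "
      f"vs {flair[healthy].mean():.0f}  (edema bright in FLAIR)")
print(f"T1C mean, enhancing vs necrotic: {t1ce[lab.labels == 4].mean():.0f} "
      f"vs {t1ce[lab.labels == 1].mean():.0f}  (rim bright, core dark in T1C)")
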