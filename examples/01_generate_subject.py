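"""Generate one synthetic subject and look at its structure.

A subject is 2 modalities (execution, imagery) x 4 sessions x 12 blocks of
beta patterns over 370 ROI voxels.  Imagery blocks reuse the execution
finger patterns at scale s = 0.3 — a scaled-down shared finger code.
"""

import numpy as np

from fingermvpa import SynthConfig, generate_subject

cfg = SynthConfig(seed=1)
ds = generate_subject(cfg)

print(f"betas shape (modality, session, block, voxel): {ds.betas.shape}")
print(f"finger labels of execution session 1: {ds.labels[0, 0]}")

# the generating finger patterns are retained for recovery checks
v = ds.truth["finger_patterns"]
corr = np.corrcoef(v)
print("correlation between neighbouring finger patterns "
      f"(somatotopic overlap): {corr[0, 1]:.2f}, {corr[1, 2]:.2f}, {corr[2, 3]:.2f}")
print(f"correlation between index and ring patterns: {corr[0, 2]:.2f}")

# imagery condition means correlate with the execution code but are weaker
exec_mean = ds.condition_means(0).mean(axis=0)   # 4 fingers x voxels
imag_mean = ds.condition_means(1).mean(axis=0)
r = np.corrcoef(exec_mean[0], imag_mean[0])[0, 1]
print(f"exec/imagery same-finger pattern correlation (noisy estimate): {r:.2f}")
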