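"""Per-slice thresholds and preprocessing diagnostics under intensity drift.

Deep slices of a confocal stack are darker (refractive-index mismatch,
bleaching).  Thresholding each slice separately compensates: the material
fraction stays constant even when the absolute intensity halves.  The
example also shows what the closing/hole-filling/cluster-removal stages
added and removed.
"""

import numpy as np

from netskel import BinarizationParams, ImageStack, VoxelGeometry, preprocess_stack
from netskel.phantoms import corrupt, make_junction

volume, _ = make_junction(radius=2.0)
stack = ImageStack(volume.material.astype(float) * 200, volume.geometry)
nz = stack.shape[0]
noisy = corrupt(stack, noise_sd=10.0, drift_per_slice=0.5 / nz, seed=1)

binary, labels, report = preprocess_stack(
    noisy,
    params=BinarizationParams(method="percentile", v_u=0.5),
    blur_widths=1.0,
    sigma=4.0,
)

print("slice  I_10    I_90    I_T")
for rec in report.thresholds[:: max(nz // 6, 1)]:
    print(f"{rec.slice_index:5d}  {rec.i_10:6.1f}  {rec.i_90:6.1f}  {rec.i_t:6.1f}")
print(f"\nmaterial voxels: {binary.count()}")
print(f"voxels added by closing/filling: {int(report.added.sum())}")
print(f"voxels removed as small clusters: {int(report.removed.sum())}")
print(f"clusters found: {len(report.cluster_sizes)}, kept: {report.n_clusters_kept}")
print("\nThe threshold I_T tracks the per-slice I_10/I_90, so the deeper,")
print("darker slices still binarize to the same structure.")
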