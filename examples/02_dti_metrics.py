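"""Fit a diffusion tensor from multi-direction signals and compute AD/RD/MD/FA.

Simulates noiseless diffusion-weighted signals from a known anisotropic
tensor (61 directions, b = 1000 s/mm^2, the usual clinical protocol scale),
refits the tensor by log-linear least squares and summarises a small ROI by
its median metric values.
"""

import numpy as np

from radnet.dti import fit_tensor, roi_median, scalar_metrics

rng = np.random.default_rng(0)
gradients = rng.standard_normal((61, 3))
gradients /= np.linalg.norm(gradients, axis=1, keepdims=True)

truth = np.diag([1.5e-3, 1.0e-3, 0.5e-3])  # mm^2/s
b = 1000.0
signals = 1000.0 * np.exp(-b * np.einsum("ij,jk,ik->i", gradients, truth, gradients))

tensor = fit_tensor(1000.0, signals, gradients, b)
m = scalar_metrics(tensor)
print(f"AD = {m.AD:.4e}  RD = {m.RD:.4e}  MD = {m.MD:.4e}  FA = {m.FA:.4f}")
# MD is the orientation-averaged diffusivity (here exactly 1.0e-3 mm^2/s);
# FA ~ 0.46 reflects the moderate eigenvalue spread of the planted tensor.

voxel_mds = rng.normal(1.0e-3, 1e-4, size=201)
print(f"ROI median MD over 201 voxels: {roi_median(voxel_mds):.4e}")
# the median, not the mean, is the per-sample trait entering the pipeline
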