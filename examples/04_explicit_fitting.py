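"""Fit a Gaussian DAP explicitly: subspace LK search + MAP shape fusion.

Each landmark's patches are aligned against the mean-appearance template
in the orthogonal complement of the appearance eigenspace; the per-scale
predictions are fused with the PCA shape prior by the closed-form MAP
shape.  Prints the fusion-energy trace and the landmark error before and
after fitting one held-out instance.
"""

import numpy as np

from dap import PhantomSpec, fit_explicit, generate_dataset, train_dap_model

spec = PhantomSpec(seed=31)
ds = generate_dataset(spec, 45)
model = train_dap_model(ds.images[:40], ds.shapes[:40], kind="gaussian")

i = 42  # held-out instance
pyr = model.geometry.build_pyramid(ds.images[i])
s0 = model.shape_model.mean_shape()
fitted, state = fit_explicit(pyr, model, s0, outer_iters=8)

truth = ds.shapes[i].points
e0 = np.mean(np.linalg.norm(s0.points - truth, axis=1))
e1 = np.mean(np.linalg.norm(fitted.points - truth, axis=1))
print("fusion energy per outer iteration:",
      [f"{e:.1f}" for e in state.energies])
print(f"mean landmark error: {e0:.2f} px (mean-shape init) -> {e1:.2f} px")
print(f"outer iterations used: {state.iteration}")
print("(each outer iteration re-runs the patch searches from the fused "
      "shape, so the energies index different observation sets and need "
      "not decrease across iterations; the landmark error drops toward "
      "the method's subpixel accuracy floor)")
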