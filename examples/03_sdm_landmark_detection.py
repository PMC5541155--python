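"""Detect landmarks with the implicit (supervised-descent) wavelet DAP.

Trains the priors and a 3-stage cascade of ridge regressors on 40 phantom
instances, then fits 10 held-out instances from the mean shape.  Prints
the per-stage training error and the held-out point-to-boundary distance
(PtoBD, px) and Dice overlap (DSC, %) against the mean-shape baseline.
"""

import numpy as np

from dap import PhantomSpec, apply_sdm, generate_dataset, train_dap_model, train_sdm
from dap.metrics import dice_coefficient, point_to_boundary

spec = PhantomSpec(seed=21)
ds = generate_dataset(spec, 50)
model = train_dap_model(ds.images[:40], ds.shapes[:40], kind="wavelet")
cascade = train_sdm(ds.images[:40], ds.shapes[:40], model, stages=3, seed=0)
print("training mean landmark error per stage:",
      [f"{e:.2e}" for e in cascade.training_errors])

groups = {"disc": np.arange(spec.n_outer),
          "canal": np.arange(spec.n_outer, spec.n_landmarks)}
pt, dc, pt0 = [], [], []
for i in range(40, 50):
    pyr = model.geometry.build_pyramid(ds.images[i])
    fitted = apply_sdm(pyr, model)
    contours = [ds.shapes[i].points[idx] for idx in groups.values()]
    pt.append(point_to_boundary(fitted, contours, list(groups.values()))[1])
    pt0.append(point_to_boundary(cascade.initial_shape(), contours,
                                 list(groups.values()))[1])
    dc.append(dice_coefficient(fitted, ds.shapes[i], groups, spec.image_size)[1])

print(f"held-out PtoBD: {np.mean(pt):.3f} px "
      f"(mean-shape init: {np.mean(pt0):.3f} px)")
print(f"held-out DSC:   {100 * np.mean(dc):.1f} %")
print("(the cascade removes most of the initialization error in 3 linear "
      "stages; DSC near 100% means the fitted contours overlap the truth)")
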