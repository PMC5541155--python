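"""Decompose an image into complementary octave subbands and invert.

Builds the raised-cosine spectral windows, splits a textured image into a
3-level wavelet pyramid, and reconstructs it.  Prints the per-band energy
shares (how the signal splits across scales) and the round-trip error,
which is at floating-point level because the squared windows tile the
spectrum exactly.
"""

import numpy as np
from scipy import ndimage

from dap import (
    band_energies,
    build_spectral_windows,
    build_wavelet_pyramid,
    reconstruct_from_wavelet,
)

rng = np.random.default_rng(0)
image = ndimage.gaussian_filter(rng.normal(size=(128, 128)), 1.0)

windows = build_spectral_windows((128, 128), L=3)
pyramid = build_wavelet_pyramid(image, windows)
recon = reconstruct_from_wavelet(pyramid, windows)

energies = band_energies(pyramid)
print("level shapes:", [lev.shape for lev in pyramid.levels])
for l, share in enumerate(energies / energies.sum(), start=1):
    print(f"  band {l} energy share: {share:.3f}")
print("sum of band energies / image energy:",
      f"{energies.sum() / np.sum(image**2):.12f}")
err = np.linalg.norm(recon - image) / np.linalg.norm(image)
print(f"analysis->synthesis relative L2 error: {err:.2e}")
print("(shares show most energy of a smoothed texture sits in the coarse "
      "bands; the ~1e-16 error confirms the subbands are complementary)")
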