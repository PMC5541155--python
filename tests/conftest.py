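"""Shared fixtures: one synthetic phantom population and trained models.

The population (M=250, seed 7) and the models trained on its first 200
instances are session-scoped because training is the expensive step; tests
must not mutate them (except ``train_sdm`` attaching the cascade, which is
itself a fixture).
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import dap
from dap.synthetic import PhantomSpec, generate_dataset

SEED = 7
N_TRAIN = 200
N_TEST = 50


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec(seed=SEED)


@pytest.fixture(scope="session")
def population(spec):
    return generate_dataset(spec, N_TRAIN + N_TEST)


@pytest.fixture(scope="session")
def train_split(population):
    return population.images[:N_TRAIN], population.shapes[:N_TRAIN]


@pytest.fixture(scope="session")
def test_indices():
    return list(range(N_TRAIN, N_TRAIN + N_TEST))


@pytest.fixture(scope="session")
def wavelet_model(train_split):
    images, shapes = train_split
    return dap.train_dap_model(images, shapes, kind="wavelet")


@pytest.fixture(scope="session")
def sdm_model(wavelet_model, train_split):
    images, shapes = train_split
    dap.train_sdm(images, shapes, wavelet_model, stages=4, seed=0)
    return wavelet_model


@pytest.fixture(scope="session")
def gaussian_model(train_split):
    images, shapes = train_split
    return dap.train_dap_model(images, shapes, kind="gaussian")


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 30-instance population for unit-scale checks."""
    return generate_dataset(PhantomSpec(seed=3), 30)


@pytest.fixture(scope="session")
def contour_groups(spec):
    """Landmark index groups of the phantom's two anatomical contours."""
    return {
        "disc": np.arange(spec.n_outer),
        "canal": np.arange(spec.n_outer, spec.n_landmarks),
    }


@pytest.fixture(scope="session")
def shift_fixture():
    """Smooth textured image + landmark grid + zero-variation DAP model.

    Training on two identical annotated copies leaves the appearance PCA
    with zero retained components, so the subspace LK search reduces to
    template alignment on a known image — the fixture for pure-translation
    recovery.
    """
    rng = np.random.default_rng(42)
    base = ndimage.gaussian_filter(rng.normal(size=(96, 96)), 2.0)
    pts = np.array([[r, c] for r in (32, 48, 64) for c in (32, 48, 64)], float)
    shapes = [dap.Shape(pts)] * 2
    model = dap.train_dap_model([base] * 2, shapes, kind="gaussian", L=2, p=17)
    return base, pts, model


def translate_periodic(image: np.ndarray, shift) -> np.ndarray:
    """Subpixel translation by Fourier phase shift (periodic, noise-free)."""
    return np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(image), shift)).real
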