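"""Gaussian and wavelet (Fourier subband) image pyramids.

Both pyramids step in octaves: level 1 is the input resolution and each
subsequent level halves the resolution per axis (``ceil(base / 2**(l-1))``).
The Gaussian pyramid is the classic smooth-and-decimate stack with
*redundant* channels; the wavelet pyramid splits the spectrum into
*complementary* octave subbands whose squared windows tile the frequency
plane, so the original image can be recovered exactly from the levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "ImagePyramid",
    "SpectralWindowSet",
    "build_gaussian_pyramid",
    "build_spectral_windows",
    "build_wavelet_pyramid",
    "reconstruct_from_wavelet",
    "band_energies",
    "level_shape",
]


def level_shape(base_shape: tuple[int, int], l: int) -> tuple[int, int]:
    """Shape of pyramid level ``l`` (1-based): ``ceil(base / 2**(l-1))``."""
    f = 2 ** (l - 1)
    return (-(-base_shape[0] // f), -(-base_shape[1] // f))


@dataclass
class ImagePyramid:
    """An L-level stack of 2-D images, finest (level 1) first."""

    levels: list[np.ndarray]
    kind: Literal["gaussian", "wavelet"]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("pyramid needs at least one level")
        base = self.levels[0].shape
        for i, lev in enumerate(self.levels):
            expect = level_shape(base, i + 1)
            if lev.shape != expect:
                raise ValueError(
                    f"level {i + 1} has shape {lev.shape}, expected {expect}"
                )

    @property
    def L(self) -> int:
        return len(self.levels)

    @property
    def base_shape(self) -> tuple[int, int]:
        return self.levels[0].shape


@dataclass
class SpectralWindowSet:
    """Radial raised-cosine windows whose squares tile the spectrum.

    ``windows[l-1]`` is the (full-grid, fftshift-free) window of level ``l``
    on the base image's FFT grid.  Octave cutoffs sit at ``pi / 2**l`` radians
    with a cosine-squared transition over ``transition_width`` octaves in
    log-frequency; the last window is the low-pass residual.  For every
    frequency bin ``sum_l W_l**2 == 1``.
    """

    windows: list[np.ndarray]
    base_shape: tuple[int, int]
    transition_width: float
    cutoffs: list[float] = field(default_factory=list)

    @property
    def L(self) -> int:
        return len(self.windows)


def _check_levels(shape: tuple[int, int], L: int) -> None:
    if L < 1:
        raise ValueError("L must be >= 1")
    if min(shape) / 2 ** (L - 1) < 4:
        raise ValueError(
            f"L={L} leaves a level smaller than 4 px for base shape {shape}"
        )


def build_gaussian_pyramid(
    image: np.ndarray, L: int, sigma: float = 1.0
) -> ImagePyramid:
    """Smooth-and-decimate pyramid; level 1 is the input itself.

    Each coarser level applies a Gaussian (reflect boundary) and keeps the
    even-index samples.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    _check_levels(image.shape, L)
    levels = [image]
    for _ in range(1, L):
        sm = ndimage.gaussian_filter(levels[-1], sigma, mode="reflect")
        levels.append(sm[::2, ::2])
    return ImagePyramid(levels=levels, kind="gaussian")


def _radial_frequency(shape: tuple[int, int]) -> np.ndarray:
    """|omega| in radians/sample on the unshifted FFT grid."""
    wr = 2.0 * np.pi * np.fft.fftfreq(shape[0])
    wc = 2.0 * np.pi * np.fft.fftfreq(shape[1])
    return np.hypot(wr[:, None], wc[None, :])


def _lowpass_energy(omega: np.ndarray, cutoff: float, width: float) -> np.ndarray:
    """cos^2 step in log2-frequency: 1 below cutoff/2**width, 0 above cutoff."""
    out = np.zeros_like(omega)
    with np.errstate(divide="ignore"):
        u = np.where(omega > 0, np.log2(omega / cutoff) / width + 1.0, 0.0)
    u = np.clip(u, 0.0, 1.0)
    out = np.cos(0.5 * np.pi * u) ** 2
    out[omega == 0] = 1.0
    return out


def build_spectral_windows(
    base_shape: tuple[int, int], L: int, transition_width: float = 0.5
) -> SpectralWindowSet:
    """Build the L multi-scale spectral windows for ``base_shape``.

    Window ``l`` (1-based) occupies the octave band ``[pi/2**l, pi/2**(l-1)]``
    plus its transition; window ``L`` additionally passes everything below.
    The squared windows telescope to exactly 1 per bin.
    """
    if not 0.0 < transition_width < 1.0:
        raise ValueError("transition_width must lie in (0, 1)")
    _check_levels(base_shape, L)
    omega = _radial_frequency(base_shape)
    cutoffs = [np.pi / 2**l for l in range(1, L)]
    # G[l] is the squared low-pass at cutoff pi/2**(l+1); energies telescope.
    energies = []
    prev = np.ones_like(omega)
    for c in cutoffs:
        g = _lowpass_energy(omega, c, transition_width)
        energies.append(prev - g)
        prev = g
    energies.append(prev)  # low-pass residual
    windows = [np.sqrt(np.clip(e, 0.0, None)) for e in energies]
    return SpectralWindowSet(
        windows=windows,
        base_shape=tuple(base_shape),
        transition_width=transition_width,
        cutoffs=cutoffs,
    )


def _crop_slices(full: int, small: int) -> slice:
    """Centered half-open index range in fftshift coordinates."""
    start = full // 2 - small // 2
    return slice(start, start + small)


def _crop_spectrum(F: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    Fs = np.fft.fftshift(F)
    r = _crop_slices(F.shape[0], shape[0])
    c = _crop_slices(F.shape[1], shape[1])
    return np.fft.ifftshift(Fs[r, c])


def _pad_spectrum(F: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=complex)
    Fs = np.fft.fftshift(F)
    r = _crop_slices(shape[0], F.shape[0])
    c = _crop_slices(shape[1], F.shape[1])
    out_s = np.fft.fftshift(out)
    out_s[r, c] = Fs
    return np.fft.ifftshift(out_s)


def build_wavelet_pyramid(
    image: np.ndarray, windows: SpectralWindowSet
) -> ImagePyramid:
    """Split ``image`` into complementary octave subbands.

    Level ``l`` is the inverse FFT of the windowed spectrum after cropping
    its central ``1/2**(l-1)`` region per axis (spectral downsampling).  The
    imaginary residue of the inverse transforms is checked (< 1e-9 of the
    level norm) and discarded.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(windows.base_shape):
        raise ValueError(
            f"image shape {image.shape} != windows base {windows.base_shape}"
        )
    F = np.fft.fft2(image)
    levels = []
    for l in range(1, windows.L + 1):
        Fl = F * windows.windows[l - 1]
        shp = level_shape(image.shape, l)
        if shp != Fl.shape:
            Fl = _crop_spectrum(Fl, shp)
        lev = np.fft.ifft2(Fl)
        nrm = np.linalg.norm(lev)
        if nrm > 0 and np.linalg.norm(lev.imag) > 1e-9 * nrm:
            raise FloatingPointError("unexpected imaginary residue in subband")
        levels.append(lev.real)
    return ImagePyramid(levels=levels, kind="wavelet")


def reconstruct_from_wavelet(
    pyramid: ImagePyramid, windows: SpectralWindowSet
) -> np.ndarray:
    """Invert :func:`build_wavelet_pyramid`.

    Zero-pads each level's spectrum back to the base grid, re-applies its
    window and sums; with unmodified levels the round trip is exact to
    floating point because the squared windows tile to unity.
    """
    if pyramid.kind != "wavelet":
        raise ValueError("reconstruction requires a wavelet pyramid")
    if pyramid.L != windows.L or pyramid.base_shape != tuple(windows.base_shape):
        raise ValueError("pyramid/window geometry mismatch")
    acc = np.zeros(windows.base_shape, dtype=complex)
    for l in range(1, pyramid.L + 1):
        Fl = np.fft.fft2(pyramid.levels[l - 1])
        if Fl.shape != tuple(windows.base_shape):
            Fl = _pad_spectrum(Fl, windows.base_shape)
        acc += Fl * windows.windows[l - 1]
    return np.fft.ifft2(acc).real


def band_energies(pyramid: ImagePyramid) -> np.ndarray:
    """Per-level signal energy measured in the base-resolution frame.

    For a wavelet pyramid these sum to ``sum(image**2)`` (Parseval under the
    squared-window tiling).
    """
    rc = float(np.prod(pyramid.base_shape))
    return np.array(
        [np.sum(np.abs(np.fft.fft2(lev)) ** 2) / rc for lev in pyramid.levels]
    )
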