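"""Centered, unitary FFT helpers shared by the simulator and reconstruction.

The DC sample sits at index floor(N/2) on every transformed axis, and the
``ortho`` normalization makes forward/inverse exactly adjoint, so k-space
noise variance maps one-to-one to image-domain variance.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cfftn", "icfftn", "crop_center", "zeropad_center"]


def cfftn(x: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def icfftn(x: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def crop_center(x: np.ndarray, shape: tuple[int, ...],
                axes: tuple[int, ...]) -> np.ndarray:
    """Crop centered k-space to ``shape`` along ``axes``."""
    slices = [slice(None)] * x.ndim
    for ax, n in zip(axes, shape):
        lo = x.shape[ax] // 2 - n // 2
        slices[ax] = slice(lo, lo + n)
    return x[tuple(slices)]


def zeropad_center(x: np.ndarray, shape: tuple[int, ...],
                   axes: tuple[int, ...]) -> np.ndarray:
    """Zero-pad centered k-space to ``shape`` along ``axes``."""
    out_shape = list(x.shape)
    for ax, n in zip(axes, shape):
        out_shape[ax] = n
    out = np.zeros(out_shape, dtype=x.dtype)
    slices = [slice(None)] * x.ndim
    for ax, n in zip(axes, shape):
        lo = n // 2 - x.shape[ax] // 2
        slices[ax] = slice(lo, lo + x.shape[ax])
    out[tuple(slices)] = x
    return out
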