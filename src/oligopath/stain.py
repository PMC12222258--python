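"""H&E stain unmixing and grayscale conversion.

Stains mix additively in optical density (Beer-Lambert), so an RGB pixel is
decomposed by least squares onto the two stain OD vectors. Convention:
base-10 logarithm, incident intensity I0 = 255, epsilon = 1 added before the
log so a zero pixel stays finite; negative unmixing coefficients are clipped
at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import RUIFROK_HE

__all__ = ["StainPair", "optical_density", "unmix_colors", "color_to_gray"]

#: ITU-R BT.601 luma weights, the scikit-image rgb2gray convention.
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class StainPair:
    """Per-pixel hematoxylin and eosin optical-density images."""

    hematoxylin: np.ndarray
    eosin: np.ndarray


def optical_density(pixels: np.ndarray, i0: float = 255.0, eps: float = 1.0) -> np.ndarray:
    """OD = −log10((I + eps) / i0) per channel, floored at 0 (white → 0)."""
    od = -np.log10((pixels.astype(float) + eps) / i0)
    return np.clip(od, 0.0, None)


def unmix_colors(
    pixels: np.ndarray,
    stain_vectors: np.ndarray | None = None,
    i0: float = 255.0,
    eps: float = 1.0,
) -> StainPair:
    """Separate an RGB patch into hematoxylin and eosin OD channels.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
    stain_vectors : 2x3 array of unit OD vectors (H first); defaults to the
        Ruifrok-Johnston H&E pair.

    Each pixel's OD vector is projected onto the stain pair by least
    squares; negative coefficients are clipped to zero.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.size == 0:
        raise ValueError("expected a nonempty (H, W, 3) RGB image")
    sv = RUIFROK_HE if stain_vectors is None else np.asarray(stain_vectors, dtype=float)
    if sv.shape != (2, 3):
        raise ValueError("stain_vectors must be 2x3")
    sv = sv / np.linalg.norm(sv, axis=1, keepdims=True)
    if np.linalg.norm(np.cross(sv[0], sv[1])) < 1e-8:
        raise ValueError("stain vectors are collinear; cannot unmix")

    od = optical_density(pixels, i0=i0, eps=eps).reshape(-1, 3)
    # least-squares coefficients via the normal equations of the 3x2 system
    coeffs, *_ = np.linalg.lstsq(sv.T, od.T, rcond=None)
    coeffs = np.clip(coeffs.T, 0.0, None)
    h = coeffs[:, 0].reshape(pixels.shape[:2])
    e = coeffs[:, 1].reshape(pixels.shape[:2])
    return StainPair(hematoxylin=h, eosin=e)


def color_to_gray(pixels: np.ndarray) -> np.ndarray:
    """Luminance grayscale of an RGB patch (float, same intensity range)."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.size == 0:
        raise ValueError("expected a nonempty (H, W, 3) RGB image")
    return pixels.astype(float) @ _LUMA
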