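"""Contact-map-to-image conversion and edge extraction.

A contact submatrix is rendered as a red-on-white RGB image (high contact
frequency -> red, zero -> white), optionally brightness-adjusted and
mean-blurred, converted to grayscale, and passed through Canny edge
detection.  The resulting binary edge map is the raw material for
vertical-line (stripe border) assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny

__all__ = [
    "EdgeMap",
    "positive_quantile_thresholds",
    "matrix_to_rgb",
    "adjust_brightness",
    "mean_blur",
    "to_grayscale",
    "canny_edges",
    "edge_stack",
]


@dataclass
class EdgeMap:
    """Binary Canny edge matrix ``edges`` with its source image shape."""

    edges: np.ndarray  # bool (h, w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.edges.shape


def positive_quantile_thresholds(values: np.ndarray, quantiles) -> list[float]:
    """Max-pixel-value levels ``M`` from quantiles of positive entries.

    ``M_q`` is the q-quantile (linear interpolation) of the strictly
    positive entries of the chromosome matrix; pixel values above ``M``
    saturate in the rendering.
    """
    quantiles = list(quantiles)
    if any(not (0.0 < q < 1.0) for q in quantiles):
        raise ValueError("quantiles must lie in (0, 1)")
    pos = np.asarray(values)[np.asarray(values) > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive entries")
    return [float(np.quantile(pos, q)) for q in quantiles]


def _round_u8(x: np.ndarray) -> np.ndarray:
    # round-half-to-even, clipped to the displayable range
    return np.clip(np.rint(x), 0, 255).astype(np.uint8)


def matrix_to_rgb(sub: np.ndarray, max_pixel_value: float) -> np.ndarray:
    """Render a submatrix as an (h, w, 3) uint8 image.

    R = 255 everywhere; G = B = max(255*(M-P)/M, 0), so P=0 is white,
    P >= M saturates to pure red.
    """
    if max_pixel_value <= 0:
        raise ValueError("max pixel value must be positive")
    p = np.asarray(sub, dtype=float)
    gb = _round_u8(np.maximum(255.0 * (max_pixel_value - p) / max_pixel_value, 0.0))
    img = np.empty(p.shape + (3,), dtype=np.uint8)
    img[..., 0] = 255
    img[..., 1] = gb
    img[..., 2] = gb
    return img


def adjust_brightness(img: np.ndarray, high_in: float) -> np.ndarray:
    """Linear intensity remap: v/255 -> min(v/high_in, 1), back to [0,255].

    ``high_in=1`` is the identity (up to rounding); smaller values brighten
    and saturate the top of the range, increasing signal/noise contrast.
    """
    if not (0.0 < high_in <= 1.0):
        raise ValueError("high_in must lie in (0, 1]")
    v = img.astype(float) / 255.0
    return _round_u8(np.minimum(v / high_in, 1.0) * 255.0)


def mean_blur(img: np.ndarray, k: int = 3) -> np.ndarray:
    """Per-channel k x k mean filter with replicate borders; k=1 is off."""
    if k < 1 or k % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    if k == 1:
        return img.copy()
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = _round_u8(
            ndimage.uniform_filter(img[..., c].astype(float), size=k, mode="nearest")
        )
    return out


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luma in [0, 1]."""
    f = img.astype(float)
    return (0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2]) / 255.0


def canny_edges(
    gray: np.ndarray,
    sigma: float = 2.0,
    low_threshold: float | None = None,
    high_threshold: float | None = None,
) -> EdgeMap:
    """Canny edge detection on a [0, 1] grayscale image.

    Thresholds default to the detector's automatic choice (fractions of the
    intensity range); only sigma is pinned by the pipeline default.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    e = canny(gray, sigma=sigma, low_threshold=low_threshold, high_threshold=high_threshold)
    return EdgeMap(edges=e.astype(bool))


def edge_stack(
    sub: np.ndarray,
    max_pixel_value: float,
    high_in: float,
    blur_kernel: int = 3,
    sigma: float = 2.0,
) -> EdgeMap:
    """Full image stack: render, brighten, blur, grayscale, Canny."""
    img = matrix_to_rgb(sub, max_pixel_value)
    img = adjust_brightness(img, high_in)
    img = mean_blur(img, blur_kernel)
    return canny_edges(to_grayscale(img), sigma=sigma)
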