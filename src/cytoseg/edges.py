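"""Edge-operator segmentation.

Five classic operators are provided: forward-difference gradient, Roberts,
Sobel, Laplacian and Kirsch. All convolutions reflect at the border so a
uniform frame produces no spurious edges. The Laplacian response is returned
signed (its zero crossing, not its magnitude, marks the edge); the other four
return non-negative magnitudes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .image import BinaryMask, GrayImage

__all__ = ["EDGE_OPERATORS", "edge_magnitude", "edge_mask"]

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)
_SOBEL_Y = _SOBEL_X.T
_ROBERTS_A = np.array([[1, 0], [0, -1]], float)
_ROBERTS_B = np.array([[0, 1], [-1, 0]], float)
_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], float)

# Kirsch compass kernels: the north kernel rotated through 8 directions.
_KIRSCH_N = np.array([[5, 5, 5], [-3, 0, -3], [-3, -3, -3]], float)


def _kirsch_kernels():
    k = _KIRSCH_N
    ring = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
    kernels = []
    vals = [k[r, c] for r, c in ring]
    for shift in range(8):
        rot = np.zeros((3, 3))
        for i, (r, c) in enumerate(ring):
            rot[r, c] = vals[(i - shift) % 8]
        kernels.append(rot)
    return kernels


_KIRSCH = _kirsch_kernels()


def _conv(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return ndi.convolve(img, kernel, mode="reflect")


def _gradient(img: np.ndarray) -> np.ndarray:
    # forward differences; reflected border makes the last row/col difference 0
    dx = np.zeros_like(img)
    dy = np.zeros_like(img)
    dx[:-1, :] = img[1:, :] - img[:-1, :]
    dy[:, :-1] = img[:, 1:] - img[:, :-1]
    return np.abs(dx) + np.abs(dy)


def _roberts(img: np.ndarray) -> np.ndarray:
    return np.hypot(_conv(img, _ROBERTS_A), _conv(img, _ROBERTS_B))


def _sobel(img: np.ndarray) -> np.ndarray:
    return np.hypot(_conv(img, _SOBEL_X), _conv(img, _SOBEL_Y))


def _laplacian(img: np.ndarray) -> np.ndarray:
    return _conv(img, _LAPLACIAN)


def _kirsch(img: np.ndarray) -> np.ndarray:
    return np.max([_conv(img, k) for k in _KIRSCH], axis=0)


EDGE_OPERATORS = {
    "gradient": _gradient,
    "roberts": _roberts,
    "sobel": _sobel,
    "laplacian": _laplacian,
    "kirsch": _kirsch,
}


def edge_magnitude(image: GrayImage, operator: str) -> np.ndarray:
    """Per-pixel edge response of the named operator as a float raster."""
    try:
        fn = EDGE_OPERATORS[operator]
    except KeyError:
        raise ValueError(
            f"unknown operator {operator!r}; choose from {sorted(EDGE_OPERATORS)}"
        ) from None
    img = image.pixels.astype(np.float64)
    if min(img.shape) < 2 or (operator != "roberts" and min(img.shape) < 3):
        raise ValueError("image smaller than the operator kernel")
    return fn(img)


def edge_mask(magnitude: np.ndarray, threshold: float, link: bool = False) -> BinaryMask:
    """Binarize an edge response; pixels with |response| > threshold are kept.

    With ``link``, gaps of up to one pixel are closed morphologically so the
    boundary of a simple convex object becomes one 8-connected closed curve.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = np.abs(np.asarray(magnitude, float)) > threshold
    if link:
        mask = ndi.binary_closing(mask, structure=np.ones((3, 3), bool))
    return BinaryMask(mask)
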