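"""Gray-threshold segmentation and maximum between-class variance thresholding.

Binary thresholding maps a pixel to 1 when f(x, y) ≥ T and to 0 otherwise.
The multiband form assigns output g0 when f ≤ T0, g_k when T_{k-1} < f ≤ T_k,
and g_n when f > T_{n-1}; note the two forms deliberately disagree on the
boundary pixel equal to the threshold — each follows its own convention and
the discrepancy is documented in docs/methods.md.

The automatic threshold maximizes the between-class variance

    σ²_B(t) = θ1 (μ1 − μ)² + θ2 (μ2 − μ)²  =  θ1 θ2 (μ1 − μ2)²

where class 1 is {pixels ≤ t}, class 2 is {pixels > t}, θ are class
probabilities and μ the class / global means, with μ = θ1 μ1 + θ2 μ2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .image import BinaryMask, GrayImage, LabelMap

__all__ = [
    "GrayHistogram",
    "ClassStats",
    "ThresholdBands",
    "binary_threshold",
    "multilevel_threshold",
    "histogram",
    "class_stats",
    "max_variance_threshold",
    "otsu_effectiveness",
]


@dataclass(frozen=True)
class GrayHistogram:
    """A 256-bin intensity histogram."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ValueError("histogram must have exactly 256 bins")
        if np.any(c < 0):
            raise ValueError("bin counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("histogram must have positive total")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_values(cls, values: np.ndarray) -> "GrayHistogram":
        return cls(np.bincount(np.asarray(values, dtype=np.int64).ravel(),
                               minlength=256)[:256])


@dataclass(frozen=True)
class ClassStats:
    """Two-class statistics of a histogram split at threshold t."""

    t: int
    theta1: float
    theta2: float
    mu1: float
    mu2: float
    mu: float
    sigmaB2: float

    def __post_init__(self):
        if abs(self.theta1 + self.theta2 - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")
        if abs(self.mu1 * self.theta1 + self.mu2 * self.theta2 - self.mu) > 1e-9:
            raise ValueError("class means inconsistent with global mean")
        if self.sigmaB2 < 0:
            raise ValueError("between-class variance must be non-negative")


@dataclass(frozen=True)
class ThresholdBands:
    """Strictly increasing thresholds T0 < … < T_{n-1} with n+1 output values."""

    thresholds: Tuple[int, ...]
    output_values: Tuple[int, ...]

    def __post_init__(self):
        ts = tuple(int(t) for t in self.thresholds)
        gs = tuple(int(g) for g in self.output_values)
        if len(gs) != len(ts) + 1:
            raise ValueError("need exactly one more output value than thresholds")
        if any(t2 <= t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if ts and not (0 <= ts[0] and ts[-1] <= 255):
            raise ValueError("thresholds must lie in [0, 255]")
        object.__setattr__(self, "thresholds", ts)
        object.__setattr__(self, "output_values", gs)


def binary_threshold(image: GrayImage, T: int) -> BinaryMask:
    """f_T(x, y) = 1 when f(x, y) ≥ T, else 0."""
    if not 0 <= T <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return BinaryMask(image.pixels >= T)


def multilevel_threshold(image: GrayImage, bands: ThresholdBands) -> LabelMap:
    """Multiband gray-threshold segmentation with left-open/right-closed bands.

    g(i, j) = g0 when f ≤ T0; g_k when T_{k-1} < f ≤ T_k; g_n when f > T_{n-1}.
    """
    f = image.pixels.astype(np.int64)
    # np.searchsorted with side='left' over thresholds implements
    # "index of first T with f <= T", i.e. the right-closed band.
    idx = np.searchsorted(np.asarray(bands.thresholds), f, side="left")
    out = np.asarray(bands.output_values, dtype=np.int64)[idx]
    if out.min() < 0:
        raise ValueError("negative output values cannot form a LabelMap")
    return LabelMap(out)


def histogram(image: GrayImage) -> GrayHistogram:
    """256-bin histogram; total equals the pixel count H·W."""
    return GrayHistogram.from_values(image.pixels)


def class_stats(hist: GrayHistogram, t: int) -> ClassStats:
    """Statistics of the split class1 = {v ≤ t}, class2 = {v > t}.

    Raises when either class is empty.
    """
    if not 0 <= t <= 255:
        raise ValueError("t must lie in [0, 255]")
    c = hist.counts.astype(np.float64)
    v = np.arange(256, dtype=np.float64)
    n1 = c[: t + 1].sum()
    n2 = c[t + 1:].sum()
    if n1 == 0 or n2 == 0:
        raise ValueError(f"threshold t={t} leaves an empty class")
    total = n1 + n2
    theta1, theta2 = n1 / total, n2 / total
    mu1 = float((c[: t + 1] * v[: t + 1]).sum() / n1)
    mu2 = float((c[t + 1:] * v[t + 1:]).sum() / n2)
    mu = theta1 * mu1 + theta2 * mu2
    sigmaB2 = theta1 * (mu1 - mu) ** 2 + theta2 * (mu2 - mu) ** 2
    return ClassStats(t=int(t), theta1=theta1, theta2=theta2,
                      mu1=mu1, mu2=mu2, mu=mu, sigmaB2=sigmaB2)


def _sigma_b2_curve(hist: GrayHistogram) -> np.ndarray:
    """σ²_B(t) for every t, NaN where a class is empty (vectorized)."""
    c = hist.counts.astype(np.float64)
    v = np.arange(256, dtype=np.float64)
    total = c.sum()
    cum_n = np.cumsum(c)
    cum_s = np.cumsum(c * v)
    theta1 = cum_n / total
    theta2 = 1.0 - theta1
    mu = cum_s[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = cum_s / cum_n
        mu2 = (cum_s[-1] - cum_s) / (total - cum_n)
        sig = theta1 * (mu1 - mu) ** 2 + theta2 * (mu2 - mu) ** 2
    sig[(cum_n == 0) | (cum_n == total)] = np.nan
    return sig


def max_variance_threshold(hist: GrayHistogram) -> Tuple[int, ClassStats]:
    """Threshold t* maximizing σ²_B(t); ties broken by smallest t."""
    occupied = np.nonzero(hist.counts)[0]
    if occupied.size < 2:
        raise ValueError("histogram needs at least two occupied bins")
    sig = _sigma_b2_curve(hist)
    t_star = int(np.nanargmax(sig))  # nanargmax returns the first maximizer
    return t_star, class_stats(hist, t_star)


def otsu_effectiveness(hist: GrayHistogram) -> float:
    """η = σ²_B(t*) / σ²_total, the separability of the optimal split.

    η is ≈ 2/π ≈ 0.64 for a unimodal Gaussian and approaches 1 for two
    well-separated modes; used to decide whether a split is meaningful.
    """
    c = hist.counts.astype(np.float64)
    v = np.arange(256, dtype=np.float64)
    mu = (c * v).sum() / c.sum()
    var = (c * (v - mu) ** 2).sum() / c.sum()
    if var == 0:
        return 0.0
    _, stats = max_variance_threshold(hist)
    return stats.sigmaB2 / var
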