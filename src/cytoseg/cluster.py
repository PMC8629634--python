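"""Clustering-based cell segmentation for single-cell and partially
overlapping cytology images.

Four method variants are provided, differing in the clustering unit (raw
pixels vs. superpixels), the feature set (intensity only vs. intensity +
spatial coordinates), and the seeding (uniform-random vs. K-means++ D²
sampling):

* ``pixel-kmeans``           — K-means on per-pixel intensity
* ``pixel-spatial-kmeans``   — K-means on per-pixel intensity + (row, col)
* ``superpixel-em``          — diagonal-covariance Gaussian-mixture EM on
                               superpixel mean intensities
* ``superpixel-kmeans-pp``   — K-means++-seeded K-means on superpixel mean
                               intensity + spatial centroid features

All four cluster into k = 3 classes (background / cytoplasm / nucleus) and
map clusters to tissue classes by ascending mean gray level: in a Pap-stained
preparation the nucleus is darkest, cytoplasm intermediate, background
brightest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import ndimage as ndi
from skimage import segmentation as sk_seg

from .image import (
    BinaryMask,
    CellInstance,
    ColorImage,
    GrayImage,
    LabelMap,
    SceneSegmentation,
    as_gray,
)

__all__ = [
    "METHODS",
    "FeatureTable",
    "ClusterModel",
    "superpixels",
    "build_features",
    "kmeans_pp_init",
    "fit_kmeans",
    "fit_em_gmm",
    "segment_cell",
]

METHODS = (
    "pixel-kmeans",
    "pixel-spatial-kmeans",
    "superpixel-em",
    "superpixel-kmeans-pp",
)


@dataclass(frozen=True)
class FeatureTable:
    """One row per clustering unit (pixel or superpixel).

    ``units`` is None for pixel rows (row-major pixel order) or the
    superpixel LabelMap whose sorted nonzero labels index the rows.
    """

    X: np.ndarray
    shape: Tuple[int, int]
    units: Optional[LabelMap] = None

    def __post_init__(self):
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("features must be a finite 2-D array")
        object.__setattr__(self, "X", X)

    @property
    def n_units(self) -> int:
        return self.X.shape[0]

    def assignment_to_labelmap(self, assignment: np.ndarray) -> np.ndarray:
        """Expand a per-unit assignment to a per-pixel class array."""
        if self.units is None:
            return assignment.reshape(self.shape)
        out = np.zeros(self.shape, dtype=np.int64)
        labels = np.unique(self.units.pixels)
        labels = labels[labels > 0]
        lut = np.zeros(int(labels.max()) + 1, dtype=np.int64)
        lut[labels] = assignment
        return lut[self.units.pixels]


@dataclass(frozen=True)
class ClusterModel:
    """Fitted clustering: centers, hard assignment and the objective trace.

    For K-means the trace is the within-cluster sum of squares after each
    Lloyd update (non-increasing); for EM it is the log-likelihood after each
    iteration (non-decreasing).
    """

    k: int
    centers: np.ndarray
    assignment: np.ndarray
    objective: float
    trace: Tuple[float, ...]
    kind: str = "kmeans"


def superpixels(image: Union[GrayImage, ColorImage], n_segments: int,
                compactness: float = 10.0, seed: int = 0) -> LabelMap:
    """SLIC-style compactness-controlled oversegmentation.

    The result tiles the image with connected regions labeled 1..L. SLIC is
    deterministic, so ``seed`` is accepted for interface uniformity only.
    """
    h, w = image.shape if isinstance(image, GrayImage) else image.pixels.shape[:2]
    if n_segments < 2:
        raise ValueError("n_segments must be at least 2")
    if n_segments > h * w:
        raise ValueError("n_segments exceeds the pixel count")
    if isinstance(image, ColorImage):
        labels = sk_seg.slic(image.pixels, n_segments=n_segments,
                             compactness=compactness, start_label=1)
    else:
        labels = sk_seg.slic(image.pixels.astype(np.float64), n_segments=n_segments,
                             compactness=compactness, start_label=1,
                             channel_axis=None)
    return LabelMap(labels.astype(np.int32))


def build_features(image: Union[GrayImage, ColorImage],
                   units: Optional[LabelMap] = None,
                   spatial: bool = False, w_s: float = 0.15) -> FeatureTable:
    """Assemble the clustering feature table.

    Intensity features are stretched to the image's own dynamic range
    (robust 1st–99th percentile normalization to [0, 1]), so tissue-class
    contrast carries full weight regardless of the absolute gray levels;
    when ``spatial`` is set, (row, col) coordinates normalized to [0, 1] and
    multiplied by the spatial weight ``w_s`` are appended. With superpixel
    units each row is the mean over the member pixels.
    """
    if isinstance(image, ColorImage):
        chan = image.pixels.astype(np.float64)
        h, w = image.pixels.shape[:2]
    else:
        chan = image.pixels.astype(np.float64)[..., None]
        h, w = image.shape
    lo, hi = np.percentile(chan, [1.0, 99.0])
    if hi > lo:
        chan = np.clip((chan - lo) / (hi - lo), 0.0, 1.0)
    else:
        chan = chan / 255.0
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    rr /= max(h - 1, 1)
    cc /= max(w - 1, 1)

    cols = [chan[..., i] for i in range(chan.shape[-1])]
    if spatial:
        cols += [w_s * rr, w_s * cc]

    if units is None:
        X = np.stack([c.ravel() for c in cols], axis=1)
        return FeatureTable(X=X, shape=(h, w), units=None)

    if units.shape != (h, w):
        raise ValueError("units shape differs from image shape")
    labels = np.unique(units.pixels)
    labels = labels[labels > 0]
    X = np.stack(
        [ndi.mean(c, labels=units.pixels, index=labels) for c in cols], axis=1
    )
    return FeatureTable(X=X, shape=(h, w), units=units)


def kmeans_pp_init(features: FeatureTable, k: int,
                   seed: Union[int, np.random.Generator] = 0) -> np.ndarray:
    """K-means++ D² seeding.

    The first center is uniform over rows; each subsequent center is drawn
    with probability proportional to the squared distance to the nearest
    center already chosen (rows coinciding with a chosen center have
    probability zero).
    """
    X = features.X if isinstance(features, FeatureTable) else np.asarray(features, float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be positive")
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for j in range(1, k):
        probs = d2 / d2.sum()
        idx = rng.choice(n, p=probs)
        centers[j] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centers[j]) ** 2, axis=1))
    return centers


def _wcss(X, centers, assignment):
    return float(np.sum((X - centers[assignment]) ** 2))


def fit_kmeans(features: FeatureTable, k: int, init: np.ndarray,
               max_iter: int = 100, tol: float = 1e-8) -> ClusterModel:
    """Lloyd's algorithm from explicit initial centers.

    An emptied cluster is re-seeded at the point farthest from its assigned
    center, which keeps every cluster nonempty and the objective
    non-increasing across the trace.
    """
    X = features.X if isinstance(features, FeatureTable) else np.asarray(features, float)
    centers = np.array(init, dtype=np.float64, copy=True)
    if centers.shape != (k, X.shape[1]):
        raise ValueError("init must be a k × n_features array")
    trace: List[float] = []
    assignment = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assignment = np.argmin(d2, axis=1)
        for j in range(k):
            member = assignment == j
            if member.any():
                centers[j] = X[member].mean(axis=0)
            else:
                far = np.argmax(d2[np.arange(X.shape[0]), assignment])
                centers[j] = X[far]
                assignment[far] = j
        obj = _wcss(X, centers, assignment)
        if trace and trace[-1] - obj <= tol:
            trace.append(obj)
            break
        trace.append(obj)
    return ClusterModel(k=k, centers=centers, assignment=assignment,
                        objective=trace[-1], trace=tuple(trace), kind="kmeans")


def fit_em_gmm(features: FeatureTable, k: int,
               seed: Union[int, np.random.Generator] = 0,
               max_iter: int = 100, tol: float = 1e-7,
               var_floor: float = 1e-6) -> ClusterModel:
    """Diagonal-covariance Gaussian mixture fitted by EM.

    Means are initialized by K-means++ seeding; variances start at the global
    per-feature variance and are floored at ``var_floor`` so a collapsing
    component cannot go singular. The hard assignment is the argmax
    responsibility; the trace is the per-iteration mean log-likelihood
    (non-decreasing).
    """
    X = features.X if isinstance(features, FeatureTable) else np.asarray(features, float)
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ft = FeatureTable(X=X, shape=(n, 1)) if not isinstance(features, FeatureTable) else features
    means = kmeans_pp_init(ft, k, rng).astype(np.float64)
    variances = np.tile(np.maximum(X.var(axis=0), var_floor), (k, 1))
    weights = np.full(k, 1.0 / k)

    trace: List[float] = []
    resp = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        # E-step: log N(x; m, diag v) per component
        log_prob = -0.5 * (
            ((X[:, None, :] - means[None, :, :]) ** 2 / variances[None, :, :]).sum(axis=2)
            + np.log(variances).sum(axis=1)[None, :]
            + d * np.log(2 * np.pi)
        ) + np.log(weights)[None, :]
        mx = log_prob.max(axis=1, keepdims=True)
        log_norm = mx[:, 0] + np.log(np.exp(log_prob - mx).sum(axis=1))
        resp = np.exp(log_prob - log_norm[:, None])
        ll = float(log_norm.mean())
        # M-step
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        variances = (resp.T @ (X ** 2)) / nk[:, None] - means ** 2
        variances = np.maximum(variances, var_floor)
        if trace and ll - trace[-1] <= tol:
            trace.append(ll)
            break
        trace.append(ll)
    assignment = np.argmax(resp, axis=1)
    return ClusterModel(k=k, centers=means, assignment=assignment,
                        objective=trace[-1], trace=tuple(trace), kind="em")


def _classes_by_mean_gray(gray: np.ndarray, class_map: np.ndarray, k: int) -> np.ndarray:
    """Order cluster indices by ascending mean gray; ties favor lower label."""
    means = np.full(k, np.inf)
    for j in range(k):
        member = class_map == j
        if member.any():
            means[j] = gray[member].mean()
    return np.argsort(means, kind="stable")


def segment_cell(image: Union[GrayImage, ColorImage], method: str,
                 seed: int = 0, k: int = 3, n_superpixels: int = 600,
                 compactness: float = 10.0, w_s: float = 0.15) -> SceneSegmentation:
    """Segment a single-cell-style image into background / cytoplasm / nucleus.

    Clusters (k = 3 by default) are mapped to tissue classes by ascending
    mean gray level. The cell mask is the largest connected component of the
    two non-background classes with holes filled; the nucleus is the largest
    darkest-class component inside it.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    gray = as_gray(image).pixels
    if np.unique(gray).size < 2:
        raise ValueError("degenerate input: image has a single gray level")

    rng = np.random.default_rng(seed)
    if method.startswith("superpixel"):
        units = superpixels(image, n_segments=n_superpixels,
                            compactness=compactness, seed=seed)
    else:
        units = None
    spatial = method in ("pixel-spatial-kmeans", "superpixel-kmeans-pp")
    feats = build_features(image, units=units, spatial=spatial, w_s=w_s)

    if method == "superpixel-em":
        model = fit_em_gmm(feats, k=k, seed=rng)
    elif method == "superpixel-kmeans-pp":
        # D² seeding can miss the small nucleus mode on any single draw;
        # best-of-R restarts by final objective recover the global optimum
        model = None
        for _ in range(10):
            init = kmeans_pp_init(feats, k, rng)
            cand = fit_kmeans(feats, k, init)
            if model is None or cand.objective < model.objective:
                model = cand
    else:
        # plain K-means: uniform-random distinct rows as initial centers,
        # best of a few restarts by final within-cluster sum of squares
        distinct = np.unique(feats.X, axis=0)
        if distinct.shape[0] < k:
            raise ValueError("degenerate input: fewer distinct features than k")
        model = None
        for _ in range(4):
            init = distinct[rng.choice(distinct.shape[0], size=k, replace=False)]
            cand = fit_kmeans(feats, k, init)
            if model is None or cand.objective < model.objective:
                model = cand

    class_map = feats.assignment_to_labelmap(model.assignment)
    order = _classes_by_mean_gray(gray.astype(float), class_map, k)
    nucleus_cls, background_cls = order[0], order[-1]

    cell_px = class_map != background_cls
    cell_px = ndi.binary_fill_holes(cell_px)
    lab, n = ndi.label(cell_px)
    if n == 0:
        raise ValueError("no foreground found")
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    cell_px = lab == (1 + int(np.argmax(sizes)))

    nuc_px = (class_map == nucleus_cls) & cell_px
    lab, n = ndi.label(nuc_px)
    if n > 0:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        nuc_px = lab == (1 + int(np.argmax(sizes)))
        nuc_px = ndi.binary_fill_holes(nuc_px) & cell_px
    else:
        # darkest pixel inside the cell as a 1-px fallback nucleus
        nuc_px = np.zeros_like(cell_px)
        masked = np.where(cell_px, gray, 256)
        nuc_px[np.unravel_index(np.argmin(masked), gray.shape)] = True

    cell = CellInstance(cytoplasm=BinaryMask(cell_px), nucleus=BinaryMask(nuc_px))
    return SceneSegmentation(cells=(cell,))
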