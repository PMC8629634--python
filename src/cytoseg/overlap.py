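"""Combined segmentation of overlapping-cell scenes.

Pipeline: graph-cut separation of background from cell clumps → nucleus
detection inside each clump → Voronoi coarse partition of the clump seeded at
nucleus centroids → overlap compensation by constrained region growing →
merge into complete per-cell masks (which may overlap — that is the point).

The graph-cut energy is the standard two-label form: unary costs are negative
log-likelihoods of two Gaussian intensity classes seeded from the maximum
between-class-variance split, and pairwise costs are a contrast-weighted
Potts term λ·exp(−(ΔI)²/(2σ²)) on 4-neighbor pairs. The exact minimum is
found as a minimum s–t cut.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .image import BinaryMask, CellInstance, GrayImage, LabelMap, SceneSegmentation
from .threshold import (
    GrayHistogram,
    histogram,
    max_variance_threshold,
    otsu_effectiveness,
)

__all__ = [
    "OverlapConfig",
    "NucleusSet",
    "CoarsePartition",
    "graph_cut",
    "separate_clumps",
    "detect_nuclei",
    "voronoi_partition",
    "compensate_overlap",
    "merge_cells",
    "segment_overlapping",
]

logger = logging.getLogger(__name__)

# Unimodal-vs-bimodal gate on the Otsu split: a single Gaussian mode has
# effectiveness η = σ²_B/σ² ≈ 2/π ≈ 0.64; two separated modes give η ≳ 0.85.
_ETA_BIMODAL = 0.75
_CAPACITY_SCALE = float(1 << 20)  # float→int energy scaling for the max-flow solver


@dataclass(frozen=True)
class OverlapConfig:
    """Tunable parameters of the overlap pipeline (defaults at 512×512 scale).

    lam / sigma: pairwise smoothness weight and contrast scale of the
    graph-cut energy. min_hole_area: clump holes below this are filled.
    Nucleus filters follow: area range in pixels and minimum solidity.
    intensity_tol: a pixel may join a cell during compensation when its gray
    value is within this tolerance of the cell's cytoplasm intensity model
    (the tolerance must span the absorbance-darkened overlap region).
    max_extension: radial cap (pixels from the nucleus centroid) on
    compensation growth; None derives it per cell as extension_factor times
    the coarse region's equivalent radius.
    """

    lam: float = 2.0
    sigma: float = 25.0
    min_hole_area: int = 256
    min_nucleus_area: int = 30
    max_nucleus_area: int = 5000
    min_solidity: float = 0.8
    intensity_tol: float = 55.0
    max_extension: Optional[float] = None
    extension_factor: float = 1.1
    closing_radius: int = 2
    min_clump_area: int = 120


@dataclass(frozen=True)
class NucleusSet:
    """Detected nuclei: disjoint masks with centroids, inside one clump."""

    nuclei: Tuple[Tuple[BinaryMask, Tuple[float, float]], ...]

    def __len__(self) -> int:
        return len(self.nuclei)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c for _, c in self.nuclei], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class CoarsePartition:
    """Voronoi labels over clump pixels: label i+1 ↔ nucleus i, 0 elsewhere."""

    labels: LabelMap
    n_cells: int


# ---------------------------------------------------------------------------
# Graph cut


def _pairwise_weights(img: np.ndarray, lam: float, sigma: float):
    """Contrast-weighted Potts costs for vertical and horizontal 4-neighbor pairs."""
    dv = img[1:, :] - img[:-1, :]
    dh = img[:, 1:] - img[:, :-1]
    wv = lam * np.exp(-(dv ** 2) / (2.0 * sigma ** 2))
    wh = lam * np.exp(-(dh ** 2) / (2.0 * sigma ** 2))
    return wv, wh


def graph_cut(unary_fg: np.ndarray, unary_bg: np.ndarray, image: GrayImage,
              lam: float, sigma: float) -> BinaryMask:
    """Exact two-label MAP via minimum s–t cut.

    Minimizes Σ_p U_p(label_p) + Σ_{p~q, label_p≠label_q} λ·exp(−(I_p−I_q)²/2σ²)
    over 4-neighbor pairs. ``unary_fg``/``unary_bg`` are the costs of labeling
    each pixel foreground/background. Returns the foreground mask.
    """
    h, w = image.shape
    n = h * w
    img = image.pixels.astype(np.float64)
    if lam == 0.0:
        return BinaryMask(unary_fg <= unary_bg)

    source, sink = n, n + 1
    idx = np.arange(n).reshape(h, w)
    wv, wh = _pairwise_weights(img, lam, sigma)

    rows, cols, caps = [], [], []

    def add(u, v, c):
        rows.append(u)
        cols.append(v)
        caps.append(c)

    scale = _CAPACITY_SCALE
    # terminal arcs: cutting p→sink pays the foreground cost (p on source side
    # means p is labeled foreground), cutting source→p pays the background
    # cost; zero-capacity reverse arcs make the sparsity structure symmetric
    # so every residual (including reverse residuals) is addressable.
    add(np.full(n, source), idx.ravel(), np.rint(unary_bg.ravel() * scale))
    add(idx.ravel(), np.full(n, source), np.zeros(n))
    add(idx.ravel(), np.full(n, sink), np.rint(unary_fg.ravel() * scale))
    add(np.full(n, sink), idx.ravel(), np.zeros(n))
    # symmetric pairwise arcs
    for a, b, wgt in (
        (idx[:-1, :].ravel(), idx[1:, :].ravel(), np.rint(wv.ravel() * scale)),
        (idx[:, :-1].ravel(), idx[:, 1:].ravel(), np.rint(wh.ravel() * scale)),
    ):
        add(a, b, wgt)
        add(b, a, wgt)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    caps = np.concatenate(caps).astype(np.int64)
    graph = coo_matrix((caps, (rows, cols)), shape=(n + 2, n + 2)).tocsr()

    res = maximum_flow(graph, source, sink)
    residual = graph.copy()
    residual.data = graph.data - res.flow.data
    reach = breadth_first_order(residual > 0, source, directed=True,
                                return_predecessors=False)
    fg = np.zeros(n + 2, bool)
    fg[reach] = True
    return BinaryMask(fg[:n].reshape(h, w))


def _gaussian_neglog(img: np.ndarray, mean: float, std: float) -> np.ndarray:
    std = max(std, 1.0)
    return 0.5 * ((img - mean) / std) ** 2 + math.log(std) + 0.5 * math.log(2 * math.pi)


def separate_clumps(image: GrayImage, lam: float = 2.0, sigma: float = 25.0,
                    min_hole_area: int = 256) -> BinaryMask:
    """Graph-cut separation of the (bright) background from cell clumps.

    Two Gaussian intensity classes are seeded from the maximum
    between-class-variance split (dark class = cells). When the split is not
    meaningfully bimodal (η < 0.75, e.g. a blank noisy background) an empty
    mask is returned. Holes smaller than ``min_hole_area`` are filled.
    """
    img = image.pixels.astype(np.float64)
    hist = histogram(image)
    if np.count_nonzero(hist.counts) < 2:
        raise ValueError("degenerate input: image has a single gray level")
    if otsu_effectiveness(hist) < _ETA_BIMODAL:
        return BinaryMask(np.zeros(image.shape, bool))
    t, _stats = max_variance_threshold(hist)
    dark = image.pixels <= t
    m_fg, s_fg = float(img[dark].mean()), float(img[dark].std())
    m_bg, s_bg = float(img[~dark].mean()), float(img[~dark].std())
    unary_fg = _gaussian_neglog(img, m_fg, s_fg)
    unary_bg = _gaussian_neglog(img, m_bg, s_bg)
    mask = graph_cut(unary_fg, unary_bg, image, lam, sigma).pixels
    if min_hole_area > 0:
        lab, nlab = ndi.label(~mask)
        if nlab:
            sizes = ndi.sum_labels(np.ones(lab.shape), lab,
                                   index=np.arange(1, nlab + 1))
            border = np.unique(np.concatenate(
                [lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
            small = np.zeros(nlab + 1, bool)
            small[1:] = sizes < min_hole_area
            small[border] = False  # background components touching the frame stay
            mask |= small[lab]
    return BinaryMask(mask)


# ---------------------------------------------------------------------------
# Nucleus detection


def detect_nuclei(image: GrayImage, clump: BinaryMask,
                  min_area: int = 30, max_area: int = 5000,
                  min_solidity: float = 0.8) -> NucleusSet:
    """Dark-blob nucleus detection inside a clump.

    The maximum between-class-variance threshold is applied to the clump's
    own histogram; if the resulting dark class is itself strongly bimodal
    (η ≥ 0.75 — overlap-darkened cytoplasm forming a middle mode), a second
    split isolates the darkest mode. Connected components are then filtered
    by area ∈ [min_area, max_area] and solidity ≥ min_solidity.
    """
    from skimage.measure import regionprops

    if clump.area == 0:
        raise ValueError("empty clump")
    vals = image.pixels[clump.pixels]
    hist = GrayHistogram.from_values(vals)
    if np.count_nonzero(hist.counts) < 2:
        return NucleusSet(nuclei=())
    t, _ = max_variance_threshold(hist)
    dark = (image.pixels <= t) & clump.pixels
    dvals = image.pixels[dark]
    if dvals.size:
        dhist = GrayHistogram.from_values(dvals)
        if (np.count_nonzero(dhist.counts) >= 2
                and otsu_effectiveness(dhist) >= _ETA_BIMODAL):
            t2, _ = max_variance_threshold(dhist)
            dark = (image.pixels <= t2) & clump.pixels
    dark = ndi.binary_opening(dark, structure=np.ones((3, 3), bool))
    lab, nlab = ndi.label(dark)
    found = []
    for rp in regionprops(lab):
        if not (min_area <= rp.area <= max_area):
            continue
        if rp.solidity < min_solidity:
            continue
        mask = np.zeros(image.shape, bool)
        mask[lab == rp.label] = True
        mask = ndi.binary_fill_holes(mask) & clump.pixels
        found.append((BinaryMask(mask), (float(rp.centroid[0]), float(rp.centroid[1]))))
    found.sort(key=lambda item: item[1])
    return NucleusSet(nuclei=tuple(found))


# ---------------------------------------------------------------------------
# Voronoi coarse partition and overlap compensation


def voronoi_partition(clump: BinaryMask, seeds: NucleusSet) -> CoarsePartition:
    """Assign every clump pixel to its nearest nucleus centroid (Euclidean).

    Ties go to the lowest seed index. Labels are 1..n_seeds; 0 outside the
    clump.
    """
    if len(seeds) == 0:
        raise ValueError("voronoi partition needs at least one seed")
    rows, cols = np.nonzero(clump.pixels)
    pts = np.stack([rows, cols], axis=1).astype(np.float64)
    cents = seeds.centroids
    d2 = ((pts[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties
    labels = np.zeros(clump.shape, dtype=np.int32)
    labels[rows, cols] = nearest + 1
    return CoarsePartition(labels=LabelMap(labels), n_cells=len(seeds))


def compensate_overlap(image: GrayImage, partition: CoarsePartition,
                       seeds: NucleusSet,
                       max_extension: Optional[float] = None,
                       intensity_tol: float = 55.0,
                       extension_factor: float = 1.1) -> List[BinaryMask]:
    """Extend each cell's coarse region into the overlap zone.

    A clump pixel may join cell c when its intensity is within
    ``intensity_tol`` of c's cytoplasm intensity model (the mean gray of c's
    coarse region) and its Euclidean distance to c's nucleus centroid is at
    most the radial cap; the grown mask is kept connected to the coarse
    region. Masks may overlap — that is the compensation. With
    ``max_extension=0`` each output equals its coarse region.
    """
    img = image.pixels.astype(np.float64)
    labels = partition.labels.pixels
    clump = labels > 0
    h, w = labels.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    out: List[BinaryMask] = []
    for i in range(partition.n_cells):
        region = labels == i + 1
        if not region.any():
            out.append(BinaryMask(region))
            continue
        model = float(img[region].mean())
        if max_extension is None:
            cap = extension_factor * math.sqrt(region.sum() / math.pi)
        else:
            cap = float(max_extension)
        cy, cx = seeds.centroids[i]
        near = (rr - cy) ** 2 + (cc - cx) ** 2 <= cap ** 2
        cand = clump & near & (np.abs(img - model) <= intensity_tol)
        grown = cand | region
        lab, nlab = ndi.label(grown)
        keep = np.unique(lab[region])
        keep = keep[keep > 0]
        grown = np.isin(lab, keep)
        out.append(BinaryMask(grown))
    return out


def merge_cells(partition: CoarsePartition, compensated: Sequence[BinaryMask],
                nuclei: NucleusSet, closing_radius: int = 2) -> SceneSegmentation:
    """Combine coarse regions with their compensation into complete cells.

    Per cell: cytoplasm = (coarse ∪ compensated), morphologically closed,
    holes filled, restricted to the clump, the component containing the
    nucleus kept, and the nucleus unioned in. Raises if a nucleus ends up
    detached from its cytoplasm.
    """
    if len(compensated) != partition.n_cells or len(nuclei) != partition.n_cells:
        raise ValueError("partition / compensation / nuclei counts differ")
    labels = partition.labels.pixels
    clump = labels > 0
    struct = _disk(closing_radius) if closing_radius > 0 else None
    cells: List[CellInstance] = []
    for i, (comp, (nmask, cent)) in enumerate(zip(compensated, nuclei.nuclei)):
        cyto = (labels == i + 1) | comp.pixels
        if struct is not None:
            cyto = ndi.binary_closing(cyto, structure=struct)
        cyto = ndi.binary_fill_holes(cyto) & clump
        lab, nlab = ndi.label(cyto)
        keep = np.unique(lab[nmask.pixels])
        keep = keep[keep > 0]
        if keep.size == 0:
            raise ValueError(f"nucleus {i} detached from its cytoplasm")
        cyto = np.isin(lab, keep) | nmask.pixels
        cells.append(CellInstance(cytoplasm=BinaryMask(cyto), nucleus=nmask))
    union = np.zeros(labels.shape, bool)
    for c in cells:
        union |= c.cytoplasm.pixels
    return SceneSegmentation(cells=tuple(cells), background=BinaryMask(~union))


def _disk(radius: int) -> np.ndarray:
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return rr ** 2 + cc ** 2 <= radius ** 2


# ---------------------------------------------------------------------------
# Full pipeline


def segment_overlapping(image: GrayImage,
                        config: OverlapConfig = OverlapConfig()
                        ) -> SceneSegmentation:
    """Run the combined model on a multicell scene.

    Clump separation runs once on the whole image; nucleus detection, Voronoi
    partition, compensation and merging run per connected clump. Clumps where
    no nucleus passes the filters produce no cells (logged). Deterministic.
    """
    clump_mask = separate_clumps(image, lam=config.lam, sigma=config.sigma,
                                 min_hole_area=config.min_hole_area)
    lab, nlab = ndi.label(clump_mask.pixels)
    all_cells: List[CellInstance] = []
    for j in range(1, nlab + 1):
        clump = BinaryMask(lab == j)
        if clump.area < config.min_clump_area:
            continue
        nuclei = detect_nuclei(image, clump,
                               min_area=config.min_nucleus_area,
                               max_area=config.max_nucleus_area,
                               min_solidity=config.min_solidity)
        if len(nuclei) == 0:
            logger.warning("clump %d (%d px): no nucleus detected, skipped",
                           j, clump.area)
            continue
        partition = voronoi_partition(clump, nuclei)
        compensated = compensate_overlap(
            image, partition, nuclei,
            max_extension=config.max_extension,
            intensity_tol=config.intensity_tol,
            extension_factor=config.extension_factor)
        scene = merge_cells(partition, compensated, nuclei,
                            closing_radius=config.closing_radius)
        all_cells.extend(scene.cells)
    if not all_cells:
        return SceneSegmentation(cells=(),
                                 background=BinaryMask(np.ones(image.shape, bool)))
    return SceneSegmentation(cells=tuple(all_cells))
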