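"""Core raster types, mask algebra, and image / label-map / scene I/O.

All coordinates are (row, col), 0-based, origin at the top-left corner.
Images are 8-bit; 16-bit image inputs are rejected rather than rescaled.
Label maps are stored as 16-bit single-channel PNG. Per-cell ground truth
and predictions are stored as one binary PNG per mask plus a JSON manifest,
because overlapping cytoplasm masks cannot share a single label map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "ColorImage",
    "BinaryMask",
    "LabelMap",
    "CellInstance",
    "SceneSegmentation",
    "read_image",
    "to_gray",
    "write_labelmap",
    "read_labelmap",
    "write_scene",
    "read_scene",
]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D raster of 8-bit intensities f(x, y) in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a nonempty 2-D array")
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)):
                raise ValueError("gray intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ColorImage:
    """An H×W×3 8-bit RGB raster."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise ValueError("ColorImage requires a nonempty H×W×3 array")
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)):
                raise ValueError("channel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class BinaryMask:
    """An H×W {0,1} mask; internally boolean."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("BinaryMask requires a 2-D array")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be strictly binary")
            px = px.astype(bool)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.pixels & other.pixels)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.pixels | other.pixels)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.pixels)


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel integer region assignment g(i, j); label 0 is background."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("LabelMap requires a 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("labels must be integers")
        if px.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "pixels", px.astype(np.int32))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def labels(self) -> np.ndarray:
        """Sorted array of labels present in the map."""
        return np.unique(self.pixels)

    @property
    def n_regions(self) -> int:
        """Number of nonzero labels present."""
        labs = self.labels
        return int(labs.size - (1 if labs.size and labs[0] == 0 else 0))


def _mask_centroid(mask: np.ndarray) -> Tuple[float, float]:
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


@dataclass(frozen=True)
class CellInstance:
    """One cell: cytoplasm and nucleus masks plus the cytoplasm centroid.

    Invariants: nucleus ⊆ cytoplasm, both nonempty, centroid inside the
    cytoplasm bounding box.
    """

    cytoplasm: BinaryMask
    nucleus: BinaryMask
    centroid: Tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.cytoplasm.shape != self.nucleus.shape:
            raise ValueError("cytoplasm and nucleus shapes differ")
        if self.cytoplasm.area == 0 or self.nucleus.area == 0:
            raise ValueError("cytoplasm and nucleus must both be nonempty")
        if np.any(self.nucleus.pixels & ~self.cytoplasm.pixels):
            raise ValueError("nucleus must be contained in cytoplasm")
        if self.centroid is None:
            object.__setattr__(self, "centroid", _mask_centroid(self.cytoplasm.pixels))
        rows, cols = np.nonzero(self.cytoplasm.pixels)
        r, c = self.centroid
        if not (rows.min() <= r <= rows.max() and cols.min() <= c <= cols.max()):
            raise ValueError("centroid outside cytoplasm bounding box")


@dataclass(frozen=True)
class SceneSegmentation:
    """Per-cell instances of one scene; cytoplasm masks may overlap.

    The background mask must be disjoint from every cytoplasm mask; it is
    derived from the cells when not given.
    """

    cells: Tuple[CellInstance, ...]
    background: BinaryMask = None  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "cells", tuple(self.cells))
        if self.background is None:
            if not self.cells:
                raise ValueError("background required for an empty scene")
            union = np.zeros(self.cells[0].cytoplasm.shape, bool)
            for c in self.cells:
                union |= c.cytoplasm.pixels
            object.__setattr__(self, "background", BinaryMask(~union))
        for c in self.cells:
            if c.cytoplasm.shape != self.background.shape:
                raise ValueError("cell/background shape mismatch")
            if np.any(c.cytoplasm.pixels & self.background.pixels):
                raise ValueError("background intersects a cytoplasm mask")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.background.shape

    def cytoplasm_union(self) -> BinaryMask:
        union = np.zeros(self.shape, bool)
        for c in self.cells:
            union |= c.cytoplasm.pixels
        return BinaryMask(union)

    def nucleus_union(self) -> BinaryMask:
        union = np.zeros(self.shape, bool)
        for c in self.cells:
            union |= c.nucleus.pixels
        return BinaryMask(union)


# ---------------------------------------------------------------------------
# I/O


def read_image(path: Union[str, Path]) -> Union[GrayImage, ColorImage]:
    """Read an 8-bit PNG or TIFF as a GrayImage or ColorImage.

    16-bit inputs raise rather than being silently rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in {".png", ".tif", ".tiff"}:
        raise ValueError(f"unsupported format: {path.suffix}")
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise ValueError(f"unsupported bit depth: {arr.dtype} (8-bit required)")
    if arr.ndim == 2:
        return GrayImage(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 3:
        return ColorImage(arr)
    raise ValueError(f"unsupported image layout with shape {arr.shape}")


def to_gray(image: ColorImage) -> GrayImage:
    """ITU-R BT.601 luminance: 0.299 R + 0.587 G + 0.114 B, rounded, clipped.

    This is the single place where color becomes gray; channel-identical
    inputs map to their common value.
    """
    rgb = image.pixels.astype(np.float64)
    lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return GrayImage(np.clip(np.rint(lum), 0, 255).astype(np.uint8))


def as_gray(image: Union[GrayImage, ColorImage]) -> GrayImage:
    """Pass through gray images, convert color ones."""
    return image if isinstance(image, GrayImage) else to_gray(image)


def write_image(image: Union[GrayImage, ColorImage], path: Union[str, Path]) -> None:
    iio.imwrite(Path(path), image.pixels)


def write_labelmap(labelmap: LabelMap, path: Union[str, Path]) -> None:
    """Write a label map as 16-bit single-channel PNG (lossless)."""
    px = labelmap.pixels
    if px.max() > 65535:
        raise ValueError("label maps with more than 65535 labels are not supported")
    iio.imwrite(Path(path), px.astype(np.uint16))


def read_labelmap(path: Union[str, Path]) -> LabelMap:
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError("label map PNG must be single-channel")
    return LabelMap(arr.astype(np.int32))


def write_mask(mask: BinaryMask, path: Union[str, Path]) -> None:
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def read_mask(path: Union[str, Path]) -> BinaryMask:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 127)


def write_scene(scene: SceneSegmentation, out_dir: Union[str, Path],
                image: Union[GrayImage, ColorImage, None] = None) -> Path:
    """Write a scene as per-cell mask PNGs plus a JSON manifest.

    One file per cytoplasm and nucleus mask (the overlapping-cell challenge convention) because
    cytoplasm masks may overlap. Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, cell in enumerate(scene.cells):
        cy, nu = f"cell_{i:03d}_cytoplasm.png", f"cell_{i:03d}_nucleus.png"
        write_mask(cell.cytoplasm, out_dir / cy)
        write_mask(cell.nucleus, out_dir / nu)
        entries.append({"id": i, "cytoplasm": cy, "nucleus": nu,
                        "centroid": list(cell.centroid)})
    manifest = {"shape": list(scene.shape), "cells": entries}
    if image is not None:
        write_image(image, out_dir / "image.png")
        manifest["image"] = "image.png"
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def read_scene(scene_dir: Union[str, Path]) -> SceneSegmentation:
    scene_dir = Path(scene_dir)
    manifest = json.loads((scene_dir / "manifest.json").read_text())
    shape = tuple(manifest["shape"])
    cells = []
    for e in manifest["cells"]:
        cells.append(CellInstance(
            cytoplasm=read_mask(scene_dir / e["cytoplasm"]),
            nucleus=read_mask(scene_dir / e["nucleus"]),
            centroid=tuple(e["centroid"]),
        ))
    if cells:
        return SceneSegmentation(cells=tuple(cells))
    return SceneSegmentation(cells=(), background=BinaryMask(np.ones(shape, bool)))
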