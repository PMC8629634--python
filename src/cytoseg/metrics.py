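"""Segmentation evaluation in the style of the overlapping-cervical-cell
challenges.

The Zijdenbos similarity index (ZSI) of two pixel sets A and B is
2|A∩B| / (|A| + |B|) — identical in form to the Dice coefficient. A per-cell
ZSI above 0.7 is conventionally a "good" segmentation; the object-based
false-negative rate FNo is the fraction of true cells whose best-match ZSI is
≤ 0.7 (the boundary value counts as an error). TPp and FPp are pixel-based
true/false positive rates of the predicted foreground union against the true
foreground and background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .image import BinaryMask, SceneSegmentation

__all__ = [
    "EvalReport",
    "zsi",
    "match_cells",
    "fno",
    "pixel_rates",
    "evaluate_scene",
    "evaluate_dataset",
    "method_table",
]

GOOD_ZSI = 0.7


def zsi(a: BinaryMask, b: BinaryMask) -> float:
    """Zijdenbos similarity index 2|A∩B| / (|A| + |B|), in [0, 1]."""
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = a.area, b.area
    if na == 0 and nb == 0:
        raise ValueError("ZSI undefined for two empty masks")
    inter = int(np.count_nonzero(a.pixels & b.pixels))
    return 2.0 * inter / (na + nb)


def match_cells(pred: SceneSegmentation, truth: SceneSegmentation
                ) -> List[Tuple[Optional[int], float]]:
    """Greedy one-to-one matching of true cells to predicted cells.

    Candidate (true, pred) pairs are taken in descending cytoplasm-ZSI order;
    each true cell gets the best still-unmatched prediction. Returns, per true
    cell, the matched prediction index (or None) and the achieved ZSI
    (0 for unmatched cells).
    """
    if truth.n_cells and pred.n_cells and pred.shape != truth.shape:
        raise ValueError("scene shapes differ")
    nt, np_ = truth.n_cells, pred.n_cells
    scores = np.zeros((nt, np_))
    for i, tc in enumerate(truth.cells):
        for j, pc in enumerate(pred.cells):
            scores[i, j] = zsi(tc.cytoplasm, pc.cytoplasm)
    result: List[Tuple[Optional[int], float]] = [(None, 0.0)] * nt
    if np_ == 0 or nt == 0:
        return result
    order = np.dstack(np.unravel_index(np.argsort(-scores, axis=None,
                                                  kind="stable"), scores.shape))[0]
    used_t, used_p = set(), set()
    for i, j in order:
        if scores[i, j] <= 0.0:
            break
        if i in used_t or j in used_p:
            continue
        result[i] = (int(j), float(scores[i, j]))
        used_t.add(int(i))
        used_p.add(int(j))
    return result


def fno(per_cell_zsi: Sequence[float], threshold: float = GOOD_ZSI) -> float:
    """Object-based false-negative rate: fraction of cells with ZSI ≤ threshold."""
    vals = np.asarray(per_cell_zsi, dtype=float)
    if vals.size == 0:
        raise ValueError("empty ZSI list")
    return float(np.count_nonzero(vals <= threshold) / vals.size)


def pixel_rates(pred: BinaryMask, truth: BinaryMask) -> Tuple[float, float]:
    """(TPp, FPp) of predicted foreground vs. true foreground/background."""
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    fg = truth.pixels
    bg = ~fg
    n_fg, n_bg = int(fg.sum()), int(bg.sum())
    if n_fg == 0 or n_bg == 0:
        raise ValueError("truth must contain both foreground and background")
    tpp = float(np.count_nonzero(pred.pixels & fg) / n_fg)
    fpp = float(np.count_nonzero(pred.pixels & bg) / n_bg)
    return tpp, fpp


@dataclass(frozen=True)
class EvalReport:
    """Aggregated per-cell ZSI plus object- and pixel-level rates."""

    per_cell_zsi: Tuple[float, ...]
    mean_zsi: float
    std_zsi: float
    fno: float
    tpp: float
    fpp: float
    n_true_cells: int
    n_pred_cells: int
    per_cell_nucleus_zsi: Tuple[float, ...] = ()

    def __post_init__(self):
        vals = np.asarray(self.per_cell_zsi)
        if vals.size:
            if abs(vals.mean() - self.mean_zsi) > 1e-9:
                raise ValueError("mean inconsistent with per-cell list")
            if abs(vals.std() - self.std_zsi) > 1e-9:
                raise ValueError("std inconsistent with per-cell list")
        for name in ("fno", "tpp", "fpp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0, 1]")

    def summary(self) -> str:
        return (f"ZSI {self.mean_zsi:.3f} ± {self.std_zsi:.3f}  "
                f"FNo {self.fno:.3f}  TPp {self.tpp:.3f}  FPp {self.fpp:.3f}  "
                f"({self.n_pred_cells}/{self.n_true_cells} cells)")


def _report(zsis: List[float], nuc_zsis: List[float], tpp: float, fpp: float,
            n_true: int, n_pred: int) -> EvalReport:
    vals = np.asarray(zsis, dtype=float)
    return EvalReport(
        per_cell_zsi=tuple(vals.tolist()),
        mean_zsi=float(vals.mean()) if vals.size else 0.0,
        std_zsi=float(vals.std()) if vals.size else 0.0,
        fno=fno(vals) if vals.size else 1.0,
        tpp=tpp, fpp=fpp,
        n_true_cells=n_true, n_pred_cells=n_pred,
        per_cell_nucleus_zsi=tuple(nuc_zsis),
    )


def evaluate_scene(pred: SceneSegmentation, truth: SceneSegmentation) -> EvalReport:
    """Per-scene evaluation: greedy matching, per-cell ZSI, FNo, TPp, FPp.

    ZSI is computed on cytoplasm masks; nucleus agreement of matched pairs is
    reported separately in ``per_cell_nucleus_zsi``.
    """
    if truth.n_cells == 0:
        raise ValueError("truth scene has no cells")
    matching = match_cells(pred, truth)
    zsis = [s for _, s in matching]
    nuc = []
    for (j, _), tc in zip(matching, truth.cells):
        if j is not None:
            try:
                nuc.append(zsi(tc.nucleus, pred.cells[j].nucleus))
            except ValueError:
                nuc.append(0.0)
    if pred.n_cells:
        tpp, fpp = pixel_rates(pred.cytoplasm_union(), truth.cytoplasm_union())
    else:
        tpp, fpp = 0.0, 0.0
    return _report(zsis, nuc, tpp, fpp, truth.n_cells, pred.n_cells)


def evaluate_dataset(pairs: Sequence[Tuple[SceneSegmentation, SceneSegmentation]]
                     ) -> EvalReport:
    """Pool per-cell ZSI across (pred, truth) scene pairs.

    Pixel rates are aggregated over all scenes' pixels; the per-cell ZSI list
    is the concatenation of the per-scene lists.
    """
    if not pairs:
        raise ValueError("empty dataset")
    zsis: List[float] = []
    nuc: List[float] = []
    tp = fp = nfg = nbg = 0
    n_true = n_pred = 0
    for pred, truth in pairs:
        rep = evaluate_scene(pred, truth)
        zsis.extend(rep.per_cell_zsi)
        nuc.extend(rep.per_cell_nucleus_zsi)
        fg = truth.cytoplasm_union().pixels
        pu = pred.cytoplasm_union().pixels if pred.n_cells else np.zeros_like(fg)
        tp += int(np.count_nonzero(pu & fg))
        fp += int(np.count_nonzero(pu & ~fg))
        nfg += int(fg.sum())
        nbg += int((~fg).sum())
        n_true += truth.n_cells
        n_pred += pred.n_cells
    return _report(zsis, nuc, tp / nfg if nfg else 0.0,
                   fp / nbg if nbg else 0.0, n_true, n_pred)


def method_table(reports: Dict[str, EvalReport]) -> pd.DataFrame:
    """One row per method with a "mean ± std" ZSI column plus the rates."""
    rows = []
    for name, rep in reports.items():
        rows.append({
            "method": name,
            "zsi": f"{rep.mean_zsi:.2f} ± {rep.std_zsi:.2f}",
            "mean_zsi": rep.mean_zsi,
            "std_zsi": rep.std_zsi,
            "fno": rep.fno,
            "tpp": rep.tpp,
            "fpp": rep.fpp,
            "n_cells": rep.n_true_cells,
        })
    return pd.DataFrame(rows)
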