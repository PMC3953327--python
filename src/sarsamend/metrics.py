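"""Evaluation metrics for boundary segmentation.

Implements the pixel-wise measures (precision, recall, F-score, pixel
error), the region-pair measures (Rand index / Rand error) and the
topology-aware warping error, plus macro (across-image) averages.

Conventions
-----------
A *boundary map* is a 2-D binary raster where nonzero marks a boundary
("marked") pixel. A *segmentation* is a 2-D integer raster of region IDs
in which label 0 means "not scored" (boundary pixels are excluded from
pair counting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from sklearn.metrics import rand_score

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "PairCounts",
    "MetricReport",
    "MacroReport",
    "confusion_counts",
    "precision_recall_f",
    "pixel_error",
    "regions_from_boundary",
    "rand_index",
    "rand_error",
    "warping_error",
    "macro_metrics",
    "evaluate_maps",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level confusion counts of a binary prediction vs. a truth map."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PairCounts:
    """Pixel-pair agreement counts between two segmentations.

    ``a`` counts pairs co-clustered in both segmentations, ``b`` pairs
    separated in both; ``n`` is the number of scored pixels.
    """

    a: int
    b: int
    n: int


@dataclass(frozen=True)
class MetricReport:
    """Per-image metric bundle; every value lies in [0, 1]."""

    precision: float
    recall: float
    f_score: float
    pixel_error: float
    rand_index: float
    rand_error: float
    warping_error: float


@dataclass(frozen=True)
class MacroReport:
    """Arithmetic means of per-image metrics over a set of images."""

    macro_precision: float
    macro_recall: float
    macro_f_score: float
    macro_rand_error: float
    macro_warping_error: float
    n_images: int


# ---------------------------------------------------------------------------
# helpers


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr != 0


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# pixel-wise measures


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Count tp/fp/fn/tn pixels between two binary boundary maps."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    _check_same_shape(p, t)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision_recall_f(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean (F-score).

    A zero denominator yields 0 for the affected quantity (with a logged
    warning) so that macro averages over many images stay defined.
    """
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        logger.warning("no predicted positives: precision set to 0")
        precision = 0.0
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        logger.warning("no true positives in reference: recall set to 0")
        recall = 0.0
    if precision + recall > 0:
        f_score = 2.0 * precision * recall / (precision + recall)
    else:
        f_score = 0.0
    return precision, recall, f_score


def pixel_error(pred, truth) -> float:
    """1 minus the maximal F-score over binarisations of ``pred``.

    ``pred`` may be a graded map in [0, 1]; the F-score is maximised over
    thresholds drawn from the distinct predicted values plus {0, 1}, with
    a pixel marked when its value is strictly above the threshold. For a
    binary prediction this reduces to 1 - F of that single binarisation.
    """
    pred = np.asarray(pred, dtype=float)
    t = _as_binary(truth, "truth")
    _check_same_shape(pred, t)
    thresholds = np.union1d(np.unique(pred), [0.0, 1.0])
    best_f = 0.0
    n_truth = int(np.count_nonzero(t))
    for thr in thresholds:
        marked = pred > thr
        tp = int(np.count_nonzero(marked & t))
        n_pred = int(np.count_nonzero(marked))
        # inline F to keep the sweep quiet about empty binarisations
        if tp == 0 or n_pred == 0 or n_truth == 0:
            continue
        p = tp / n_pred
        r = tp / n_truth
        best_f = max(best_f, 2.0 * p * r / (p + r))
    return 1.0 - best_f


# ---------------------------------------------------------------------------
# Rand measures

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def regions_from_boundary(boundary_map) -> np.ndarray:
    """Label the regions a boundary map delineates.

    Non-boundary pixels are grouped by 4-connected component labelling
    and receive positive region IDs; boundary pixels receive ID 0 and are
    excluded from pair counting downstream.
    """
    b = _as_binary(boundary_map, "boundary_map")
    labels, _ = ndimage.label(~b, structure=_FOUR_CONN)
    return labels


def pair_counts(x, y) -> PairCounts:
    """Exhaustive pixel-pair agreement counts (quadratic; for small inputs)."""
    xv, yv = _scored_labels(x, y)
    a = b = 0
    for i, j in combinations(range(xv.size), 2):
        same_x = xv[i] == xv[j]
        same_y = yv[i] == yv[j]
        if same_x and same_y:
            a += 1
        elif not same_x and not same_y:
            b += 1
    return PairCounts(a=a, b=b, n=int(xv.size))


def _scored_labels(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    y = np.asarray(y)
    _check_same_shape(x, y)
    mask = (x != 0) & (y != 0)
    xv = x[mask].ravel()
    yv = y[mask].ravel()
    if xv.size < 2:
        raise ValueError("fewer than 2 scored pixels: Rand index undefined")
    return xv, yv


def rand_index(x, y) -> float:
    """Rand index between two segmentations (label 0 excluded)."""
    xv, yv = _scored_labels(x, y)
    return float(rand_score(xv, yv))


def rand_error(x, y) -> float:
    """1 minus the Rand index: disagreement frequency over pixel pairs."""
    return 1.0 - rand_index(x, y)


# ---------------------------------------------------------------------------
# warping error
#
# Digital-topology background: flipping a *simple point* of a binary image
# does not change the number of connected components of foreground
# (8-adjacency) or background (4-adjacency). The warping error relaxes the
# Hamming distance by letting the reference deform onto the candidate
# through simple-point flips only, so pure boundary-location jitter can be
# warped away while splits/merges cannot.

_RING_OFFSETS = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def _build_simple_lut() -> np.ndarray:
    """Simplicity of the centre pixel for each 8-bit ring configuration.

    Bit k of the index is the foreground state of ``_RING_OFFSETS[k]``.
    The centre is simple iff its foreground ring forms exactly one
    8-component and the background ring cells that are 4-adjacent to the
    centre form exactly one 4-component.
    """
    lut = np.zeros(256, dtype=bool)
    ring_pos = [(r + 1, c + 1) for r, c in _RING_OFFSETS]
    edge_pos = [(0, 1), (1, 0), (1, 2), (2, 1)]  # 4-adjacent ring cells
    for code in range(256):
        patch = np.zeros((3, 3), dtype=bool)
        for k, pos in enumerate(ring_pos):
            patch[pos] = bool(code >> k & 1)
        fg = patch.copy()
        n_fg = ndimage.label(fg, structure=_EIGHT_CONN)[1]
        bg = ~patch
        bg[1, 1] = False
        bg_labels, _ = ndimage.label(bg, structure=_FOUR_CONN)
        n_bg = len({bg_labels[p] for p in edge_pos if bg_labels[p] > 0})
        lut[code] = n_fg == 1 and n_bg == 1
    return lut


_SIMPLE_LUT = _build_simple_lut()


def _neighbor_code(padded: np.ndarray, r: int, c: int) -> int:
    # r, c index into the padded array (i.e. original coords + 1)
    code = 0
    for k, (dr, dc) in enumerate(_RING_OFFSETS):
        if padded[r + dr, c + dc]:
            code |= 1 << k
    return code


def is_simple_point(img, r: int, c: int) -> bool:
    """True when flipping pixel (r, c) preserves the digital topology."""
    b = _as_binary(img, "img")
    padded = np.pad(b, 1, constant_values=False)
    return bool(_SIMPLE_LUT[_neighbor_code(padded, r + 1, c + 1)])


def warp_reference(candidate, reference) -> np.ndarray:
    """Greedily deform ``reference`` onto ``candidate`` by simple-point flips.

    Each accepted flip targets a pixel where the two maps disagree (so
    every flip lowers the Hamming distance by one) and is a simple point
    of the current warped image, preserving foreground and background
    component counts throughout. Sweeps run in raster order until no flip
    is possible.
    """
    cand = _as_binary(candidate, "candidate")
    ref = _as_binary(reference, "reference")
    _check_same_shape(cand, ref)
    warped = np.pad(ref, 1, constant_values=False)
    target = np.pad(cand, 1, constant_values=False)
    while True:
        mismatches = np.argwhere(warped != target)
        flipped = False
        for r, c in mismatches:
            if warped[r, c] != target[r, c] and _SIMPLE_LUT[_neighbor_code(warped, r, c)]:
                warped[r, c] = target[r, c]
                flipped = True
        if not flipped:
            break
    return warped[1:-1, 1:-1]


def warping_error(candidate, reference) -> float:
    """Normalised Hamming distance to the best topology-preserving warping.

    The reference is deformed toward the candidate through simple-point
    flips (foreground 8-adjacency, background 4-adjacency); the residual
    disagreement, divided by the pixel count, is the error. It is 0 when
    the maps differ only by deformable boundary jitter and positive when
    they disagree topologically (splits/merges).
    """
    cand = _as_binary(candidate, "candidate")
    ref = _as_binary(reference, "reference")
    _check_same_shape(cand, ref)
    warped = warp_reference(cand, ref)
    return float(np.count_nonzero(warped != cand)) / cand.size


# ---------------------------------------------------------------------------
# macro averaging & convenience


def macro_metrics(reports: Sequence[MetricReport]) -> MacroReport:
    """Unweighted arithmetic means of per-image metrics."""
    if not reports:
        raise ValueError("macro_metrics requires at least one report")
    mean = lambda name: float(np.mean([getattr(r, name) for r in reports]))
    return MacroReport(
        macro_precision=mean("precision"),
        macro_recall=mean("recall"),
        macro_f_score=mean("f_score"),
        macro_rand_error=mean("rand_error"),
        macro_warping_error=mean("warping_error"),
        n_images=len(reports),
    )


def evaluate_maps(pred, truth, metrics: Iterable[str] = ("pixel", "rand", "warping")) -> MetricReport:
    """Full metric bundle for a predicted vs. a reference boundary map.

    ``metrics`` selects which of the expensive measures to compute; a
    deselected measure is reported as 0.0.
    """
    wanted = set(metrics)
    p, r, f = precision_recall_f(confusion_counts(pred, truth))
    pe = pixel_error(np.asarray(pred, dtype=float) != 0, truth) if "pixel" in wanted else 0.0
    if "rand" in wanted:
        ri = rand_index(regions_from_boundary(pred), regions_from_boundary(truth))
    else:
        ri = 1.0
    we = warping_error(pred, truth) if "warping" in wanted else 0.0
    return MetricReport(
        precision=p,
        recall=r,
        f_score=f,
        pixel_error=float(pe),
        rand_index=ri,
        rand_error=1.0 - ri,
        warping_error=we,
    )
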