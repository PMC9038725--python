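"""Segmentation losses and evaluation metrics.

Training uses the minus-Dice objective (loss = -soft Dice, range
[-1, 0], minimised at perfect overlap). Evaluation reports the hard
Dice similarity coefficient DSC = 2|A∩B| / (|A|+|B|), the Jaccard
coefficient JSC = |A∩B| / |A∪B| and the symmetric Hausdorff distance
between mask contours,

    HD(A, B) = max( max_a min_b d(a,b), max_b min_a d(a,b) )

with Euclidean d, in pixels or in mm when a pixel spacing is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .autodiff import Tensor

__all__ = [
    "soft_dice", "dice_loss", "hard_dsc", "jsc", "binarize",
    "extract_contour", "hausdorff", "UndefinedMetricError",
    "MetricReport", "SOFT_DICE_EPS",
]

SOFT_DICE_EPS = 1e-6

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (e.g. Hausdorff of an empty mask)."""


def _check_same_shape(a, b):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def soft_dice(pred, target, eps: float = SOFT_DICE_EPS):
    """Differentiable Dice on a probability map vs a binary target.

    Accepts NumPy arrays or autodiff tensors; returns the same kind.
    (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if isinstance(pred, Tensor) or isinstance(target, Tensor):
        p = pred if isinstance(pred, Tensor) else Tensor(pred)
        t = target if isinstance(target, Tensor) else Tensor(target)
        _check_same_shape(p.data, t.data)
        inter = (p * t).sum()
        return (2.0 * inter + eps) / (p.sum() + t.sum() + eps)
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    _check_same_shape(pred, target)
    return (2.0 * float((pred * target).sum()) + eps) / (
        float(pred.sum()) + float(target.sum()) + eps)


def dice_loss(pred, target, eps: float = SOFT_DICE_EPS):
    """Minus soft Dice: in [-1, 0], equal to -1 at perfect prediction."""
    return -soft_dice(pred, target, eps=eps)


def _as_binary(mask) -> np.ndarray:
    mask = np.asarray(mask)
    out = mask.astype(bool)
    if not np.array_equal(mask.astype(float), out.astype(float)):
        raise ValueError("mask entries must be 0 or 1")
    return out


def hard_dsc(a, b) -> float:
    """Dice coefficient of two binary masks; both empty -> 1.0."""
    a, b = _as_binary(a), _as_binary(b)
    _check_same_shape(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def jsc(a, b) -> float:
    """Jaccard coefficient |A∩B| / |A∪B|; both empty -> 1.0."""
    a, b = _as_binary(a), _as_binary(b)
    _check_same_shape(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def binarize(prob, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (== threshold) go to foreground."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly in (0, 1)")
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def extract_contour(mask) -> np.ndarray:
    """Boundary pixels of a binary mask as an (n, 2) array of (row, col).

    A foreground pixel is on the contour if any 4-neighbour is
    background or it lies on the image border. An empty mask yields an
    empty (0, 2) array.
    """
    mask = _as_binary(mask)
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    interior = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~interior)


def hausdorff(a: np.ndarray, b: np.ndarray,
              spacing: float | None = None) -> float:
    """Symmetric Hausdorff distance between two contour point sets.

    `a`, `b` are (n, 2) coordinate arrays (as from extract_contour);
    the result is in pixels, or mm when `spacing` (mm/px) is given.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        raise UndefinedMetricError(
            "Hausdorff distance is undefined for an empty contour")
    d = max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    return d * spacing if spacing is not None else d


@dataclass
class MetricReport:
    """Per-sample and aggregate DSC / JSC / Hausdorff results.

    `per_sample` rows are (id, dsc, jsc, hd) with hd None when
    undefined (an empty contour); undefined values are excluded from
    the HD aggregate and counted in `n_hd_undefined`.
    """

    per_sample: list = field(default_factory=list)

    def add(self, sample_id: str, dsc: float, jsc_val: float,
            hd: float | None):
        self.per_sample.append((sample_id, dsc, jsc_val, hd))

    @property
    def n(self) -> int:
        return len(self.per_sample)

    @property
    def n_hd_undefined(self) -> int:
        return sum(1 for row in self.per_sample if row[3] is None)

    def summary(self) -> dict:
        """Mean and (n-1) standard deviation per metric."""
        out = {}
        for idx, name in ((1, "dsc"), (2, "jsc"), (3, "hd")):
            vals = [row[idx] for row in self.per_sample if row[idx] is not None]
            if vals:
                out[f"{name}_mean"] = float(np.mean(vals))
                out[f"{name}_sd"] = (float(np.std(vals, ddof=1))
                                     if len(vals) > 1 else 0.0)
            else:
                out[f"{name}_mean"] = float("nan")
                out[f"{name}_sd"] = float("nan")
        out["n"] = self.n
        out["n_hd_undefined"] = self.n_hd_undefined
        return out

    def to_csv(self, path):
        import pandas as pd

        df = pd.DataFrame(self.per_sample, columns=["id", "dsc", "jsc", "hd"])
        s = self.summary()
        footer = pd.DataFrame(
            [("mean", s["dsc_mean"], s["jsc_mean"], s["hd_mean"]),
             ("sd", s["dsc_sd"], s["jsc_sd"], s["hd_sd"])],
            columns=df.columns)
        pd.concat([df, footer], ignore_index=True).to_csv(path, index=False)
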