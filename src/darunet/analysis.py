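"""Clinical agreement analytics.

Structure length is the maximum Feret diameter (largest pairwise
Euclidean distance between contour points) of the largest 8-connected
foreground component — the natural "crown to rump" extent of a
segmented structure. Automatic vs manual lengths are compared with
Bland-Altman statistics (bias and 1.96-SD limits of agreement) and the
Pearson correlation; score distributions are summarised with Tukey
box-whisker statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .metrics import UndefinedMetricError, extract_contour

__all__ = ["LengthMeasurement", "BlandAltmanResult", "WhiskerSummary",
           "measure_length", "bland_altman", "pearson_r", "whisker_summary",
           "bland_altman_plot"]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class LengthMeasurement:
    id: str
    auto_length: float
    manual_length: float


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired differences."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class WhiskerSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple


def measure_length(mask: np.ndarray, spacing: float | None = None) -> float:
    """Maximum Feret diameter of the largest 8-connected component.

    Returned in pixels, or mm when `spacing` (mm/px) is given. A single
    pixel has length 0; an empty mask raises UndefinedMetricError.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise UndefinedMetricError("length is undefined for an empty mask")
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
    pts = extract_contour(mask.astype(np.uint8)).astype(float)
    if len(pts) < 2:
        return 0.0
    d = float(pdist(pts).max())
    return d * spacing if spacing is not None else d


def bland_altman(pairs: list) -> BlandAltmanResult:
    """Bland-Altman bias and limits from (auto, manual) measurements.

    `pairs` is a list of LengthMeasurement or (auto, manual) tuples.
    Differences are auto - manual; SD uses the n-1 denominator and the
    limits are bias +/- 1.96 SD.
    """
    diffs = np.array([
        (p.auto_length - p.manual_length) if isinstance(p, LengthMeasurement)
        else (p[0] - p[1])
        for p in pairs], dtype=float)
    if len(diffs) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd,
                             loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd,
                             n=len(diffs))


def pearson_r(pairs: list) -> float:
    """Product-moment correlation of auto vs manual measurements."""
    auto = np.array([
        p.auto_length if isinstance(p, LengthMeasurement) else p[0]
        for p in pairs], dtype=float)
    manual = np.array([
        p.manual_length if isinstance(p, LengthMeasurement) else p[1]
        for p in pairs], dtype=float)
    if len(auto) < 2:
        raise ValueError("correlation needs at least 2 pairs")
    if auto.std() == 0 or manual.std() == 0:
        raise UndefinedMetricError(
            "correlation is undefined for a constant variable")
    return float(pearsonr(auto, manual).statistic)


def whisker_summary(values) -> WhiskerSummary:
    """Tukey box-whisker summary.

    Quartiles use linear interpolation between order statistics;
    fences sit at Q1 - 1.5 IQR and Q3 + 1.5 IQR; whiskers are the most
    extreme data inside the fences; everything outside is an outlier.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("whisker_summary needs at least one value")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return WhiskerSummary(median=float(med), q1=float(q1), q3=float(q3),
                          whisker_low=float(inside.min()),
                          whisker_high=float(inside.max()),
                          outliers=tuple(float(v) for v in np.sort(outliers)))


def bland_altman_plot(pairs: list, path, title: str = "Bland-Altman"):
    """Write a Bland-Altman scatter (difference vs mean) to `path`."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    auto = np.array([p.auto_length if isinstance(p, LengthMeasurement)
                     else p[0] for p in pairs], dtype=float)
    manual = np.array([p.manual_length if isinstance(p, LengthMeasurement)
                       else p[1] for p in pairs], dtype=float)
    means, diffs = (auto + manual) / 2.0, auto - manual
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=12)
    for y, style in ((res.bias, "-"), (res.loa_low, "--"),
                     (res.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("auto - manual")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res
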