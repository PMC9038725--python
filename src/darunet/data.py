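"""Loading, preprocessing and splitting of image/mask pairs.

Pairs are described by a TSV manifest with one line per sample:

    id <TAB> image_path <TAB> mask_path [<TAB> spacing_mm_per_px]

Relative paths resolve against the manifest's directory. Images are
converted to grayscale luminance, optionally resized (bilinear for the
image, nearest for the mask so it stays binary), standardised per image
to zero mean and unit population standard deviation, and zero-padded to
spatial dimensions divisible by 32 before entering the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "SegmentationSample", "DatasetSplit", "StandardizeParams", "PadSpec",
    "load_sample", "rgb_to_gray", "standardize", "resize_pair",
    "split_dataset", "filter_empty_masks", "pad_to_multiple", "crop_back",
    "read_manifest", "write_manifest", "save_mask_png",
    "DEFAULT_RESIZE", "preprocess_sample",
]

# default target resolution (width, height) for resampled clinical frames
DEFAULT_RESIZE = (472, 320)

_LUMA = np.array([0.299, 0.587, 0.114])
_STD_EPS = 1e-8


@dataclass
class SegmentationSample:
    """One image/mask pair; the unit all pipelines operate on."""

    id: str
    image: np.ndarray
    mask: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"sample {self.id!r}: image shape {self.image.shape} != "
                f"mask shape {self.mask.shape}")


@dataclass
class DatasetSplit:
    train: list
    test: list
    seed: int
    test_fraction: float


@dataclass
class StandardizeParams:
    mean: float
    s: float


@dataclass
class PadSpec:
    top: int
    bottom: int
    left: int
    right: int
    original_shape: tuple


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Luminance conversion 0.299 R + 0.587 G + 0.114 B.

    Integer inputs are rounded back to the nearest integer gray level.
    """
    gray = np.tensordot(rgb[..., :3].astype(float), _LUMA, axes=([-1], [0]))
    if np.issubdtype(rgb.dtype, np.integer):
        gray = np.rint(gray).astype(rgb.dtype)
    return gray


def load_sample(image_path, mask_path, sample_id: str | None = None,
                pixel_spacing: float | None = None) -> SegmentationSample:
    """Read an image/mask pair from disk (PNG/TIFF/BMP/JPEG).

    RGB(A) images collapse to luminance gray; 8-bit masks binarise at
    value > 127.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        image = np.asarray(iio.imread(image_path))
        mask = np.asarray(iio.imread(mask_path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image pair "
                      f"({image_path}, {mask_path}): {exc}") from exc
    if image.ndim == 3:
        image = rgb_to_gray(image)
    if mask.ndim == 3:
        mask = rgb_to_gray(mask)
    mask = (mask.astype(float) > 127).astype(np.uint8)
    return SegmentationSample(
        id=sample_id if sample_id is not None else image_path.stem,
        image=image.astype(float), mask=mask, pixel_spacing=pixel_spacing)


def standardize(image: np.ndarray
                ) -> tuple[np.ndarray, StandardizeParams]:
    """Per-image z-score: (x - mean(x)) / s with population SD.

    A constant image maps to all zeros (the SD is guarded by 1e-8).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot standardize an empty image")
    mean = float(image.mean())
    s = float(image.std())
    out = (image - mean) / max(s, _STD_EPS)
    return out, StandardizeParams(mean=mean, s=s)


def resize_pair(sample: SegmentationSample,
                target: tuple = DEFAULT_RESIZE) -> SegmentationSample:
    """Resize to `target` = (width, height): image bilinear, mask nearest."""
    width, height = int(target[0]), int(target[1])
    if width < 1 or height < 1:
        raise ValueError("target dimensions must be >= 1")
    if sample.image.shape == (height, width):
        return sample
    image = _sk_resize(sample.image, (height, width), order=1,
                       preserve_range=True, anti_aliasing=False)
    mask = _sk_resize(sample.mask, (height, width), order=0,
                      preserve_range=True, anti_aliasing=False)
    return SegmentationSample(id=sample.id, image=image,
                              mask=mask.astype(np.uint8),
                              pixel_spacing=sample.pixel_spacing)


def split_dataset(samples: list, test_fraction: float = 0.2,
                  seed: int = 0) -> DatasetSplit:
    """Seeded uniform shuffle into train/test; test size = round(n*f)."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    order = np.random.default_rng(seed).permutation(n)
    n_test = int(round(n * test_fraction))
    test_idx = set(order[:n_test].tolist())
    return DatasetSplit(
        train=[samples[i] for i in range(n) if i not in test_idx],
        test=[samples[i] for i in sorted(test_idx, key=list(order).index)],
        seed=seed, test_fraction=test_fraction)


def filter_empty_masks(samples: list) -> list:
    """Drop samples whose mask has no foreground pixel (order preserved)."""
    return [s for s in samples if np.asarray(s.mask).any()]


def pad_to_multiple(image: np.ndarray, m: int = 32
                    ) -> tuple[np.ndarray, PadSpec]:
    """Zero-pad symmetrically so both spatial dims divide by `m`.

    Odd remainders put the extra pixel on the bottom/right.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    h, w = image.shape[:2]
    dh = (-h) % m
    dw = (-w) % m
    spec = PadSpec(top=dh // 2, bottom=dh - dh // 2,
                   left=dw // 2, right=dw - dw // 2,
                   original_shape=(h, w))
    padded = np.pad(image, ((spec.top, spec.bottom),
                            (spec.left, spec.right)))
    return padded, spec


def crop_back(image: np.ndarray, spec: PadSpec) -> np.ndarray:
    """Exact inverse of pad_to_multiple."""
    h, w = spec.original_shape
    return image[spec.top:spec.top + h, spec.left:spec.left + w]


def preprocess_sample(sample: SegmentationSample,
                      target: tuple | None = None) -> SegmentationSample:
    """Optional resize followed by per-image standardisation."""
    if target is not None:
        sample = resize_pair(sample, target)
    image, _ = standardize(sample.image)
    return SegmentationSample(id=sample.id, image=image, mask=sample.mask,
                              pixel_spacing=sample.pixel_spacing)


def read_manifest(path) -> list[SegmentationSample]:
    """Load every sample listed in a TSV manifest."""
    path = Path(path)
    root = path.parent
    rows, seen = [], set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (3, 4):
            raise ValueError(
                f"{path}:{lineno}: expected 3 or 4 tab-separated fields")
        sid = parts[0]
        if sid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        seen.add(sid)
        spacing = float(parts[3]) if len(parts) == 4 else None
        rows.append((sid, parts[1], parts[2], spacing))
    return [load_sample(root / img, root / msk, sample_id=sid,
                        pixel_spacing=spacing)
            for sid, img, msk, spacing in rows]


def write_manifest(path, rows: list):
    """Write manifest rows (id, image_path, mask_path[, spacing])."""
    lines = []
    for row in rows:
        lines.append("\t".join(str(x) for x in row if x is not None))
    Path(path).write_text("\n".join(lines) + "\n")


def save_mask_png(path, mask: np.ndarray):
    """Write a binary mask as an 8-bit PNG with foreground 255."""
    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)
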