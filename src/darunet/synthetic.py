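"""Synthetic ultrasound-like phantoms with ground-truth masks.

Each sample is a single connected, randomly deformed ellipse (the
"lesion") brighter than a textured background. The rendered image is
the two-level template multiplied row-wise by a linear top-to-bottom
attenuation profile and pixel-wise by unit-mean Gamma speckle, then
Gaussian-blurred and clipped to [0, 1] — a standard surrogate for
fully developed speckle in coherent imaging, adequate for exercising a
segmentation pipeline though not a physical ultrasound simulation.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .config import SynthConfig
from .data import SegmentationSample, write_manifest

__all__ = ["ellipse_mask", "generate_mask", "render_image",
           "generate_samples", "generate_dataset", "GenerationError"]

_N_HARMONICS = 4
_MAX_REJECTIONS = 1000


class GenerationError(RuntimeError):
    """Mask generation failed to satisfy the area constraint."""


def ellipse_mask(h: int, w: int, cy: float, cx: float, a: float, b: float,
                 theta: float = 0.0) -> np.ndarray:
    """Rasterise an exact (undeformed) ellipse; pixel centers inside -> 1."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    return (u * u + v * v <= 1.0).astype(np.uint8)


def _deformed_ellipse(cfg: SynthConfig, rng: np.random.Generator
                      ) -> np.ndarray:
    h, w = cfg.height, cfg.width
    lo, hi = cfg.area_fraction
    # draw axes so the undeformed area pi*a*b sits inside the target range
    frac = rng.uniform(lo, hi)
    aspect = rng.uniform(0.5, 2.0)
    area = frac * h * w
    a = np.sqrt(area * aspect / np.pi)
    b = area / (np.pi * a)
    cy = rng.uniform(0.3 * h, 0.7 * h)
    cx = rng.uniform(0.3 * w, 0.7 * w)
    theta = rng.uniform(0.0, np.pi)
    phases = rng.uniform(0.0, 2 * np.pi, _N_HARMONICS)
    amps = rng.uniform(0.0, 1.0, _N_HARMONICS)
    amps *= cfg.boundary_roughness / max(amps.sum(), 1e-12)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    r = np.sqrt(u * u + v * v)
    if cfg.boundary_roughness > 0:
        ang = np.arctan2(v, u)
        mod = np.zeros_like(r)
        for k in range(_N_HARMONICS):
            mod += amps[k] * np.cos((k + 2) * ang + phases[k])
        limit = 1.0 + mod
    else:
        limit = 1.0
    return (r <= limit).astype(np.uint8)


def generate_mask(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """One connected deformed-ellipse mask with area fraction in range.

    Candidates violating the area-fraction window or connectivity are
    rejected and redrawn (up to 1000 attempts).
    """
    lo, hi = cfg.area_fraction
    total = cfg.height * cfg.width
    for _ in range(_MAX_REJECTIONS):
        mask = _deformed_ellipse(cfg, rng)
        frac = mask.sum() / total
        if not lo <= frac <= hi:
            continue
        _, n_comp = ndimage.label(mask)
        if n_comp == 1:
            return mask
    raise GenerationError(
        f"no admissible mask after {_MAX_REJECTIONS} rejections")


def render_image(mask: np.ndarray, cfg: SynthConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Render a speckled, attenuated, blurred image for `mask`."""
    mask = np.asarray(mask, dtype=bool)
    base = np.where(mask, cfg.fg_mean, cfg.bg_mean).astype(float)
    rows = np.linspace(1.0, 1.0 - cfg.attenuation, mask.shape[0])
    img = base * rows[:, None]
    k = cfg.speckle_shape
    if np.isfinite(k):
        img = img * rng.gamma(k, 1.0 / k, size=img.shape)
    if cfg.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma)
    return np.clip(img, 0.0, 1.0)


def generate_samples(cfg: SynthConfig) -> list[SegmentationSample]:
    """Generate `cfg.n_samples` in-memory image/mask pairs."""
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for i in range(cfg.n_samples):
        mask = generate_mask(cfg, rng)
        image = render_image(mask, cfg, rng)
        samples.append(SegmentationSample(
            id=f"synth_{i:04d}", image=image, mask=mask))
    return samples


def generate_dataset(cfg: SynthConfig, out_dir) -> Path:
    """Write PNG pairs plus a TSV manifest; return the manifest path.

    Images are quantised to 8-bit; masks are 0/255 PNGs. The manifest
    is the dialect `darunet.data.read_manifest` consumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in generate_samples(cfg):
        img_name, msk_name = f"{s.id}_image.png", f"{s.id}_mask.png"
        iio.imwrite(out_dir / img_name,
                    np.rint(s.image * 255).astype(np.uint8))
        iio.imwrite(out_dir / msk_name, s.mask.astype(np.uint8) * 255)
        rows.append((s.id, img_name, msk_name))
    manifest = out_dir / "manifest.tsv"
    write_manifest(manifest, rows)
    return manifest
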