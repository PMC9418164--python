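"""Synthetic polyp-like fixtures.

Each image is a textured background with one or more bright, pink-shifted
blobs — ellipses whose boundary radius is modulated by a low-frequency
harmonic, mimicking the irregular outline of real polyps — together with the
exact binary mask.  All sampling is threaded through one seeded generator, so
a config produces byte-identical datasets across runs and platforms.  The
generated layout is interchangeable with real image/mask directories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .data import ImageSample, save_dataset
from .nn.functional import linear_resize_matrix

__all__ = ["FixtureConfig", "generate_fixture_set", "fixture_difficulty_report",
           "write_fixture_dataset", "LUMA"]

LUMA = np.array([0.299, 0.587, 0.114])
# background base tone (grey-pink) and foreground colour shift at contrast 1
_BG_TONE = np.array([0.45, 0.33, 0.31])
_FG_SHIFT = np.array([0.50, 0.28, 0.22])   # luminance shift ~0.34 per unit contrast
_TEXTURE_AMP = 0.06                        # per-channel low-frequency texture span
_CONTRAST_JITTER = (0.5, 1.0)              # per-image multiplier on the contrast


@dataclass
class FixtureConfig:
    n_images: int = 32
    image_size: tuple[int, int] = (64, 64)
    blobs_per_image: tuple[int, int] = (1, 2)
    blob_radius_frac: tuple[float, float] = (0.12, 0.30)
    intensity_contrast: float = 0.45
    background_noise_sd: float = 0.10
    deform_amplitude: float = 0.25
    tone_jitter: float = 0.16
    vignette_strength: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        for name in ("blobs_per_image", "blob_radius_frac"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must be ordered (min <= max)")
        if not 0.0 < self.intensity_contrast <= 1.0:
            raise ValueError("intensity_contrast must be in (0, 1]")
        if min(self.background_noise_sd, self.deform_amplitude,
               self.tone_jitter, self.vignette_strength) < 0:
            raise ValueError("noise sd, deform amplitude, tone jitter and "
                             "vignette strength must be >= 0")
        lo, hi = self.blob_radius_frac
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("blob_radius_frac must lie in (0, 1)")
        if hi * (1.0 + self.deform_amplitude) >= 0.5:
            raise ValueError(
                "blob radius times (1 + deform_amplitude) exceeds the image half-side; "
                "a blob could not fit inside the frame"
            )


def _background(rng: np.random.Generator, size: tuple[int, int],
                tone_jitter: float, vignette_strength: float) -> np.ndarray:
    """Low-frequency (Perlin-like) texture around a per-image base tone, with
    an optional radial illumination falloff (vignette) of random centre and
    strength.

    The tone shift (and vignette, when enabled) varies per image, emulating
    illumination variability of endoscopic frames: a single global intensity
    threshold cannot segment the whole dataset even though each image alone
    remains separable.  The vignette darkens the background only (the
    foreground shift is added afterwards), so per-image separability is
    preserved.
    """
    h, w = size
    tone = _BG_TONE + rng.uniform(-tone_jitter, tone_jitter)
    k = 4
    coarse = rng.uniform(-1.0, 1.0, (k, k))
    ah = linear_resize_matrix(h, k)
    aw = linear_resize_matrix(w, k)
    field = ah @ coarse @ aw.T
    bg = tone[None, None, :] + _TEXTURE_AMP * field[:, :, None]
    if vignette_strength > 0:
        s = rng.uniform(0.0, vignette_strength)
        cy, cx = rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((yy - cy) / h) ** 2 + ((xx - cx) / w) ** 2
        bg = bg * (1.0 - s * (r2 / max(r2.max(), 1e-9)))[:, :, None]
    return np.clip(bg, 0.0, 1.0)


def _blob_mask(rng: np.random.Generator, size: tuple[int, int],
               radius_frac: tuple[float, float], deform: float) -> np.ndarray:
    h, w = size
    side = min(h, w)
    a = rng.uniform(*radius_frac) * side
    b = rng.uniform(*radius_frac) * side
    reach = max(a, b) * (1.0 + deform) + 1.0
    cy = rng.uniform(reach, h - reach)
    cx = rng.uniform(reach, w - reach)
    phi = rng.uniform(0.0, np.pi)
    # low-frequency radial modulation of the ellipse boundary
    n_harm = 3
    coeffs = rng.normal(0.0, 1.0, (n_harm, 2))
    norm = np.abs(coeffs).sum() or 1.0
    coeffs = coeffs / norm * deform

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = (dx * np.cos(phi) + dy * np.sin(phi)) / a
    v = (-dx * np.sin(phi) + dy * np.cos(phi)) / b
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    boundary = 1.0
    for k in range(n_harm):
        boundary = boundary + coeffs[k, 0] * np.cos((k + 2) * theta) \
                            + coeffs[k, 1] * np.sin((k + 2) * theta)
    return rho <= boundary


def generate_fixture_set(config: FixtureConfig) -> list[ImageSample]:
    """Deterministically generate ``n_images`` image/mask samples."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    samples = []
    for i in range(config.n_images):
        bg = _background(rng, config.image_size, config.tone_jitter,
                         config.vignette_strength)
        lo, hi = config.blobs_per_image
        n_blobs = int(rng.integers(lo, hi + 1))
        mask = np.zeros((h, w), dtype=bool)
        for _ in range(n_blobs):
            mask |= _blob_mask(rng, config.image_size, config.blob_radius_frac,
                               config.deform_amplitude)
        contrast = config.intensity_contrast * rng.uniform(*_CONTRAST_JITTER)
        img = bg + contrast * mask[:, :, None] * _FG_SHIFT[None, None, :]
        if config.background_noise_sd > 0:
            img = img + rng.normal(0.0, config.background_noise_sd, img.shape)
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        samples.append(ImageSample(
            id=f"fixture_{i:04d}", image=img, mask=mask.astype(np.uint8),
            source_path=f"synthetic://seed{config.seed}/{i}", original_size=(h, w),
        ))
    return samples


def fixture_difficulty_report(samples: list[ImageSample]) -> pd.DataFrame:
    """Per-sample difficulty table: foreground fraction, component count,
    luminance contrast, and an empty-foreground warning flag."""
    rows = []
    for s in samples:
        if s.mask is None:
            raise ValueError(f"sample {s.id!r} has no mask")
        mask = s.mask.astype(bool)
        frac = float(mask.mean())
        lum = s.image @ LUMA
        contrast = float(lum[mask].mean() - lum[~mask].mean()) if 0 < frac < 1 else np.nan
        rows.append({
            "id": s.id,
            "foreground_fraction": frac,
            "n_components": int(cc_label(mask).max()),
            "luminance_contrast": contrast,
            "empty_foreground": frac == 0.0,
        })
    return pd.DataFrame(rows)


def write_fixture_dataset(config: FixtureConfig, image_dir, mask_dir) -> list[ImageSample]:
    """Generate and persist fixtures in the directory layout ``load_dataset`` reads."""
    samples = generate_fixture_set(config)
    save_dataset(samples, image_dir, mask_dir)
    return samples
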