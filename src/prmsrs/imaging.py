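"""Downstream image products built on PRM score maps.

Ratiometric maps (pixelwise score ratios, revealing relative subtype
abundance independent of overall intensity), top-percentile pixel-spectrum
extraction, threshold masks, additive channel merges, cross-modality
agreement metrics (structural similarity and normalized mean squared
error) and bilinear line profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.metrics import structural_similarity

from .exceptions import ConfigError, DimensionError
from .preprocess import PreprocessConfig, preprocess_matrix
from .spectrum import HyperspectralStack, ScoreImage, Spectrum, Stage

__all__ = [
    "RatioImage",
    "ratio_image",
    "top_percentile_spectra",
    "threshold_mask",
    "merge_channels",
    "image_agreement",
    "line_profile",
]


@dataclass
class RatioImage:
    """Pixelwise ratio of two score maps.

    ``mask`` is True where the ratio is undefined: the denominator fell
    below ``epsilon`` or either input pixel was masked.  Values at masked
    pixels are 0 so arrays remain finite.
    """

    values: np.ndarray
    mask: np.ndarray
    numerator_name: str = ""
    denominator_name: str = ""
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise DimensionError("ratio values and mask must share a shape")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise DimensionError("unmasked ratio values must be finite")


def ratio_image(num: ScoreImage, den: ScoreImage, epsilon: float = 1e-6) -> RatioImage:
    """Elementwise num/den where den >= epsilon; elsewhere masked.

    Input masks propagate as a union.
    """
    if num.shape != den.shape:
        raise DimensionError(f"shape mismatch {num.shape} vs {den.shape}")
    mask = num.mask | den.mask | (den.scores < epsilon)
    values = np.zeros(num.shape)
    ok = ~mask
    values[ok] = num.scores[ok] / den.scores[ok]
    return RatioImage(values, mask, num.reference_name, den.reference_name, epsilon)


def top_percentile_spectra(
    stack: HyperspectralStack,
    score: ScoreImage,
    pct: float,
    pcfg: PreprocessConfig | None = None,
) -> tuple[Spectrum, np.ndarray]:
    """Mean preprocessed spectrum of the highest-scoring pixels.

    Selects pixels whose score is >= the ``pct``-th percentile of the
    unmasked scores (linear-interpolation percentile) and returns their
    mean unit-norm spectrum plus the per-band standard deviation.
    """
    if not 0 < pct < 100:
        raise ConfigError("pct must be in (0, 100)")
    if score.shape != stack.shape[:2]:
        raise DimensionError("score map and stack are not co-registered")
    pcfg = pcfg or PreprocessConfig()
    valid = ~score.mask
    if not valid.any():
        raise ConfigError("all pixels are masked; nothing to select")
    thr = np.percentile(score.scores[valid], pct)
    selected = valid & (score.scores >= thr)
    p, degenerate, _ = preprocess_matrix(
        stack.flat()[selected.ravel()], stack.axis, pcfg
    )
    p = p[~degenerate]
    if p.shape[0] == 0:
        raise ConfigError("all selected pixels were degenerate")
    mean = p.mean(axis=0)
    sd = p.std(axis=0)
    label = f"top{pct:g}pct_{score.reference_name}"
    return Spectrum(pcfg.grid(), mean, Stage.BASELINE_CORRECTED, label), sd


def threshold_mask(score: ScoreImage, t: float) -> np.ndarray:
    """Binary mask of pixels with score >= t; masked pixels excluded."""
    if not 0 <= t <= 1 + 1e-12:
        raise ConfigError("threshold must be in [0, 1]")
    return (score.scores >= t) & ~score.mask


_NAMED_COLORS = {
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "magenta": (1.0, 0.0, 1.0),
    "cyan": (0.0, 1.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
    "gray": (1.0, 1.0, 1.0),
}


@dataclass
class MergeResult:
    """Additive RGB composite; ``clipped`` marks channels that saturated."""

    rgb: np.ndarray
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]


def merge_channels(images: list[ScoreImage], colors: list) -> MergeResult:
    """Additive color composite with fixed [0, 1] per-channel scaling.

    Scores add per RGB channel and clip at 1; overlapping subtypes mix
    additively (red + green -> yellow), mirroring co-localization merges.
    """
    if len(images) == 0:
        raise ConfigError("merge_channels needs at least one image")
    if len(images) != len(colors):
        raise ConfigError("one color per image required")
    shape = images[0].shape
    rgb = np.zeros(shape + (3,))
    for img, color in zip(images, colors):
        if img.shape != shape:
            raise DimensionError("all images must share a shape")
        c = np.asarray(_NAMED_COLORS.get(color, color), dtype=float)
        if c.shape != (3,):
            raise ConfigError(f"color {color!r} is not a name or RGB triple")
        scores = np.where(img.mask, 0.0, img.scores)
        rgb += scores[:, :, None] * c[None, None, :]
    clipped = rgb > 1.0
    return MergeResult(np.clip(rgb, 0.0, 1.0), clipped)


def image_agreement(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Agreement between two images of the same scene.

    Returns the structural similarity index (standard constants, inputs
    rescaled to [0, 1] jointly) and the normalized mean squared error
    ||a - b||^2 / ||b||^2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DimensionError("images must be finite")
    denom = float(np.sum(b**2))
    if denom == 0:
        raise ConfigError("nmse undefined for an all-zero second image")
    nmse = float(np.sum((a - b) ** 2)) / denom
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    scale = hi - lo if hi > lo else 1.0
    a1 = (a - lo) / scale
    b1 = (b - lo) / scale
    win = min(7, min(a.shape) - (min(a.shape) + 1) % 2)  # largest odd <= 7
    ssim = float(structural_similarity(a1, b1, data_range=1.0, win_size=max(win, 3)))
    return {"similarity_index": ssim, "nmse": nmse}


def line_profile(
    img: np.ndarray, p0: tuple[float, float], p1: tuple[float, float]
) -> np.ndarray:
    """Bilinear samples at unit-spaced points along the segment p0 -> p1.

    Returns ceil(Euclidean distance) + 1 samples including both endpoints.
    """
    img = np.asarray(img, dtype=float)
    rows, cols = img.shape[:2]
    for p in (p0, p1):
        if not (0 <= p[0] <= rows - 1 and 0 <= p[1] <= cols - 1):
            raise DimensionError(f"endpoint {p} outside image {img.shape[:2]}")
    dist = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    n = int(np.ceil(dist)) + 1
    t = np.linspace(0.0, 1.0, n)
    rr = p0[0] + t * (p1[0] - p0[0])
    cc = p0[1] + t * (p1[1] - p0[1])
    return map_coordinates(img, np.vstack([rr, cc]), order=1, mode="nearest")
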