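"""Synthetic reference spectra and hyperspectral stacks with known truth.

Fixtures emulate CH-stretching-region SRS acquisitions: Gaussian-peaked
lipid-like reference spectra on a dense 1 cm^-1 grid, and stacks whose
pixels are known mixtures of those references with per-pixel brightness
randomization, spectral jitter (a random rigid shift of the whole pixel
spectrum, mimicking calibration drift), additive Gaussian noise, and
down-sampling to the acquisition band spacing (75 bands at 6 cm^-1 by
default) so the pipeline's re-interpolation path is exercised end to end.
Every output is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .preprocess import PreprocessConfig, build_library
from .spectrum import HyperspectralStack, ReferenceLibrary, Spectrum, Stage

__all__ = [
    "SimSpec",
    "make_reference",
    "default_library_peaks",
    "make_library",
    "make_stack",
    "make_fraction_series",
]

# Gaussian peak tables (amplitude, center cm^-1, sigma cm^-1) for
# lipid-like synthetic standards.  "tag_like" is CH2-dominant (saturated
# acyl chains), "pe_like" CH3-dominant with an olefinic shoulder,
# "chol_like" has the sterol 2870/2935 pattern.
_LIPID_PEAKS: dict[str, list[tuple[float, float, float]]] = {
    "tag_like": [(1.0, 2850.0, 14.0), (0.55, 2880.0, 16.0), (0.45, 2935.0, 22.0), (0.10, 3010.0, 18.0)],
    "pe_like": [(0.45, 2850.0, 14.0), (0.40, 2880.0, 16.0), (1.0, 2935.0, 20.0), (0.35, 3065.0, 20.0)],
    "chol_like": [(0.70, 2850.0, 13.0), (0.95, 2870.0, 14.0), (0.80, 2935.0, 24.0), (0.25, 3065.0, 22.0)],
}


@dataclass(frozen=True)
class SimSpec:
    """Stack-simulation settings.

    The dense grid matches the analysis window (2700-3150 cm^-1, 1 cm^-1);
    ``n_bands_acquired`` bands at ``band_spacing`` emulate the instrument's
    coarser sampling.  ``noise_sd`` is additive Gaussian noise on raw
    intensities (reference peak amplitudes are O(1)); ``jitter_sd`` is the
    standard deviation of the per-pixel rigid spectral shift in cm^-1.
    """

    seed: int = 0
    grid_range: tuple[float, float] = (2700.0, 3150.0)
    grid_step: float = 1.0
    n_bands_acquired: int = 75
    band_spacing: float = 6.0
    noise_sd: float = 0.0
    jitter_sd: float = 0.0
    brightness_range: tuple[float, float] = (0.5, 2.0)
    layout: str = "two_phase"  # two_phase | droplets | fraction_ramp
    shape: tuple[int, int] = (16, 16)
    fractions: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ConfigError("noise_sd and jitter_sd must be >= 0")
        if self.layout not in ("two_phase", "droplets", "fraction_ramp"):
            raise ConfigError(f"unknown layout {self.layout!r}")
        lo, hi = self.grid_range
        top = lo + self.band_spacing * (self.n_bands_acquired - 1)
        if top > hi:
            raise ConfigError("acquired bands exceed the dense grid range")

    def grid(self) -> np.ndarray:
        lo, hi = self.grid_range
        n = int(round((hi - lo) / self.grid_step)) + 1
        return lo + self.grid_step * np.arange(n)

    def band_axis(self) -> np.ndarray:
        lo = self.grid_range[0]
        return lo + self.band_spacing * np.arange(self.n_bands_acquired)


def make_reference(
    peaks: list[tuple[float, float, float]], grid: np.ndarray, label: str = ""
) -> Spectrum:
    """Sum-of-Gaussians raw spectrum on ``grid``.

    ``peaks`` are (amplitude, center, sigma) triples with centers inside
    the grid span.
    """
    grid = np.asarray(grid, dtype=float)
    if len(peaks) == 0:
        raise ConfigError("at least one peak required")
    y = np.zeros_like(grid)
    for a, c, w in peaks:
        if not grid[0] <= c <= grid[-1]:
            raise ConfigError(f"peak center {c} outside grid")
        y += a * np.exp(-((grid - c) ** 2) / (2.0 * w**2))
    return Spectrum(grid, y, Stage.RAW, label)


def make_regime_pair(grid: np.ndarray | None = None) -> dict[str, Spectrum]:
    """Reference pair exhibiting the penalty-coefficient regimes.

    ``matched``: two sharp CH bands (2850/2935 cm^-1, sigma 5).
    ``confounder``: the same bands broadened (sigma 25) plus a half-weight
    copy of the sharp bands offset +25 cm^-1.

    Scored against ``matched``, a confounder pixel responds almost flatly
    to small shifts (broad bands) but gains from a ~+23 cm^-1 shift that
    aligns the offset copy.  Under-penalization therefore inflates
    confounder scores (the free-shift false positive: a reference peak
    matching a displaced pixel band), while over-penalization taxes the
    genuine spectral jitter of matched pixels.  Matched-vs-confounder
    contrast consequently peaks at intermediate penalty coefficients.
    """
    if grid is None:
        grid = SimSpec().grid()
    m_peaks = [(1.0, 2850.0, 5.0), (0.6, 2935.0, 5.0)]
    u_peaks = [(1.0, 2850.0, 25.0), (0.6, 2935.0, 25.0),
               (0.5, 2875.0, 5.0), (0.3, 2960.0, 5.0)]
    return {
        "matched": make_reference(m_peaks, grid, "matched"),
        "confounder": make_reference(u_peaks, grid, "confounder"),
    }


def default_library_peaks() -> dict[str, list[tuple[float, float, float]]]:
    """Peak tables for the built-in lipid-like standards (copy)."""
    return {k: list(v) for k, v in _LIPID_PEAKS.items()}


def make_library(
    spec: SimSpec | None = None, names: list[str] | None = None
) -> ReferenceLibrary:
    """Preprocessed library of the built-in lipid-like references."""
    spec = spec or SimSpec()
    names = names or list(_LIPID_PEAKS)
    grid = spec.grid()
    raw = {n: make_reference(_LIPID_PEAKS[n], grid, n) for n in names}
    pcfg = PreprocessConfig(grid_step=spec.grid_step, grid_range=spec.grid_range)
    return build_library(raw, pcfg)


def _weight_maps(spec: SimSpec, n_refs: int, rng: np.random.Generator) -> np.ndarray:
    """Ground-truth mixture weights, (rows, cols, n_refs), rows sum to 1."""
    rows, cols = spec.shape
    w = np.zeros((rows, cols, n_refs))
    if spec.layout == "two_phase":
        half = cols // 2
        w[:, :half, 0] = 1.0
        w[:, half:, 1 % n_refs] = 1.0
        if n_refs == 1:
            w[:, :, 0] = 1.0
    elif spec.layout == "droplets":
        w[:, :, -1] = 1.0  # background phase
        rr, cc = np.mgrid[0:rows, 0:cols]
        n_drops = max(3, (rows * cols) // 80)
        for _ in range(n_drops):
            k = int(rng.integers(0, max(n_refs - 1, 1)))
            r0 = rng.uniform(0, rows)
            c0 = rng.uniform(0, cols)
            rad = rng.uniform(1.5, max(2.5, min(rows, cols) / 6))
            inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            w[inside] = 0.0
            w[inside, k] = 1.0
    else:  # fraction_ramp: component 0 fraction ramps 0 -> 1 across columns
        f = np.linspace(0.0, 1.0, cols)[None, :]
        w[:, :, 0] = f
        w[:, :, 1 % n_refs] += 1.0 - f
    return w


def make_stack(
    spec: SimSpec, lib_raw: dict[str, Spectrum] | None = None
) -> tuple[HyperspectralStack, dict]:
    """Simulate a stack plus its ground truth.

    Per pixel: mixture sum(w_i * ref_i) of *raw* reference intensities,
    scaled by a random brightness factor, rigidly shifted by
    N(0, jitter_sd) cm^-1 via interpolation on the dense grid, plus
    N(0, noise_sd) noise, then sampled at the acquisition bands.

    Returns ``(stack, truth)`` where ``truth`` holds ``weights``
    (rows x cols x n_refs), ``shift`` (rows x cols, cm^-1),
    ``brightness`` and ``names``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    if lib_raw is None:
        lib_raw = {n: make_reference(p, grid, n) for n, p in _LIPID_PEAKS.items()}
    names = list(lib_raw)
    refs = np.stack([lib_raw[n].intensity for n in names])  # (n_refs, n_grid)
    w = _weight_maps(spec, len(names), rng)
    sums = w.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ConfigError("mixture weights must sum to 1 per pixel")
    rows, cols = spec.shape
    n_pix = rows * cols
    mix = w.reshape(n_pix, len(names)) @ refs  # dense-grid mixtures
    brightness = rng.uniform(*spec.brightness_range, size=n_pix)
    shift = (
        rng.normal(0.0, spec.jitter_sd, size=n_pix) if spec.jitter_sd > 0 else np.zeros(n_pix)
    )
    band_axis = spec.band_axis()
    data = np.empty((n_pix, band_axis.size))
    for i in range(n_pix):
        # sample the shifted dense spectrum at the acquisition bands:
        # a shift of +s moves features toward higher wavenumber
        data[i] = brightness[i] * np.interp(band_axis - shift[i], grid, mix[i])
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    stack = HyperspectralStack(
        data.reshape(rows, cols, band_axis.size),
        band_axis,
        meta={"seed": spec.seed, "layout": spec.layout},
    )
    truth = {
        "weights": w,
        "shift": shift.reshape(rows, cols),
        "brightness": brightness.reshape(rows, cols),
        "names": names,
    }
    return stack, truth


def make_fraction_series(
    ref_a: Spectrum,
    ref_b: Spectrum,
    fractions,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[Spectrum]:
    """Two-component mixture series f*a + (1-f)*b on the shared grid."""
    rng = np.random.default_rng(seed)
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ConfigError("fractions must lie in [0, 1]")
    if not np.array_equal(ref_a.axis, ref_b.axis):
        raise ConfigError("references must share a grid")
    out = []
    for f in fractions:
        y = f * ref_a.intensity + (1.0 - f) * ref_b.intensity
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        out.append(Spectrum(ref_a.axis, y, Stage.RAW, f"mix_f{f:g}"))
    return out
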