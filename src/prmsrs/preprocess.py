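"""Spectral preprocessing: baseline correction, common-grid interpolation,
min-max scaling and Euclidean normalization.

The chain is fixed as baseline -> interpolate -> min-max -> unit-norm and is
applied identically to hyperspectral pixel spectra and to reference spectra,
so that a pixel/reference inner product compares spectral *shape* only:
min-max scaling removes any affine intensity transform (gain and offset),
and the Euclidean normalization makes the dot product a cosine similarity.

Baseline estimation uses arPLS (asymmetrically reweighted penalized least
squares): iterate Whittaker smoothing with a second-difference roughness
penalty, reweighting points by a logistic function of their residual so
that peaks (large positive residuals) are progressively excluded from the
baseline while noise below the baseline keeps full weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .exceptions import ConfigError, CoverageError, DegenerateSpectrumError
from .spectrum import Spectrum, Stage

__all__ = [
    "PreprocessConfig",
    "interpolate_to_grid",
    "minmax_normalize",
    "unit_normalize",
    "arpls_baseline",
    "preprocess_pixel",
    "preprocess_matrix",
    "build_library",
    "counters",
]

# Instrumentation: incremented by the number of pixel spectra pushed through
# the full chain.  Lets callers verify that multi-reference scoring
# preprocesses each pixel once, not once per reference.
counters: dict[str, int] = {"pixel_spectra_preprocessed": 0}


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    grid_step/grid_range define the common interpolation axis (default the
    CH-stretching window 2700-3150 cm^-1 at 1 cm^-1 steps).  ``baseline``
    selects no correction, subtraction of a measured background spectrum,
    or arPLS estimation.
    """

    grid_step: float = 1.0
    grid_range: tuple[float, float] = (2700.0, 3150.0)
    baseline: str = "none"  # none | subtract_measured | arpls
    arpls_lambda: float = 1e5
    arpls_ratio: float = 1e-6
    arpls_max_iter: int = 50
    background: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be > 0")
        lo, hi = self.grid_range
        if not lo < hi:
            raise ConfigError("grid_range must satisfy lo < hi")
        if self.baseline not in ("none", "subtract_measured", "arpls"):
            raise ConfigError(f"unknown baseline mode {self.baseline!r}")
        if self.arpls_lambda <= 0:
            raise ConfigError("arpls_lambda must be > 0")

    def grid(self) -> np.ndarray:
        """The interpolation axis: lo, lo+step, ... up to hi inclusive."""
        lo, hi = self.grid_range
        n = int(np.floor((hi - lo) / self.grid_step + 1e-9)) + 1
        return lo + self.grid_step * np.arange(n)


def interpolate_to_grid(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Linearly interpolate a spectrum onto the common grid.

    Grid points outside the source axis coverage are set to 0 and flagged
    False in the returned spectrum's ``coverage`` mask.
    """
    grid = cfg.grid()
    lo, hi = float(s.axis[0]), float(s.axis[-1])
    covered = (grid >= lo) & (grid <= hi)
    if not covered.any():
        raise CoverageError(
            f"spectrum [{lo}, {hi}] does not overlap grid "
            f"[{grid[0]}, {grid[-1]}]"
        )
    vals = np.interp(grid, s.axis, s.intensity)
    vals[~covered] = 0.0
    return Spectrum(grid, vals, s.stage, s.label, coverage=covered)


def minmax_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities to [0, 1]: (I - Imin) / (Imax - Imin).

    When a coverage mask is present the statistics are taken over covered
    points only and zero-filled out-of-coverage points stay 0, so the
    zero-fill cannot fake a dynamic range on an otherwise constant pixel
    (and an intensity offset is still removed on the covered region).
    """
    cov = s.coverage if s.coverage is not None else np.ones(len(s), dtype=bool)
    vals = s.intensity[cov]
    imin = float(vals.min())
    imax = float(vals.max())
    if imax - imin <= 0:
        raise DegenerateSpectrumError("constant spectrum cannot be min-max scaled")
    out = np.zeros_like(s.intensity)
    out[cov] = (vals - imin) / (imax - imin)
    return s.with_intensity(out, Stage.MINMAX)


def unit_normalize(s: Spectrum) -> Spectrum:
    """Divide intensities by their Euclidean norm."""
    norm = float(np.linalg.norm(s.intensity))
    if norm <= 0:
        raise DegenerateSpectrumError("zero spectrum cannot be unit-normalized")
    return s.with_intensity(s.intensity / norm, Stage.UNIT_NORM)


def _arpls_solve(y: np.ndarray, lam: float, ratio: float, max_iter: int) -> tuple[np.ndarray, bool]:
    """Return (baseline, converged) for one trace."""
    n = y.size
    d = sp.eye(n, format="csc")
    d = d[1:] - d[:-1]
    d = d[1:] - d[:-1]  # second difference, (n-2) x n
    h = lam * (d.T @ d)
    w = np.ones(n)
    converged = False
    for _ in range(max_iter):
        wmat = sp.diags(w, format="csc")
        z = spsolve(wmat + h, w * y)
        resid = y - z
        neg = resid[resid < 0]
        if neg.size == 0:
            converged = True
            break
        m = neg.mean()
        s = neg.std()
        if s <= 0:
            converged = True
            break
        w_new = 1.0 / (1.0 + np.exp(np.clip(2.0 * (resid - (2.0 * s - m)) / s, -500, 500)))
        if np.linalg.norm(w - w_new) / max(np.linalg.norm(w), 1e-30) < ratio:
            w = w_new
            converged = True
            break
        w = w_new
    return z, converged


def arpls_baseline(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Subtract an arPLS-estimated baseline.

    With ``cfg.baseline == 'none'`` this is the identity; with
    ``'subtract_measured'`` the configured background trace (sampled on the
    same axis) is subtracted instead of an estimate.  Non-convergence past
    ``arpls_max_iter`` returns the best estimate (a warning flag is stored
    in the label-preserving output only through the ``converged`` return of
    the private solver; the public path never raises for it).
    """
    if cfg.baseline == "none":
        return s
    if cfg.baseline == "subtract_measured":
        if cfg.background is None:
            raise ConfigError("subtract_measured requires a background trace")
        bg = np.asarray(cfg.background, dtype=float)
        if bg.shape != s.intensity.shape:
            raise ConfigError("background trace must match spectrum length")
        return s.with_intensity(s.intensity - bg, Stage.BASELINE_CORRECTED)
    if len(s) < 10:
        raise ConfigError("arPLS needs at least 10 points")
    z, _ = _arpls_solve(s.intensity, cfg.arpls_lambda, cfg.arpls_ratio, cfg.arpls_max_iter)
    return s.with_intensity(s.intensity - z, Stage.BASELINE_CORRECTED)


def preprocess_pixel(raw: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Full chain: baseline -> interpolate -> min-max -> unit-norm.

    Used verbatim for both pixel and reference spectra.  Degenerate
    (constant or zero) inputs raise :class:`DegenerateSpectrumError`; the
    stack path converts that to a masked pixel.
    """
    s = arpls_baseline(raw, cfg)
    s = interpolate_to_grid(s, cfg)
    s = minmax_normalize(s)
    counters["pixel_spectra_preprocessed"] += 1
    return unit_normalize(s)


def preprocess_matrix(
    data: np.ndarray, axis: np.ndarray, cfg: PreprocessConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pixel chain for (n_pixels, n_bands) data.

    Returns ``(P, degenerate, coverage)`` where ``P`` is (n_pixels, n_grid)
    unit-norm spectra (degenerate rows zeroed), ``degenerate`` flags
    constant/zero pixels and ``coverage`` is the shared grid-coverage mask.
    Row-wise operations only, so results are independent of how pixels are
    chunked.
    """
    data = np.asarray(data, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if cfg.baseline == "arpls":
        corrected = np.empty_like(data)
        for i in range(data.shape[0]):
            z, _ = _arpls_solve(data[i], cfg.arpls_lambda, cfg.arpls_ratio, cfg.arpls_max_iter)
            corrected[i] = data[i] - z
        data = corrected
    elif cfg.baseline == "subtract_measured":
        if cfg.background is None:
            raise ConfigError("subtract_measured requires a background trace")
        data = data - np.asarray(cfg.background, dtype=float)[None, :]

    grid = cfg.grid()
    covered = (grid >= axis[0]) & (grid <= axis[-1])
    if not covered.any():
        raise CoverageError("stack axis does not overlap the grid")
    # one set of interpolation weights shared by every pixel
    idx = np.searchsorted(axis, grid, side="right") - 1
    idx = np.clip(idx, 0, axis.size - 2)
    frac = (grid - axis[idx]) / (axis[idx + 1] - axis[idx])
    frac = np.clip(frac, 0.0, 1.0)
    p = data[:, idx] * (1.0 - frac)[None, :] + data[:, idx + 1] * frac[None, :]
    p[:, ~covered] = 0.0

    # min-max statistics over covered grid points only (see minmax_normalize)
    pmin = p[:, covered].min(axis=1, keepdims=True)
    pmax = p[:, covered].max(axis=1, keepdims=True)
    degenerate = (pmax - pmin).ravel() <= 0
    span = np.where(degenerate[:, None], 1.0, pmax - pmin)
    p[:, covered] = (p[:, covered] - pmin) / span
    p[:, ~covered] = 0.0
    norm = np.linalg.norm(p, axis=1, keepdims=True)
    degenerate |= norm.ravel() <= 0
    p = p / np.where(norm <= 0, 1.0, norm)
    p[degenerate] = 0.0
    counters["pixel_spectra_preprocessed"] += data.shape[0]
    return p, degenerate, covered


def build_library(
    spectra: dict[str, Spectrum] | list[Spectrum], cfg: PreprocessConfig
):
    """Preprocess named raw reference spectra onto the common grid.

    Accepts a name->Spectrum mapping or a list of labelled spectra and
    returns a :class:`~prmsrs.spectrum.ReferenceLibrary`.
    """
    from .spectrum import ReferenceLibrary

    if not isinstance(spectra, dict):
        spectra = {s.label or f"ref{i}": s for i, s in enumerate(spectra)}
    if len(set(spectra)) != len(spectra):
        raise ConfigError("reference names must be unique")
    entries = {name: preprocess_pixel(s, cfg) for name, s in spectra.items()}
    return ReferenceLibrary(entries, cfg.grid())
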