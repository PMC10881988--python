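"""Pseudo-inverse (PINV) linear unmixing baseline.

Each pixel spectrum s is modelled as a linear combination of the
library's unit-norm reference spectra R (columns): the Moore-Penrose
least-squares solution c = R^+ s minimizes ||R c - s||_2.  Unlike PRM
scores, the coefficients are unbounded and may be negative, which is the
qualitative contrast this baseline exists to demonstrate.  Solving is
per pixel, so a pixel's coefficients do not depend on the image it is
embedded in.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigError, DimensionError, GridMismatchError
from .preprocess import PreprocessConfig, preprocess_matrix
from .spectrum import HyperspectralStack, ReferenceLibrary, Spectrum, Stage

__all__ = ["PinvResult", "PinvUnmixer", "pinv_unmix", "pinv_unmix_stack"]


@dataclass
class PinvResult:
    """Least-squares coefficients for one pixel (one per library entry)."""

    coefficients: np.ndarray
    residual_norm: float
    rank: int
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.residual_norm < 0:
            raise DimensionError("residual norm must be >= 0")


class PinvUnmixer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer for per-pixel pseudo-inverse unmixing.

    ``fit`` stores the reference matrix (library entries as columns);
    ``transform`` maps (n_samples, n_grid) unit-norm spectra to
    (n_samples, n_refs) coefficient rows.  Rank deficiency yields the
    minimum-norm solution with a warning.
    """

    def __init__(self, rcond: float = 1e-12):
        self.rcond = rcond

    def fit(self, X: ReferenceLibrary, y=None):
        if not isinstance(X, ReferenceLibrary):
            raise ConfigError("PinvUnmixer.fit expects a ReferenceLibrary")
        self.library_ = X
        self.reference_names_ = X.names
        r = X.matrix().T  # (n_grid, n_refs)
        self.components_ = r
        self.rank_ = int(np.linalg.matrix_rank(r))
        if self.rank_ < r.shape[1]:
            warnings.warn(
                "reference matrix is rank deficient; minimum-norm solutions returned",
                RuntimeWarning,
                stacklevel=2,
            )
        self.pinv_ = np.linalg.pinv(r, rcond=self.rcond)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "pinv_"):
            raise ConfigError("PinvUnmixer is not fitted; call fit() first")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.components_.shape[0]:
            raise GridMismatchError("pixel spectra are not on the library grid")
        return X @ self.pinv_.T

    def residual_norms(self, X: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
        recon = coeffs @ self.components_.T
        return np.linalg.norm(np.atleast_2d(X) - recon, axis=1)


def pinv_unmix(pixel: Spectrum, lib: ReferenceLibrary) -> PinvResult:
    """Unmix one spectrum (on the library grid) against the library."""
    if pixel.axis.shape != lib.grid.shape or not np.array_equal(pixel.axis, lib.grid):
        raise GridMismatchError("pixel must be on the library grid")
    um = PinvUnmixer().fit(lib)
    c = um.transform(pixel.intensity)[0]
    resid = float(um.residual_norms(pixel.intensity, c[None, :])[0])
    return PinvResult(c, resid, um.rank_, rank_deficient=um.rank_ < len(lib))


def pinv_unmix_stack(
    stack: HyperspectralStack,
    lib: ReferenceLibrary,
    pcfg: PreprocessConfig | None = None,
    timing: dict | None = None,
) -> dict[str, np.ndarray]:
    """Per-pixel coefficient maps for every library entry.

    Pixels go through the same preprocessing chain as PRM scoring so the
    two methods see identical unit-norm inputs.  Pass a dict as ``timing``
    to receive wall-clock seconds under the key ``"seconds"``.
    """
    pcfg = pcfg or PreprocessConfig()
    rows, cols, _ = stack.shape
    t0 = time.perf_counter()
    p, degenerate, _ = preprocess_matrix(stack.flat(), stack.axis, pcfg)
    um = PinvUnmixer().fit(lib)
    coeffs = um.transform(p)
    coeffs[degenerate] = 0.0
    if timing is not None:
        timing["seconds"] = time.perf_counter() - t0
    return {
        name: coeffs[:, j].reshape(rows, cols) for j, name in enumerate(lib.names)
    }
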