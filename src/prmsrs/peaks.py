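"""Four-Gaussian decomposition of CH-stretching-region reference spectra.

Lipid spectra in the 2700-3150 cm^-1 window are dominated by four bands:
symmetric CH2 stretching near 2850 cm^-1, CH2 asymmetric / CH3 Fermi
resonance near 2880 cm^-1, CH3 stretching near 2935 cm^-1 and the
olefinic =C-H stretch near 3065 cm^-1.  Fitting a sum of four Gaussians
with these canonical initial centers yields an interpretable parameter
table (e.g. the CH2/CH3 amplitude ratio tracks acyl-chain saturation)
that separates lipid subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import ConfigError, CoverageError
from .spectrum import ReferenceLibrary, Spectrum

__all__ = ["GaussianFit", "CANONICAL_CENTERS", "fit_four_gaussians", "fit_library"]

# canonical CH-stretch band centers (cm^-1): CH2 sym, CH2 asym/Fermi, CH3, olefinic
CANONICAL_CENTERS = (2850.0, 2880.0, 2935.0, 3065.0)

_MIN_WIDTH = 2.0
_MAX_WIDTH = 100.0


@dataclass
class GaussianFit:
    """Four (amplitude, center, width) triples sorted by center, plus RSS."""

    components: np.ndarray  # (4, 3): amplitude, center cm^-1, sigma cm^-1
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != (4, 3):
            raise ConfigError("expected 4 components of (amplitude, center, width)")

    @property
    def amplitudes(self) -> np.ndarray:
        return self.components[:, 0]

    @property
    def centers(self) -> np.ndarray:
        return self.components[:, 1]

    @property
    def widths(self) -> np.ndarray:
        return self.components[:, 2]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return _sum_of_gaussians(np.asarray(x, float), *self.components.ravel())


def _sum_of_gaussians(x, *params):
    y = np.zeros_like(x, dtype=float)
    for a, c, w in np.reshape(params, (-1, 3)):
        y = y + a * np.exp(-((x - c) ** 2) / (2.0 * w**2))
    return y


def fit_four_gaussians(
    s: Spectrum,
    window: tuple[float, float] = (2700.0, 3150.0),
    init_centers=None,
    init_components: np.ndarray | None = None,
) -> GaussianFit:
    """Nonlinear least-squares fit of four Gaussians inside ``window``.

    Initial centers default to the canonical CH bands; amplitudes start at
    the spectrum value nearest each center, widths at 15 cm^-1.  A full
    (4, 3) ``init_components`` array (amplitude, center, width) overrides
    both, letting a previous fit seed a refit.  Bounds: amplitude >= 0,
    center inside the window, width in [2, 100] cm^-1.  Non-convergence
    returns ``converged=False`` with the best parameters.
    """
    lo, hi = window
    sel = (s.axis >= lo) & (s.axis <= hi)
    if sel.sum() < 12:
        raise CoverageError("spectrum does not cover the fit window")
    x = s.axis[sel]
    y = s.intensity[sel]

    centers = np.asarray(init_centers if init_centers is not None else CANONICAL_CENTERS, float)
    if centers.size != 4:
        raise ConfigError("exactly 4 initial centers required")
    centers = np.clip(centers, lo, hi)

    span = float(y.max() - y.min())
    if span <= 0 or y.max() <= 0:
        # flat spectrum: nothing to fit
        comps = np.column_stack([np.zeros(4), centers, np.full(4, 15.0)])
        return GaussianFit(comps, rss=float(np.sum((y - y.mean()) ** 2)), converged=True)

    if init_components is not None:
        init_components = np.asarray(init_components, dtype=float)
        if init_components.shape != (4, 3):
            raise ConfigError("init_components must be (4, 3)")
        p0 = np.clip(
            init_components,
            [0.0, lo, _MIN_WIDTH],
            [np.inf, hi, _MAX_WIDTH],
        ).ravel()
    else:
        amp0 = np.array([max(float(np.interp(c, x, y)), 1e-3 * span) for c in centers])
        p0 = np.column_stack([amp0, centers, np.full(4, 15.0)]).ravel()
    lower = np.tile([0.0, lo, _MIN_WIDTH], 4)
    upper = np.tile([np.inf, hi, _MAX_WIDTH], 4)
    try:
        popt, _ = curve_fit(
            _sum_of_gaussians, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    comps = popt.reshape(4, 3)
    comps = comps[np.argsort(comps[:, 1])]
    rss = float(np.sum((y - _sum_of_gaussians(x, *comps.ravel())) ** 2))
    return GaussianFit(comps, rss=rss, converged=converged)


def fit_library(
    lib: ReferenceLibrary, window: tuple[float, float] = (2700.0, 3150.0)
) -> pd.DataFrame:
    """Fit every library entry; one row per reference.

    Columns: name, a1..a4, c1..c4, w1..w4 (components sorted by center),
    rss, converged.  Per-entry failures surface as ``converged=False``
    rows rather than aborting the table.
    """
    rows = []
    for name, spec in lib.entries.items():
        fit = fit_four_gaussians(spec, window)
        row: dict = {"name": name}
        for i in range(4):
            row[f"a{i + 1}"] = fit.amplitudes[i]
            row[f"c{i + 1}"] = fit.centers[i]
            row[f"w{i + 1}"] = fit.widths[i]
        row["rss"] = fit.rss
        row["converged"] = fit.converged
        rows.append(row)
    cols = ["name"]
    for i in range(1, 5):
        cols += [f"a{i}", f"c{i}", f"w{i}"]
    cols += ["rss", "converged"]
    return pd.DataFrame(rows, columns=cols)
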