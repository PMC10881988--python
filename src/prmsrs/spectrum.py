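"""Core domain containers: spectra, reference libraries, stacks, score maps.

A :class:`Spectrum` is a single trace (wavenumber axis in cm^-1 plus
intensities in arbitrary units) tagged with its preprocessing ``stage``.
The stages mirror the normalization chain used throughout the package:
raw -> baseline_corrected -> minmax (scaled to [0, 1]) -> unit_norm
(divided by the Euclidean norm).  Pixel spectra and reference spectra go
through the same chain so their inner products are comparable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

from .exceptions import AxisError, DegenerateSpectrumError, DimensionError

__all__ = [
    "Stage",
    "Spectrum",
    "ReferenceLibrary",
    "HyperspectralStack",
    "ScoreImage",
]


class Stage(str, enum.Enum):
    """Preprocessing stage of a spectrum."""

    RAW = "raw"
    BASELINE_CORRECTED = "baseline_corrected"
    MINMAX = "minmax"
    UNIT_NORM = "unit_norm"


@dataclass(frozen=True)
class Spectrum:
    """One spectral trace.

    Parameters
    ----------
    axis:
        Wavenumbers in cm^-1, strictly increasing, length >= 2.
    intensity:
        Intensities (arbitrary units), same length as ``axis``.
    stage:
        Preprocessing stage; normalization invariants are enforced for
        ``minmax`` and ``unit_norm``.
    label:
        Free-text name (e.g. "cholesterol").
    coverage:
        Optional boolean mask, True where the value was interpolated from
        measured data and False where the grid point lies outside the
        source spectrum and was zero-filled.
    """

    axis: np.ndarray
    intensity: np.ndarray
    stage: Stage = Stage.RAW
    label: str = ""
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if axis.ndim != 1 or intensity.ndim != 1:
            raise DimensionError("axis and intensity must be 1-D")
        if axis.size != intensity.size:
            raise DimensionError(
                f"axis length {axis.size} != intensity length {intensity.size}"
            )
        if axis.size < 2:
            raise DimensionError("a spectrum needs at least 2 points")
        diffs = np.diff(axis)
        if np.any(diffs <= 0):
            raise AxisError("wavenumber axis must be strictly increasing")
        stage = Stage(self.stage)
        object.__setattr__(self, "stage", stage)
        if stage is Stage.MINMAX:
            if not (
                abs(float(intensity.min())) < 1e-9
                and abs(float(intensity.max()) - 1.0) < 1e-9
            ):
                raise DegenerateSpectrumError(
                    "minmax stage requires min 0 and max 1"
                )
        if stage is Stage.UNIT_NORM:
            if abs(float(np.linalg.norm(intensity)) - 1.0) >= 1e-9:
                raise DegenerateSpectrumError(
                    "unit_norm stage requires Euclidean norm 1"
                )
        if self.coverage is not None:
            cov = np.asarray(self.coverage, dtype=bool)
            if cov.shape != axis.shape:
                raise DimensionError("coverage mask must match axis length")
            object.__setattr__(self, "coverage", cov)

    def __len__(self) -> int:
        return int(self.axis.size)

    def with_intensity(
        self, intensity: np.ndarray, stage: Stage, coverage: np.ndarray | None = None
    ) -> "Spectrum":
        """Return a copy with new intensities (and stage)."""
        return replace(
            self,
            intensity=np.asarray(intensity, dtype=float),
            stage=stage,
            coverage=self.coverage if coverage is None else coverage,
        )


@dataclass(frozen=True)
class ReferenceLibrary:
    """Ordered collection of preprocessed (unit-norm) reference spectra.

    All entries share one interpolation grid; names are unique.  Build one
    with :func:`prmsrs.preprocess.build_library`.
    """

    entries: Mapping[str, Spectrum]
    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", grid)
        entries = dict(self.entries)
        if len(entries) == 0:
            raise DimensionError("reference library must not be empty")
        for name, spec in entries.items():
            if spec.stage is not Stage.UNIT_NORM:
                raise DegenerateSpectrumError(
                    f"library entry {name!r} is not unit-normalized"
                )
            if spec.axis.shape != grid.shape or not np.array_equal(spec.axis, grid):
                raise AxisError(f"library entry {name!r} is not on the shared grid")
        object.__setattr__(self, "entries", entries)

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __getitem__(self, name: str) -> Spectrum:
        return self.entries[name]

    def matrix(self) -> np.ndarray:
        """Stack entries into an (n_refs, n_grid) array in library order."""
        return np.stack([s.intensity for s in self.entries.values()])


@dataclass
class HyperspectralStack:
    """rows x cols x bands intensity volume with one shared wavenumber axis."""

    data: np.ndarray
    axis: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError("stack data must be rows x cols x bands")
        rows, cols, bands = self.data.shape
        if rows < 1 or cols < 1:
            raise DimensionError("stack must have at least one pixel")
        if self.axis.ndim != 1 or self.axis.size != bands:
            raise DimensionError(
                f"axis length {self.axis.size} != band count {bands}"
            )
        if np.any(np.diff(self.axis) <= 0):
            raise AxisError("stack wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise DimensionError("stack intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def pixel(self, row: int, col: int, label: str = "") -> Spectrum:
        """Extract one pixel spectrum (raw stage)."""
        return Spectrum(self.axis, self.data[row, col], Stage.RAW, label)

    def flat(self) -> np.ndarray:
        """View the stack as (n_pixels, bands)."""
        rows, cols, bands = self.data.shape
        return self.data.reshape(rows * cols, bands)


@dataclass
class ScoreImage:
    """Per-pixel PRM similarity scores (and best-shift map) for one reference.

    ``mask`` is True at degenerate pixels (constant/zero spectra); those
    pixels carry score 0 and shift 0 so downstream arithmetic stays finite.
    """

    scores: np.ndarray
    best_shift: np.ndarray
    reference_name: str
    config_snapshot: dict = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.best_shift = np.asarray(self.best_shift, dtype=float)
        if self.scores.ndim != 2:
            raise DimensionError("score image must be 2-D")
        if self.best_shift.shape != self.scores.shape:
            raise DimensionError("best_shift map must match score shape")
        if self.mask is None:
            self.mask = np.zeros(self.scores.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.scores.shape:
                raise DimensionError("mask must match score shape")
        valid = self.scores[~self.mask]
        if valid.size and (valid.min() < -1e-9 or valid.max() > 1 + 1e-9):
            raise DimensionError("scores must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape  # type: ignore[return-value]
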