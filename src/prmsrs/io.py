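"""File I/O for reference spectra, hyperspectral stacks and score maps.

Reference spectra are two-column CSV/TSV tables (wavenumber_cm-1,
intensity).  Stacks are band-sequential multi-page TIFFs (one grayscale
page per band) with a sidecar axis file: a one-column CSV or a JSON list
of band wavenumbers.  Score maps are single-page TIFFs, either raw
float32 or uint8 with the fixed mapping [0, 1] -> [0, 255] so images stay
comparable across references.  The band axis is stored ascending in
memory; a descending sidecar is accepted and the pages are reversed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import AxisError, DimensionError, SpectrumParseError
from .spectrum import HyperspectralStack, ScoreImage, Spectrum, Stage

__all__ = [
    "read_reference",
    "write_reference",
    "read_axis",
    "write_axis",
    "read_stack",
    "write_stack",
    "read_score_image",
    "write_score_image",
    "read_mask",
    "write_mask",
]

_DELIMS = {"csv_2col": ",", "tsv_2col": "\t"}


def read_reference(path, dialect: str = "csv_2col", label: str | None = None) -> Spectrum:
    """Read a two-column (wavenumber, intensity) table as a raw Spectrum.

    Rows are sorted to ascending wavenumber; duplicate wavenumbers are
    rejected.  A single header line of non-numeric text is tolerated.
    """
    path = Path(path)
    if dialect not in _DELIMS:
        raise SpectrumParseError(f"unknown dialect {dialect!r}")
    sep = _DELIMS[dialect]
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path.name}:{lineno}: expected 2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise SpectrumParseError(
                    f"{path.name}:{lineno}: non-numeric value in {parts[:2]!r}"
                ) from None
    if len(rows) < 2:
        raise DimensionError(f"{path.name}: a spectrum needs at least 2 points")
    arr = np.asarray(sorted(rows), dtype=float)
    if np.any(np.diff(arr[:, 0]) == 0):
        dup = arr[np.diff(arr[:, 0], prepend=np.nan) == 0, 0][0]
        raise AxisError(f"{path.name}: duplicated wavenumber {dup}")
    return Spectrum(arr[:, 0], arr[:, 1], Stage.RAW, label or path.stem)


def write_reference(s: Spectrum, path, dialect: str = "csv_2col") -> None:
    """Write a spectrum as a two-column table with a header line."""
    sep = _DELIMS[dialect]
    df = pd.DataFrame({"wavenumber_cm-1": s.axis, "intensity": s.intensity})
    df.to_csv(path, sep=sep, index=False)


def read_axis(path) -> np.ndarray:
    """Read a band-axis sidecar: one-column CSV or a JSON list."""
    path = Path(path)
    text = path.read_text().strip()
    if path.suffix.lower() == ".json" or text.startswith("["):
        vals = np.asarray(json.loads(text), dtype=float)
    else:
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if lines and not _is_number(lines[0].split(",")[0]):
            lines = lines[1:]  # header
        try:
            vals = np.asarray([float(ln.split(",")[0]) for ln in lines])
        except ValueError as exc:
            raise SpectrumParseError(f"{path.name}: non-numeric axis entry") from exc
    if vals.ndim != 1 or vals.size < 1:
        raise DimensionError(f"{path.name}: axis sidecar must be a flat list")
    return vals


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_axis(axis: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(list(map(float, axis))))
    else:
        pd.DataFrame({"wavenumber_cm-1": axis}).to_csv(path, index=False)


def read_stack(image_path, axis_path) -> HyperspectralStack:
    """Read a multi-page TIFF stack plus its wavenumber sidecar.

    Pages are reordered to ascending wavenumber if the sidecar is
    descending, so in-memory stacks are axis-order invariant.
    """
    pages = tifffile.imread(image_path)
    pages = np.asarray(pages, dtype=float)
    if pages.ndim == 2:
        pages = pages[None, :, :]
    if pages.ndim != 3:
        raise DimensionError("stack TIFF must contain 2-D grayscale pages")
    axis = read_axis(axis_path)
    if pages.shape[0] != axis.size:
        raise DimensionError(
            f"TIFF has {pages.shape[0]} pages but axis lists {axis.size} bands"
        )
    order = np.argsort(axis, kind="stable")
    axis = axis[order]
    pages = pages[order]
    if np.any(np.diff(axis) <= 0):
        raise AxisError("band axis is not strictly monotone after sorting")
    # pages are band-major on disk; in memory we use rows x cols x bands
    return HyperspectralStack(np.moveaxis(pages, 0, -1), axis)


def write_stack(stack: HyperspectralStack, image_path, axis_path) -> None:
    """Write a stack as band-sequential float32 TIFF pages plus sidecar."""
    pages = np.moveaxis(stack.data, -1, 0).astype(np.float32)
    tifffile.imwrite(image_path, pages, photometric="minisblack")
    write_axis(stack.axis, axis_path)


def write_score_image(img: ScoreImage, path, mode: str = "float32") -> None:
    """Write a score map as a single-page TIFF.

    ``float32`` stores raw scores; ``uint8_fixed`` maps [0, 1] to
    [0, 255] via round(score * 255) (numpy round-half-even at exact .5
    ties).  Masked pixels are written as 0; the mask and reference name go
    into the TIFF description tag.
    """
    scores = np.where(img.mask, 0.0, img.scores)
    meta = {
        "reference_name": img.reference_name,
        "config": img.config_snapshot,
        "mask_true_count": int(img.mask.sum()),
    }
    if mode == "float32":
        tifffile.imwrite(path, scores.astype(np.float32), description=json.dumps(meta))
    elif mode == "uint8_fixed":
        scaled = np.round(np.clip(scores, 0.0, 1.0) * 255.0).astype(np.uint8)
        tifffile.imwrite(path, scaled, description=json.dumps(meta))
    else:
        raise SpectrumParseError(f"unknown score-image mode {mode!r}")


def read_score_image(path) -> np.ndarray:
    """Read a score map back as a float array (uint8 maps are rescaled)."""
    arr = tifffile.imread(path)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return np.asarray(arr, dtype=float)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a 0/255 uint8 TIFF."""
    tifffile.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return np.asarray(arr) > 0
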