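"""Domain types and preprocessing for silent-region Raman spectra.

The analysis operates on the C-D stretch "silent region" of the Raman
spectrum (roughly 1800-2600 cm^-1), where endogenous cellular bands are
absent and the signal of deuterated fatty acids dominates.  This module
holds the shared containers (spectra, hyperspectral cubes), their text/TIFF
I/O, window cropping, axis resampling and the detrend-and-normalize
preprocessing that every analysis window passes through before fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "SpectrumParseError",
    "CubeFormatError",
    "DegenerateSpectrumError",
    "WavenumberAxis",
    "Spectrum",
    "HyperspectralCube",
    "design_vectors",
    "read_spectrum",
    "write_spectrum",
    "read_cube",
    "write_cube",
    "crop_window",
    "resample_to_axis",
    "preprocess_normalize",
]


class SpectrumParseError(ValueError):
    """Raised when a two-column spectrum file cannot be parsed."""


class CubeFormatError(ValueError):
    """Raised when a hyperspectral cube container is inconsistent."""


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum is exactly linear (zero detrended residual)."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid (cm^-1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("axis needs at least two wavenumbers")
        if not np.all(np.isfinite(v)):
            raise ValueError("axis values must be finite")
        if not np.all(np.diff(v) > 0):
            raise ValueError("axis must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )


@dataclass
class Spectrum:
    """One measurement: intensity (arbitrary counts) on a wavenumber axis."""

    axis: WavenumberAxis
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (len(self.axis),):
            raise ValueError(
                f"intensity length {y.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity must be finite")
        self.intensity = y


@dataclass
class HyperspectralCube:
    """(height, width, channels) intensity stack sharing one wavenumber axis.

    ``pixel_size_um`` is the spatial sampling of the raster scan; the
    instrument configuration emulated here steps 0.3 um per pixel.
    """

    data: np.ndarray
    axis: WavenumberAxis
    pixel_size_um: float = 0.3

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError("cube data must be (height, width, channels)")
        if d.shape[2] != len(self.axis):
            raise ValueError(
                f"channel count {d.shape[2]} != axis length {len(self.axis)}"
            )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        self.data = d

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def pixel_spectrum(self, row: int, col: int, label: str = "") -> Spectrum:
        if not (0 <= row < self.height and 0 <= col < self.width):
            raise IndexError(f"pixel ({row}, {col}) outside cube")
        return Spectrum(self.axis, self.data[row, col].astype(float), label)


def design_vectors(length: int) -> tuple[np.ndarray, np.ndarray]:
    """Slope/intercept nuisance regressors: the integer ramp 1..L and ones."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return np.arange(1, length + 1, dtype=float), np.ones(length)


def _parse_row(token_line: str, delimiter: str | None) -> tuple[float, float] | None:
    parts = token_line.split(delimiter) if delimiter else token_line.replace(",", " ").split()
    parts = [p for p in parts if p != ""]
    if len(parts) < 2:
        return None
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        return None


def read_spectrum(path: str | Path, delimiter: str | None = None) -> Spectrum:
    """Read a two-column (wavenumber, intensity) delimited text file.

    One leading header line is tolerated; any other non-numeric row raises
    :class:`SpectrumParseError` naming the offending line.  The returned
    spectrum has its axis sorted ascending.
    """
    path = Path(path)
    wn: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            row = _parse_row(line, delimiter)
            if row is None:
                if lineno == 1:
                    continue  # header
                raise SpectrumParseError(
                    f"{path}: cannot parse line {lineno}: {line!r}"
                )
            if not all(np.isfinite(row)):
                raise SpectrumParseError(
                    f"{path}: non-finite value at line {lineno}: {line!r}"
                )
            wn.append(row[0])
            inten.append(row[1])
    if len(wn) < 2:
        raise SpectrumParseError(f"{path}: fewer than two data rows")
    wn_arr = np.asarray(wn)
    if np.unique(wn_arr).size != wn_arr.size:
        raise SpectrumParseError(f"{path}: duplicate wavenumbers")
    order = np.argsort(wn_arr)
    return Spectrum(WavenumberAxis(wn_arr[order]), np.asarray(inten)[order], path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path, delimiter: str = ",") -> None:
    with open(path, "w") as fh:
        for w, y in zip(spectrum.axis.values, spectrum.intensity):
            fh.write(f"{float(w)!r}{delimiter}{float(y)!r}\n")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_cube(cube: HyperspectralCube, path: str | Path) -> None:
    """Write a cube as a multi-page TIFF (one page per channel) + JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(cube.data, 2, 0)  # (channels, H, W)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "wavenumbers": [float(v) for v in cube.axis.values],
        "pixel_size_um": float(cube.pixel_size_um),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh)


def read_cube(path: str | Path) -> HyperspectralCube:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise CubeFormatError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    wavenumbers = np.asarray(meta["wavenumbers"], dtype=float)
    if wavenumbers.size != pages.shape[0]:
        raise CubeFormatError(
            f"sidecar lists {wavenumbers.size} wavenumbers for {pages.shape[0]} pages"
        )
    data = np.moveaxis(pages, 0, 2)
    return HyperspectralCube(
        data, WavenumberAxis(wavenumbers), float(meta.get("pixel_size_um", 0.3))
    )


def crop_window(obj: Spectrum | HyperspectralCube, lo: float, hi: float):
    """Keep channels with lo <= wavenumber <= hi (inclusive bounds)."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    mask = (obj.axis.values >= lo) & (obj.axis.values <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] outside axis")
    axis = WavenumberAxis(obj.axis.values[mask])
    if isinstance(obj, Spectrum):
        return Spectrum(axis, obj.intensity[mask], obj.label)
    return HyperspectralCube(obj.data[:, :, mask], axis, obj.pixel_size_um)


def resample_to_axis(spectrum: Spectrum, target: WavenumberAxis) -> Spectrum:
    """Linear interpolation of intensity onto ``target`` (no extrapolation)."""
    src = spectrum.axis.values
    if target.values[0] < src[0] or target.values[-1] > src[-1]:
        raise ValueError("target axis extends past source span (extrapolation)")
    return Spectrum(
        target, np.interp(target.values, src, spectrum.intensity), spectrum.label
    )


def preprocess_normalize(intensity: np.ndarray) -> np.ndarray:
    """Detrend by the OLS straight line over the channel index, unit-L2 scale.

    This makes the reference family scale-free: affine trends a*v + c*ramp + d
    with a > 0 all map to the same normalized vector, and the free signal
    amplitude in the unmixing model absorbs any remaining global scale.
    """
    v = np.asarray(intensity, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1-D vector of length >= 3")
    idx = np.arange(v.size, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(idx, v, 1)
    resid = v - np.polynomial.polynomial.polyval(idx, coeffs)
    norm = float(np.linalg.norm(resid))
    if norm <= v.size * np.finfo(float).eps * max(1.0, float(np.abs(v).max())):
        raise DegenerateSpectrumError("degenerate spectrum: exactly linear in index")
    return resid / norm
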