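"""Hyperspectral cube data model, file I/O, calibration and ROI extraction.

The central object is :class:`HSICube`, an ``(M, N, C)`` reflectance array with
a strictly increasing wavelength axis (:class:`WavelengthGrid`).  Raw camera
frames are converted to reflectance with a dark/white two-point calibration
against a near-perfect diffuse reference panel:

    Re = (D_raw - D_dark) / (D_white - D_dark)

Downstream stages (band trimming, masking, ROI mean spectra) all operate on
calibrated cubes.  Two on-disk dialects are supported: a classic ENVI text
header plus raw binary payload, and a self-describing ``.npz`` archive that
round-trips bit-exactly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu

from .errors import (
    DegenerateReferenceError,
    DegenerateThresholdError,
    EmptySelectionError,
    FormatError,
    IntegrityError,
    ParameterError,
    ShapeMismatchError,
)

__all__ = [
    "WavelengthGrid",
    "HSICube",
    "CalibrationFrames",
    "PixelMask",
    "Spectrum",
    "read_cube",
    "write_cube",
    "calibrate_reflectance",
    "drop_noisy_bands",
    "threshold_mask",
    "extract_roi_mean_spectrum",
    "spectra_to_csv",
    "spectra_from_csv",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nanometres."""

    centers_nm: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers_nm, dtype=float)
        object.__setattr__(self, "centers_nm", centers)
        if centers.ndim != 1 or centers.size == 0:
            raise ParameterError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(centers)) or np.any(centers <= 0):
            raise ParameterError("wavelengths must be finite and positive")
        if np.any(np.diff(centers) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")

    @property
    def count(self) -> int:
        return int(self.centers_nm.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.centers_nm[0]), float(self.centers_nm[-1])

    def nearest_band(self, target_nm: float) -> int:
        """Index of the band center minimizing |center - target|; ties -> lower wavelength."""
        dist = np.abs(self.centers_nm - float(target_nm))
        # np.argmin returns the first minimum, i.e. the lower wavelength on a tie
        return int(np.argmin(dist))


@dataclass
class HSICube:
    """An M x N x C reflectance cube with its wavelength axis."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ShapeMismatchError(f"cube values must be 3-D, got {v.ndim}-D")
        if v.shape[2] != self.grid.count:
            raise ShapeMismatchError(
                f"cube has {v.shape[2]} bands but grid declares {self.grid.count}"
            )
        if not np.all(np.isfinite(v)):
            raise ParameterError("cube contains non-finite values")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class CalibrationFrames:
    """Raw digital numbers plus dark and white reference frames.

    ``dark`` and ``white`` may be per-band vectors ``(C,)`` or full frames
    ``(M, N, C)``; both broadcast against ``raw``.
    """

    raw: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 3 or self.raw.shape[2] != self.grid.count:
            raise ShapeMismatchError("raw frame must be (M, N, C) matching the grid")
        self.dark = self._conform(np.asarray(self.dark, dtype=float), "dark")
        self.white = self._conform(np.asarray(self.white, dtype=float), "white")

    def _conform(self, arr: np.ndarray, name: str) -> np.ndarray:
        if arr.ndim == 1:
            if arr.size != self.grid.count:
                raise ShapeMismatchError(f"per-band {name} frame must have C entries")
            return arr.reshape(1, 1, -1)
        if arr.shape != self.raw.shape:
            raise ShapeMismatchError(f"{name} frame must be per-band (C,) or full (M, N, C)")
        return arr


@dataclass
class PixelMask:
    """Boolean M x N mask sharing the spatial shape of its source cube."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.flags)
        if f.ndim != 2 or f.dtype != bool:
            raise ShapeMismatchError("mask must be a 2-D boolean array")
        self.flags = f

    @property
    def count(self) -> int:
        return int(self.flags.sum())


@dataclass
class Spectrum:
    """A single length-C reflectance vector tagged with sample/species ids."""

    reflectance: np.ndarray
    grid: WavelengthGrid
    sample_id: str = ""
    species_id: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        if r.ndim != 1 or r.size != self.grid.count:
            raise ShapeMismatchError("spectrum length must equal grid count")
        if not np.all(np.isfinite(r)):
            raise ParameterError("spectrum contains non-finite values")
        self.reflectance = r


# ---------------------------------------------------------------------------
# calibration / band ops
# ---------------------------------------------------------------------------

def calibrate_reflectance(
    frames: CalibrationFrames, on_degenerate: str = "error"
) -> HSICube:
    """Two-point reflectance calibration (raw - dark) / (white - dark).

    Parameters
    ----------
    frames
        Raw, dark and white digital-number frames.
    on_degenerate
        ``"error"``: raise if white == dark anywhere; ``"mask"``: set those
        pixels to NaN-free 0 and return the rest.
    """
    denom = frames.white - frames.dark
    bad = denom <= 0
    if np.any(bad):
        if on_degenerate == "error":
            raise DegenerateReferenceError(
                "white reference does not exceed dark level everywhere"
            )
        if on_degenerate != "mask":
            raise ParameterError(f"unknown on_degenerate mode {on_degenerate!r}")
        denom = np.where(bad, 1.0, denom)
    ref = (frames.raw - frames.dark) / denom
    if np.any(bad):
        ref = np.where(np.broadcast_to(bad, ref.shape), 0.0, ref)
    return HSICube(values=ref, grid=frames.grid)


def drop_noisy_bands(
    cube: HSICube, keep_min_nm: float = 397.0, keep_max_nm: float = 982.0
) -> HSICube:
    """Retain only bands whose centers lie in ``[keep_min_nm, keep_max_nm]``.

    The camera's long-wavelength tail (above ~982 nm on the 397-1003 nm
    instrument) is dominated by sensor noise and is trimmed before analysis.
    Both endpoints are inclusive; band order is preserved.
    """
    if not keep_min_nm < keep_max_nm:
        raise ParameterError("keep_min_nm must be below keep_max_nm")
    centers = cube.grid.centers_nm
    keep = (centers >= keep_min_nm) & (centers <= keep_max_nm)
    if not np.any(keep):
        raise EmptySelectionError(
            f"no band centers inside [{keep_min_nm}, {keep_max_nm}] nm"
        )
    return HSICube(values=cube.values[:, :, keep], grid=WavelengthGrid(centers[keep]))


def threshold_mask(
    cube: HSICube,
    band_nm: float | None = None,
    method: str = "otsu",
    t: float | None = None,
) -> PixelMask:
    """Binary vegetation mask from a single-band grayscale image.

    The grayscale band defaults to the band nearest 800 nm, where the
    vegetation NIR plateau gives maximal contrast against soil background.
    ``method="otsu"`` picks the threshold automatically; ``method="fixed"``
    uses ``t`` and flags pixels with value >= t.
    """
    if band_nm is None:
        band_nm = 800.0
    lo, hi = cube.grid.span
    if not lo <= band_nm <= hi:
        raise ParameterError(f"band {band_nm} nm outside grid span [{lo}, {hi}]")
    gray = cube.values[:, :, cube.grid.nearest_band(band_nm)]
    if method == "fixed":
        if t is None:
            raise ParameterError("fixed thresholding requires t")
        return PixelMask(flags=gray >= t)
    if method != "otsu":
        raise ParameterError(f"unknown threshold method {method!r}")
    if np.ptp(gray) == 0:
        raise DegenerateThresholdError("constant grayscale image; otsu undefined")
    thr = threshold_otsu(gray)
    return PixelMask(flags=gray > thr)


def extract_roi_mean_spectrum(
    cube: HSICube, roi: PixelMask, sample_id: str = "", species_id: int = 0
) -> Spectrum:
    """Per-band arithmetic mean over the ROI's flagged pixels."""
    if roi.flags.shape != cube.values.shape[:2]:
        raise ShapeMismatchError("ROI shape does not match cube spatial shape")
    if roi.count == 0:
        raise EmptySelectionError("ROI contains no pixels")
    mean = cube.values[roi.flags].mean(axis=0)
    return Spectrum(reflectance=mean, grid=cube.grid, sample_id=sample_id, species_id=species_id)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 12: np.uint16}
_ENVI_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.uint16): 12}


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("missing ENVI magic line")
    fields: dict[str, str] = {}
    # collapse brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def _read_envi(path: Path) -> HSICube:
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        raise FormatError(f"ENVI header not found: {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing field {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header lacks a wavelength list")
    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(w) for w in wl_text.replace(",", " ").split()])
    if wavelengths.size != bands:
        raise IntegrityError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    payload_path = hdr_path.with_suffix("") if hdr_path.suffix == ".hdr" else hdr_path
    if not payload_path.exists():
        raise FormatError(f"ENVI payload not found: {payload_path}")
    data = np.fromfile(payload_path, dtype=_ENVI_DTYPES[dtype_code])
    if data.size != samples * lines * bands:
        raise IntegrityError(
            f"payload holds {data.size} values, header implies {samples * lines * bands}"
        )
    if interleave == "bsq":
        cube = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = data.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    return HSICube(values=cube.astype(float), grid=WavelengthGrid(wavelengths))


def _write_envi(cube: HSICube, path: Path, interleave: str = "bsq") -> None:
    payload_path = Path(path)
    hdr_path = payload_path.with_suffix(payload_path.suffix + ".hdr")
    m, n, c = cube.shape
    data = cube.values.astype(np.float32)
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = data
    else:
        raise ParameterError(f"unsupported interleave {interleave!r}")
    flat.tofile(payload_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.centers_nm)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {n}\n"
        f"lines = {m}\n"
        f"bands = {c}\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )


def read_cube(path: str | Path, dialect: str = "archive") -> HSICube:
    """Read a cube from disk.

    ``dialect="envi"`` expects ``<path>`` (payload) + ``<path>.hdr``;
    ``dialect="archive"`` expects a self-describing ``.npz``.
    """
    path = Path(path)
    if dialect == "envi":
        return _read_envi(path)
    if dialect != "archive":
        raise ParameterError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FormatError(f"archive not found: {path}")
    with np.load(path) as z:
        if "values" not in z or "wavelengths_nm" not in z:
            raise FormatError("archive lacks values/wavelengths_nm entries")
        values = z["values"]
        wl = z["wavelengths_nm"]
    if values.ndim != 3 or values.shape[2] != wl.size:
        raise IntegrityError("archive band count disagrees with wavelength list")
    return HSICube(values=values, grid=WavelengthGrid(wl))


def write_cube(
    cube: HSICube,
    path: str | Path,
    dialect: str = "archive",
    labels: np.ndarray | None = None,
    interleave: str = "bsq",
) -> None:
    """Write a cube; the archive dialect round-trips bit-exactly."""
    path = Path(path)
    if dialect == "envi":
        _write_envi(cube, path, interleave=interleave)
        return
    if dialect != "archive":
        raise ParameterError(f"unknown dialect {dialect!r}")
    payload = {"values": cube.values, "wavelengths_nm": cube.grid.centers_nm}
    if labels is not None:
        payload["labels"] = np.asarray(labels)
    np.savez(path, **payload)


def read_labels(path: str | Path) -> np.ndarray | None:
    """Label map stored alongside a cube in an archive, if any."""
    with np.load(Path(path)) as z:
        return z["labels"] if "labels" in z else None


# ---------------------------------------------------------------------------
# spectra CSV
# ---------------------------------------------------------------------------

def spectra_to_csv(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as CSV: sample_id, species_id, one column per wavelength."""
    if not spectra:
        raise EmptySelectionError("no spectra to write")
    grid = spectra[0].grid
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "species_id"] + [f"{w:.6f}" for w in grid.centers_nm]
        )
        for s in spectra:
            if s.grid.count != grid.count:
                raise ShapeMismatchError("spectra share one wavelength grid per file")
            writer.writerow(
                [s.sample_id, s.species_id] + [format(float(v), ".17g") for v in s.reflectance]
            )


def spectra_from_csv(path: str | Path) -> list[Spectrum]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["sample_id", "species_id"]:
            raise FormatError("spectra CSV must start with sample_id,species_id columns")
        grid = WavelengthGrid(np.array([float(w) for w in header[2:]]))
        out = []
        for row in reader:
            out.append(
                Spectrum(
                    reflectance=np.array([float(v) for v in row[2:]]),
                    grid=grid,
                    sample_id=row[0],
                    species_id=int(row[1]),
                )
            )
    return out
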