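"""Hyperspectral cube I/O, radiometric calibration and band windowing.

Cubes live in memory as ``(row, column, band)`` float arrays with an attached
wavelength grid in nanometres.  On disk the ENVI convention is used: a raw
binary raster next to an ASCII ``.hdr`` describing dimensions, interleave,
data type and per-band wavelengths.  All three interleaves (BSQ/BIL/BIP) are
readable; BSQ is written.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import (
    ConsistencyError,
    DegenerateReferenceError,
    EmptySelectionError,
    FormatError,
)

__all__ = [
    "WavelengthGrid",
    "HyperspectralCube",
    "CalibrationFrames",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_reflectance",
    "crop_band_window",
    "export_tiff",
]

# ENVI numeric codes for the dtypes this package reads and writes.
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-centre wavelengths in nanometres."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size == 0:
            raise ConsistencyError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(centers)) or np.any(centers <= 0):
            raise ConsistencyError("wavelengths must be finite and positive")
        if np.any(np.diff(centers) <= 0):
            raise ConsistencyError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.centers.size)


@dataclass
class HyperspectralCube:
    """A ``(row, column, band)`` raster with wavelength metadata.

    ``calibrated`` distinguishes raw sensor counts from flat-field-corrected
    transmittance/reflectance, which is constrained to ``[0, 1]``.
    """

    values: np.ndarray
    wavelengths: WavelengthGrid
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ConsistencyError(
                f"cube must have 3 axes (row, column, band), got {self.values.ndim}"
            )
        if self.values.shape[2] != len(self.wavelengths):
            raise ConsistencyError(
                f"band axis has {self.values.shape[2]} entries but the wavelength "
                f"grid has {len(self.wavelengths)}"
            )
        if self.calibrated:
            vmin, vmax = float(self.values.min()), float(self.values.max())
            if vmin < 0.0 or vmax > 1.0:
                raise ConsistencyError(
                    f"calibrated cube values must lie in [0, 1], got [{vmin}, {vmax}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class CalibrationFrames:
    """White (blank illuminated glass) and dark (capped sensor) references.

    Either a full frame with the cube's shape or a push-broom per-column line
    average (``(columns, bands)``); any shape broadcastable against the raw
    cube is accepted.
    """

    white: np.ndarray
    dark: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        if self.dark is None:
            self.dark = np.zeros_like(self.white)
        self.dark = np.asarray(self.dark, dtype=float)
        np.broadcast_shapes(self.white.shape, self.dark.shape)


def _parse_header_text(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing leading 'ENVI' magic)")
    body = text.split("ENVI", 1)[1]
    fields: dict[str, str] = {}
    # key = value, where a value may be a {...} block spanning several lines
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL)
    pos = 0
    while pos < len(body):
        match = pattern.search(body, pos)
        if match is None:
            break
        key = match.group(1).strip().lower()
        value = match.group(2).strip()
        fields[key] = value
        pos = match.end()
    return fields


def _header_path(path: Path) -> Path:
    for candidate in (path.with_suffix(path.suffix + ".hdr"), path.with_suffix(".hdr")):
        if candidate.exists():
            return candidate
    raise FormatError(f"no ENVI header found next to {path}")


def read_envi_cube(path: str | Path) -> HyperspectralCube:
    """Read an ENVI raster + header into a ``(row, column, band)`` cube.

    Raises :class:`FormatError` for a missing or malformed header and
    :class:`ConsistencyError` when the declared wavelengths do not match the
    declared band count.
    """
    path = Path(path)
    if path.suffix == ".hdr":
        header_file, path = path, path.with_suffix("")
    else:
        header_file = _header_path(path)
    fields = _parse_header_text(header_file.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    interleave = fields.get("interleave", "bsq").strip().lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise FormatError(f"unknown interleave {interleave!r}")
    offset = int(fields.get("header offset", "0"))
    byte_order = int(fields.get("byte order", "0"))

    if "wavelength" not in fields:
        raise FormatError("ENVI header declares no wavelengths")
    raw = fields["wavelength"].strip()
    if not (raw.startswith("{") and raw.endswith("}")):
        raise FormatError("wavelength field must be a { ... } list")
    centers = np.array([float(tok) for tok in raw[1:-1].replace("\n", " ").split(",") if tok.strip()])
    if centers.size != bands:
        raise ConsistencyError(
            f"header declares {bands} bands but lists {centers.size} wavelengths"
        )

    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if byte_order == 1:
        dtype = dtype.newbyteorder(">")
    data = np.fromfile(path, dtype=dtype, count=samples * lines * bands, offset=offset)
    if data.size != samples * lines * bands:
        raise ConsistencyError(
            f"raster holds {data.size} values, expected {samples * lines * bands}"
        )
    if interleave == "bsq":
        values = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = data.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        values = data.reshape(lines, samples, bands)

    calibrated = fields.get("calibrated", "false").strip().lower() in ("true", "1", "yes")
    return HyperspectralCube(
        values=np.ascontiguousarray(values),
        wavelengths=WavelengthGrid(centers),
        calibrated=calibrated,
    )


def write_envi_cube(cube: HyperspectralCube, path: str | Path) -> Path:
    """Write ``cube`` as a BSQ ENVI raster plus ``.hdr``; returns the raster path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(cube.values)
    if np.dtype(values.dtype) not in _DTYPE_CODES:
        values = values.astype(np.float32)
    rows, cols, bands = values.shape
    values.transpose(2, 0, 1).tofile(path)

    wl = ", ".join(repr(float(w)) for w in cube.wavelengths.centers)
    header = (
        "ENVI\n"
        "description = {hsipatho hyperspectral cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(values.dtype)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"calibrated = {'true' if cube.calibrated else 'false'}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(header)
    return path


def calibrate_reflectance(
    raw: HyperspectralCube, refs: CalibrationFrames
) -> HyperspectralCube:
    """Flat-field calibration ``(raw − dark) / (white − dark)``, clipped to [0, 1].

    The white reference dynamic range sets the degeneracy guard: any used
    pixel/band where ``white − dark`` falls below 1e-8 of that range raises
    :class:`DegenerateReferenceError` instead of producing infinities.
    """
    white = np.broadcast_to(refs.white, raw.values.shape)
    dark = np.broadcast_to(refs.dark, raw.values.shape)
    denom = white - dark
    eps = 1e-8 * float(np.ptp(refs.white))
    if np.any(denom <= eps):
        raise DegenerateReferenceError(
            "white and dark references coincide (white - dark <= eps) at some pixel/band"
        )
    values = np.clip((raw.values.astype(float) - dark) / denom, 0.0, 1.0)
    return HyperspectralCube(values=values, wavelengths=raw.wavelengths, calibrated=True)


def crop_band_window(
    cube: HyperspectralCube, lo_nm: float, hi_nm: float
) -> HyperspectralCube:
    """Keep the bands whose centres satisfy ``lo_nm <= center <= hi_nm``.

    Endpoints are inclusive.  Raises :class:`EmptySelectionError` when no band
    falls inside the window.
    """
    if not lo_nm < hi_nm:
        raise EmptySelectionError(f"invalid window [{lo_nm}, {hi_nm}]")
    centers = cube.wavelengths.centers
    keep = (centers >= lo_nm) & (centers <= hi_nm)
    if not keep.any():
        raise EmptySelectionError(
            f"window [{lo_nm}, {hi_nm}] nm selects no band from "
            f"[{centers[0]}, {centers[-1]}] nm"
        )
    return HyperspectralCube(
        values=cube.values[:, :, keep],
        wavelengths=WavelengthGrid(centers[keep]),
        calibrated=cube.calibrated,
    )


def export_tiff(cube: HyperspectralCube, path: str | Path) -> Path:
    """Export the cube as a multi-page TIFF (one page per band) for inspection."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.ascontiguousarray(cube.values.transpose(2, 0, 1)).astype(np.float32)
    tifffile.imwrite(path, pages)
    return path
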