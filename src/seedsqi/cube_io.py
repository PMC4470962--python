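"""Hyperspectral cube container, ENVI I/O, and reflectance calibration.

A cube is a (rows, cols, bands) raster with one wavelength (nm) per band.
Values are either raw sensor radiance (arbitrary units) or reflectance in
percent (0-100+). Reflectance is always stored in percent, never as a
fraction: the seed-quality index computed downstream is built on unit x-axis
steps in percent-reflectance space and is not scale-invariant, so mixing the
two conventions silently corrupts results.

On-disk format is ENVI: an ASCII ``.hdr`` describing dimensions, interleave
(BSQ/BIL/BIP), data type and the wavelength list, next to a bare little-endian
binary raster. Only the header keys listed in ``_REQUIRED_KEYS`` plus
``wavelength`` are required; unknown keys are preserved in ``meta``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("seedsqi")

KIND_RADIANCE = "radiance"
KIND_REFLECTANCE = "reflectance_percent"

# ENVI numeric "data type" codes <-> numpy dtypes (little-endian on disk).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_REQUIRED_KEYS = ("samples", "lines", "bands", "data type", "interleave")


@dataclass
class SpectralCube:
    """A (rows, cols, bands) hyperspectral raster with band-center wavelengths.

    Parameters
    ----------
    data
        Raster of shape (rows, cols, bands).
    wavelengths_nm
        Strictly increasing band centers in nanometres, one per band.
    kind
        ``"radiance"`` or ``"reflectance_percent"``.
    meta
        Free-form header key/value pairs carried through I/O.
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    kind: str = KIND_RADIANCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (rows, cols, bands), got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"cube dimensions must all be >= 1, got shape {self.data.shape}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths_nm.size} != band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if self.kind not in (KIND_RADIANCE, KIND_REFLECTANCE):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


def _parse_envi_header(text: str) -> dict:
    """Parse an ENVI header into a flat dict of lower-cased keys."""
    # Strip the leading magic line if present.
    text = re.sub(r"^\s*ENVI\s*\n", "", text)
    # Fold brace-delimited multi-line values onto one line.
    out: dict[str, str] = {}
    pos = 0
    pattern = re.compile(r"^\s*([^=\n]+?)\s*=\s*", re.M)
    while True:
        m = pattern.search(text, pos)
        if m is None:
            break
        key = m.group(1).strip().lower()
        rest = text[m.end():]
        if rest.lstrip().startswith("{"):
            close = rest.index("}")
            value = rest.lstrip()[1:close - (len(rest) - len(rest.lstrip()))].strip()
            pos = m.end() + close + 1
        else:
            eol = rest.find("\n")
            eol = len(rest) if eol < 0 else eol
            value = rest[:eol].strip()
            pos = m.end() + eol
        out[key] = value
    return out


def read_envi_cube(header_path: str | Path) -> SpectralCube:
    """Read an ENVI header + binary raster pair into a :class:`SpectralCube`.

    The raster file is located by dropping/replacing the ``.hdr`` suffix, or
    from an ``image file`` header entry. Any interleave (BSQ, BIL, BIP) is
    normalised to (rows, cols, bands) in memory.
    """
    header_path = Path(header_path)
    header = _parse_envi_header(header_path.read_text())

    for key in _REQUIRED_KEYS:
        if key not in header:
            raise ValueError(f"ENVI header {header_path} is missing required field {key!r}")
    if "wavelength" not in header:
        raise ValueError(f"ENVI header {header_path} is missing the 'wavelength' field")

    cols = int(header["samples"])
    rows = int(header["lines"])
    bands = int(header["bands"])
    interleave = header["interleave"].lower()
    dtype_code = int(header["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<")
    wavelengths = np.array([float(w) for w in header["wavelength"].replace(",", " ").split()])

    data_path = Path(header.get("image file", ""))
    if not data_path.name:
        data_path = header_path.with_suffix(".img")
        if not data_path.exists():
            data_path = header_path.with_suffix("")
    elif not data_path.is_absolute():
        data_path = header_path.parent / data_path

    raw = np.fromfile(data_path, dtype=dtype)
    expected = rows * cols * bands
    if raw.size != expected:
        raise ValueError(
            f"raster {data_path} holds {raw.size} values but header declares "
            f"{rows}x{cols}x{bands} = {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    kind = header.get("cube kind", KIND_RADIANCE)
    bookkeeping = (*_REQUIRED_KEYS, "wavelength", "cube kind", "image file",
                   "header offset", "file type", "byte order")
    meta = {k: v for k, v in header.items() if k not in bookkeeping}
    return SpectralCube(np.ascontiguousarray(data), wavelengths, kind=kind, meta=meta)


def write_envi_cube(cube: SpectralCube, header_path: str | Path, interleave: str = "bsq") -> None:
    """Write ``cube`` as an ENVI header + raster so that read is the exact inverse.

    The raster goes to ``header_path`` with its suffix replaced by ``.img``,
    little-endian, in the requested interleave.
    """
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    data = np.asarray(cube.data)
    dtype = np.dtype(data.dtype)
    if dtype not in _DTYPE_CODES:
        data = data.astype(np.float64)
        dtype = np.dtype(np.float64)
    data_path = header_path.with_suffix(".img")

    if interleave == "bsq":
        on_disk = data.transpose(2, 0, 1)
    elif interleave == "bil":
        on_disk = data.transpose(0, 2, 1)
    else:
        on_disk = data
    np.ascontiguousarray(on_disk, dtype=dtype.newbyteorder("<")).tofile(data_path)

    lines = [
        "ENVI",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"image file = {data_path.name}",
        f"cube kind = {cube.kind}",
        "wavelength = {" + ", ".join(f"{w:.6f}" for w in cube.wavelengths_nm) + "}",
    ]
    for key, value in cube.meta.items():
        lines.append(f"{key} = {value}")
    header_path.write_text("\n".join(lines) + "\n")


def calibrate_reflectance(
    raw: SpectralCube,
    reference: SpectralCube,
    reference_reflectance_percent: float,
    dark: SpectralCube | None = None,
) -> SpectralCube:
    """Convert raw radiance to percent reflectance by pixelwise linear scaling.

    R(x, y, λ) = (raw − dark) / (reference − dark) × reference_reflectance_percent,
    with the dark frame taken as zero when absent. ``reference`` is an image of
    a diffuse standard of known reflectance (e.g. 50 for grey Spectralon, 90
    for a PTFE sheet). Negative results clip to 0; pixels where the reference
    signal does not exceed the dark level are invalid, stored as 0, and
    counted in ``meta["calibration_invalid_px"]`` and the log.
    """
    if reference_reflectance_percent <= 0:
        raise ValueError(f"reference_reflectance_percent must be > 0, got {reference_reflectance_percent}")
    others = [reference] + ([dark] if dark is not None else [])
    for other in others:
        if other.data.shape != raw.data.shape:
            raise ValueError(f"cube shape mismatch: {raw.data.shape} vs {other.data.shape}")
        if not np.allclose(other.wavelengths_nm, raw.wavelengths_nm):
            raise ValueError("cube wavelength grids differ")

    raw_v = raw.data.astype(np.float64)
    ref_v = reference.data.astype(np.float64)
    if dark is not None:
        dark_v = dark.data.astype(np.float64)
        raw_v = raw_v - dark_v
        ref_v = ref_v - dark_v

    invalid = ref_v <= 0
    n_invalid = int(invalid.sum())
    if n_invalid:
        logger.warning("calibration: %d pixel-band samples had non-positive reference signal; zeroed", n_invalid)
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = np.where(invalid, 0.0, raw_v / np.where(invalid, 1.0, ref_v)) * reference_reflectance_percent
    refl = np.clip(refl, 0.0, None)

    meta = dict(raw.meta)
    meta["calibration_invalid_px"] = n_invalid
    return SpectralCube(refl, raw.wavelengths_nm.copy(), kind=KIND_REFLECTANCE, meta=meta)


def nearest_band(cube: SpectralCube, target_nm: float, max_offset_nm: float = 5.0) -> int:
    """Index of the band whose center is nearest ``target_nm``.

    Band centers are instrument-defined, so a requested index wavelength (for
    example 1734 nm) maps to the closest available center. Ties break toward
    the lower wavelength. If the nearest center is farther than
    ``max_offset_nm`` the request is refused.
    """
    if max_offset_nm <= 0:
        raise ValueError("max_offset_nm must be > 0")
    offsets = np.abs(cube.wavelengths_nm - float(target_nm))
    idx = int(np.argmin(offsets))  # argmin takes the first (lower-λ) minimum on ties
    if offsets[idx] > max_offset_nm:
        raise ValueError(
            f"no band within {max_offset_nm} nm of {target_nm} nm; "
            f"nearest center is {cube.wavelengths_nm[idx]:.2f} nm ({offsets[idx]:.2f} nm away)"
        )
    return idx


def export_band_tsv(cube: SpectralCube, band: int, path: str | Path) -> None:
    """Write one band image as a plain TSV grid (rows x cols)."""
    np.savetxt(path, cube.data[:, :, band], fmt="%.6g", delimiter="\t")


def export_spectrum_tsv(wavelengths_nm: np.ndarray, values: np.ndarray, path: str | Path) -> None:
    """Write a spectrum as two-column TSV: wavelength_nm, value."""
    table = np.column_stack([np.asarray(wavelengths_nm, float), np.asarray(values, float)])
    np.savetxt(path, table, fmt="%.6g", delimiter="\t", header="wavelength_nm\tvalue", comments="")
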