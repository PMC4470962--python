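"""Seed-area detection by spectral similarity and region bookkeeping.

Seeds sit in known wells on a matt black plate, so segmentation reduces to
"find every pixel whose spectrum resembles a reference seed spectrum, then
label the connected blobs". Two similarity measures are provided: the
spectral angle mapper (SAM; scale-invariant angle between spectra viewed as
vectors) and Pearson cross-correlation (additionally invariant to positive
affine offsets). Detected regions get their interior holes filled, a size
filter, a border-contact flag, and an optional margin-eroded analysis mask
that drops pixels near the contour whose spectra are contaminated by
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .cube_io import KIND_REFLECTANCE, SpectralCube


@dataclass
class SeedRegion:
    """One detected seed area on a plate.

    ``mask`` is the full (hole-filled) seed footprint; ``analysis_mask`` is
    the subset retained after excluding pixels within ``margin_px`` of the
    contour. ``valid`` is False when erosion leaves nothing to analyse.
    """

    label: int
    mask: np.ndarray
    analysis_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    margin_px: int = 0
    centroid: tuple[float, float] = (0.0, 0.0)
    touches_border: bool = False
    valid: bool = True

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.analysis_mask is None:
            self.analysis_mask = self.mask.copy()
        self.analysis_mask = np.asarray(self.analysis_mask, bool)
        if self.analysis_mask.shape != self.mask.shape:
            raise ValueError("analysis_mask shape differs from mask shape")
        if np.any(self.analysis_mask & ~self.mask):
            raise ValueError("analysis_mask must be a subset of mask")
        if not self.analysis_mask.any():
            self.valid = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def _flatten_spectra(cube: SpectralCube) -> np.ndarray:
    return cube.data.reshape(-1, cube.bands).astype(np.float64)


def spectral_angle_map(cube: SpectralCube, reference_spectrum: np.ndarray) -> np.ndarray:
    """Per-pixel spectral angle (radians) between each spectrum and a reference.

    θ = arccos(s·r / (‖s‖‖r‖)) ∈ [0, π]. Zero-norm pixels (no signal) are
    maximally dissimilar: θ = π.
    """
    ref = np.asarray(reference_spectrum, float).ravel()
    if ref.size != cube.bands:
        raise ValueError(f"reference length {ref.size} != band count {cube.bands}")
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValueError("reference spectrum has zero norm")
    flat = _flatten_spectra(cube)
    norms = np.linalg.norm(flat, axis=1)
    zero = norms == 0
    cosines = flat @ ref / (np.where(zero, 1.0, norms) * ref_norm)
    angles = np.arccos(np.clip(cosines, -1.0, 1.0))
    angles[zero] = np.pi
    return angles.reshape(cube.spatial_shape)


def cross_correlation_map(cube: SpectralCube, reference_spectrum: np.ndarray) -> np.ndarray:
    """Per-pixel Pearson correlation between each spectrum and a reference.

    Values lie in [−1, 1]; zero-variance (flat) pixels get 0.
    """
    ref = np.asarray(reference_spectrum, float).ravel()
    if ref.size != cube.bands:
        raise ValueError(f"reference length {ref.size} != band count {cube.bands}")
    if cube.bands < 2:
        raise ValueError("cross-correlation needs at least 2 bands")
    ref_c = ref - ref.mean()
    ref_sd = np.linalg.norm(ref_c)
    if ref_sd == 0:
        raise ValueError("reference spectrum is constant")
    flat = _flatten_spectra(cube)
    flat_c = flat - flat.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(flat_c, axis=1)
    zero = sd == 0
    corr = flat_c @ ref_c / (np.where(zero, 1.0, sd) * ref_sd)
    corr[zero] = 0.0
    return np.clip(corr, -1.0, 1.0).reshape(cube.spatial_shape)


def threshold_similarity(sim_image: np.ndarray, threshold: float, mode: str) -> np.ndarray:
    """Turn a similarity image into a boolean candidate-seed mask.

    mode ``"max_angle"``: keep pixels with angle ≤ threshold (radians).
    mode ``"min_correlation"``: keep pixels with correlation ≥ threshold.
    """
    sim = np.asarray(sim_image)
    if mode == "max_angle":
        if not 0 <= threshold <= np.pi:
            raise ValueError(f"angle threshold must be in [0, pi], got {threshold}")
        return sim <= threshold
    if mode == "min_correlation":
        if not -1 <= threshold <= 1:
            raise ValueError(f"correlation threshold must be in [-1, 1], got {threshold}")
        return sim >= threshold
    raise ValueError(f"unknown similarity mode {mode!r}")


def detect_regions(
    mask: np.ndarray,
    min_area_px: int = 10,
    connectivity: int = 8,
    exclude_border: bool = True,
) -> list[SeedRegion]:
    """Label connected components of a candidate mask as seed regions.

    Components get their holes filled ("closed areas"), ones smaller than
    ``min_area_px`` are dropped, and ones touching the image border are
    flagged (and dropped when ``exclude_border``, the default, since their
    spectra are unreliable). Labels are assigned 1..n in raster-scan order of
    each component's top-left pixel.
    """
    mask = np.asarray(mask, bool)
    if connectivity == 8:
        structure = np.ones((3, 3), bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")

    labeled, n = ndimage.label(mask, structure=structure)
    regions: list[SeedRegion] = []
    for i in range(1, n + 1):
        blob = labeled == i
        blob = ndimage.binary_fill_holes(blob)
        if int(blob.sum()) < min_area_px:
            continue
        rr, cc = np.nonzero(blob)
        touches = bool(
            rr.min() == 0 or cc.min() == 0
            or rr.max() == mask.shape[0] - 1 or cc.max() == mask.shape[1] - 1
        )
        if touches and exclude_border:
            continue
        regions.append(
            SeedRegion(
                label=0,
                mask=blob,
                centroid=(float(rr.mean()), float(cc.mean())),
                touches_border=touches,
            )
        )
    # Raster-scan order of each component's top-left (first raster) pixel.
    regions.sort(key=lambda r: tuple(np.transpose(np.nonzero(r.mask))[0]))
    for new_label, region in enumerate(regions, start=1):
        region.label = new_label
    return regions


def erode_margin(region: SeedRegion, margin_px: int) -> SeedRegion:
    """Exclude pixels within ``margin_px`` of the seed contour.

    Uses the Euclidean distance transform: a pixel survives when its distance
    to the nearest background pixel exceeds ``margin_px``, which is faithful
    to a metric margin on diagonal boundaries where iterated structuring
    elements are not. ``margin_px == 0`` is the identity.
    """
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    if margin_px == 0:
        analysis = region.mask.copy()
    else:
        dist = ndimage.distance_transform_edt(region.mask)
        analysis = dist > margin_px
    return replace(
        region,
        analysis_mask=analysis,
        margin_px=margin_px,
        valid=bool(analysis.any()),
    )


def region_mean_spectrum(cube: SpectralCube, region: SeedRegion) -> np.ndarray:
    """Unweighted mean reflectance spectrum over a region's analysis mask."""
    if not region.valid:
        raise ValueError(f"region {region.label} has an empty analysis mask")
    if cube.kind != KIND_REFLECTANCE:
        raise ValueError("region_mean_spectrum expects a reflectance cube")
    return cube.data[region.analysis_mask].mean(axis=0)


def mean_spectrum_in_box(cube: SpectralCube, row0: int, col0: int, row1: int, col1: int) -> np.ndarray:
    """Mean spectrum over a rectangle [row0:row1, col0:col1] — the usual way a
    reference seed area is supplied from config or CLI coordinates."""
    patch = cube.data[row0:row1, col0:col1]
    if patch.size == 0:
        raise ValueError("reference rectangle is empty")
    return patch.reshape(-1, cube.bands).mean(axis=0)


def regions_table(regions: list[SeedRegion]):
    """Region summary (label, area, centroid, flags) as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [r.label for r in regions],
            "area_px": [r.area_px for r in regions],
            "centroid_row": [r.centroid[0] for r in regions],
            "centroid_col": [r.centroid[1] for r in regions],
            "touches_border": [r.touches_border for r in regions],
            "valid": [r.valid for r in regions],
        }
    )


def label_image(regions: list[SeedRegion], shape: tuple[int, int]) -> np.ndarray:
    """Combine region masks into a uint16 label raster (0 = background)."""
    out = np.zeros(shape, np.uint16)
    for region in regions:
        out[region.mask] = region.label
    return out
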