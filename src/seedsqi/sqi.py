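"""The seed quality index (SQI): a three-band SWIR reflectance angle.

Sound conifer seeds absorb strongly near 1,730 nm (first overtone of C–H
stretching, abundant in fatty acids), so their reflectance spectra dip at the
centre band relative to the flanks near 1,637 and 1,854 nm ("m-shaped");
unsound seeds show no dip or a mild bump ("n-shaped"). SQI quantifies this as
the clockwise angle, in degrees, at the middle vertex of the polyline through
the three points (−1, R1637), (0, R1734), (1, R1854) — percent reflectance on
the y-axis, *unit* steps on the x-axis. A deep dip gives a small angle; a
flat or collinear triplet gives exactly 180°; a bump gives a reflex angle
above 180°. Because the x-steps are fixed at 1, SQI is deliberately not
scale-invariant: reflectance must be in percent.

SQI from a seed's mean spectrum is ``SQI_areal``; computed independently per
pixel it is ``SQI_pixel``. The peak-to-base ratio (PBR) of a seed is the
fraction of its pixels whose SQI_pixel falls strictly below a threshold
maxSQI — sound seeds concentrate low SQI_pixel at their centre, so their PBR
is high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube_io import SpectralCube, nearest_band
from .segmentation import SeedRegion, region_mean_spectrum

# The selection rules use strict inequalities throughout ("lower than" /
# "greater than"); this constant centralises that choice.
STRICT_THRESHOLDS = True

#: Default index wavelengths (nm): lower flank, dip centre, upper flank.
DEFAULT_BAND_TARGETS_NM = (1637.0, 1734.0, 1854.0)


@dataclass(frozen=True)
class BandTriplet:
    """Resolved band indices and centers for the three SQI wavebands."""

    idx_1637: int
    idx_1734: int
    idx_1854: int
    centers_nm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.idx_1637 < self.idx_1734 < self.idx_1854:
            raise ValueError(
                f"band indices must be strictly ordered, got "
                f"{self.idx_1637}, {self.idx_1734}, {self.idx_1854}"
            )

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.idx_1637, self.idx_1734, self.idx_1854)


def resolve_bands(
    cube: SpectralCube,
    targets_nm: tuple[float, float, float] = DEFAULT_BAND_TARGETS_NM,
    max_offset_nm: float = 5.0,
) -> BandTriplet:
    """Map the three index wavelengths to the cube's nearest instrument bands."""
    idx = [nearest_band(cube, t, max_offset_nm) for t in targets_nm]
    centers = tuple(float(cube.wavelengths_nm[i]) for i in idx)
    return BandTriplet(idx[0], idx[1], idx[2], centers)  # type: ignore[arg-type]


@dataclass
class SQIMap:
    """Pixelwise SQI over one seed region, plus the region's areal SQI."""

    values: np.ndarray  # 1-D, one SQI per mask pixel (degrees)
    mask: np.ndarray  # boolean raster the values cover, raster order
    sqi_areal: float
    smoothing_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.size != int(self.mask.sum()):
            raise ValueError("one SQI value per mask pixel required")

    def raster(self) -> np.ndarray:
        """SQI as a full-frame raster with NaN off-mask."""
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = self.values
        return out


def sqi_from_triplet(r1637, r1734, r1854):
    """SQI (degrees) from the three percent-reflectance values; vectorised.

    With u = (−1, r1637 − r1734) and v = (1, r1854 − r1734) anchored at the
    centre vertex, cos α = u·v/(‖u‖‖v‖); SQI is the arccos in degrees when
    the centre sits at or below the flank mean (a dip), and its 360°
    complement otherwise (a bump → reflex angle). Collinear triplets give
    exactly 180°, and SQI is continuous across that branch boundary.
    """
    r1637 = np.asarray(r1637, float)
    r1734 = np.asarray(r1734, float)
    r1854 = np.asarray(r1854, float)
    if not (np.all(np.isfinite(r1637)) and np.all(np.isfinite(r1734)) and np.all(np.isfinite(r1854))):
        raise ValueError("reflectance values must be finite")
    d_left = r1637 - r1734
    d_right = r1854 - r1734
    alpha = (d_left * d_right - 1.0) / (np.sqrt(d_left**2 + 1.0) * np.sqrt(d_right**2 + 1.0))
    theta = np.degrees(np.arccos(np.clip(alpha, -1.0, 1.0)))
    sqi = np.where(r1734 <= (r1637 + r1854) / 2.0, theta, 360.0 - theta)
    return sqi if sqi.ndim else float(sqi)


def sqi_areal(cube: SpectralCube, region: SeedRegion, bands: BandTriplet) -> float:
    """SQI of a seed's mean spectrum (mean first, SQI second — the order
    matters because SQI is nonlinear in reflectance)."""
    spectrum = region_mean_spectrum(cube, region)
    i, j, k = bands.indices
    return float(sqi_from_triplet(spectrum[i], spectrum[j], spectrum[k]))


# 3x3 distance-weighted kernel: weight = 2^(-Euclidean offset distance),
# i.e. centre 1, edge 0.5, corner 2^(-sqrt(2)).
_SMOOTH_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
_SMOOTH_WEIGHTS = np.array([2.0 ** (-np.hypot(dr, dc)) for dr, dc in _SMOOTH_OFFSETS])


def smooth_band_image(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Denoise a band image inside a mask with a 3×3 2^(−distance) kernel.

    At each mask pixel the result is the weighted mean of the in-mask pixels
    of its 3×3 neighbourhood, the weights renormalised to the pixels actually
    included; out-of-mask and out-of-frame neighbours carry no weight, so
    constants are preserved everywhere including at mask edges. Off-mask
    output pixels are left unchanged.
    """
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    acc = np.zeros_like(image)
    wsum = np.zeros_like(image)
    padded_img = np.pad(image, 1)
    padded_mask = np.pad(mask, 1)
    rows, cols = image.shape
    for (dr, dc), w in zip(_SMOOTH_OFFSETS, _SMOOTH_WEIGHTS):
        nb_img = padded_img[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
        nb_in = padded_mask[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
        acc += w * nb_img * nb_in
        wsum += w * nb_in
    out = image.copy()
    out[mask] = acc[mask] / wsum[mask]
    return out


def sqi_pixel_map(
    cube: SpectralCube,
    region: SeedRegion,
    bands: BandTriplet,
    smooth: bool = False,
    use_analysis_mask: bool = False,
) -> SQIMap:
    """Pixelwise SQI over a seed region.

    Band images are optionally denoised within the full seed mask first (the
    smoothing is a display aid; selection statistics use ``smooth=False``).
    By default the map covers the full seed mask (margin 0); set
    ``use_analysis_mask`` to restrict it to the margin-eroded mask.
    """
    if not region.valid:
        raise ValueError(f"region {region.label} has an empty analysis mask")
    mask = region.analysis_mask if use_analysis_mask else region.mask
    planes = []
    for idx in bands.indices:
        plane = cube.data[:, :, idx].astype(float)
        if smooth:
            plane = smooth_band_image(plane, region.mask)
        planes.append(plane[mask])
    values = sqi_from_triplet(*planes)
    return SQIMap(
        values=np.atleast_1d(values),
        mask=mask,
        sqi_areal=sqi_areal(cube, region, bands),
        smoothing_applied=smooth,
    )


def pbr(sqi_map: SQIMap, max_sqi: float) -> float:
    """Peak-to-base area ratio: fraction of the map's pixels with SQI_pixel
    strictly below ``max_sqi``."""
    if sqi_map.values.size == 0:
        raise ValueError("SQI map is empty")
    return float(np.mean(sqi_map.values < max_sqi))


def export_sqi_map_tsv(sqi_map: SQIMap, path) -> None:
    """Write an SQI map as TSV rows: pixel row, col, SQI (degrees)."""
    rr, cc = np.nonzero(sqi_map.mask)
    table = np.column_stack([rr, cc, sqi_map.values])
    np.savetxt(path, table, fmt=("%d", "%d", "%.6f"), delimiter="\t",
               header="row\tcol\tsqi", comments="")


def render_sqi_heatmap(sqi_map: SQIMap, path, vmin: float = 0.0, vmax: float = 360.0) -> None:
    """Render an SQI map as a PNG heat map.

    Fixed colour scale 0–360° on a reversed warm-to-cold map, so low SQI
    (sound tissue) draws warm and comparable across seeds and plates.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    im = ax.imshow(sqi_map.raster(), cmap="jet_r", vmin=vmin, vmax=vmax)
    fig.colorbar(im, ax=ax, label="SQI (deg)")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
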