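"""End-to-end plate analysis: calibrate → segment → SQI → seed records.

This is the glue the command-line interface and the test harness share. It
takes raw and reference radiance cubes, produces percent reflectance,
segments seed areas by spectral similarity to a reference seed spectrum,
and returns one :class:`~seedsqi.selection.SeedRecord` per seed carrying
SQI_areal and the SQI_pixel map needed for PBR-based selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cube_io import SpectralCube, calibrate_reflectance
from .segmentation import (
    SeedRegion,
    detect_regions,
    erode_margin,
    mean_spectrum_in_box,
    spectral_angle_map,
    threshold_similarity,
)
from .selection import SeedRecord
from .sqi import DEFAULT_BAND_TARGETS_NM, BandTriplet, SQIMap, resolve_bands, sqi_pixel_map

logger = logging.getLogger("seedsqi")


@dataclass
class PlateAnalysis:
    """Everything produced by one pass over a plate."""

    cube: SpectralCube  # percent reflectance
    regions: list[SeedRegion]
    bands: BandTriplet
    records: list[SeedRecord]
    sqi_maps: dict[int, SQIMap]  # keyed by region label


def reference_spectrum_from_boxes(
    cube: SpectralCube, boxes: list[tuple[int, int, int, int]]
) -> np.ndarray:
    """Mean spectrum over one or more (row0, col0, row1, col1) rectangles —
    the "pre-assigned reference area" for similarity segmentation."""
    spectra = [mean_spectrum_in_box(cube, *box) for box in boxes]
    return np.mean(spectra, axis=0)


def analyze_plate(
    raw: SpectralCube,
    reference: SpectralCube,
    *,
    reference_reflectance_percent: float = 50.0,
    dark: SpectralCube | None = None,
    reference_spectrum: np.ndarray | None = None,
    reference_boxes: list[tuple[int, int, int, int]] | None = None,
    sam_threshold_rad: float = 0.1,
    min_area_px: int = 10,
    connectivity: int = 8,
    exclude_border: bool = True,
    margin_px: int = 0,
    band_targets_nm: tuple[float, float, float] = DEFAULT_BAND_TARGETS_NM,
    max_offset_nm: float = 5.0,
    smooth: bool = False,
) -> PlateAnalysis:
    """Run the full scoring pipeline on one plate.

    The reference seed spectrum for segmentation comes either directly
    (``reference_spectrum``) or as the mean over rectangles on the
    reflectance image (``reference_boxes``). SQI_areal uses the
    margin-eroded analysis mask; the SQI_pixel map and hence PBR use the
    full seed mask.
    """
    cube = calibrate_reflectance(raw, reference, reference_reflectance_percent, dark=dark)
    if reference_spectrum is None:
        if reference_boxes is None:
            raise ValueError("provide reference_spectrum or reference_boxes")
        reference_spectrum = reference_spectrum_from_boxes(cube, reference_boxes)

    angles = spectral_angle_map(cube, reference_spectrum)
    candidate = threshold_similarity(angles, sam_threshold_rad, "max_angle")
    regions = detect_regions(
        candidate, min_area_px=min_area_px, connectivity=connectivity, exclude_border=exclude_border
    )
    regions = [erode_margin(r, margin_px) for r in regions]
    n_invalid = sum(not r.valid for r in regions)
    if n_invalid:
        logger.warning("%d regions became empty after margin erosion and are dropped", n_invalid)

    bands = resolve_bands(cube, band_targets_nm, max_offset_nm)
    records: list[SeedRecord] = []
    sqi_maps: dict[int, SQIMap] = {}
    for region in regions:
        if not region.valid:
            continue
        smap = sqi_pixel_map(cube, region, bands, smooth=smooth)
        sqi_maps[region.label] = smap
        records.append(
            SeedRecord(seed_id=region.label, sqi_areal=smap.sqi_areal, sqi_pixels=smap.values)
        )
    logger.info(
        "plate analysed: %d regions, %d valid records, bands %s",
        len(regions), len(records), bands.centers_nm,
    )
    return PlateAnalysis(cube=cube, regions=regions, bands=bands, records=records, sqi_maps=sqi_maps)


def attach_truth(analysis: PlateAnalysis, labels: np.ndarray, seed_table) -> None:
    """Assign truth classes to records by majority overlap between detected
    region masks and a truth label raster."""
    class_of = dict(zip(seed_table["seed_id"], seed_table["seed_class"]))
    region_by_label = {r.label: r for r in analysis.regions}
    for record in analysis.records:
        region = region_by_label[record.seed_id]
        overlap = labels[region.mask]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            record.truth_class = "unknown"
            continue
        truth_id = int(np.bincount(overlap).argmax())
        record.truth_class = class_of.get(truth_id, "unknown")


def default_reference_boxes(config, half: int = 2) -> list[tuple[int, int, int, int]]:
    """Small rectangles at every well centre of a plate layout — wells are a
    fixed property of the plate, so this needs no ground truth."""
    boxes = []
    cell_h = config.rows / config.grid_rows
    cell_w = config.cols / config.grid_cols
    for gi in range(config.grid_rows):
        for gj in range(config.grid_cols):
            r = int((gi + 0.5) * cell_h)
            c = int((gj + 0.5) * cell_w)
            boxes.append((r - half, c - half, r + half + 1, c + half + 1))
    return boxes
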