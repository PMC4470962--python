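"""Synthetic SWIR seed plates with known ground truth.

No study imagery is redistributed, so every pipeline stage is exercised on
generated plates that reproduce the phenomenology the method rests on: a
dark matt background; 18 elliptical seeds in a 3×6 well grid imaged at
roughly 200×320 px over 163 bands spanning 1,250–2,500 nm; sound seeds with
an absorption dip centred near 1,730 nm ("m-shaped" spectrum) whose depth is
maximal at the seed centre and fades radially; unsound seeds with no dip or
a mild bump ("n-shaped"), either spatially flat (sugi-like) or with a weak
central dip of their own (hinoki-like). Reflectance is converted to raw
radiance through a smooth lamp spectrum (optionally with multiplicative
vignetting), so that reference-target calibration inverts the construction
exactly and the whole chain — calibration, segmentation, SQI, threshold
calibration — can be checked against the generator's truth.

The generator is a model of the index-level phenomenology only: no
radiative transfer, no biochemical simulation, and seed shapes are
axis-aligned ellipses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cube_io import KIND_RADIANCE, KIND_REFLECTANCE, SpectralCube

SEED_CLASSES = ("sound", "shibudane", "other")


@dataclass(frozen=True)
class PlateConfig:
    """Geometry, spectral model, class mix and noise of a synthetic plate.

    Dip depths are in percent reflectance at the dip centre; a negative
    depth is a bump (the "n-shaped" unsound signature). ``unsound_radial``
    selects between hinoki-like unsound seeds (their weak dip also fades
    radially from the centre) and sugi-like ones (spatially flat).
    """

    rows: int = 200
    cols: int = 320
    n_bands: int = 163
    band_start_nm: float = 1250.0
    band_end_nm: float = 2500.0
    grid_rows: int = 3
    grid_cols: int = 6
    seed_radius_range_px: tuple[float, float] = (9.0, 13.0)
    background_percent: float = 5.0
    baseline_start_percent: float = 40.0
    baseline_end_percent: float = 20.0
    dip_center_nm: float = 1730.0
    dip_sigma_nm: float = 30.0
    class_dip_depth_percent: dict = field(
        default_factory=lambda: {"sound": (12.0, 20.0), "shibudane": (-6.0, -3.0), "other": (0.0, 0.0)}
    )
    radial_exponent: float = 2.0
    unsound_radial: bool = False
    class_proportions: dict = field(
        default_factory=lambda: {"sound": 0.6, "shibudane": 0.3, "other": 0.1}
    )
    noise_sd_percent: float = 1.0
    reference_reflectance_percent: float = 50.0
    gain_field: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.band_end_nm <= self.band_start_nm or self.n_bands < 2:
            raise ValueError("band grid must be ascending with >= 2 bands")
        if self.noise_sd_percent < 0:
            raise ValueError("noise sd must be >= 0")
        lo, hi = self.class_dip_depth_percent["sound"]
        if lo < 0 or hi < lo:
            raise ValueError("sound dip depth range must be non-negative and ordered")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.linspace(self.band_start_nm, self.band_end_nm, self.n_bands)

    @property
    def n_seeds(self) -> int:
        return self.grid_rows * self.grid_cols

    def baseline(self) -> np.ndarray:
        """Seed-tissue baseline reflectance (percent): a gentle downward ramp."""
        return np.linspace(self.baseline_start_percent, self.baseline_end_percent, self.n_bands)

    def dip_profile(self) -> np.ndarray:
        """Unit-depth Gaussian absorption profile over the band grid."""
        lam = self.wavelengths_nm
        return np.exp(-((lam - self.dip_center_nm) ** 2) / (2.0 * self.dip_sigma_nm**2))


def default_sugi_like_config(**overrides) -> PlateConfig:
    """Sugi-like plate: well-separated SQI classes; unsound seeds spatially
    flat, so their SQI_areal does not respond to margin erosion."""
    base = PlateConfig(
        class_dip_depth_percent={"sound": (12.0, 20.0), "shibudane": (-6.0, -3.0), "other": (0.0, 0.0)},
        class_proportions={"sound": 0.6, "shibudane": 0.3, "other": 0.1},
        unsound_radial=False,
    )
    return replace(base, **overrides)


def default_hinoki_like_config(**overrides) -> PlateConfig:
    """Hinoki-like plate: weaker class separation; unsound seeds carry a
    small central dip of their own, so they too have nonzero PBR and respond
    to margin erosion — the regime where the dual-parameter rule helps."""
    base = PlateConfig(
        class_dip_depth_percent={"sound": (10.0, 16.0), "shibudane": (2.0, 5.0), "other": (1.5, 3.0)},
        class_proportions={"sound": 0.33, "shibudane": 0.48, "other": 0.19},
        unsound_radial=True,
    )
    return replace(base, **overrides)


def generate_seed_spectrum(
    seed_class: str,
    depth_percent: float,
    rng: np.random.Generator | int | None = None,
    config: PlateConfig | None = None,
) -> np.ndarray:
    """One seed-tissue spectrum: baseline ramp minus a Gaussian dip.

    ``depth_percent`` is the reflectance deficit at the dip centre (negative
    for a bump). Per-band Gaussian noise of the config's sd is added when an
    rng (or seed) is given; equal seeds give identical spectra.
    """
    if seed_class not in SEED_CLASSES:
        raise ValueError(f"unknown seed class {seed_class!r}")
    config = config or PlateConfig()
    spectrum = config.baseline() - depth_percent * config.dip_profile()
    if rng is not None and config.noise_sd_percent > 0:
        rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
        spectrum = spectrum + rng.normal(0.0, config.noise_sd_percent, spectrum.size)
    return np.clip(spectrum, 0.0, None)


@dataclass
class SyntheticPlate:
    """A generated plate with its ground truth."""

    config: PlateConfig
    raw: SpectralCube  # radiance, as a camera would deliver
    reference: SpectralCube  # radiance image of the reflectance standard
    reflectance: SpectralCube  # ground-truth reflectance (noise included)
    labels: np.ndarray  # uint16 truth label raster, 0 = background
    seed_table: pd.DataFrame  # seed_id, seed_class, dip depth, centroid, area
    depth_map: np.ndarray  # per-pixel dip depth (percent; negative = bump)

    def truth_mask(self, seed_id: int) -> np.ndarray:
        return self.labels == seed_id

    def expected_mean_spectrum(self, seed_id: int) -> np.ndarray:
        """Noise-free analytic mean spectrum over a seed's truth mask."""
        mean_depth = float(self.depth_map[self.truth_mask(seed_id)].mean())
        return self.config.baseline() - mean_depth * self.config.dip_profile()


def _assign_classes(config: PlateConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic class counts from the proportions, then a shuffle."""
    n = config.n_seeds
    counts = {c: int(np.floor(config.class_proportions.get(c, 0.0) * n)) for c in SEED_CLASSES}
    # distribute the rounding remainder by largest fractional part
    remainder = n - sum(counts.values())
    fracs = sorted(
        SEED_CLASSES,
        key=lambda c: config.class_proportions.get(c, 0.0) * n - counts[c],
        reverse=True,
    )
    for c in fracs[:remainder]:
        counts[c] += 1
    classes = [c for c in SEED_CLASSES for _ in range(counts[c])]
    rng.shuffle(classes)
    return classes


def generate_plate(config: PlateConfig | None = None) -> SyntheticPlate:
    """Generate one plate: raw + reference radiance cubes and full truth.

    Seeds are axis-aligned ellipses centred on the well grid. For seeds with
    a radial gradient the per-pixel dip depth is depth × (1 − (r/R)^γ) with
    r the normalised elliptical radius, so the dip (and hence low SQI_pixel)
    is strongest at the seed centre. Raw radiance is reflectance-scaled
    reference radiance, making reference calibration exactly invertible.
    """
    config = config or PlateConfig()
    rng = np.random.default_rng(config.rng_seed)
    rows, cols, bands = config.rows, config.cols, config.n_bands
    cell_h = rows / config.grid_rows
    cell_w = cols / config.grid_cols
    r_lo, r_hi = config.seed_radius_range_px
    if 2 * r_hi >= min(cell_h, cell_w):
        raise ValueError(
            f"seed radius up to {r_hi} px cannot fit the {cell_h:.0f}x{cell_w:.0f} px wells; "
            "reduce seed_radius_range_px"
        )

    classes = _assign_classes(config, rng)
    yy, xx = np.mgrid[0:rows, 0:cols]

    masks: list[np.ndarray] = []
    radials: list[np.ndarray] = []
    records: list[dict] = []
    for gi in range(config.grid_rows):
        for gj in range(config.grid_cols):
            k = gi * config.grid_cols + gj
            cy = (gi + 0.5) * cell_h + rng.uniform(-2, 2)
            cx = (gj + 0.5) * cell_w + rng.uniform(-2, 2)
            ay = rng.uniform(r_lo, r_hi)
            ax = rng.uniform(r_lo, r_hi)
            r_norm = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
            mask = r_norm <= 1.0
            cls = classes[k]
            lo, hi = config.class_dip_depth_percent[cls]
            depth = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            masks.append(mask)
            radials.append(np.where(mask, r_norm, 1.0))
            records.append(
                {"seed_class": cls, "dip_depth_percent": depth,
                 "centroid_row": cy, "centroid_col": cx, "area_px": int(mask.sum())}
            )

    # Truth labels in raster-scan order of each seed's top-left pixel, the
    # same order the region detector assigns, so labels line up one-to-one.
    order = sorted(
        range(len(masks)),
        key=lambda i: tuple(np.transpose(np.nonzero(masks[i]))[0]),
    )

    labels = np.zeros((rows, cols), np.uint16)
    depth_map = np.zeros((rows, cols))
    table_rows = []
    for new_id, i in enumerate(order, start=1):
        mask, rec = masks[i], records[i]
        labels[mask] = new_id
        depth = rec["dip_depth_percent"]
        if rec["seed_class"] == "sound" or config.unsound_radial:
            scale = 1.0 - np.clip(radials[i], 0.0, 1.0) ** config.radial_exponent
        else:
            scale = np.ones_like(radials[i])
        depth_map[mask] = depth * scale[mask]
        table_rows.append({"seed_id": new_id, **rec})
    seed_table = pd.DataFrame(table_rows)

    baseline = config.baseline()
    profile = config.dip_profile()
    reflectance = np.empty((rows, cols, bands))
    reflectance[:] = config.background_percent
    on = labels > 0
    reflectance[on] = baseline[None, :] - depth_map[on, None] * profile[None, :]
    if config.noise_sd_percent > 0:
        reflectance += rng.normal(0.0, config.noise_sd_percent, reflectance.shape)
    reflectance = np.clip(reflectance, 0.0, None)

    # Smooth halogen-lamp-like radiance spectrum; optional vignetting gain.
    lam = config.wavelengths_nm
    lamp = 800.0 * np.exp(-(((lam - 1900.0) / 700.0) ** 2)) + 200.0
    gain = np.ones((rows, cols))
    if config.gain_field:
        gy = np.cos((yy / rows - 0.5) * np.pi / 2)
        gx = np.cos((xx / cols - 0.5) * np.pi / 2)
        gain = 0.85 + 0.3 * gy * gx
    reference_data = gain[:, :, None] * lamp[None, None, :]
    raw_data = reflectance / config.reference_reflectance_percent * reference_data

    wl = config.wavelengths_nm
    return SyntheticPlate(
        config=config,
        raw=SpectralCube(raw_data, wl, kind=KIND_RADIANCE),
        reference=SpectralCube(reference_data, wl, kind=KIND_RADIANCE),
        reflectance=SpectralCube(reflectance, wl, kind=KIND_REFLECTANCE),
        labels=labels,
        seed_table=seed_table,
        depth_map=depth_map,
    )


def write_plate(plate: SyntheticPlate, out_dir) -> dict:
    """Write a plate to disk as ENVI cubes + truth TSV + label PNG; returns paths."""
    from pathlib import Path

    from PIL import Image

    from .cube_io import write_envi_cube

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "raw": out_dir / "raw.hdr",
        "reference": out_dir / "reference.hdr",
        "truth_table": out_dir / "truth.tsv",
        "labels": out_dir / "labels.png",
    }
    write_envi_cube(plate.raw, paths["raw"])
    write_envi_cube(plate.reference, paths["reference"])
    plate.seed_table.to_csv(paths["truth_table"], sep="\t", index=False)
    Image.fromarray(plate.labels).save(paths["labels"])
    return paths
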