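import numpy as np
import pytest

from seedsqi import (
    analyze_plate,
    attach_truth,
    default_hinoki_like_config,
    default_reference_boxes,
    default_sugi_like_config,
    generate_plate,
)


def analyzed(plate, box_half=2):
    """Run the standard pipeline on a synthetic plate and attach truth."""
    cfg = plate.config
    analysis = analyze_plate(
        plate.raw,
        plate.reference,
        reference_reflectance_percent=cfg.reference_reflectance_percent,
        reference_boxes=default_reference_boxes(cfg, half=box_half),
    )
    attach_truth(analysis, plate.labels, plate.seed_table)
    return analysis


@pytest.fixture(scope="session")
def sugi_plate_noise_free():
    return generate_plate(default_sugi_like_config(noise_sd_percent=0.0))


@pytest.fixture(scope="session")
def sugi_plate_noisy():
    # generator defaults: 1% reflectance noise, fixed rng seed
    return generate_plate(default_sugi_like_config())


@pytest.fixture(scope="session")
def hinoki_plate_noise_free():
    return generate_plate(default_hinoki_like_config(noise_sd_percent=0.0))


@pytest.fixture(scope="session")
def sugi_analysis_noise_free(sugi_plate_noise_free):
    return analyzed(sugi_plate_noise_free)


@pytest.fixture(scope="session")
def sugi_analysis_noisy(sugi_plate_noisy):
    return analyzed(sugi_plate_noisy)


@pytest.fixture(scope="session")
def hinoki_analysis_noise_free(hinoki_plate_noise_free):
    return analyzed(hinoki_plate_noise_free)


def sqi_planar_oracle(r1637, r1734, r1854):
    """Independent geometric oracle: clockwise angle (degrees) at the middle
    vertex of the polyline through (−1, r1637), (0, r1734), (1, r1854)."""
    theta_ba = np.degrees(np.arctan2(r1637 - r1734, -1.0))
    theta_bc = np.degrees(np.arctan2(r1854 - r1734, 1.0))
    return (theta_ba - theta_bc) % 360.0
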