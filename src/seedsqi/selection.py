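"""Sound-seed selection rules, selection statistics, and TER calibration.

A seed lot of N seeds contains N_OK sound and N_NG = N − N_OK unsound seeds;
a selection recovers N_get seeds of which N_get|OK are sound. The selection
statistics are

    SR_init = N_OK / N          initial sound seed rate
    RR      = N_get / N         recovery rate
    SR      = N_get|OK / N_get  sound seed rate among the selected (N_get > 0)
    YR      = N_get|OK / N_OK   yield rate of sound seeds (N_OK > 0)
    TER     = (N_get + N_OK − 2·N_get|OK) / N   total error rate,

where the TER numerator counts the selected-unsound plus excluded-sound
seeds. Two rules are supported: the single-parameter rule selects seeds with
SQI_areal strictly below maxSQI; the dual-parameter rule selects seeds whose
PBR at maxSQI is strictly above minPBR. Calibration picks thresholds by
minimising TER — exactly over data-driven candidate thresholds for the
single rule, and over an explicit (maxSQI, minPBR) grid for the dual rule.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("seedsqi")

TRUTH_CLASSES = ("sound", "shibudane", "other", "unknown")


@dataclass
class SeedRecord:
    """Per-seed quantities feeding the selection rules."""

    seed_id: int | str
    sqi_areal: float
    sqi_pixels: np.ndarray | None = None  # SQI_pixel values over the seed mask
    truth_class: str = "unknown"
    selected: bool = False
    _sorted_pixels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0 < self.sqi_areal < 360:
            raise ValueError(f"sqi_areal must lie in (0, 360), got {self.sqi_areal}")
        if self.truth_class not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth class {self.truth_class!r}")
        if self.sqi_pixels is not None:
            self.sqi_pixels = np.asarray(self.sqi_pixels, float)

    @property
    def truth_sound(self) -> bool:
        return self.truth_class == "sound"

    def pbr_at(self, max_sqi: float) -> float:
        """PBR at a given maxSQI: fraction of pixels with SQI strictly below."""
        if self.sqi_pixels is None:
            raise ValueError(f"seed {self.seed_id} has no SQI_pixel map")
        if self._sorted_pixels is None:
            self._sorted_pixels = np.sort(self.sqi_pixels)
        n_below = int(np.searchsorted(self._sorted_pixels, max_sqi, side="left"))
        return n_below / self._sorted_pixels.size


@dataclass
class SelectionStats:
    """Counts and rates of one selection outcome. SR/YR are None when their
    denominators vanish (nothing selected / no sound seeds), never 0."""

    N: int
    N_OK: int
    N_get: int
    N_get_OK: int

    def __post_init__(self) -> None:
        if not (0 <= self.N_get_OK <= min(self.N_get, self.N_OK) and self.N_get <= self.N and self.N_OK <= self.N):
            raise ValueError(
                f"inconsistent counts N={self.N}, N_OK={self.N_OK}, "
                f"N_get={self.N_get}, N_get_OK={self.N_get_OK}"
            )

    @property
    def N_NG(self) -> int:
        return self.N - self.N_OK

    @property
    def sr_init(self) -> float:
        return self.N_OK / self.N

    @property
    def rr(self) -> float:
        return self.N_get / self.N

    @property
    def sr(self) -> float | None:
        return self.N_get_OK / self.N_get if self.N_get > 0 else None

    @property
    def yr(self) -> float | None:
        return self.N_get_OK / self.N_OK if self.N_OK > 0 else None

    @property
    def misclassified(self) -> int:
        """Selected-unsound plus excluded-sound seeds (the TER numerator)."""
        return self.N_get + self.N_OK - 2 * self.N_get_OK

    @property
    def ter(self) -> float:
        return self.misclassified / self.N

    def as_dict(self) -> dict:
        return {
            "N": self.N, "N_OK": self.N_OK, "N_NG": self.N_NG,
            "N_get": self.N_get, "N_get_OK": self.N_get_OK,
            "SR_init": self.sr_init, "RR": self.rr, "SR": self.sr,
            "YR": self.yr, "TER": self.ter,
        }


def selection_stats(truth_sound, selected) -> SelectionStats:
    """Selection statistics from per-seed truth and selection flag vectors."""
    truth = np.asarray(truth_sound, bool)
    sel = np.asarray(selected, bool)
    if truth.shape != sel.shape:
        raise ValueError(f"flag vectors differ in length: {truth.size} vs {sel.size}")
    if truth.size < 1:
        raise ValueError("need at least one seed")
    return SelectionStats(
        N=truth.size,
        N_OK=int(truth.sum()),
        N_get=int(sel.sum()),
        N_get_OK=int((truth & sel).sum()),
    )


def select_single(records: list[SeedRecord], max_sqi: float) -> np.ndarray:
    """Single-parameter rule: select seeds with SQI_areal < maxSQI (strict)."""
    return np.array([r.sqi_areal < max_sqi for r in records], bool)


def select_dual(records: list[SeedRecord], max_sqi: float, min_pbr: float) -> np.ndarray:
    """Dual-parameter rule: select seeds with PBR(maxSQI) > minPBR (strict);
    maxSQI acts only through PBR here."""
    return np.array([r.pbr_at(max_sqi) > min_pbr for r in records], bool)


@dataclass
class CalibrationResult:
    """Outcome of a TER-minimising threshold search."""

    method: str  # "single" | "dual"
    optimal_params: list[tuple]  # all TER-minimising parameter tuples
    chosen_params: tuple
    min_ter: float
    ter_curve: "object"  # DataFrame of params -> TER (curve or surface)

    def __post_init__(self) -> None:
        if self.chosen_params not in self.optimal_params:
            raise ValueError("chosen_params must be one of optimal_params")


def _truth_vector(records: list[SeedRecord]) -> np.ndarray:
    unknown = [r.seed_id for r in records if r.truth_class == "unknown"]
    if unknown:
        raise ValueError(f"records without truth labels: {unknown}")
    truth = np.array([r.truth_sound for r in records], bool)
    if truth.all() or not truth.any():
        warnings.warn(
            "calibration lot contains only one truth class; the optimum is degenerate",
            stacklevel=3,
        )
    return truth


def calibrate_single(records: list[SeedRecord]) -> CalibrationResult:
    """Calibrate maxSQI by exact TER minimisation over the threshold sweep.

    Candidate thresholds are the midpoints between consecutive sorted
    distinct SQI_areal values plus one sentinel below the minimum and one
    above the maximum — every achievable selection by the rule appears
    exactly once, so the sweep optimum is the exact optimum. Of all
    TER-minimising candidates the smallest is chosen.
    """
    import pandas as pd

    if not records:
        raise ValueError("no records to calibrate on")
    truth = _truth_vector(records)
    values = np.array([r.sqi_areal for r in records], float)
    distinct = np.unique(values)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )

    # misclassification count is an integer, so minima compare exactly
    errors = np.array(
        [selection_stats(truth, values < c).misclassified for c in candidates], int
    )
    best = errors.min()
    optimal = [(float(c),) for c in candidates[errors == best]]
    curve = pd.DataFrame({"max_sqi": candidates, "ter": errors / truth.size})
    return CalibrationResult(
        method="single",
        optimal_params=optimal,
        chosen_params=min(optimal),
        min_ter=best / truth.size,
        ter_curve=curve,
    )


def _mode_smallest(values) -> float:
    """Most frequent value; ties broken toward the smaller value."""
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def calibrate_dual(
    records: list[SeedRecord],
    sqi_step: float = 1.0,
    pbr_step: float = 0.01,
) -> CalibrationResult:
    """Calibrate (maxSQI, minPBR) by a grid search for minimum TER.

    The grid spans [floor(min SQI_pixel), ceil(max SQI_pixel)] at ``sqi_step``
    intervals and [0, 1] at ``pbr_step`` intervals. All TER-minimising grid
    cells are returned; the chosen pair takes the per-coordinate mode of the
    optima (ties toward smaller values), falling back to the optimal cell
    nearest that mode pair if the modes do not themselves coincide on an
    optimal cell.
    """
    import pandas as pd

    if not records:
        raise ValueError("no records to calibrate on")
    truth = _truth_vector(records)
    pixel_pool = [r.sqi_pixels for r in records]
    if any(p is None for p in pixel_pool):
        raise ValueError("all records need SQI_pixel maps for dual calibration")
    lo = float(np.floor(min(p.min() for p in pixel_pool)))
    hi = float(np.ceil(max(p.max() for p in pixel_pool)))
    sqi_grid = np.arange(lo, hi + sqi_step / 2, sqi_step)
    pbr_grid = np.round(np.arange(0.0, 1.0 + pbr_step / 2, pbr_step), 10)
    if sqi_grid.size == 0 or pbr_grid.size == 0:
        raise ValueError("empty calibration grid")

    # PBR matrix: records x maxSQI candidates, via sorted-pixel bisection.
    pbr_matrix = np.stack([
        np.searchsorted(np.sort(p), sqi_grid, side="left") / p.size for p in pixel_pool
    ])
    n_ok = int(truth.sum())
    errors = np.empty((sqi_grid.size, pbr_grid.size), int)
    for j, min_pbr in enumerate(pbr_grid):
        sel = pbr_matrix > min_pbr  # records x sqi candidates
        n_get = sel.sum(axis=0)
        n_get_ok = (sel & truth[:, None]).sum(axis=0)
        errors[:, j] = n_get + n_ok - 2 * n_get_ok

    best = int(errors.min())
    ii, jj = np.nonzero(errors == best)
    optimal = [(float(sqi_grid[i]), float(pbr_grid[j])) for i, j in zip(ii, jj)]
    mode_pair = (_mode_smallest([p[0] for p in optimal]), _mode_smallest([p[1] for p in optimal]))
    if mode_pair in optimal:
        chosen = mode_pair
    else:
        chosen = min(
            optimal,
            key=lambda p: ((p[0] - mode_pair[0]) ** 2 + (p[1] - mode_pair[1]) ** 2, p),
        )
        logger.info("dual calibration: per-coordinate mode %s is not optimal; chose nearest optimum %s",
                    mode_pair, chosen)

    surface = pd.DataFrame(errors / truth.size, index=sqi_grid, columns=pbr_grid)
    surface.index.name = "max_sqi"
    surface.columns.name = "min_pbr"
    return CalibrationResult(
        method="dual",
        optimal_params=optimal,
        chosen_params=chosen,
        min_ter=best / truth.size,
        ter_curve=surface,
    )


def apply_selection(records: list[SeedRecord], method: str, params: tuple) -> np.ndarray:
    if method == "single":
        return select_single(records, params[0])
    if method == "dual":
        return select_dual(records, params[0], params[1])
    raise ValueError(f"unknown selection method {method!r}")


def cross_validate(
    calib_records: list[SeedRecord],
    valid_records: list[SeedRecord],
    method: str = "single",
) -> dict:
    """Calibrate on one lot, validate on another, report stats both ways.

    Returns a dict with the calibration result, the self-application
    ("calibration error") stats on the calibration lot, and the
    transferred-threshold ("validation error") stats on the validation lot.
    """
    calibrate = calibrate_single if method == "single" else calibrate_dual
    result = calibrate(calib_records)
    params = result.chosen_params

    stats = {}
    for name, lot in (("calibration", calib_records), ("validation", valid_records)):
        truth = np.array([r.truth_sound for r in lot], bool)
        selected = apply_selection(lot, method, params)
        for record, flag in zip(lot, selected):
            record.selected = bool(flag)
        stats[name] = selection_stats(truth, selected)

    return {
        "method": method,
        "calibration_result": result,
        "chosen_params": params,
        "calibration_stats": stats["calibration"],
        "validation_stats": stats["validation"],
    }


def records_table(records: list[SeedRecord], max_sqi: float | None = None):
    """Seed table as a DataFrame (seed_id, sqi_areal, pbr, truth_class, selected)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "seed_id": [r.seed_id for r in records],
            "sqi_areal": [r.sqi_areal for r in records],
            "pbr": [
                (r.pbr_at(max_sqi) if (max_sqi is not None and r.sqi_pixels is not None) else np.nan)
                for r in records
            ],
            "truth_class": [r.truth_class for r in records],
            "selected": [r.selected for r in records],
        }
    )
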