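"""Per-curve standard normal variate (SNV) transform and grid alignment.

SNV removes the device-dependent offset and scale of each scattered-light
trajectory by centering it at zero mean and scaling to unit standard
deviation, curve by curve:

    SNV(SL(t)) = (SL(t) − mean(SL)) / std(SL)

The sample (n−1) standard-deviation convention is used. Alignment
interpolates each SNV curve linearly onto a common time grid so that a set
of cultures becomes a rectangular matrix suitable for PCA; extrapolation is
never performed — a culture that does not cover the grid is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from inductionscope.errors import DegenerateCurveError, GridCoverageError, InsufficientDataError
from inductionscope.plate_io import CultureRecord, PlateDataset


@dataclass
class SNVCurve:
    """A single SNV-transformed trajectory (zero mean, unit sample std)."""

    times: np.ndarray
    values: np.ndarray
    source_well: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if abs(float(np.mean(self.values))) > 1e-10:
            raise ValueError("SNV curve mean deviates from 0 beyond 1e-10")
        if abs(float(np.std(self.values, ddof=1)) - 1.0) > 1e-10:
            raise ValueError("SNV curve sample std deviates from 1 beyond 1e-10")


@dataclass
class AlignedMatrix:
    """SNV trajectories interpolated onto a shared strictly increasing grid."""

    grid: np.ndarray
    rows: np.ndarray  # cultures x grid points
    well_ids: list[str]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.rows = np.asarray(self.rows, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.rows.ndim != 2 or self.rows.shape[1] != self.grid.size:
            raise ValueError("rows must be 2-D with one column per grid point")
        if self.rows.shape[0] != len(self.well_ids):
            raise ValueError("one well id per row required")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("aligned matrix contains non-finite entries")


def snv_transform(curve: CultureRecord) -> SNVCurve:
    """SNV-transform one culture's scattered-light trajectory.

    Raises :class:`DegenerateCurveError` for a constant signal and
    :class:`InsufficientDataError` below 3 time points. The transform is
    idempotent and invariant to positive affine rescaling of the input.
    """
    if curve.times.size < 3:
        raise InsufficientDataError(f"{curve.well}: SNV needs >= 3 time points")
    sl = curve.scattered_light
    std = float(np.std(sl, ddof=1))
    if std == 0.0:
        raise DegenerateCurveError(f"{curve.well}: constant signal, SNV undefined")
    values = (sl - float(np.mean(sl))) / std
    return SNVCurve(times=curve.times.copy(), values=values, source_well=curve.well)


def align_to_common_grid(
    dataset: PlateDataset,
    grid_start: float,
    grid_end: float,
    n_points: int,
) -> AlignedMatrix:
    """SNV-transform every culture and interpolate onto a common grid.

    The transform is applied on each culture's native grid first (so it
    matches per-culture processing exactly), then interpolated linearly.
    Every culture must cover ``[grid_start, grid_end]``; rows keep the
    dataset order.
    """
    if n_points < 2 or not grid_end > grid_start:
        raise ValueError("need n_points >= 2 and grid_end > grid_start")
    grid = np.linspace(grid_start, grid_end, n_points)
    rows = np.empty((len(dataset.cultures), n_points))
    well_ids = []
    for i, culture in enumerate(dataset.cultures):
        t = culture.times
        if t[0] > grid_start or t[-1] < grid_end:
            raise GridCoverageError(
                f"{culture.well}: time range [{t[0]}, {t[-1]}] h does not cover "
                f"grid [{grid_start}, {grid_end}] h"
            )
        snv = snv_transform(culture)
        rows[i] = np.interp(grid, snv.times, snv.values)
        well_ids.append(culture.well)
    return AlignedMatrix(grid=grid, rows=rows, well_ids=well_ids)
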