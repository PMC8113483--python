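"""Biological quantification: histology extrapolation, signal-to-cell-count
calibration, tumor volume and longitudinal summaries.

The histology route estimates per-slice cell numbers by density
extrapolation — a sub-area with countable nuclei gives cells/area, scaled
to the whole tumor mask area — and sums slices into a 3D tumor count.
Pairing those counts with integrated reconstruction signals over several
tumors yields a linear calibration (ordinary least squares) used to convert
signal to cell quantity in longitudinal experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inversion import ReconVolume
from .postprocess import ThresholdReport

__all__ = [
    "SliceCount",
    "CalibrationModel",
    "TumorTimepointSummary",
    "estimate_slice_cells",
    "tumor_total_cells",
    "fit_calibration",
    "integrated_signal",
    "tumor_volume",
    "longitudinal_summary",
]


@dataclass(frozen=True)
class SliceCount:
    """One histological section: total tumor area A1 (mm^2), counted
    sub-area A2 (mm^2), cells counted in the sub-area C_sub, and the slice
    thickness (um)."""

    a1: float
    a2: float
    c_sub: float
    thickness_um: float = 4.5

    def __post_init__(self) -> None:
        if self.a1 <= 0 or self.a2 <= 0:
            raise ValueError("areas must be > 0")
        if self.a2 > self.a1 + 1e-12:
            raise ValueError(f"sub-area A2={self.a2} exceeds tumor area A1={self.a1}")
        if self.c_sub < 0:
            raise ValueError("cell count must be >= 0")

    @property
    def estimated_cells(self) -> float:
        return estimate_slice_cells(self.a1, self.a2, self.c_sub)


def estimate_slice_cells(a1: float, a2: float, c_sub: float) -> float:
    """Extrapolate a slice cell count: cells = C_sub * A1 / A2.

    The sub-area density C_sub/A2 (cells per mm^2) is assumed
    representative of the whole tumor mask of area A1.
    """
    if a1 <= 0 or a2 <= 0:
        raise ValueError("areas must be > 0")
    if a2 > a1 + 1e-12:
        raise ValueError(f"sub-area A2={a2} exceeds tumor area A1={a1}")
    return c_sub * a1 / a2


def tumor_total_cells(slices: list[SliceCount]) -> float:
    """Sum of per-slice estimates over all sections of one tumor."""
    if not slices:
        raise ValueError("need at least one slice")
    return float(sum(s.estimated_cells for s in slices))


@dataclass
class CalibrationModel:
    """Linear calibration cells = slope * signal + intercept."""

    slope: float
    intercept: float
    r_squared: float
    rmse: float
    n: int

    def predict(self, signal: float | np.ndarray):
        return self.slope * np.asarray(signal, dtype=float) + self.intercept


def fit_calibration(pairs: list[tuple[float, float]] | np.ndarray) -> CalibrationModel:
    """Ordinary least squares of cell count on integrated signal.

    ``pairs`` is a sequence of (integrated signal, cells).  Reports R^2 and
    RMSE (root mean squared residual, in the cell-count axis scale).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (signal, cells) pairs")
    sig, cells = arr[:, 0], arr[:, 1]
    if np.any(sig < 0):
        raise ValueError("signals must be non-negative")
    if np.allclose(sig, sig[0]):
        raise ValueError("rank-deficient calibration: all signals equal")
    res = stats.linregress(sig, cells)
    pred = res.slope * sig + res.intercept
    rmse = float(np.sqrt(np.mean((cells - pred) ** 2)))
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        rmse=rmse,
        n=len(sig),
    )


def integrated_signal(recon: ReconVolume, report: ThresholdReport) -> float:
    """Sum of reconstructed voxel values inside the final threshold mask."""
    return float(recon.values[report.mask].sum())


def tumor_volume(recon: ReconVolume, report: ThresholdReport) -> float:
    """Thresholded tumor volume (mm^3): surviving voxels x voxel volume."""
    return float(report.surviving_voxels * recon.grid.voxel_volume)


@dataclass
class TumorTimepointSummary:
    """Per-timepoint quantification of a longitudinal series."""

    timepoint_days: float
    integrated_signal: float
    cell_count: float | None
    volume_mm3: float
    normalized_volume: float
    dox_state: str


def longitudinal_summary(
    series: list[tuple[ReconVolume, ThresholdReport]],
    calibration: CalibrationModel | None = None,
    timepoints: list[float] | None = None,
    dox_states: list[str] | None = None,
) -> list[TumorTimepointSummary]:
    """Quantify a reconstruction series; volumes normalized to the first
    acquisition, cell counts via the calibration when supplied."""
    if len(series) < 2:
        raise ValueError("need at least two timepoints")
    timepoints = timepoints or [float(k) for k in range(len(series))]
    dox_states = dox_states or ["unknown"] * len(series)
    grids = {tuple(r.grid.shape) for r, _ in series}
    if len(grids) > 1:
        raise ValueError(f"inconsistent grids across timepoints: {grids}")
    out: list[TumorTimepointSummary] = []
    v0 = None
    for (recon, report), t, dox in zip(series, timepoints, dox_states):
        sig = integrated_signal(recon, report)
        vol = tumor_volume(recon, report)
        if v0 is None:
            v0 = vol
        out.append(
            TumorTimepointSummary(
                timepoint_days=t,
                integrated_signal=sig,
                cell_count=float(calibration.predict(sig)) if calibration else None,
                volume_mm3=vol,
                normalized_volume=vol / v0 if v0 > 0 else 0.0,
                dox_state=dox,
            )
        )
    return out
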