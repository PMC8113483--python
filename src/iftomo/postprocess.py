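"""Preprocessing and unbiased thresholding of reconstructions.

Three fixed stages, in order:

1. median noise filter — raw values strictly below the global median over
   the measurement vector (all scan positions x included detectors) are
   zeroed, removing the systematic noise floor;
2. centre-detector gate — the zero-separation detector image keeps only
   scan positions between (mean - 2 SD) and the maximum, suppressing the
   diffuse signal halo; and
3. mutual-information threshold scan — the reconstruction is thresholded
   over a grid of candidate values, each masked volume's maximum intensity
   projection is compared with the raw reference image via mutual
   information, and the argmax-MI threshold wins.

The MI reference image defaults to the gated, median-filtered
centre-detector image on the scan grid (config-overridable).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .forward import RawScan

__all__ = [
    "ThresholdReport",
    "median_noise_filter",
    "center_detector_gate",
    "mutual_information",
    "mip",
    "mi_threshold_scan",
    "fixed_fraction_mask",
]

DEFAULT_MI_BINS = 64  # upper cap; bins=None applies the sqrt(N) rule
DEFAULT_N_THRESHOLDS = 50


@dataclass
class ThresholdReport:
    """Record of the threshold-selection pipeline for one reconstruction."""

    thresholds: np.ndarray
    mi_values: np.ndarray
    chosen_threshold: float
    mask: np.ndarray                      # 3D bool, surviving voxels
    surviving_voxels: int
    degenerate: bool = False
    median_cut: float | None = None
    center_mean: float | None = None
    center_sd: float | None = None
    center_lower_bound: float | None = None

    def to_json(self) -> str:
        d = {
            "thresholds": self.thresholds.tolist(),
            "mi_values": self.mi_values.tolist(),
            "chosen_threshold": self.chosen_threshold,
            "surviving_voxels": self.surviving_voxels,
            "degenerate": self.degenerate,
            "median_cut": self.median_cut,
            "center_mean": self.center_mean,
            "center_sd": self.center_sd,
            "center_lower_bound": self.center_lower_bound,
        }
        return json.dumps(d)


def median_noise_filter(scan: RawScan) -> tuple[RawScan, float]:
    """Zero raw values strictly below the global median intensity.

    The median is taken over the measurement vector (all scan positions x
    included detectors — 80,688 points on the full instrument geometry)
    and the cut applied to the whole 4D array, centre detector included.
    Returns the filtered scan and the median used.
    """
    if scan.data.size == 0:
        raise ValueError("empty scan")
    med = float(np.median(scan.to_vector()))
    data = scan.data.copy()
    data[data < med] = 0.0
    meta = dict(scan.meta)
    meta["median_cut"] = med
    return (
        RawScan(data=data, geometry=scan.geometry, power_mw=scan.power_mw,
                seed=scan.seed, meta=meta),
        med,
    )


def center_detector_gate(scan: RawScan) -> tuple[np.ndarray, dict]:
    """Source-signal mask from the zero-separation detector image.

    Keeps scan positions whose centre-detector value lies in
    [mean - 2*SD, max] (population SD over the centre-detector image).
    A zero-variance image passes everything, with a warning.
    Returns the boolean (ny, nx) mask and the gate statistics.
    """
    img = scan.center_detector_image()
    mean = float(img.mean())
    sd = float(img.std())  # population convention
    if sd == 0.0:
        warnings.warn("centre-detector image has zero variance; gate passes all positions")
        mask = np.ones_like(img, dtype=bool)
        lower = mean
    else:
        lower = mean - 2.0 * sd
        mask = (img >= lower) & (img <= img.max())
    stats = {"mean": mean, "sd": sd, "lower_bound": lower}
    return mask, stats


def mutual_information(
    img_a: np.ndarray, img_b: np.ndarray, bins: int | None = DEFAULT_MI_BINS
) -> float:
    """Mutual information (bits) between two equal-shape images.

    Both images are min-max scaled to [0, 1], a ``bins`` x ``bins`` joint
    histogram is formed, and MI = sum p(a,b) log2[p(a,b)/(p(a) p(b))]
    with empty bins contributing zero.

    Default 64 equal-width bins; ``bins=None`` applies the square-root
    rule sqrt(n_pixels) clipped to [8, 64] for very small images.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if bins is None:
        bins = int(np.clip(np.sqrt(a.size), 8, DEFAULT_MI_BINS))
    if bins < 2:
        raise ValueError("need at least 2 bins")

    def _scale(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)

    h, _, _ = np.histogram2d(
        _scale(a).ravel(), _scale(b).ravel(), bins=bins, range=[[0, 1], [0, 1]]
    )
    p = h / h.sum()
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pa @ pb))
    return float(np.nansum(terms))


def mip(volume: np.ndarray) -> np.ndarray:
    """Maximum intensity projection along z of a (nz, ny, nx) volume."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={volume.ndim}")
    return volume.max(axis=0)


def mi_threshold_scan(
    recon_values: np.ndarray,
    reference: np.ndarray,
    thresholds: np.ndarray | None = None,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    bins: int | None = DEFAULT_MI_BINS,
) -> ThresholdReport:
    """Iterative threshold scan maximizing MI against the raw reference.

    For each candidate threshold t the volume is masked to voxels >= t,
    its MIP compared to ``reference`` (resampled to the scan grid by the
    caller) via mutual information, and the argmax-MI threshold returned
    with its mask.  Default thresholds: ``n_thresholds`` linearly spaced
    values in (0, max(recon)].
    """
    vol = np.asarray(recon_values, dtype=float)
    vmax = vol.max()
    if thresholds is None:
        if vmax <= 0:
            thresholds = np.array([0.0])
        else:
            thresholds = np.linspace(0.0, vmax, n_thresholds + 1)[1:]
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold list")
    ref = np.asarray(reference, dtype=float)
    mi_vals = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        masked = np.where(vol >= t, vol, 0.0)
        mi_vals[i] = mutual_information(mip(masked), ref, bins=bins)
    best = int(np.argmax(mi_vals))
    chosen = float(thresholds[best])
    mask = vol >= chosen
    degenerate = not mask.any()
    if degenerate:
        warnings.warn("threshold scan is degenerate: no voxel survives any threshold")
    return ThresholdReport(
        thresholds=thresholds,
        mi_values=mi_vals,
        chosen_threshold=chosen,
        mask=mask,
        surviving_voxels=int(mask.sum()),
        degenerate=degenerate,
    )


def resample_to_grid(
    image: np.ndarray,
    geometry,
    grid,
) -> np.ndarray:
    """Bilinearly resample a scan-grid image onto voxel-centre lateral
    coordinates, so it can be compared with a reconstruction MIP.

    Scan positions sit at multiples of the scan step from the origin;
    voxel centres are offset by half a voxel, so the two lattices differ
    even at matched pitch.
    """
    from scipy.interpolate import RegularGridInterpolator

    ny, nx = geometry.scan_shape
    sy = np.arange(ny) * geometry.scan_step
    sx = np.arange(nx) * geometry.scan_step
    interp = RegularGridInterpolator(
        (sy, sx), np.asarray(image, dtype=float), bounds_error=False, fill_value=0.0
    )
    xs, ys, _zs = grid.centers()
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    return interp(np.column_stack([Y.ravel(), X.ravel()])).reshape(len(ys), len(xs))


def fixed_fraction_mask(recon_values: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Fixed-percentage threshold baseline (e.g. 50% of max), for comparison
    against the MI-based rule only."""
    vol = np.asarray(recon_values, dtype=float)
    return vol >= fraction * vol.max()
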