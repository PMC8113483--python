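"""Physical coordinate system, voxel grid, scan raster and detector array.

Conventions used throughout the package
---------------------------------------
* Right-handed coordinates, all lengths in millimetres, ``z`` positive into
  the tissue, origin at the top-left corner of the scan area on the tissue
  surface (``z = 0``).
* Scan raster order is row-major with ``x`` fastest: position index
  ``k = iy * nx + ix``.  This order defines the layout of the flattened
  measurement vector ``b`` and of every Jacobian row block.
* Voxel indexing is 0-based and a voxel's coordinate is its centre;
  volumes are stored as ``(nz, ny, nx)`` arrays (one z-slice per page when
  written to TIFF).
* Detector identifiers are ``(row, col)`` pairs on the superpixel grid;
  detector offsets are relative to the current source position.  The
  zero-separation (centre) detector is excluded from the inversion
  measurement vector by default but kept in the raw 4D data, where the
  thresholding pipeline uses it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "OpticalProperties",
    "VoxelGrid",
    "ScanGeometry",
    "build_scan_grid",
    "detector_offsets",
    "measurement_size",
    "raw_dataset_bytes",
    "exposure_margin",
]

#: Default maximum reconstruction depth (mm).  Deeper voxels are poorly
#: constrained at the available source-detector separations.
MAX_RECON_DEPTH_MM = 2.0

_INTEGRALITY_TOL = 1e-9


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a homogeneous tissue slab.

    Parameters
    ----------
    mu_s : float
        Scattering coefficient (mm^-1), > 0.
    mu_a : float
        Absorption coefficient (mm^-1), >= 0.
    g : float
        Scattering anisotropy (mean cosine of the Henyey-Greenstein phase
        function), in (-1, 1].
    n : float
        Refractive index, >= 1.
    """

    mu_s: float = 20.0
    mu_a: float = 0.1
    g: float = 0.85
    n: float = 1.37

    def __post_init__(self) -> None:
        if not self.mu_s > 0:
            raise ValueError(f"mu_s must be > 0, got {self.mu_s}")
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"g must be in [-1, 1], got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not self.mu_s * (1.0 - self.g) > 0:
            raise ValueError(
                f"reduced scattering mu_s*(1-g) must be > 0 "
                f"(mu_s={self.mu_s}, g={self.g})"
            )

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient mu_s' = mu_s * (1 - g) (mm^-1)."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(3 mu_a (mu_a + mu_s')) (mm^-1)."""
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_reduced))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalProperties":
        return cls(**d)


@dataclass(frozen=True)
class VoxelGrid:
    """Reconstruction voxel grid over the slab.

    ``extent`` is the physical (x, y, z) size in mm and must be an integer
    multiple of ``voxel_size`` per axis.  The z extent may not exceed
    ``max_depth`` (reconstruction depth limit).
    """

    extent: tuple[float, float, float]
    voxel_size: tuple[float, float, float] = (0.25, 0.25, 0.1)
    max_depth: float = MAX_RECON_DEPTH_MM

    def __post_init__(self) -> None:
        for ext, vox, ax in zip(self.extent, self.voxel_size, "xyz"):
            if vox <= 0 or ext <= 0:
                raise ValueError(f"extent and voxel size must be > 0 on axis {ax}")
            ratio = ext / vox
            if abs(ratio - round(ratio)) > _INTEGRALITY_TOL * max(1.0, ratio):
                raise ValueError(
                    f"extent {ext} mm is not divisible by voxel size {vox} mm "
                    f"on axis {ax}"
                )
        if self.extent[2] > self.max_depth + _INTEGRALITY_TOL:
            raise ValueError(
                f"z extent {self.extent[2]} mm exceeds the maximum "
                f"reconstruction depth {self.max_depth} mm"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        """Voxel counts as (nz, ny, nx) — the array storage order."""
        nx = round(self.extent[0] / self.voxel_size[0])
        ny = round(self.extent[1] / self.voxel_size[1])
        nz = round(self.extent[2] / self.voxel_size[2])
        return (nz, ny, nx)

    @property
    def n_voxels(self) -> int:
        nz, ny, nx = self.shape
        return nz * ny * nx

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel (mm^3)."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates per axis: arrays (xs, ys, zs)."""
        nz, ny, nx = self.shape
        dx, dy, dz = self.voxel_size
        xs = (np.arange(nx) + 0.5) * dx
        ys = (np.arange(ny) + 0.5) * dy
        zs = (np.arange(nz) + 0.5) * dz
        return xs, ys, zs

    def to_dict(self) -> dict:
        return {
            "extent": list(self.extent),
            "voxel_size": list(self.voxel_size),
            "max_depth": self.max_depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGrid":
        return cls(
            extent=tuple(d["extent"]),
            voxel_size=tuple(d["voxel_size"]),
            max_depth=d.get("max_depth", MAX_RECON_DEPTH_MM),
        )


def build_scan_grid(fov: tuple[float, float], step: float) -> np.ndarray:
    """Raster of source positions covering ``fov`` at pitch ``step``.

    Returns an ``(N, 2)`` array of (x, y) surface coordinates in raster
    order (row-major, x fastest).  Per axis the number of positions is
    ``fov/step + 1`` (fence-post counting), so a 10 x 10 mm field at
    0.25 mm pitch yields 41 x 41 = 1681 positions.

    A zero-extent axis degenerates to a single position at the origin.
    """
    if step <= 0:
        raise ValueError(f"scan step must be > 0, got {step}")
    counts = []
    for ext, ax in zip(fov, "xy"):
        if ext < 0:
            raise ValueError(f"fov must be >= 0 on axis {ax}, got {ext}")
        ratio = ext / step
        if abs(ratio - round(ratio)) > _INTEGRALITY_TOL * max(1.0, ratio):
            raise ValueError(
                f"fov {ext} mm is not an integer multiple of scan step "
                f"{step} mm on axis {ax}"
            )
        counts.append(int(round(ratio)) + 1)
    nx, ny = counts
    xs = np.arange(nx) * step
    ys = np.arange(ny) * step
    gx, gy = np.meshgrid(xs, ys)  # row-major: y slow, x fast
    return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class ScanGeometry:
    """Raster scan plus detector superpixel array.

    The detector grid is centred on the instantaneous source position
    (de-scanned detection); ``detector_pitch`` is the superpixel spacing in
    sample space.  ``excluded_detectors`` are omitted from the flattened
    measurement vector; by default this is the centre (zero source-detector
    separation) detector, reconciling the 7 x 7 = 49 superpixels with the
    48 detectors entering the inversion.
    """

    fov: tuple[float, float] = (10.0, 10.0)
    scan_step: float = 0.25
    detector_grid: tuple[int, int] = (7, 7)
    detector_pitch: float = 0.5
    max_sd_separation: float = 3.5
    exclude_center: bool = True
    excluded_detectors: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rows, cols = self.detector_grid
        if rows % 2 == 0 or cols % 2 == 0:
            raise ValueError(
                f"detector grid must have odd dimensions so that a centre "
                f"(zero-separation) detector exists, got {self.detector_grid}"
            )
        if self.excluded_detectors is None:
            excl = frozenset({self.center_detector_index}) if self.exclude_center else frozenset()
            object.__setattr__(self, "excluded_detectors", excl)
        else:
            object.__setattr__(
                self, "excluded_detectors", frozenset(map(tuple, self.excluded_detectors))
            )
        build_scan_grid(self.fov, self.scan_step)  # validates integrality

    @property
    def center_detector_index(self) -> tuple[int, int]:
        rows, cols = self.detector_grid
        return (rows // 2, cols // 2)

    @property
    def scan_shape(self) -> tuple[int, int]:
        """(n_scan_y, n_scan_x)."""
        nx = int(round(self.fov[0] / self.scan_step)) + 1
        ny = int(round(self.fov[1] / self.scan_step)) + 1
        return (ny, nx)

    @property
    def n_scan_positions(self) -> int:
        ny, nx = self.scan_shape
        return ny * nx

    def scan_positions(self) -> np.ndarray:
        return build_scan_grid(self.fov, self.scan_step)

    def included_detectors(self) -> list[tuple[int, int]]:
        """Detector ids entering the measurement vector, row-major order."""
        rows, cols = self.detector_grid
        return [
            (r, c)
            for r in range(rows)
            for c in range(cols)
            if (r, c) not in self.excluded_detectors
        ]

    @property
    def n_detectors(self) -> int:
        rows, cols = self.detector_grid
        return rows * cols - len(self.excluded_detectors)

    def to_dict(self) -> dict:
        return {
            "fov": list(self.fov),
            "scan_step": self.scan_step,
            "detector_grid": list(self.detector_grid),
            "detector_pitch": self.detector_pitch,
            "max_sd_separation": self.max_sd_separation,
            "exclude_center": self.exclude_center,
            "excluded_detectors": sorted(list(t) for t in self.excluded_detectors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            fov=tuple(d["fov"]),
            scan_step=d["scan_step"],
            detector_grid=tuple(d["detector_grid"]),
            detector_pitch=d["detector_pitch"],
            max_sd_separation=d.get("max_sd_separation", 3.5),
            exclude_center=d.get("exclude_center", True),
            excluded_detectors=frozenset(tuple(t) for t in d["excluded_detectors"])
            if "excluded_detectors" in d
            else None,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ScanGeometry":
        return cls.from_dict(json.loads(s))


def detector_offsets(geometry: ScanGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-detector (dx, dy) offsets from the source, in detector row-major order.

    Returns ``(offsets, separations, within_limit)`` where ``offsets`` is a
    ``(K, 2)`` array over all K superpixels (including excluded ones),
    ``separations`` the Euclidean source-detector separations and
    ``within_limit`` a boolean flag marking offsets not exceeding
    ``max_sd_separation``.
    """
    rows, cols = geometry.detector_grid
    if rows % 2 == 0 or cols % 2 == 0:
        raise ValueError("detector grid must be odd-sized (no centre detector)")
    r0, c0 = geometry.center_detector_index
    offs = np.array(
        [
            [(c - c0) * geometry.detector_pitch, (r - r0) * geometry.detector_pitch]
            for r in range(rows)
            for c in range(cols)
        ]
    )
    sep = np.hypot(offs[:, 0], offs[:, 1])
    within = sep <= geometry.max_sd_separation + 1e-12
    return offs, sep, within


def measurement_size(geometry: ScanGeometry) -> int:
    """Length m of the flattened measurement vector.

    m = (scan positions) x (included detectors); the instrument geometry
    (41 x 41 positions, 48 detectors) gives 80,688 data points.
    """
    return geometry.n_scan_positions * geometry.n_detectors


def raw_dataset_bytes(
    n_frames: int, frame_shape: tuple[int, int], bit_depth: int
) -> tuple[int, int]:
    """Raw-frame storage accounting: (bytes, decimal megabytes rounded).

    1681 frames of 512 x 512 16-bit pixels occupy 881,266,688 bytes
    (~881 MB), one frame per scan position.
    """
    if n_frames < 0 or any(s <= 0 for s in frame_shape) or bit_depth <= 0:
        raise ValueError("frame counts, shape and bit depth must be positive")
    if bit_depth % 8 != 0:
        raise ValueError(f"bit depth must be a multiple of 8, got {bit_depth}")
    n_bytes = n_frames * frame_shape[0] * frame_shape[1] * (bit_depth // 8)
    return n_bytes, round(n_bytes / 1e6)


def exposure_margin(mpe_j_per_cm2: float, max_density_mj_per_cm2: float) -> tuple[float, int]:
    """Safety margin of the maximum permissible exposure over the applied dose.

    Returns ``(ratio, nearest_int)`` after harmonizing J/cm^2 against
    mJ/cm^2; e.g. a 1.3 J/cm^2 MPE against a worst-case 150 mJ/cm^2
    energy density is an ~8.7x (rounds to 9x) margin.
    """
    if mpe_j_per_cm2 <= 0 or max_density_mj_per_cm2 <= 0:
        raise ValueError("exposure values must be > 0")
    ratio = mpe_j_per_cm2 / (max_density_mj_per_cm2 * 1e-3)
    return ratio, round(ratio)
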