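"""Jacobian (sensitivity) assembly and synthetic measurement generation.

The emission model is Born-linear: the signal at source s / detector d is

    A[(s, d), v] = G_x(r_s -> r_v) * G_m(r_v -> r_d) * V_voxel

with excitation and (adjoint, by reciprocity) emission Green's functions
from either transport engine.  Excitation and emission share one set of
optical properties (their measured difference is <5% for this system).

Measurement-vector layout (the single documented flattening rule): scan
positions in raster order (row-major, x fastest), and within each position
the included detectors in detector-grid row-major order.  The centre
detector is excluded from b by default but present in the 4D RawScan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    OpticalProperties,
    ScanGeometry,
    VoxelGrid,
    detector_offsets,
    measurement_size,
)
from .transport import diffusion_green, run_mc

__all__ = [
    "JacobianModel",
    "RawScan",
    "assemble_jacobian",
    "forward_project",
    "add_noise",
    "normalize_by_power",
]


@dataclass
class JacobianModel:
    """m x n sensitivity matrix linking voxel density to measurements."""

    matrix: np.ndarray
    geometry: ScanGeometry
    grid: VoxelGrid
    engine: str = "diffusion"
    photons: int = 0
    seed: int = 0
    detectors: list[tuple[int, int]] = field(default_factory=list)
    _gram: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        m, n = self.matrix.shape
        if n != self.grid.n_voxels:
            raise ValueError(f"Jacobian has {n} columns but grid has {self.grid.n_voxels} voxels")
        if m != self.geometry.n_scan_positions * len(self.detectors):
            raise ValueError("Jacobian row count inconsistent with geometry/detector list")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def gram(self) -> np.ndarray:
        """A^T A, computed once and cached; reused across lambda candidates."""
        if self._gram is None:
            self._gram = self.matrix.T @ self.matrix
        return self._gram

    def without_excluded(self) -> "JacobianModel":
        """Drop rows of detectors excluded from the inversion vector."""
        keep = [i for i, d in enumerate(self.detectors) if d not in self.geometry.excluded_detectors]
        if len(keep) == len(self.detectors):
            return self
        n_det = len(self.detectors)
        rows = self.matrix.reshape(self.geometry.n_scan_positions, n_det, -1)[:, keep, :]
        return JacobianModel(
            matrix=rows.reshape(-1, self.grid.n_voxels),
            geometry=self.geometry,
            grid=self.grid,
            engine=self.engine,
            photons=self.photons,
            seed=self.seed,
            detectors=[self.detectors[i] for i in keep],
        )


@dataclass
class RawScan:
    """4D raw data: (scan_y, scan_x, det_row, det_col) intensities."""

    data: np.ndarray
    geometry: ScanGeometry
    power_mw: float = 1.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.geometry.scan_shape + tuple(self.geometry.detector_grid)
        if self.data.shape != expected:
            raise ValueError(f"raw data shape {self.data.shape} != geometry {expected}")
        if np.any(self.data < 0):
            raise ValueError("raw intensities must be >= 0")

    def to_vector(self) -> np.ndarray:
        """Flatten to the m-vector b over included detectors (documented order)."""
        ny, nx = self.geometry.scan_shape
        flat = self.data.reshape(ny * nx, -1)
        rows, cols = self.geometry.detector_grid
        idx = [r * cols + c for (r, c) in self.geometry.included_detectors()]
        return flat[:, idx].ravel()

    @classmethod
    def from_vector(
        cls,
        b: np.ndarray,
        geometry: ScanGeometry,
        center_image: np.ndarray | None = None,
        **kwargs,
    ) -> "RawScan":
        """Inverse of :meth:`to_vector`; excluded detectors filled from
        ``center_image`` (scan-grid shaped) or zero."""
        ny, nx = geometry.scan_shape
        rows, cols = geometry.detector_grid
        if b.size != measurement_size(geometry):
            raise ValueError(f"vector length {b.size} != measurement size {measurement_size(geometry)}")
        data = np.zeros((ny * nx, rows * cols))
        idx = [r * cols + c for (r, c) in geometry.included_detectors()]
        data[:, idx] = b.reshape(ny * nx, len(idx))
        if center_image is not None:
            r0, c0 = geometry.center_detector_index
            data[:, r0 * cols + c0] = np.asarray(center_image).ravel()
        return cls(data=data.reshape(ny, nx, rows, cols), geometry=geometry, **kwargs)

    def center_detector_image(self) -> np.ndarray:
        """The zero-separation detector arranged on the (ny, nx) scan grid."""
        r0, c0 = self.geometry.center_detector_index
        return self.data[:, :, r0, c0]


_GREEN_SUBSAMPLES = 2  # sub-voxel quadrature points per axis


def _surface_green_table(
    props: OpticalProperties,
    grid: VoxelGrid,
    surface_points: np.ndarray,
    engine: str,
    photons: int,
    seed: int,
) -> np.ndarray:
    """Green's function from each surface point to every voxel, (P, n).

    The diffusion Green's function is averaged over a small sub-voxel
    quadrature rather than evaluated at the centre only: voxel-mean fluence
    is what the Monte-Carlo engine scores, and near the source the
    difference is substantial on coarse voxels.
    """
    xs, ys, zs = grid.centers()
    out = np.empty((len(surface_points), grid.n_voxels))
    if engine == "diffusion":
        ss = _GREEN_SUBSAMPLES
        dx, dy, dz = grid.voxel_size
        offs = (np.arange(ss) + 0.5) / ss - 0.5
        sub = np.array(
            [(ox * dx, oy * dy, oz * dz) for ox in offs for oy in offs for oz in offs]
        )
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        for i, (px, py) in enumerate(surface_points):
            acc = np.zeros(grid.n_voxels)
            for off in sub:
                acc += diffusion_green(props, (px, py, 0.0), centers + off)
            out[i] = acc / len(sub)
    else:
        for i, (px, py) in enumerate(surface_points):
            fm = run_mc(props, grid, (px, py), photons=photons, seed=(seed + i) % (2**31 - 1))
            out[i] = fm.values.ravel()
    return out


def assemble_jacobian(
    props: OpticalProperties,
    geometry: ScanGeometry,
    grid: VoxelGrid,
    engine: str = "diffusion",
    photons: int = 10**5,
    seed: int = 0,
    include_excluded: bool = False,
    dtype=np.float64,
) -> JacobianModel:
    """Assemble the sensitivity matrix for a homogeneous slab.

    Exploits lateral translation invariance: one excitation Green's
    function per scan position and one adjoint (emission) run per *unique*
    detector surface position, instead of one transport run per
    (source, detector) pair.  Detectors beyond ``max_sd_separation`` are
    dropped.  ``include_excluded=True`` keeps the centre detector's rows —
    used when simulating full raw scans, never for inversion.
    """
    if engine not in ("diffusion", "mc"):
        raise ValueError(f"unknown engine {engine!r}")
    if grid.extent[2] > grid.max_depth + 1e-9:
        raise ValueError("grid deeper than the maximum reconstruction depth")

    sources = geometry.scan_positions()
    offs, sep, within = detector_offsets(geometry)
    rows, cols = geometry.detector_grid
    all_ids = [(r, c) for r in range(rows) for c in range(cols)]
    det_ids = []
    for k, d in enumerate(all_ids):
        if not within[k]:
            continue  # beyond max S-D separation
        if not include_excluded and d in geometry.excluded_detectors:
            continue
        det_ids.append((k, d))

    # excitation table: one column block per scan position
    G_src = _surface_green_table(props, grid, sources, engine, photons, seed)

    # unique detector surface positions (lattice union of source + offset)
    det_pos = (sources[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    uniq, inverse = np.unique(np.round(det_pos / 1e-6).astype(np.int64), axis=0, return_inverse=True)
    uniq_pos = uniq * 1e-6
    G_det = _surface_green_table(props, grid, uniq_pos, engine, photons, seed + 10_000)
    inverse = inverse.reshape(len(sources), len(offs))

    n = grid.n_voxels
    m = len(sources) * len(det_ids)
    A = np.empty((m, n), dtype=dtype)
    vv = grid.voxel_volume
    row = 0
    for si in range(len(sources)):
        gs = G_src[si]
        for k, _d in det_ids:
            A[row] = (gs * G_det[inverse[si, k]] * vv).astype(dtype, copy=False)
            row += 1
    return JacobianModel(
        matrix=A,
        geometry=geometry,
        grid=grid,
        engine=engine,
        photons=photons if engine == "mc" else 0,
        seed=seed,
        detectors=[d for _k, d in det_ids],
    )


def forward_project(model: JacobianModel, x: np.ndarray) -> np.ndarray:
    """Born projection b = A x for a density map on the model's grid."""
    x = np.asarray(x)
    if x.shape == model.grid.shape:
        x = x.ravel()
    if x.shape != (model.grid.n_voxels,):
        raise ValueError(
            f"density map shape {x.shape} does not match the Jacobian grid "
            f"{model.grid.shape}"
        )
    return model.matrix @ x


def add_noise(
    b: np.ndarray,
    model: str = "gaussian_relative",
    level: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Add measurement noise to a projection.

    ``gaussian_relative`` adds N(0, (level * b_i)^2), clipped at zero.
    ``shot`` draws Poisson counts with ``level`` expected counts at the
    maximum of b (and rescales back), emulating a photon budget.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    rng = np.random.default_rng(seed)
    b = np.asarray(b, dtype=float)
    if model == "gaussian_relative":
        if level == 0:
            return b.copy()
        return np.clip(b + rng.normal(scale=level * np.abs(b)), 0.0, None)
    if model == "shot":
        if level == 0:
            return b.copy()
        bmax = b.max()
        if bmax <= 0:
            return b.copy()
        scale = level / bmax
        return rng.poisson(b * scale).astype(float) / scale
    raise ValueError(f"unknown noise model {model!r}")


def normalize_by_power(scan: RawScan, power_mw: float) -> RawScan:
    """Divide intensities by the excitation power (mW) to unit-power scale."""
    if power_mw <= 0:
        raise ValueError(f"power must be > 0, got {power_mw}")
    meta = dict(scan.meta)
    meta["power_normalized"] = True
    return RawScan(
        data=scan.data / power_mw,
        geometry=scan.geometry,
        power_mw=1.0,
        seed=scan.seed,
        meta=meta,
    )
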