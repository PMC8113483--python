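"""Digital phantoms: fluorescent inclusions in a scattering slab.

The phantoms emulate the bench objects used to characterize mesoscopic
fluorescence tomography systems: sub-voxel fluorescent microspheres for
point-spread checks, fluorescein-filled capillary tubes at decade-spaced
concentrations for linearity, and Gaussian-lobed "tumor" blobs whose
integrated cell count follows a growth/regression schedule.

Densities are in arbitrary units per mm^3 (proportional to fluorophore
concentration); rasterized maps store the mean density per voxel so that
``sum(map) * voxel_volume`` equals the analytic inclusion integral up to
quantization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import OpticalProperties, VoxelGrid

__all__ = [
    "Inclusion",
    "PhantomScene",
    "TumorTimeSeries",
    "make_bead_phantom",
    "make_tube_phantom",
    "make_blob_phantom",
    "make_tumor_series",
    "CELL_DIAMETER_MM",
    "CELL_VOLUME_MM3",
]

#: Nominal tumor-cell diameter (mm), midpoint of the 10-15 um range.
CELL_DIAMETER_MM = 0.0125
#: Nominal single-cell volume (mm^3).
CELL_VOLUME_MM3 = (4.0 / 3.0) * math.pi * (CELL_DIAMETER_MM / 2.0) ** 3

_SUPERSAMPLE = 8  # sub-samples per voxel axis when rasterizing hard shapes


@dataclass(frozen=True)
class Inclusion:
    """A fluorescent inclusion inside the slab.

    ``shape`` is one of ``sphere`` (radius), ``cylinder`` (radius + length,
    axis along x) or ``blob`` (isotropic Gaussian of width ``sigma``
    truncated at half maximum).  ``density`` is fluorophore density in
    a.u./mm^3 (for tumor blobs, proportional to cells per volume).
    """

    shape: str
    center: tuple[float, float, float]
    density: float
    radius: float = 0.0
    length: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cylinder", "blob"):
            raise ValueError(f"unknown inclusion shape {self.shape!r}")
        if self.density < 0:
            raise ValueError("density must be >= 0")

    def analytic_integral(self) -> float:
        """Integrated density (a.u.) of the analytic shape."""
        if self.shape == "sphere":
            return self.density * (4.0 / 3.0) * math.pi * self.radius**3
        if self.shape == "cylinder":
            return self.density * math.pi * self.radius**2 * self.length
        # Gaussian truncated at half maximum: integrate exp(-r^2/2s^2) over
        # r <= s*sqrt(2 ln 2), in closed form via the radial integral.
        s = self.sigma
        rmax = s * math.sqrt(2.0 * math.log(2.0))
        # int_0^rmax 4 pi r^2 exp(-r^2/2s^2) dr
        a = rmax / (s * math.sqrt(2.0))
        integral = (
            4.0
            * math.pi
            * s**3
            * (math.sqrt(math.pi / 2.0) * math.erf(a) - (rmax / s) * math.exp(-(a**2)))
        )
        return self.density * integral

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, dtype=float)
        if self.shape == "sphere":
            half = np.array([self.radius] * 3)
        elif self.shape == "cylinder":
            half = np.array([self.length / 2.0, self.radius, self.radius])
        else:
            half = np.array([self.sigma * math.sqrt(2.0 * math.log(2.0))] * 3)
        return c - half, c + half


@dataclass
class PhantomScene:
    """Optical slab plus fluorescent inclusions on a reconstruction grid."""

    slab: OpticalProperties
    thickness: float
    grid: VoxelGrid
    inclusions: list[Inclusion] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        for inc in self.inclusions:
            lo, hi = inc.bounding_box()
            if lo[2] < -1e-9 or hi[2] > self.thickness + 1e-9:
                raise ValueError(
                    f"inclusion at z={inc.center[2]} mm extends outside the "
                    f"slab (thickness {self.thickness} mm)"
                )

    def ground_truth(self) -> np.ndarray:
        """Rasterize all inclusions to a (nz, ny, nx) density map (a.u./mm^3)."""
        vol = np.zeros(self.grid.shape, dtype=np.float64)
        for inc in self.inclusions:
            _rasterize(inc, self.grid, vol)
        return vol

    def total_integral(self) -> float:
        """Sum of analytic inclusion integrals (a.u.)."""
        return sum(inc.analytic_integral() for inc in self.inclusions)

    def metadata(self) -> dict:
        return {
            "label": self.label,
            "thickness": self.thickness,
            "slab": self.slab.to_dict(),
            "grid": self.grid.to_dict(),
            "inclusions": [
                {
                    "shape": i.shape,
                    "center": list(i.center),
                    "density": i.density,
                    "radius": i.radius,
                    "length": i.length,
                    "sigma": i.sigma,
                }
                for i in self.inclusions
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.metadata(), sort_keys=True)


def _rasterize(inc: Inclusion, grid: VoxelGrid, out: np.ndarray) -> None:
    dx, dy, dz = grid.voxel_size
    nz, ny, nx = grid.shape
    xs, ys, zs = grid.centers()
    lo, hi = inc.bounding_box()

    if inc.shape == "blob":
        # smooth profile: evaluate at voxel centres, truncate at half max
        ix = np.where((xs >= lo[0] - dx) & (xs <= hi[0] + dx))[0]
        iy = np.where((ys >= lo[1] - dy) & (ys <= hi[1] + dy))[0]
        iz = np.where((zs >= lo[2] - dz) & (zs <= hi[2] + dz))[0]
        if ix.size == 0 or iy.size == 0 or iz.size == 0:
            return
        X, Y, Z = np.meshgrid(xs[ix], ys[iy], zs[iz], indexing="ij")
        r2 = (
            (X - inc.center[0]) ** 2
            + (Y - inc.center[1]) ** 2
            + (Z - inc.center[2]) ** 2
        )
        prof = inc.density * np.exp(-r2 / (2.0 * inc.sigma**2))
        prof[prof < 0.5 * inc.density] = 0.0
        out[np.ix_(iz, iy, ix)] += prof.transpose(2, 1, 0)
        return

    extent = hi - lo
    if np.all(extent < np.array([dx, dy, dz])):
        # sub-voxel inclusion: deposit the analytic integral as a point mass
        ix = min(max(int(inc.center[0] / dx), 0), nx - 1)
        iy = min(max(int(inc.center[1] / dy), 0), ny - 1)
        iz = min(max(int(inc.center[2] / dz), 0), nz - 1)
        out[iz, iy, ix] += inc.analytic_integral() / grid.voxel_volume
        return

    # hard-edged shape: supersampled occupancy fractions over the bbox voxels
    i0 = np.maximum(np.floor(lo / [dx, dy, dz]).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / [dx, dy, dz]).astype(int), [nx, ny, nz])
    ss = _SUPERSAMPLE
    sub = (np.arange(ss) + 0.5) / ss
    for izv in range(i0[2], i1[2]):
        for iyv in range(i0[1], i1[1]):
            for ixv in range(i0[0], i1[0]):
                px = (ixv + sub) * dx
                py = (iyv + sub) * dy
                pz = (izv + sub) * dz
                X, Y, Z = np.meshgrid(px, py, pz, indexing="ij")
                if inc.shape == "sphere":
                    inside = (
                        (X - inc.center[0]) ** 2
                        + (Y - inc.center[1]) ** 2
                        + (Z - inc.center[2]) ** 2
                    ) <= inc.radius**2
                else:  # cylinder along x
                    inside = (
                        (np.abs(X - inc.center[0]) <= inc.length / 2.0)
                        & (
                            (Y - inc.center[1]) ** 2 + (Z - inc.center[2]) ** 2
                            <= inc.radius**2
                        )
                    )
                frac = inside.mean()
                if frac > 0:
                    out[izv, iyv, ixv] += inc.density * frac


def _default_grid(extent_xy: float = 5.0, depth: float = 2.0) -> VoxelGrid:
    return VoxelGrid(extent=(extent_xy, extent_xy, depth), voxel_size=(0.25, 0.25, 0.1))


def make_bead_phantom(
    depth: float = 0.75,
    diameter_um: float = 50.0,
    separation: float = 1.0,
    *,
    grid: VoxelGrid | None = None,
    slab: OpticalProperties | None = None,
    thickness: float = 2.0,
    density: float = 100.0,
) -> PhantomScene:
    """Two sub-voxel fluorescent microspheres for resolution checks.

    Beads of ``diameter_um`` (default 50 um, well below a voxel) are placed
    at the stated depth, laterally centred in the field and separated along
    x by ``separation`` mm.  Zero separation degenerates to a single merged
    source of doubled integrated density.
    """
    grid = grid or _default_grid()
    slab = slab or OpticalProperties()
    r = diameter_um / 2.0 * 1e-3
    if depth + r > thickness or depth - r < 0:
        raise ValueError(f"bead at depth {depth} mm lies outside the slab")
    cx, cy = grid.extent[0] / 2.0, grid.extent[1] / 2.0
    centers = [(cx - separation / 2.0, cy, depth), (cx + separation / 2.0, cy, depth)]
    incs = [
        Inclusion(shape="sphere", center=c, density=density, radius=r) for c in centers
    ]
    return PhantomScene(
        slab=slab, thickness=thickness, grid=grid, inclusions=incs,
        label=f"beads d={diameter_um}um z={depth}mm sep={separation}mm",
    )


#: Capillary tube volume (uL == mm^3) and inner radius (mm).
TUBE_VOLUME_MM3 = 3.0
TUBE_RADIUS_MM = 0.5


def make_tube_phantom(
    concentration_uM: float,
    depth: float = 1.3,
    *,
    grid: VoxelGrid | None = None,
    slab: OpticalProperties | None = None,
    thickness: float = 2.0,
) -> PhantomScene:
    """Fluorescein-filled capillary in a scattering (Intralipid-like) tank.

    A ~3 uL cylinder (0.5 mm inner radius, length set by volume) lies along
    x at the stated depth; density in a.u./mm^3 equals the concentration in
    uM, so the 25 / 2.5 / 0.25 uM standard fixtures have exact 100:10:1
    ground-truth density ratios.
    """
    if concentration_uM < 0:
        raise ValueError("concentration must be >= 0")
    grid = grid or _default_grid()
    slab = slab or OpticalProperties()
    length = TUBE_VOLUME_MM3 / (math.pi * TUBE_RADIUS_MM**2)
    cx, cy = grid.extent[0] / 2.0, grid.extent[1] / 2.0
    incs = []
    if concentration_uM > 0:
        incs.append(
            Inclusion(
                shape="cylinder",
                center=(cx, cy, depth),
                density=concentration_uM,
                radius=TUBE_RADIUS_MM,
                length=min(length, grid.extent[0]),
            )
        )
    return PhantomScene(
        slab=slab, thickness=thickness, grid=grid, inclusions=incs,
        label=f"tube {concentration_uM}uM z={depth}mm",
    )


def make_blob_phantom(
    center: tuple[float, float, float] = (2.5, 2.5, 1.0),
    sigma: float = 0.4,
    peak_density: float = 100.0,
    *,
    grid: VoxelGrid | None = None,
    slab: OpticalProperties | None = None,
    thickness: float = 2.0,
) -> PhantomScene:
    """Single Gaussian tumor-like blob, truncated at half maximum."""
    grid = grid or _default_grid()
    slab = slab or OpticalProperties()
    inc = Inclusion(shape="blob", center=center, density=peak_density, sigma=sigma)
    return PhantomScene(
        slab=slab, thickness=thickness, grid=grid, inclusions=[inc],
        label=f"blob sigma={sigma}mm z={center[2]}mm",
    )


@dataclass
class TumorTimeSeries:
    """Longitudinal series of tumor scenes with exact ground-truth counts."""

    timepoints: list[float]          # days
    scenes: list[PhantomScene]
    true_cell_counts: list[float]
    dox_states: list[str]            # "on" (growth) / "off" (regression)

    def __post_init__(self) -> None:
        if not all(b > a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")


def cells_from_density_map(density_map: np.ndarray, grid: VoxelGrid) -> float:
    """Convert an a.u./mm^3 density map to a cell count.

    For tumor phantoms density is a packed-cell volume fraction (mm^3 of
    labelled cell material per mm^3 of tissue), so
    cells = sum(density) * voxel_volume / cell_volume with the nominal
    12.5 um cell diameter.
    """
    return float(density_map.sum() * grid.voxel_volume / CELL_VOLUME_MM3)


def make_tumor_series(
    growth_fold: float = 10.0,
    n_timepoints: int = 6,
    seed: int = 0,
    *,
    baseline_cells: float = 1e5,
    grid: VoxelGrid | None = None,
    slab: OpticalProperties | None = None,
    thickness: float = 2.0,
    interval_days: float = 7.0,
) -> TumorTimeSeries:
    """Growth/regression series under an inducible-oncogene schedule.

    During the induction (DoX-on) phase the integrated cell count rises
    geometrically from ``baseline_cells`` to ``growth_fold`` times it; after
    withdrawal (DoX-off) it decays back to baseline.  Blob shapes are sums
    of three Gaussian lobes whose centres are perturbed per timepoint by a
    seeded RNG; each scene's density map is rescaled so its integrated
    count matches the schedule exactly.
    """
    if growth_fold <= 0:
        raise ValueError("growth_fold must be > 0")
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    grid = grid or _default_grid()
    slab = slab or OpticalProperties()
    rng = np.random.default_rng(seed)

    n_on = max(2, (n_timepoints + 1) // 2)
    n_off = n_timepoints - n_on
    counts = list(baseline_cells * growth_fold ** (np.arange(n_on) / (n_on - 1)))
    if n_off > 0:
        # geometric decay back to baseline
        decay = (
            baseline_cells
            * growth_fold ** (1.0 - (np.arange(1, n_off + 1) / n_off))
        )
        counts += list(decay)
    dox = ["on"] * n_on + ["off"] * n_off

    cx, cy = grid.extent[0] / 2.0, grid.extent[1] / 2.0
    base_centers = np.array([[cx, cy, 1.0], [cx + 0.5, cy - 0.3, 0.9], [cx - 0.4, cy + 0.4, 1.1]])
    base_sigmas = np.array([0.45, 0.3, 0.35])

    scenes: list[PhantomScene] = []
    true_counts: list[float] = []
    for k, target in enumerate(counts):
        jitter = rng.normal(scale=0.08, size=base_centers.shape)
        centers = base_centers + jitter
        centers[:, 2] = np.clip(centers[:, 2], 0.4, thickness - 0.4)
        centers[:, 0] = np.clip(centers[:, 0], 1.0, grid.extent[0] - 1.0)
        centers[:, 1] = np.clip(centers[:, 1], 1.0, grid.extent[1] - 1.0)
        sigmas = base_sigmas * rng.uniform(0.9, 1.1, size=3)
        incs = [
            Inclusion(shape="blob", center=tuple(c), density=1.0, sigma=float(s))
            for c, s in zip(centers, sigmas)
        ]
        scene = PhantomScene(
            slab=slab, thickness=thickness, grid=grid, inclusions=incs,
            label=f"tumor t{k}",
        )
        unit_map = scene.ground_truth()
        unit_cells = unit_map.sum() * grid.voxel_volume / CELL_VOLUME_MM3
        scale = target / unit_cells
        scene.inclusions = [
            Inclusion(shape=i.shape, center=i.center, density=i.density * scale,
                      sigma=i.sigma)
            for i in incs
        ]
        true_map = scene.ground_truth()
        true_counts.append(true_map.sum() * grid.voxel_volume / CELL_VOLUME_MM3)
        scenes.append(scene)

    return TumorTimeSeries(
        timepoints=[k * interval_days for k in range(n_timepoints)],
        scenes=scenes,
        true_cell_counts=true_counts,
        dox_states=dox,
    )
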