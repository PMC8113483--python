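"""Run configuration, file formats and manifests.

HDF5 is the canonical interchange format (arrays + provenance attributes);
multi-page TIFF is written alongside for visual inspection (ImageJ
convention, one z-slice or scan position per page).  Every artifact is
accompanied by a manifest entry with the config hash, seeds and package
version so archived runs can be verified and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from . import __version__
from .forward import JacobianModel, RawScan
from .geometry import OpticalProperties, ScanGeometry, VoxelGrid
from .inversion import ReconVolume
from .transport import FluenceMap

__all__ = [
    "RunConfig",
    "ConfigError",
    "write_raw_scan",
    "read_raw_scan",
    "write_volume",
    "read_volume",
    "write_fluence_map",
    "read_fluence_map",
    "write_jacobian",
    "read_jacobian",
    "write_manifest",
    "verify_manifest",
]


class ConfigError(ValueError):
    """Invalid run configuration; message lists the offending keys."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulate/reconstruct run."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid(extent=(10.0, 10.0, 2.0)))
    optics: OpticalProperties = field(default_factory=OpticalProperties)
    engine: str = "diffusion"
    photons: int = 10**6
    noise_model: str = "gaussian_relative"
    noise_level: float = 0.01
    lambda_candidates: int = 11
    fine_tune_factors: tuple[float, ...] = (
        0.25, 0.3536, 0.5, 0.7071, 1.0, 1.4142, 2.0, 2.8284, 4.0
    )
    n_thresholds: int = 50
    tol: float = 1e-6
    max_iter: int = 5000
    seed: int = 0
    power_mw: float = 1.0
    output_dir: str = "ift_output"

    def validate(self) -> None:
        bad: list[str] = []
        if self.engine not in ("diffusion", "mc"):
            bad.append(f"engine={self.engine!r} (expected 'diffusion' or 'mc')")
        if self.photons < 10**3:
            bad.append(f"photons={self.photons} (< 1000)")
        if self.noise_model not in ("gaussian_relative", "shot"):
            bad.append(f"noise_model={self.noise_model!r}")
        if self.noise_level < 0:
            bad.append(f"noise_level={self.noise_level}")
        if self.lambda_candidates < 1:
            bad.append(f"lambda_candidates={self.lambda_candidates}")
        if self.n_thresholds < 1:
            bad.append(f"n_thresholds={self.n_thresholds}")
        if self.tol <= 0:
            bad.append(f"tol={self.tol}")
        if self.max_iter < 1:
            bad.append(f"max_iter={self.max_iter}")
        if self.power_mw <= 0:
            bad.append(f"power_mw={self.power_mw}")
        if bad:
            raise ConfigError("invalid run config: " + "; ".join(bad))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = self.geometry.to_dict()
        d["grid"] = self.grid.to_dict()
        d["optics"] = self.optics.to_dict()
        d["fine_tune_factors"] = list(self.fine_tune_factors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"invalid run config: unknown keys {sorted(unknown)}")
        kwargs = dict(d)
        if "geometry" in kwargs:
            kwargs["geometry"] = ScanGeometry.from_dict(kwargs["geometry"])
        if "grid" in kwargs:
            kwargs["grid"] = VoxelGrid.from_dict(kwargs["grid"])
        if "optics" in kwargs:
            kwargs["optics"] = OpticalProperties.from_dict(kwargs["optics"])
        if "fine_tune_factors" in kwargs:
            kwargs["fine_tune_factors"] = tuple(kwargs["fine_tune_factors"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# raw scans

def write_raw_scan(scan: RawScan, path: str | Path, tiff: bool = True) -> None:
    """Write a raw scan to HDF5 (canonical) and optional companion TIFF."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=scan.data, track_times=False)
        f.attrs["geometry"] = scan.geometry.to_json()
        f.attrs["power_mw"] = scan.power_mw
        f.attrs["seed"] = -1 if scan.seed is None else scan.seed
        f.attrs["meta"] = json.dumps(scan.meta)
        f.attrs["version"] = __version__
    if tiff:
        ny, nx, dr, dc = scan.data.shape
        pages = scan.data.reshape(ny * nx, dr, dc).astype(np.float32)
        tifffile.imwrite(path.with_suffix(".tiff"), pages)


def read_raw_scan(path: str | Path) -> RawScan:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        geom = ScanGeometry.from_json(f.attrs["geometry"])
        seed = int(f.attrs["seed"])
        return RawScan(
            data=data,
            geometry=geom,
            power_mw=float(f.attrs["power_mw"]),
            seed=None if seed < 0 else seed,
            meta=json.loads(f.attrs["meta"]),
        )


# ---------------------------------------------------------------------------
# volumes (ground truth or reconstructions)

def write_volume(
    values: np.ndarray,
    grid: VoxelGrid,
    path: str | Path,
    attrs: dict | None = None,
    tiff: bool = True,
) -> None:
    """Write a (nz, ny, nx) volume to HDF5 + TIFF (one z-slice per page)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=values, track_times=False)
        f.attrs["grid"] = json.dumps(grid.to_dict())
        f.attrs["version"] = __version__
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
    if tiff:
        tifffile.imwrite(path.with_suffix(".tiff"), values.astype(np.float32))


def read_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid, dict]:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        grid = VoxelGrid.from_dict(json.loads(f.attrs["grid"]))
        attrs = {k: f.attrs[k] for k in f.attrs if k != "grid"}
    return values, grid, attrs


def write_recon(recon: ReconVolume, path: str | Path, tiff: bool = True) -> None:
    attrs = {
        "lambda": recon.lam,
        "iterations": recon.iterations,
        "residual_norm": recon.residual_norm,
        "l1_norm": recon.l1_norm,
        "objective_trace": json.dumps(list(map(float, recon.objective_trace))),
    }
    write_volume(recon.values, recon.grid, path, attrs=attrs, tiff=tiff)


# ---------------------------------------------------------------------------
# transport and forward-model artifacts

def write_fluence_map(fm: FluenceMap, path: str | Path) -> None:
    """Persist a Monte-Carlo fluence map with its provenance attributes."""
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("values", data=fm.values, track_times=False)
        f.create_dataset("stderr", data=fm.stderr, track_times=False)
        f.attrs["grid"] = json.dumps(fm.grid.to_dict())
        f.attrs["source"] = list(fm.source)
        f.attrs["photon_count"] = fm.photon_count
        f.attrs["rng_seed"] = fm.rng_seed
        f.attrs["absorbed_fraction"] = fm.absorbed_fraction
        f.attrs["escaped_fraction"] = fm.escaped_fraction
        f.attrs["killed_fraction"] = fm.killed_fraction
        f.attrs["version"] = __version__


def read_fluence_map(path: str | Path) -> FluenceMap:
    with h5py.File(Path(path), "r") as f:
        return FluenceMap(
            grid=VoxelGrid.from_dict(json.loads(f.attrs["grid"])),
            values=f["values"][...],
            stderr=f["stderr"][...],
            source=tuple(f.attrs["source"]),
            photon_count=int(f.attrs["photon_count"]),
            rng_seed=int(f.attrs["rng_seed"]),
            absorbed_fraction=float(f.attrs["absorbed_fraction"]),
            escaped_fraction=float(f.attrs["escaped_fraction"]),
            killed_fraction=float(f.attrs["killed_fraction"]),
        )


def write_jacobian(model: JacobianModel, path: str | Path) -> None:
    """Persist a sensitivity matrix with geometry/grid/engine provenance."""
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("matrix", data=model.matrix, track_times=False)
        f.attrs["geometry"] = model.geometry.to_json()
        f.attrs["grid"] = json.dumps(model.grid.to_dict())
        f.attrs["engine"] = model.engine
        f.attrs["photons"] = model.photons
        f.attrs["seed"] = model.seed
        f.attrs["detectors"] = json.dumps([list(d) for d in model.detectors])
        f.attrs["version"] = __version__


def read_jacobian(path: str | Path) -> JacobianModel:
    with h5py.File(Path(path), "r") as f:
        return JacobianModel(
            matrix=f["matrix"][...],
            geometry=ScanGeometry.from_json(f.attrs["geometry"]),
            grid=VoxelGrid.from_dict(json.loads(f.attrs["grid"])),
            engine=str(f.attrs["engine"]),
            photons=int(f.attrs["photons"]),
            seed=int(f.attrs["seed"]),
            detectors=[tuple(d) for d in json.loads(f.attrs["detectors"])],
        )


# ---------------------------------------------------------------------------
# manifests

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: RunConfig, files: list[str | Path]) -> Path:
    """Record config hash, seeds, package version and file checksums."""
    out_dir = Path(out_dir)
    entries = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "files": {str(Path(f).name): _sha256(Path(f)) for f in files},
    }
    man = out_dir / "manifest.json"
    man.write_text(json.dumps(entries, indent=2, sort_keys=True))
    return man


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash the manifest's files; True if every checksum matches."""
    out_dir = Path(out_dir)
    entries = json.loads((out_dir / "manifest.json").read_text())
    return all(
        _sha256(out_dir / name) == digest for name, digest in entries["files"].items()
    )
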