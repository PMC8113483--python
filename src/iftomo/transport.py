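"""Photon transport in a scattering slab.

Two engines back the forward model:

* a voxelized Monte-Carlo random walk (pencil beam, Henyey-Greenstein
  scattering, implicit capture with Russian roulette, Fresnel handling at
  the z=0 surface), the desk-scale analogue of GPU Monte-Carlo codes; and
* the steady-state diffusion-approximation Green's function for a
  semi-infinite medium with an extrapolated boundary, used both as a fast
  Jacobian engine and as an independent verification oracle for the MC.

Fluence is reported per launched photon in 1/mm^2: the absorbed weight in
a voxel divided by (mu_a * voxel_volume * n_photons), which the diffusion
Green's function (unit isotropic point source) matches in absolute units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import OpticalProperties, VoxelGrid

__all__ = [
    "FluenceMap",
    "sample_scatter_cosine",
    "run_mc",
    "diffusion_green",
]

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


def sample_scatter_cosine(g: float, rng: np.random.Generator, size: int | None = None):
    """Draw scattering-angle cosines from the Henyey-Greenstein distribution.

    For g = 0 the isotropic branch returns cos(theta) uniform on [-1, 1];
    otherwise the standard inverse-CDF sampling is used.  E[cos(theta)] = g.
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"anisotropy g must satisfy |g| < 1, got {g}")
    xi = rng.random(size) if size is not None else rng.random()
    if g == 0.0:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


@dataclass
class FluenceMap:
    """Per-voxel fluence from one source, with Monte-Carlo error estimates.

    ``values`` is the batch-mean fluence (1/mm^2 per launched photon) on the
    (nz, ny, nx) grid; ``stderr`` the per-voxel standard error across
    batches.  The energy ledger (absorbed/escaped/roulette-killed weight
    fractions) supports conservation checks.
    """

    grid: VoxelGrid
    values: np.ndarray
    stderr: np.ndarray
    source: tuple[float, float, float]
    photon_count: int
    rng_seed: int
    absorbed_fraction: float = 0.0
    escaped_fraction: float = 0.0
    killed_fraction: float = 0.0

    def energy_balance(self) -> float:
        """absorbed + escaped + killed; unity within MC noise."""
        return self.absorbed_fraction + self.escaped_fraction + self.killed_fraction


@njit(cache=True, fastmath=True)
def _fresnel_reflectance(n1: float, n2: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance for incidence cosine cos_i from n1 to n2."""
    if n1 == n2:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) ** 2 * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _mc_batch(
    seed: int,
    n_photons: int,
    mu_s: float,
    mu_a: float,
    g: float,
    n_tissue: float,
    n_outside: float,
    src_x: float,
    src_y: float,
    src_z: float,
    isotropic: bool,
    nx: int,
    ny: int,
    nz: int,
    dx: float,
    dy: float,
    dz: float,
):
    """One batch of the random walk; returns (deposit, absorbed, escaped, killed)."""
    np.random.seed(seed)
    deposit = np.zeros((nz, ny, nx))
    absorbed = 0.0
    escaped = 0.0
    killed = 0.0
    mu_t = mu_s + mu_a
    albedo_absorb = mu_a / mu_t
    for _ in range(n_photons):
        x = src_x
        y = src_y
        z = src_z
        if isotropic:
            uz = 2.0 * np.random.random() - 1.0
            phi0 = 2.0 * math.pi * np.random.random()
            sz = math.sqrt(max(0.0, 1.0 - uz * uz))
            ux = sz * math.cos(phi0)
            uy = sz * math.sin(phi0)
        else:
            ux = 0.0
            uy = 0.0
            uz = 1.0
        w = 1.0
        alive = True
        while alive:
            s = -math.log(np.random.random()) / mu_t
            # surface crossing during this step?
            if uz < 0.0 and z + uz * s < 0.0:
                s_to_surface = -z / uz
                x += ux * s_to_surface
                y += uy * s_to_surface
                z = 0.0
                refl = _fresnel_reflectance(n_tissue, n_outside, -uz)
                if np.random.random() < refl:
                    uz = -uz
                    s -= s_to_surface
                    x += ux * s
                    y += uy * s
                    z += uz * s
                else:
                    escaped += w
                    alive = False
                    continue
            else:
                x += ux * s
                y += uy * s
                z += uz * s
            # implicit capture at the interaction site
            dep = w * albedo_absorb
            absorbed += dep
            w -= dep
            ix = int(x / dx)
            iy = int(y / dy)
            iz = int(z / dz)
            if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                deposit[iz, iy, ix] += dep
            if w < ROULETTE_THRESHOLD:
                if np.random.random() < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    killed += w
                    alive = False
                    continue
            # Henyey-Greenstein scatter
            xi = np.random.random()
            if g == 0.0:
                ct = 2.0 * xi - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                nux = st * cp
                nuy = st * sp
                nuz = ct * (1.0 if uz >= 0.0 else -1.0)
            else:
                denom = math.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / denom + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / denom + uy * ct
                nuz = -st * cp * denom + uz * ct
            norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
            ux = nux / norm
            uy = nuy / norm
            uz = nuz / norm
    return deposit, absorbed, escaped, killed


def run_mc(
    props: OpticalProperties,
    grid: VoxelGrid,
    source: tuple[float, float, float] | tuple[float, float],
    photons: int = 10**6,
    seed: int = 0,
    n_batches: int = 10,
    n_outside: float | None = None,
) -> FluenceMap:
    """Monte-Carlo fluence from a source at ``source``.

    A source on the surface (z = 0) is a pencil beam directed into the
    tissue; a source with z > 0 is an isotropic internal point emitter
    (used e.g. for reciprocity checks).

    The medium is a laterally infinite slab with the grid's optical
    properties; photons are tracked beyond the voxel grid (weight deposited
    only inside it) so the energy ledger stays exact.  Photons are split
    into ``n_batches`` independent batches to estimate the per-voxel
    standard error.  By default the surface is index-matched
    (``n_outside = props.n``), the flat-boundary condition provided by a
    coverslip; pass a different ``n_outside`` for Fresnel reflection.
    """
    if photons < 10**3:
        raise ValueError("need at least 1000 photons")
    src = tuple(source)
    src_z = 0.0
    if len(src) == 3:
        src_z = float(src[2])
        if src_z < -1e-12:
            raise ValueError(f"source must lie on or below the z=0 surface, got z={src_z}")
        src = (src[0], src[1])
    isotropic = src_z > 1e-12  # internal sources emit isotropically
    if n_outside is None:
        n_outside = props.n  # index-matched by default
    nz, ny, nx = grid.shape
    dx, dy, dz = grid.voxel_size
    per_batch = photons // n_batches
    batch_fluence = np.empty((n_batches, nz, ny, nx))
    absorbed = escaped = killed = 0.0
    launched = 0
    norm = props.mu_a * grid.voxel_volume
    for b in range(n_batches):
        nb = per_batch if b < n_batches - 1 else photons - per_batch * (n_batches - 1)
        dep, a, e, k = _mc_batch(
            (seed + 7919 * b) % (2**31 - 1),
            nb,
            props.mu_s,
            props.mu_a,
            props.g,
            props.n,
            n_outside,
            src[0],
            src[1],
            src_z,
            isotropic,
            nx,
            ny,
            nz,
            dx,
            dy,
            dz,
        )
        batch_fluence[b] = dep / (norm * nb)
        absorbed += a
        escaped += e
        killed += k
        launched += nb
    values = batch_fluence.mean(axis=0)
    stderr = batch_fluence.std(axis=0, ddof=1) / math.sqrt(n_batches)
    return FluenceMap(
        grid=grid,
        values=values,
        stderr=stderr,
        source=(src[0], src[1], src_z),
        photon_count=photons,
        rng_seed=seed,
        absorbed_fraction=absorbed / launched,
        escaped_fraction=escaped / launched,
        killed_fraction=killed / launched,
    )


def diffusion_green(
    props: OpticalProperties,
    r_src: tuple[float, float, float],
    r: tuple[float, float, float] | np.ndarray,
):
    """Semi-infinite diffusion Green's function with extrapolated boundary.

    A source on the surface (z=0) is represented as an isotropic point
    source one transport mean free path deep (z0 = 1/mu_s'); its negative
    image across the extrapolated boundary at z = -2*zb (zb = 2*A*D, A = 1
    for an index-matched boundary) enforces the zero-fluence condition:

        G(r) = [exp(-mu_eff r1)/r1 - exp(-mu_eff r2)/r2] / (4 pi D)

    with D = 1/(3 (mu_a + mu_s')) and mu_eff = sqrt(3 mu_a (mu_a + mu_s')).
    Units: 1/mm^2 per unit source power.  ``r`` may be an (N, 3) array.
    """
    musp = props.mu_s_reduced
    if musp <= 0:
        raise ValueError("reduced scattering must be > 0 for the diffusion model")
    D = 1.0 / (3.0 * (props.mu_a + musp))
    mu_eff = props.mu_eff
    zb = 2.0 * D  # A = 1: index-matched boundary
    sx, sy, sz = r_src
    if abs(sz) < 1e-12:
        sz = 1.0 / musp  # bury a surface source one transport mfp deep
    pts = np.atleast_2d(np.asarray(r, dtype=float))
    dx = pts[:, 0] - sx
    dy = pts[:, 1] - sy
    r1 = np.sqrt(dx**2 + dy**2 + (pts[:, 2] - sz) ** 2)
    r2 = np.sqrt(dx**2 + dy**2 + (pts[:, 2] + sz + 2.0 * zb) ** 2)
    if np.any(r1 < 1e-9) or np.any(r2 < 1e-9):
        raise ValueError("field point coincides with a source singularity")
    g = (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4.0 * math.pi * D)
    g = np.maximum(g, 0.0)
    return float(g[0]) if np.isscalar(r[0]) and np.ndim(r) == 1 else g
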