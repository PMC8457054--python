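"""Volumes, particle sets and their file formats.

Array convention used throughout the package: 3D grids are indexed ``(z, y,
x)``, slice-major, matching multi-page TIFF layout.  Physical coordinates are
continuous; voxel ``(i, j, k)`` covers the half-open box ``[i*dz, (i+1)*dz) x
[j*dy, (j+1)*dy) x [k*dx, (k+1)*dx)`` with its center at the half-offsets.
Particle coordinate files list columns ``x y z`` (the common convention for
tracking output); they are mapped onto the ``(z, y, x)`` grid on projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "VoxelGeometry",
    "ImageStack",
    "BinaryVolume",
    "ParticleSet",
    "PSFKernel",
    "InputError",
    "read_stack",
    "read_coordinates",
    "default_psf",
    "project_particles",
    "write_stack",
]


class InputError(ValueError):
    """Unreadable, malformed or unsupported input data."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel edge lengths; anisotropy (dz != dx) is permitted.

    ``unit_label`` records whether lengths are micrometres ("um") or particle
    diameters ("sigma"); it only affects reporting, never geometry.
    """

    dx: float
    dy: float
    dz: float
    unit_label: str = "um"

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel edge lengths must be positive")
        if self.unit_label not in ("um", "sigma"):
            raise ValueError("unit_label must be 'um' or 'sigma'")

    @property
    def zyx(self) -> np.ndarray:
        """Edge lengths in array axis order (dz, dy, dx)."""
        return np.array([self.dz, self.dy, self.dx])

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dy * self.dz


@dataclass
class ImageStack:
    """3D grayscale intensity grid with physical voxel dimensions."""

    values: np.ndarray  # float64, shape (nz, ny, nx), non-negative
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("ImageStack requires a 3D array")
        if min(self.values.shape) < 3:
            raise ValueError("ImageStack needs at least 3 voxels along every axis")
        if np.any(self.values < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class BinaryVolume:
    """3D boolean grid of material / non-material voxels."""

    material: np.ndarray  # bool, shape (nz, ny, nx)
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.material = np.asarray(self.material, dtype=bool)
        if self.material.ndim != 3:
            raise ValueError("BinaryVolume requires a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material.shape

    def count(self) -> int:
        return int(self.material.sum())


@dataclass
class ParticleSet:
    """Particle centers in physical units with a global diameter sigma.

    ``positions`` has shape (n, 3) with columns (x, y, z); ``box`` is the
    axis-aligned bounding box ``((xmin, ymin, zmin), (xmax, ymax, zmax))``.
    """

    positions: np.ndarray
    sigma: float
    box: tuple[tuple[float, float, float], tuple[float, float, float]]
    unit_label: str = "um"

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        if self.positions.shape[1] != 3:
            raise ValueError("positions must have 3 columns (x, y, z)")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        lo, hi = np.asarray(self.box[0]), np.asarray(self.box[1])
        if np.any(self.positions < lo - 1e-9) or np.any(self.positions > hi + 1e-9):
            raise ValueError("all particle positions must lie inside the box")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PSFKernel:
    """Normalized, odd-extent point-spread-function sampled on the voxel grid."""

    weights: np.ndarray  # (nz, ny, nx), non-negative, sums to 1
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ValueError("PSF weights must be 3D")
        if any(s % 2 == 0 for s in self.weights.shape):
            raise ValueError("PSF extent must be odd along every axis")
        if np.any(self.weights < 0):
            raise ValueError("PSF weights must be non-negative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("PSF weights must sum to 1")


def read_stack(path: str | Path, geometry: VoxelGeometry) -> ImageStack:
    """Read a multi-page 8/16-bit grayscale TIFF.

    Voxel dimensions always come from ``geometry``; TIFF metadata is not
    trusted (microscope files rarely carry reliable axial calibration).
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise InputError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:
        # pages decoded with a sample axis => color data
        for page_index in range(data.shape[0]):
            if data[page_index].ndim == 3:
                raise InputError(
                    f"{path}: page {page_index} is not grayscale (RGB/multi-sample "
                    "pages are unsupported)"
                )
    if data.ndim != 3:
        raise InputError(f"{path}: expected a stack of 2D grayscale pages")
    if data.dtype not in (np.uint8, np.uint16):
        raise InputError(
            f"{path}: unsupported dtype {data.dtype}; expected 8- or 16-bit grayscale"
        )
    return ImageStack(values=data.astype(np.float64), geometry=geometry)


def read_coordinates(
    path: str | Path,
    sigma: float,
    unit_label: str = "um",
    box: tuple | None = None,
) -> ParticleSet:
    """Read a delimited text table of particle centers (columns x y z).

    Whitespace- or comma-delimited; lines starting with '#' are comments.  The
    bounding box defaults to the per-axis min/max of the data unless given.
    """
    path = Path(path)
    rows: list[list[float]] = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputError(f"cannot read coordinate file {path}: {exc}") from exc
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in (line.split(",") if "," in line else line.split()) if p]
        if len(parts) < 3:
            raise InputError(
                f"{path}:{lineno}: expected at least 3 numeric columns, got {len(parts)}"
            )
        try:
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: non-numeric coordinate value") from exc
    if not rows:
        raise InputError(f"{path}: no particles (file contains no data rows)")
    positions = np.array(rows)
    if box is None:
        box = (tuple(positions.min(axis=0)), tuple(positions.max(axis=0)))
    return ParticleSet(positions=positions, sigma=sigma, box=box, unit_label=unit_label)


def default_psf(
    geometry: VoxelGeometry, sigma_xy: float, sigma_z: float
) -> PSFKernel:
    """Anisotropic Gaussian PSF sampled on the voxel grid.

    Truncated at 3 standard deviations per axis and normalized to unit sum.
    The default widths used by the pipeline (0.21 sigma lateral, 0.75 sigma
    axial) mimic the typical lateral/axial asymmetry of a confocal microscope.
    """
    if not (sigma_xy > 0 and sigma_z > 0):
        raise ValueError("PSF widths must be positive")
    steps = geometry.zyx  # (dz, dy, dx)
    widths = np.array([sigma_z, sigma_xy, sigma_xy])
    if np.any(widths < steps / 2):
        warnings.warn(
            "PSF width below half a voxel: kernel degenerates toward a delta",
            stacklevel=2,
        )
    half = np.maximum(np.floor(3 * widths / steps + 1e-12).astype(int), 0)
    axes = [np.arange(-h, h + 1) * d for h, d in zip(half, steps)]
    gz = np.exp(-0.5 * (axes[0] / widths[0]) ** 2)
    gy = np.exp(-0.5 * (axes[1] / widths[1]) ** 2)
    gx = np.exp(-0.5 * (axes[2] / widths[2]) ** 2)
    weights = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    weights /= weights.sum()
    return PSFKernel(weights=weights, geometry=geometry)


def _grid_shape(box, geometry: VoxelGeometry) -> tuple[int, int, int]:
    lo, hi = np.asarray(box[0], float), np.asarray(box[1], float)
    extent_xyz = hi - lo
    steps_xyz = np.array([geometry.dx, geometry.dy, geometry.dz])
    n = np.maximum(np.ceil(extent_xyz / steps_xyz - 1e-9).astype(int), 1)
    return int(n[2]), int(n[1]), int(n[0])  # (nz, ny, nx)


def project_particles(
    particles: ParticleSet,
    geometry: VoxelGeometry,
    psf: PSFKernel | None = None,
    point_emitters: bool = False,
) -> ImageStack:
    """Render a particle set into an image stack.

    Every voxel whose center lies within sigma/2 of a particle center receives
    intensity 1 (union of solid spheres, the default); with
    ``point_emitters=True`` only the voxel containing each center is lit,
    which models ideal point sources prior to PSF convolution.  If ``psf`` is
    given, the render is convolved with it (zero-padded boundaries) and
    rescaled to a maximum of 1.
    """
    sigma = particles.sigma
    if not point_emitters and sigma / 2 < 1.5 * min(geometry.dx, geometry.dy):
        warnings.warn(
            "particle diameter spans fewer than 3 voxels laterally; "
            "rendered spheres will be poorly resolved",
            stacklevel=2,
        )
    lo = np.asarray(particles.box[0], float)
    nz, ny, nx = _grid_shape(particles.box, geometry)
    steps_xyz = np.array([geometry.dx, geometry.dy, geometry.dz])

    # particle positions in fractional voxel units, (x, y, z) order
    frac = (particles.positions - lo) / steps_xyz
    outside = np.any(frac < -1e-9, axis=1) | np.any(
        frac > np.array([nx, ny, nz]) + 1e-9, axis=1
    )
    if np.any(outside):
        raise ValueError(
            f"particles outside the voxelized box: indices {np.flatnonzero(outside).tolist()}"
        )

    out = np.zeros((nz, ny, nx), dtype=bool)
    if point_emitters:
        idx = np.clip(
            np.floor(frac).astype(int), 0, np.array([nx, ny, nz]) - 1
        )
        out[idx[:, 2], idx[:, 1], idx[:, 0]] = True
    else:
        r = sigma / 2
        half = np.ceil(r / steps_xyz).astype(int) + 1  # (x, y, z) window half-extent
        for px, py, pz in frac:
            cx, cy, cz = int(np.floor(px)), int(np.floor(py)), int(np.floor(pz))
            x0, x1 = max(cx - half[0], 0), min(cx + half[0] + 1, nx)
            y0, y1 = max(cy - half[1], 0), min(cy + half[1] + 1, ny)
            z0, z1 = max(cz - half[2], 0), min(cz + half[2] + 1, nz)
            if x0 >= x1 or y0 >= y1 or z0 >= z1:
                continue
            zz, yy, xx = np.meshgrid(
                (np.arange(z0, z1) + 0.5) * geometry.dz,
                (np.arange(y0, y1) + 0.5) * geometry.dy,
                (np.arange(x0, x1) + 0.5) * geometry.dx,
                indexing="ij",
            )
            d2 = (
                (xx - px * geometry.dx) ** 2
                + (yy - py * geometry.dy) ** 2
                + (zz - pz * geometry.dz) ** 2
            )
            out[z0:z1, y0:y1, x0:x1] |= d2 <= r * r

    out = out.astype(np.float64)
    if psf is not None:
        out = ndimage.convolve(out, psf.weights, mode="constant", cval=0.0)
        peak = out.max()
        if peak > 0:
            out = out / peak
    return ImageStack(values=out, geometry=geometry)


def write_stack(stack: ImageStack | BinaryVolume, path: str | Path) -> None:
    """Write a stack as a multi-page grayscale TIFF.

    Binary volumes are written as 8-bit {0, 255}.  Integer-valued grayscale
    data is written at the narrowest lossless integer dtype so that
    ``read_stack`` round-trips voxel values exactly.
    """
    path = Path(path)
    if isinstance(stack, BinaryVolume):
        data = np.where(stack.material, 255, 0).astype(np.uint8)
    else:
        values = stack.values
        if np.allclose(values, np.round(values)) and values.max(initial=0) <= 65535:
            data = values.astype(np.uint16 if values.max(initial=0) > 255 else np.uint8)
        else:
            data = values.astype(np.float32)
    try:
        tifffile.imwrite(path, data, photometric="minisblack")
    except OSError as exc:
        raise InputError(f"cannot write TIFF stack {path}: {exc}") from exc
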