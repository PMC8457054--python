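"""Grayscale stack -> cleaned binary material volume.

The stages mirror the standard confocal-gel workflow: Gaussian blur (noise in
the raw image otherwise surfaces as spurious side chains of the skeleton),
per-slice binarization (thresholding each z-slice separately compensates for
depth-dependent fluorescence intensity and bleaching), morphological closing
with an ellipsoidal element (two structures merge when their binarized shapes
are closer than twice the element radius), removal of small unconnected
clusters, and filling of background cavities fully enclosed in 3D.

Foreground connectivity is 26, background 6, throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume_io import BinaryVolume, ImageStack

__all__ = [
    "BinarizationParams",
    "ThresholdRecord",
    "PreprocessReport",
    "NoStructureError",
    "gaussian_blur",
    "slice_threshold_percentile",
    "slice_threshold_otsu",
    "binarize",
    "ellipsoid_element",
    "morphological_close",
    "remove_small_clusters",
    "fill_holes",
    "preprocess_stack",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class NoStructureError(RuntimeError):
    """Raised when preprocessing removes every material cluster."""


@dataclass(frozen=True)
class BinarizationParams:
    """How slices are thresholded.

    ``method`` is "otsu" (automatic, 256-bin between-class variance) or
    "percentile", where the threshold is I_10 + V_u * (I_90 - I_10) with I_10
    and I_90 the intensities below which 10% and 90% of the slice's pixel
    intensities fall.  Thresholding is always per-slice in this version.
    """

    method: str = "otsu"
    v_u: float = 0.5
    per_slice: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "percentile"):
            raise ValueError("method must be 'otsu' or 'percentile'")
        if not 0.0 <= self.v_u <= 1.0:
            raise ValueError("V_u must lie in [0, 1]")


@dataclass(frozen=True)
class ThresholdRecord:
    """Per-slice threshold diagnostics."""

    slice_index: int
    i_10: float
    i_90: float
    i_t: float
    degenerate: bool = False


@dataclass
class PreprocessReport:
    """What preprocessing did: thresholds, voxels added/removed, cluster sizes.

    ``added`` and ``removed`` are the exact diff between the binarized input
    and the final output (added = gained by closing/filling, removed = lost to
    cluster removal), so they reconcile the two volumes and are disjoint by
    construction.
    """

    thresholds: list[ThresholdRecord] = field(default_factory=list)
    added: np.ndarray | None = None
    removed: np.ndarray | None = None
    cluster_sizes: list[int] = field(default_factory=list)
    n_clusters_kept: int = 0


def gaussian_blur(stack: ImageStack, widths) -> ImageStack:
    """Separable Gaussian filtering with reflective boundaries; width is in
    voxels per axis (z, y, x); a scalar applies to all axes; 0 is the identity."""
    widths = np.broadcast_to(np.asarray(widths, dtype=float), (3,))
    if np.any(widths < 0):
        raise ValueError("blur widths must be >= 0")
    if np.all(widths == 0):
        return ImageStack(values=stack.values.copy(), geometry=stack.geometry)
    blurred = ndimage.gaussian_filter(stack.values, sigma=widths, mode="reflect")
    return ImageStack(values=np.clip(blurred, 0, None), geometry=stack.geometry)


def slice_threshold_percentile(
    slice_values: np.ndarray, v_u: float, slice_index: int = 0
) -> ThresholdRecord:
    """Percentile threshold I_T = I_10 + V_u (I_90 - I_10) for one slice."""
    if slice_values.size == 0:
        raise ValueError("empty slice")
    if not 0.0 <= v_u <= 1.0:
        raise ValueError("V_u must lie in [0, 1]")
    i10, i90 = np.percentile(slice_values, [10.0, 90.0])
    i_t = float(i10 + v_u * (i90 - i10))
    return ThresholdRecord(
        slice_index=slice_index,
        i_10=float(i10),
        i_90=float(i90),
        i_t=i_t,
        degenerate=bool(np.isclose(i10, i90)),
    )


def slice_threshold_otsu(slice_values: np.ndarray, slice_index: int = 0) -> ThresholdRecord:
    """Otsu threshold (256-bin between-class variance) for one slice.

    A constant slice has no separable classes; it is flagged degenerate and
    the threshold is set to the constant value so that the strict ``>``
    comparison marks the whole slice background.
    """
    if slice_values.size == 0:
        raise ValueError("empty slice")
    i10, i90 = np.percentile(slice_values, [10.0, 90.0])
    flat = slice_values.ravel()
    if np.all(flat == flat[0]):
        return ThresholdRecord(
            slice_index=slice_index,
            i_10=float(i10),
            i_90=float(i90),
            i_t=float(flat[0]),
            degenerate=True,
        )
    i_t = float(threshold_otsu(flat, nbins=256))
    return ThresholdRecord(
        slice_index=slice_index, i_10=float(i10), i_90=float(i90), i_t=i_t
    )


def binarize(
    stack: ImageStack, params: BinarizationParams
) -> tuple[BinaryVolume, list[ThresholdRecord]]:
    """Threshold each z-slice independently; material iff intensity > I_T."""
    records: list[ThresholdRecord] = []
    material = np.zeros(stack.shape, dtype=bool)
    for z in range(stack.shape[0]):
        sl = stack.values[z]
        if params.method == "percentile":
            rec = slice_threshold_percentile(sl, params.v_u, slice_index=z)
        else:
            rec = slice_threshold_otsu(sl, slice_index=z)
        records.append(rec)
        if not (params.method == "otsu" and rec.degenerate):
            material[z] = sl > rec.i_t
    return BinaryVolume(material=material, geometry=stack.geometry), records


def ellipsoid_element(radii_voxels) -> np.ndarray:
    """Digital ellipsoid with the given semi-axes in voxels (z, y, x order).

    Membership is the continuous test (d/a)^2 summed <= 1, so a semi-axis
    below 1 voxel contributes no off-center offsets along that axis; all
    semi-axes below 1 yield the single-voxel (identity) element.
    """
    radii = np.asarray(radii_voxels, dtype=float)
    if np.any(radii < 0):
        raise ValueError("element semi-axes must be >= 0")
    half = np.floor(radii + 1e-9).astype(int)
    zz, yy, xx = np.meshgrid(
        np.arange(-half[0], half[0] + 1),
        np.arange(-half[1], half[1] + 1),
        np.arange(-half[2], half[2] + 1),
        indexing="ij",
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.zeros(zz.shape)
        for d, a in ((zz, radii[0]), (yy, radii[1]), (xx, radii[2])):
            r2 = r2 + np.where(d == 0, 0.0, np.inf if a == 0 else (d / a) ** 2)
    return r2 <= 1.0 + 1e-9


def morphological_close(volume: BinaryVolume, radii) -> BinaryVolume:
    """Dilation then erosion with an ellipsoidal element.

    ``radii`` are physical semi-axes per axis (z, y, x) — a scalar is
    isotropic in physical units, which on an anisotropic grid yields an
    anisotropic digital ellipsoid.  Radius 0 on all axes is the identity.
    The volume is zero-padded by the element extent before closing so the
    result is extensive (contains its input) and idempotent.
    """
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (3,))
    if np.any(radii < 0):
        raise ValueError("closing radii must be >= 0")
    radii_vox = radii / volume.geometry.zyx
    element = ellipsoid_element(radii_vox)
    if element.size == 1:
        return BinaryVolume(material=volume.material.copy(), geometry=volume.geometry)
    pad = tuple((s // 2, s // 2) for s in element.shape)
    padded = np.pad(volume.material, pad)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=element), structure=element
    )
    sl = tuple(slice(p[0], p[0] + n) for p, n in zip(pad, volume.shape))
    return BinaryVolume(material=closed[sl], geometry=volume.geometry)


def remove_small_clusters(
    volume: BinaryVolume, min_fraction: float
) -> tuple[BinaryVolume, np.ndarray, list[int]]:
    """Delete 26-connected clusters smaller than ``min_fraction`` of all material.

    Returns the filtered volume, a label grid of the surviving clusters (so
    each can be analyzed as a separate network structure), and the size list
    of all clusters found.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    labels, n = ndimage.label(volume.material, structure=_STRUCT_26)
    if n == 0:
        return (
            BinaryVolume(material=volume.material.copy(), geometry=volume.geometry),
            labels,
            [],
        )
    sizes = ndimage.sum_labels(volume.material, labels, index=np.arange(1, n + 1))
    total = volume.count()
    keep = sizes >= min_fraction * total
    if not np.any(keep):
        raise NoStructureError(
            f"no structure survives cluster removal; cluster sizes: "
            f"{sorted(sizes.astype(int).tolist(), reverse=True)}"
        )
    keep_mask = np.concatenate([[False], keep])[labels]
    out_labels, _ = ndimage.label(keep_mask, structure=_STRUCT_26)
    return (
        BinaryVolume(material=keep_mask, geometry=volume.geometry),
        out_labels,
        sizes.astype(int).tolist(),
    )


def fill_holes(volume: BinaryVolume, max_hole_voxels: int) -> BinaryVolume:
    """Fill 6-connected background cavities enclosed on all sides in 3D.

    Background components touching any volume face are pore space, never
    filled; enclosed cavities larger than ``max_hole_voxels`` are kept as
    genuine voids.
    """
    if max_hole_voxels < 0:
        raise ValueError("max_hole_voxels must be >= 0")
    bg = ~volume.material
    labels, n = ndimage.label(bg)  # 6-connectivity
    if n == 0:
        return BinaryVolume(material=volume.material.copy(), geometry=volume.geometry)
    border = np.zeros(volume.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    touching = np.zeros(n + 1, dtype=bool)
    touching[np.unique(labels[border & bg])] = True
    sizes = ndimage.sum_labels(bg, labels, index=np.arange(n + 1))
    fill = ~touching & (sizes <= max_hole_voxels)
    fill[0] = False
    out = volume.material | fill[labels]
    return BinaryVolume(material=out, geometry=volume.geometry)


def preprocess_stack(
    stack: ImageStack,
    params: BinarizationParams | None = None,
    blur_widths=1.0,
    closing_radii=None,
    min_fraction: float = 0.01,
    max_hole_voxels: int | None = None,
    sigma: float | None = None,
) -> tuple[BinaryVolume, np.ndarray, PreprocessReport]:
    """Full preprocessing chain: blur -> binarize -> close -> declutter -> fill.

    Defaults that depend on the particle diameter sigma (closing semi-axes
    0.25*sigma, hole threshold = voxel volume of one particle) require
    ``sigma`` in the geometry's physical units.  Thresholds are computed on
    the blurred stack.  Returns the final volume, surviving-cluster labels,
    and a report reconciling input and output.
    """
    params = params or BinarizationParams()
    if closing_radii is None or max_hole_voxels is None:
        if sigma is None:
            raise ValueError("sigma is required to derive default parameters")
    if closing_radii is None:
        closing_radii = 0.25 * sigma
    if max_hole_voxels is None:
        max_hole_voxels = int(
            np.ceil((np.pi / 6.0) * sigma**3 / stack.geometry.voxel_volume)
        )

    blurred = gaussian_blur(stack, blur_widths)
    binarized, records = binarize(blurred, params)
    closed = morphological_close(binarized, closing_radii)
    filtered, labels, cluster_sizes = remove_small_clusters(closed, min_fraction)
    final = fill_holes(filtered, max_hole_voxels)

    report = PreprocessReport(
        thresholds=records,
        added=final.material & ~binarized.material,
        removed=binarized.material & ~final.material,
        cluster_sizes=cluster_sizes,
        n_clusters_kept=int(labels.max()),
    )
    return final, labels, report
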