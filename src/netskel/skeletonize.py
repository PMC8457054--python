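"""Topology-preserving 3D thinning to a single-voxel-thin skeleton.

The algorithm iteratively deletes material voxels that border background,
subject to three conditions evaluated on the 3x3x3 neighborhood D_3(i) of the
candidate voxel i:

* **not an end point** — D_3(i) contains more than two material voxels
  (an end point is i plus exactly one neighbor, and is protected so that
  strand tips survive);
* **Euler invariant** — deleting i leaves the Euler characteristic of the
  structure unchanged, evaluated as a sum of per-octant contributions from
  the block table of :mod:`netskel.topology` (two table lookups per octant);
* **simple** — deleting i changes neither the local foreground connectivity
  (the 26 neighbors must form exactly one 26-connected component) nor the
  local background connectivity (exactly one 6-connected background
  component within the 18-neighborhood touches a face neighbor of i).

Each full pass visits the six border directions in the fixed order
up, down, north, south, east, west (−z, +z, −y, +y, −x, +x).  Within a
sub-iteration, candidates are collected simultaneously and then re-checked
sequentially in (z, y, x) scan order before actual deletion, because deleting
one voxel can invalidate a later candidate.  Passes repeat until a full pass
deletes nothing, which makes the procedure idempotent by construction.

Thinning operates on the voxel lattice and ignores physical anisotropy (the
Euler/simple machinery is lattice-combinatorial); physical voxel dimensions
re-enter when link lengths are measured.  Voxels on the volume face treat
out-of-bounds as background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .topology import BLOCK_CHI_TABLE
from .volume_io import BinaryVolume, VoxelGeometry

__all__ = [
    "Skeleton",
    "is_end_point",
    "is_euler_invariant",
    "is_simple_point",
    "thin_volume",
]


@dataclass
class Skeleton:
    """Single-voxel-thin backbone: a subset of the source material voxels."""

    data: np.ndarray  # bool, shape == source_shape
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("Skeleton requires a 3D array")

    @property
    def source_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxels(self) -> np.ndarray:
        """(n, 3) integer voxel coordinates in (z, y, x) order."""
        return np.argwhere(self.data)

    def count(self) -> int:
        return int(self.data.sum())

    def to_volume(self) -> BinaryVolume:
        return BinaryVolume(material=self.data.copy(), geometry=self.geometry)


# ---------------------------------------------------------------------------
# neighborhood index tables (27-cell cube, index = (dz+1)*9 + (dy+1)*3 + (dx+1))

_CENTER = 13


def _build_neighbor_tables():
    coords = [(i // 9 - 1, (i // 3) % 3 - 1, i % 3 - 1) for i in range(27)]
    adj26 = np.full((27, 26), -1, dtype=np.int64)
    n26 = np.zeros(27, dtype=np.int64)
    adj6 = np.full((27, 6), -1, dtype=np.int64)
    n6 = np.zeros(27, dtype=np.int64)
    in_n18 = np.zeros(27, dtype=np.uint8)
    is_face = np.zeros(27, dtype=np.uint8)
    for i, (az, ay, ax) in enumerate(coords):
        manh = abs(az) + abs(ay) + abs(ax)
        in_n18[i] = 1 if 1 <= manh <= 2 else 0
        is_face[i] = 1 if manh == 1 else 0
        for j, (bz, by, bx) in enumerate(coords):
            if i == j:
                continue
            dz, dy, dx = abs(az - bz), abs(ay - by), abs(ax - bx)
            if max(dz, dy, dx) == 1:
                adj26[i, n26[i]] = j
                n26[i] += 1
            if dz + dy + dx == 1:
                adj6[i, n6[i]] = j
                n6[i] += 1
    return adj26, n26, adj6, n6, in_n18, is_face


_ADJ26, _N26, _ADJ6, _N6, _IN_N18, _IS_FACE = _build_neighbor_tables()


@njit(cache=True)
def _count_material(nb):
    total = 0
    for i in range(27):
        total += nb[i]
    return total


@njit(cache=True)
def _euler_delta(nb, table):
    """Change of chi if the center voxel is deleted (0 => Euler invariant).

    The only 2x2x2 blocks whose contribution changes are the 8 octants of
    D_3(i) that contain the center; each contributes
    T[mask without center] - T[mask with center].
    """
    delta = 0
    for ez in range(2):
        for ey in range(2):
            for ex in range(2):
                mask = 0
                for b in range(8):
                    bz = (b >> 2) & 1
                    by = (b >> 1) & 1
                    bx = b & 1
                    idx = (bz - ez + 1) * 9 + (by - ey + 1) * 3 + (bx - ex + 1)
                    if nb[idx]:
                        mask |= 1 << b
                cbit = 1 << ((ez << 2) | (ey << 1) | ex)
                delta += table[mask & ~cbit] - table[mask]
    return delta


@njit(cache=True)
def _fg_components_without_center(nb, adj26, n26):
    """Number of 26-connected components among the 26 neighbors (center removed)."""
    visited = np.zeros(27, dtype=np.uint8)
    stack = np.empty(27, dtype=np.int64)
    ncomp = 0
    for s in range(27):
        if s == _CENTER or not nb[s] or visited[s]:
            continue
        ncomp += 1
        top = 0
        stack[top] = s
        top += 1
        visited[s] = 1
        while top > 0:
            top -= 1
            cur = stack[top]
            for k in range(n26[cur]):
                nxt = adj26[cur, k]
                if nxt == _CENTER or not nb[nxt] or visited[nxt]:
                    continue
                visited[nxt] = 1
                stack[top] = nxt
                top += 1
    return ncomp


@njit(cache=True)
def _bg_components_touching_faces(nb, adj6, n6, in_n18, is_face):
    """6-connected background components within N18 that contain a face neighbor."""
    visited = np.zeros(27, dtype=np.uint8)
    stack = np.empty(27, dtype=np.int64)
    ncomp = 0
    for s in range(27):
        if not is_face[s] or nb[s] or visited[s]:
            continue
        ncomp += 1
        top = 0
        stack[top] = s
        top += 1
        visited[s] = 1
        while top > 0:
            top -= 1
            cur = stack[top]
            for k in range(n6[cur]):
                nxt = adj6[cur, k]
                if nxt == _CENTER or not in_n18[nxt] or nb[nxt] or visited[nxt]:
                    continue
                visited[nxt] = 1
                stack[top] = nxt
                top += 1
    return ncomp


@njit(cache=True)
def _is_simple_nb(nb, adj26, n26, adj6, n6, in_n18, is_face):
    if _fg_components_without_center(nb, adj26, n26) != 1:
        return False
    return _bg_components_touching_faces(nb, adj6, n6, in_n18, is_face) == 1


@njit(cache=True)
def _extract_nb(vol, z, y, x, nb):
    for dz in range(-1, 2):
        for dy in range(-1, 2):
            for dx in range(-1, 2):
                nb[(dz + 1) * 9 + (dy + 1) * 3 + (dx + 1)] = vol[z + dz, y + dy, x + dx]


@njit(cache=True)
def _thin_core(vol, table, adj26, n26, adj6, n6, in_n18, is_face):
    """In-place thinning of a zero-padded uint8 volume; returns deletions."""
    nz, ny, nx = vol.shape
    nb = np.zeros(27, dtype=np.uint8)
    cand = np.empty(nz * ny * nx, dtype=np.int64)
    # border directions in fixed order: -z, +z, -y, +y, -x, +x
    dirs = np.array(
        [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]],
        dtype=np.int64,
    )
    total_deleted = 0
    changed = True
    while changed:
        changed = False
        for d in range(6):
            dz, dy, dx = dirs[d, 0], dirs[d, 1], dirs[d, 2]
            ncand = 0
            for z in range(1, nz - 1):
                for y in range(1, ny - 1):
                    for x in range(1, nx - 1):
                        if not vol[z, y, x]:
                            continue
                        if vol[z + dz, y + dy, x + dx]:
                            continue  # not a border voxel of this direction
                        _extract_nb(vol, z, y, x, nb)
                        if _count_material(nb) <= 2:
                            continue  # end point (or isolated): protected
                        if _euler_delta(nb, table) != 0:
                            continue
                        if not _is_simple_nb(nb, adj26, n26, adj6, n6, in_n18, is_face):
                            continue
                        cand[ncand] = (z * ny + y) * nx + x
                        ncand += 1
            # sequential re-check in scan order: earlier deletions can
            # invalidate later candidates
            for c in range(ncand):
                lin = cand[c]
                x = lin % nx
                y = (lin // nx) % ny
                z = lin // (nx * ny)
                _extract_nb(vol, z, y, x, nb)
                if _count_material(nb) <= 2:
                    continue
                if _euler_delta(nb, table) != 0:
                    continue
                if not _is_simple_nb(nb, adj26, n26, adj6, n6, in_n18, is_face):
                    continue
                vol[z, y, x] = 0
                total_deleted += 1
                changed = True
    return total_deleted


def _as_nb_array(neighborhood) -> np.ndarray:
    nb = np.asarray(neighborhood)
    if nb.shape == (3, 3, 3):
        nb = nb.reshape(27)
    if nb.shape != (27,):
        raise ValueError("neighborhood must have shape (27,) or (3, 3, 3)")
    nb = nb.astype(np.uint8)
    if not nb[_CENTER]:
        raise ValueError("the center voxel of the neighborhood must be material")
    return nb


def is_end_point(neighborhood) -> bool:
    """True iff D_3(i) contains exactly two material voxels (i plus one)."""
    nb = _as_nb_array(neighborhood)
    return int(nb.sum()) == 2


def is_euler_invariant(neighborhood) -> bool:
    """True iff deleting the center leaves the Euler characteristic unchanged."""
    nb = _as_nb_array(neighborhood)
    return _euler_delta(nb, BLOCK_CHI_TABLE) == 0


def is_simple_point(neighborhood) -> bool:
    """True iff deleting the center preserves local fg (26) and bg (6) connectivity."""
    nb = _as_nb_array(neighborhood)
    return bool(_is_simple_nb(nb, _ADJ26, _N26, _ADJ6, _N6, _IN_N18, _IS_FACE))


def thin_volume(volume: BinaryVolume) -> Skeleton:
    """Thin a binary volume to its single-voxel-thin skeleton.

    Deterministic (fixed sub-iteration schedule and scan order), a pure
    deletion process, and preserves both the 26-connected component count
    and the Euler characteristic of the material.
    """
    padded = np.pad(volume.material.astype(np.uint8), 1)
    _thin_core(
        padded, BLOCK_CHI_TABLE, _ADJ26, _N26, _ADJ6, _N6, _IN_N18, _IS_FACE
    )
    out = padded[1:-1, 1:-1, 1:-1].astype(bool)
    return Skeleton(data=out, geometry=volume.geometry)
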