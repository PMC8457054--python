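"""Synthetic phantoms with known ground truth.

These emulate the study systems at desk scale: solid tubes, junctions and
tori exercise the skeletonization topology, and the bead-on-a-graph network
mimics a colloidal gel imaged twice — once as explicit particle coordinates
and once as a rendered, noise- and drift-corrupted image stack — so that the
two analysis routes can be compared quantitatively.

All randomness flows through one seeded generator; generation is fully
reproducible from (parameters, seed).  Voxel phantoms verify their expected
topology (components, Euler characteristic) at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import topology
from .volume_io import BinaryVolume, ImageStack, ParticleSet, VoxelGeometry

__all__ = [
    "GroundTruth",
    "make_tube",
    "make_arc",
    "make_junction",
    "make_torus",
    "make_bead_network",
    "corrupt",
]

_UNIT_GEOMETRY = VoxelGeometry(1.0, 1.0, 1.0, "sigma")


@dataclass
class GroundTruth:
    """Expected graph and topology of a phantom."""

    node_positions: list  # [(z, y, x) physical], junctions and strand ends
    node_kinds: list  # "end" | "branching"
    links: list  # [(i, j, true_length)] indices into node_positions
    expected_chi: int
    expected_components: int

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    @property
    def n_links(self) -> int:
        return len(self.links)


def _verify_topology(volume: np.ndarray, truth: GroundTruth, name: str) -> None:
    chi = topology.euler_characteristic(volume)
    comps = topology.count_components(volume)
    if chi != truth.expected_chi or comps != truth.expected_components:
        raise AssertionError(
            f"{name} phantom violates its ground truth: chi {chi} (expected "
            f"{truth.expected_chi}), components {comps} (expected "
            f"{truth.expected_components})"
        )


def _ball_mask(shape, center, radius) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        (zz + 0.5 - center[0]) ** 2
        + (yy + 0.5 - center[1]) ** 2
        + (xx + 0.5 - center[2]) ** 2
    ) <= radius**2


def _stamp_curve(volume: np.ndarray, points: np.ndarray, radius: float) -> None:
    """Mark all voxels whose center is within ``radius`` of a sampled curve."""
    shape = volume.shape
    if radius <= 0:
        idx = np.floor(points).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        volume[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return
    h = int(np.ceil(radius)) + 1
    for p in points:
        c = np.floor(p).astype(int)
        z0, z1 = max(c[0] - h, 0), min(c[0] + h + 1, shape[0])
        y0, y1 = max(c[1] - h, 0), min(c[1] + h + 1, shape[1])
        x0, x1 = max(c[2] - h, 0), min(c[2] + h + 1, shape[2])
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1) + 0.5,
            np.arange(y0, y1) + 0.5,
            np.arange(x0, x1) + 0.5,
            indexing="ij",
        )
        d2 = (zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2
        volume[z0:z1, y0:y1, x0:x1] |= d2 <= radius**2


_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


def make_tube(
    length: int,
    radius: float,
    axis: str = "x",
    shape=None,
    geometry: VoxelGeometry = _UNIT_GEOMETRY,
) -> tuple[BinaryVolume, GroundTruth]:
    """Solid digital cylinder along a grid axis.

    Truth: one link between two end nodes with Lambda = (length - 1) voxel
    steps (center-to-center axis length).  ``radius`` 0 gives a 1-voxel-thin
    line, already a skeleton.  Defaults to the x axis.
    """
    if length < 3:
        raise ValueError("tube length must be >= 3 voxels")
    ax = _AXIS_INDEX[axis]
    lateral = max(int(np.ceil(radius)) * 2 + 3, 3)
    auto = [lateral, lateral, lateral]
    auto[ax] = length
    shape = tuple(shape) if shape is not None else tuple(auto)
    if shape[ax] < length:
        raise ValueError("tube does not fit in the requested shape")
    vol = np.zeros(shape, dtype=bool)
    center = [s / 2 for s in shape]
    lo = (shape[ax] - length) // 2
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = sum(
        (grids[i] + 0.5 - center[i]) ** 2 for i in range(3) if i != ax
    )
    along = (grids[ax] >= lo) & (grids[ax] < lo + length)
    vol |= (d2 <= max(radius, 0.5) ** 2) & along

    ends = []
    for pos in (lo + 0.5, lo + length - 0.5):
        p = list(center)
        p[ax] = pos
        ends.append(tuple(p))
    truth = GroundTruth(
        node_positions=ends,
        node_kinds=["end", "end"],
        links=[(0, 1, float(length - 1))],
        expected_chi=1,
        expected_components=1,
    )
    _verify_topology(vol, truth, "tube")
    return BinaryVolume(material=vol, geometry=geometry), truth


def make_arc(
    arc_radius: float,
    tube_radius: float,
    angle_deg: float = 180.0,
    geometry: VoxelGeometry = _UNIT_GEOMETRY,
) -> tuple[BinaryVolume, GroundTruth]:
    """Solid circular arc in the xy-plane whose chord endpoints touch the x faces.

    The centerline runs from polar angle 0 to ``angle_deg`` around a center
    placed so both endpoints lie on voxel centers of the first/last x-slice
    (for 180 degrees the arc spans the box along x, the configuration used
    for tortuosity checks: xi = arc/chord = pi/2 for a semicircle).  Truth
    Lambda is the analytic arc length.
    """
    if arc_radius <= 2 * tube_radius:
        raise ValueError("arc radius must exceed the tube diameter")
    theta = np.deg2rad(angle_deg)
    pad = tube_radius + 2.0
    r = arc_radius
    # physical center of the arc circle, in voxel units
    cx = r + 0.5 if angle_deg >= 90 else pad
    cy = pad
    xs = cx + r * np.cos(np.linspace(0, theta, max(int(8 * r * theta), 64)))
    ys = cy + r * np.sin(np.linspace(0, theta, max(int(8 * r * theta), 64)))
    nz = int(2 * pad + 1)
    cz = nz / 2
    nx = int(np.ceil(xs.max() + pad)) if angle_deg < 180 else int(2 * r + 1)
    ny = int(np.ceil(ys.max() + pad))
    vol = np.zeros((nz, ny, nx), dtype=bool)
    pts = np.stack([np.full_like(xs, cz), ys, xs], axis=1)
    _stamp_curve(vol, pts, tube_radius)
    truth = GroundTruth(
        node_positions=[(cz, ys[0], xs[0]), (cz, ys[-1], xs[-1])],
        node_kinds=["end", "end"],
        links=[(0, 1, float(r * theta))],
        expected_chi=1,
        expected_components=1,
    )
    _verify_topology(vol, truth, "arc")
    return BinaryVolume(material=vol, geometry=geometry), truth


def make_junction(
    arms=None,
    radius: float = 2.0,
    geometry: VoxelGeometry = _UNIT_GEOMETRY,
) -> tuple[BinaryVolume, GroundTruth]:
    """Solid arms radiating from a single center.

    ``arms`` is a list of (direction, length_voxels) with direction a 3-vector
    in (z, y, x) order; default is three orthogonal arms (+z, +y, +x) of 20
    voxels.  Truth: one branching node, one end node and one link per arm.
    """
    if arms is None:
        arms = [((1, 0, 0), 20), ((0, 1, 0), 20), ((0, 0, 1), 20)]
    if len(arms) < 3:
        raise ValueError("a junction needs at least 3 arms")
    dirs = [np.asarray(d, float) / np.linalg.norm(np.asarray(d, float)) for d, _ in arms]
    lengths = [float(l) for _, l in arms]
    pad = radius + 2.0
    reach = np.zeros(3)
    for d, l in zip(dirs, lengths):
        reach = np.maximum(reach, np.abs(d) * l)
    center = reach + pad
    shape = tuple(int(np.ceil(2 * c)) for c in center)
    vol = np.zeros(shape, dtype=bool)
    node_positions = [tuple(center)]
    node_kinds = ["branching"]
    links = []
    for i, (d, l) in enumerate(zip(dirs, lengths)):
        t = np.linspace(0, l, max(int(8 * l), 32))
        pts = center[None, :] + t[:, None] * d[None, :]
        _stamp_curve(vol, pts, radius)
        node_positions.append(tuple(center + l * d))
        node_kinds.append("end")
        links.append((0, i + 1, l))
    truth = GroundTruth(
        node_positions=node_positions,
        node_kinds=node_kinds,
        links=links,
        expected_chi=1,
        expected_components=1,
    )
    _verify_topology(vol, truth, "junction")
    return BinaryVolume(material=vol, geometry=geometry), truth


def make_torus(
    major_radius: float,
    minor_radius: float,
    shape=None,
    geometry: VoxelGeometry = _UNIT_GEOMETRY,
) -> tuple[BinaryVolume, GroundTruth]:
    """Solid torus around the z axis: chi = 0, one component, skeleton = cycle."""
    if minor_radius >= major_radius:
        raise ValueError("minor radius must be smaller than major radius")
    R, r = float(major_radius), float(minor_radius)
    if shape is None:
        lateral = int(np.ceil(2 * (R + r + 2)))
        shape = (int(np.ceil(2 * r + 5)), lateral, lateral)
    cz, cy, cx = (s / 2 for s in shape)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    rho = np.sqrt((yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2)
    vol = (rho - R) ** 2 + (zz + 0.5 - cz) ** 2 <= max(r, 0.5) ** 2
    truth = GroundTruth(
        node_positions=[],
        node_kinds=[],
        links=[(0, 0, float(2 * np.pi * R))],
        expected_chi=0,
        expected_components=1,
    )
    _verify_topology(vol, truth, "torus")
    return BinaryVolume(material=vol, geometry=geometry), truth


# ---------------------------------------------------------------------------
# bead-on-a-graph gel phantom


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between segments p1-p2 and q1-q2."""
    u = p2 - p1
    v = q2 - q1
    w = p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = np.clip((b * s + e) / c, 0.0, 1.0) if c > 1e-12 else 0.0
    # refine s for clamped t
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm((p1 + s * u) - (q1 + t * v)))


def make_bead_network(
    n_nodes: int,
    box: float | tuple = 40.0,
    sigma: float = 1.0,
    bead_spacing: float = 0.4,
    seed: int = 0,
    min_separation: float | None = None,
    edge_cutoff: float | None = None,
    extra_edge_fraction: float = 0.3,
) -> tuple[ParticleSet, GroundTruth, nx.MultiGraph]:
    """Random bead-on-a-graph gel: beads of diameter sigma laid along the
    edges of a random geometric graph.

    Construction: ``n_nodes`` points are dart-throw sampled with a minimum
    separation (default 5 sigma); the point nearest each box face is pulled
    onto that face so the structure percolates along all three axes; the
    Euclidean minimum spanning tree guarantees connectivity and extra short
    edges (up to ``extra_edge_fraction`` * n_nodes) add loops.  Edges that
    would pass within 2 sigma of an unrelated strand or node are rejected,
    since two strands closer than the morphological closing diameter would
    fuse during imaging.  Beads are placed at ``bead_spacing`` intervals
    (endpoints included).

    Returns the particle set, the ground truth *as the pipeline should see
    it* (degree-2 waypoints contracted into their strands), and the raw
    generative graph.
    """
    if bead_spacing > sigma:
        raise ValueError("bead_spacing must be <= sigma for strand contiguity")
    if min_separation is None:
        min_separation = 5.0 * sigma
    if edge_cutoff is None:
        edge_cutoff = 16.0 * sigma
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,))
    rng = np.random.default_rng(seed)

    # dart-throwing with minimum separation
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n_nodes:
        attempts += 1
        if attempts > 200 * n_nodes:
            raise RuntimeError(
                "cannot place nodes at the requested separation; enlarge the box"
            )
        p = rng.uniform(0, 1, 3) * box
        if all(np.linalg.norm(p - q) >= min_separation for q in points):
            points.append(p)
    pts = np.array(points)  # (x, y, z) == columns; box is isotropic so order-free

    # pull the node nearest each face onto that face (percolation anchors)
    for axis in range(3):
        for face_value in (0.0, box[axis]):
            dist_to_face = np.abs(pts[:, axis] - face_value)
            k = int(np.argmin(dist_to_face))
            pts[k, axis] = face_value

    # Edge construction: Kruskal-style spanning structure with geometric
    # constraints that keep the rendered strands recoverable — max node
    # degree 3 (higher-degree junctions generically skeletonize into split
    # Y-pairs), a minimum angle between edges sharing a node, and a minimum
    # separation between unrelated strands (closer strands fuse under the
    # morphological closing of the imaging route).
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    cand = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            cand.append((float(np.linalg.norm(pts[i] - pts[j])), i, j))
    cand.sort()

    edges: list[tuple[int, int]] = []
    min_angle_cos = np.cos(np.deg2rad(55.0))

    def angle_ok(i, j):
        u = pts[j] - pts[i]
        u = u / np.linalg.norm(u)
        for a, b in edges:
            for shared, far, direction in ((i, j, u), (j, i, -u)):
                if shared == a:
                    v = pts[b] - pts[a]
                elif shared == b:
                    v = pts[a] - pts[b]
                else:
                    continue
                v = v / np.linalg.norm(v)
                if float(direction @ v) > min_angle_cos:
                    return False
        return True

    def separation_ok(i, j):
        for a, b in edges:
            if len({i, j, a, b}) < 4:
                continue  # shares a node: adjacency, not a crossing
            if _segment_distance(pts[i], pts[j], pts[a], pts[b]) < 2.0 * sigma:
                return False
        for k in range(n_nodes):
            if k in (i, j):
                continue
            if _segment_distance(pts[i], pts[j], pts[k], pts[k]) < 2.0 * sigma:
                return False
        return True

    parent = list(range(n_nodes))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    degree = np.zeros(n_nodes, dtype=int)

    def try_add(i, j, join_only):
        if degree[i] >= 3 or degree[j] >= 3:
            return False
        if join_only and find(i) == find(j):
            return False
        if not (angle_ok(i, j) and separation_ok(i, j)):
            return False
        edges.append((i, j))
        degree[i] += 1
        degree[j] += 1
        parent[find(i)] = find(j)
        return True

    for d, i, j in cand:  # spanning pass (no length cutoff: connectivity first)
        try_add(i, j, join_only=True)
    n_components = len({find(k) for k in range(n_nodes)})
    if n_components > 1:
        # constraints too tight for full connectivity: join remaining
        # components by their cheapest bridging edges, angle waived
        for d, i, j in cand:
            if find(i) != find(j) and degree[i] < 3 and degree[j] < 3:
                edges.append((i, j))
                degree[i] += 1
                degree[j] += 1
                parent[find(i)] = find(j)
    n_extra = int(round(extra_edge_fraction * n_nodes))
    added = 0
    for d, i, j in cand:  # loop pass: short extra edges
        if added >= n_extra:
            break
        if d > edge_cutoff or (i, j) in edges:
            continue
        if try_add(i, j, join_only=False):
            added += 1

    g.add_edges_from(edges)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])

    # ground truth as the pipeline sees it: contract degree-2 waypoints
    reduced = nx.MultiGraph()
    for n in g.nodes:
        reduced.add_node(n)
    for i, j in g.edges:
        reduced.add_edge(i, j, length=float(np.linalg.norm(pts[i] - pts[j])))
    changed = True
    while changed:
        changed = False
        for n in sorted(reduced.nodes):
            if reduced.degree(n) != 2:
                continue
            inc = list(reduced.edges(n, keys=True, data=True))
            if len(inc) != 2:
                continue  # a self-loop counts degree 2 with one edge: keep
            (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
            a = v1 if u1 == n else u1
            b = v2 if u2 == n else u2
            reduced.remove_edge(u1, v1, k1)
            reduced.remove_edge(u2, v2, k2)
            reduced.remove_node(n)
            reduced.add_edge(a, b, length=d1["length"] + d2["length"])
            changed = True
            break
    reduced.remove_nodes_from([n for n in list(reduced.nodes) if reduced.degree(n) == 0])

    truth_nodes = sorted(reduced.nodes)
    index = {n: k for k, n in enumerate(truth_nodes)}
    truth_links = [
        (index[u], index[v], data["length"])
        for u, v, data in sorted(reduced.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    kinds = [
        "end" if reduced.degree(n) == 1 else "branching" for n in truth_nodes
    ]
    truth = GroundTruth(
        node_positions=[tuple(pts[n]) for n in truth_nodes],  # (x, y, z)
        node_kinds=kinds,
        links=truth_links,
        expected_chi=g.number_of_nodes() - g.number_of_edges(),
        expected_components=nx.number_connected_components(g),
    )

    # beads along every generative edge
    beads = [pts[i] for i in sorted(g.nodes)]
    for i, j in edges:
        d = np.linalg.norm(pts[j] - pts[i])
        n_seg = max(int(np.ceil(d / bead_spacing)), 1)
        for t in range(1, n_seg):
            beads.append(pts[i] + (pts[j] - pts[i]) * (t / n_seg))
    particles = ParticleSet(
        positions=np.array(beads),
        sigma=sigma,
        box=((0.0, 0.0, 0.0), tuple(box)),
        unit_label="sigma",
    )
    return particles, truth, g


def corrupt(
    stack: ImageStack, noise_sd: float, drift_per_slice: float, seed: int = 0
) -> ImageStack:
    """Depth-dependent intensity drift plus additive Gaussian noise.

    Slice z is scaled by (1 - drift_per_slice * z) — emulating fluorescence
    attenuation with focal depth — then zero-mean Gaussian noise of standard
    deviation ``noise_sd`` is added and the result clipped at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    nz = stack.shape[0]
    gain = 1.0 - drift_per_slice * np.arange(nz)
    values = stack.values * gain[:, None, None]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return ImageStack(values=np.clip(values, 0.0, None), geometry=stack.geometry)
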