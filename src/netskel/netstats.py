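"""Quantitative network statistics from a cleaned graph.

Reported quantities: node and link counts N_N and N_L, their ratio, node and
link densities rho_N and rho_L in 1/um^3 and 1/sigma^3, the normalized
link-length distribution N~(Lambda) (a probability density over the
along-path link length Lambda), and the tortuosity

    xi = < lambda / lambda_Euc >

averaged over paths along the backbone whose ends intersect the upper and
lower box face in either Cartesian direction, where lambda is the trajectory
length following the strand and lambda_Euc the Euclidean distance between the
path's end points.  Box edge effects are corrected by excluding a margin zone
(default 1.5 sigma) from the counts and from the density volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .graphify import NetworkGraph
from .skeletonize import Skeleton

__all__ = [
    "NetworkSummary",
    "LinkLengthHistogram",
    "TortuosityResult",
    "summarize",
    "link_length_histogram",
    "tortuosity",
    "analyze",
]


@dataclass
class NetworkSummary:
    """Counts and densities after box-edge correction.

    Unit conversion between um^-3 and sigma^-3 needs the particle diameter in
    micrometres; when the geometry is specified in sigma units and no
    um-per-sigma factor is known, the um-based densities are None.
    """

    n_nodes: int
    n_links: int
    links_per_node: float | None
    rho_n_um: float | None
    rho_l_um: float | None
    rho_n_sigma: float | None
    rho_l_sigma: float | None
    analysis_volume: float
    margin: float

    def as_dict(self) -> dict:
        return {
            "N_N": self.n_nodes,
            "N_L": self.n_links,
            "links_per_node": self.links_per_node,
            "rho_N_um": self.rho_n_um,
            "rho_L_um": self.rho_l_um,
            "rho_N_sigma": self.rho_n_sigma,
            "rho_L_sigma": self.rho_l_sigma,
            "analysis_volume": self.analysis_volume,
            "margin": self.margin,
        }


@dataclass
class LinkLengthHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray  # N~(Lambda), integrates to 1 over Lambda
    empty: bool = False


@dataclass
class TortuosityResult:
    xi_mean: float | None
    xi_std: float | None
    n_paths: int
    per_axis: dict  # axis name -> {"mean": float | None, "n": int}
    percolating: bool
    xi_values: np.ndarray = field(default_factory=lambda: np.empty(0))


def _interior_nodes(graph: NetworkGraph, margin: float) -> set[int]:
    (lo, hi) = np.asarray(graph.box[0]), np.asarray(graph.box[1])
    eps = 1e-9 * max(1.0, float(np.max(hi - lo)))
    keep = set()
    for nid, node in graph.nodes.items():
        p = np.asarray(node.position)
        if np.all(p >= lo + margin - eps) and np.all(p <= hi - margin + eps):
            keep.add(nid)
    return keep


def summarize(
    graph: NetworkGraph, margin: float, sigma_um: float | None = None
) -> NetworkSummary:
    """Counts and densities, excluding a margin zone at the box faces.

    Nodes within ``margin`` of any box face are excluded from N_N; links with
    either endpoint excluded are excluded from N_L.  The density volume is
    the margin-shrunken box.  ``sigma_um`` is the particle diameter in
    micrometres (needed for unit conversion when the grid is in sigma units).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    lo, hi = np.asarray(graph.box[0]), np.asarray(graph.box[1])
    extent = hi - lo - 2 * margin
    if np.any(extent <= 0):
        raise ValueError("margin consumes the whole analysis box")
    volume = float(np.prod(extent))  # in geometry units^3

    keep = _interior_nodes(graph, margin)
    n_nodes = len(keep)
    n_links = sum(
        1 for l in graph.links.values() if l.u in keep and l.v in keep
    )
    links_per_node = (n_links / n_nodes) if n_nodes > 0 else None

    sigma = graph.sigma  # in geometry units
    rho_n = n_nodes / volume
    rho_l = n_links / volume
    if graph.geometry.unit_label == "um":
        rho_n_um, rho_l_um = rho_n, rho_l
        rho_n_sigma = rho_n * sigma**3
        rho_l_sigma = rho_l * sigma**3
    else:  # grid in sigma units
        rho_n_sigma = rho_n * sigma**3
        rho_l_sigma = rho_l * sigma**3
        if sigma_um is not None:
            rho_n_um = rho_n_sigma / sigma_um**3
            rho_l_um = rho_l_sigma / sigma_um**3
        else:
            rho_n_um = rho_l_um = None
    return NetworkSummary(
        n_nodes=n_nodes,
        n_links=n_links,
        links_per_node=links_per_node,
        rho_n_um=rho_n_um,
        rho_l_um=rho_l_um,
        rho_n_sigma=rho_n_sigma,
        rho_l_sigma=rho_l_sigma,
        analysis_volume=volume,
        margin=margin,
    )


def link_length_histogram(
    graph: NetworkGraph, bins=20, margin: float = 0.0
) -> LinkLengthHistogram:
    """Histogram of link lengths Lambda with density normalization.

    ``bins`` is either a bin count (equal-width bins from 0 to the maximum
    Lambda) or explicit edges.  Links excluded by the edge margin are not
    counted, so the counts total matches N_L of :func:`summarize` at the same
    margin.
    """
    keep = _interior_nodes(graph, margin) if margin > 0 else set(graph.nodes)
    lengths = np.array(
        [l.length for l in graph.links.values() if l.u in keep and l.v in keep]
    )
    if lengths.size == 0:
        edges = np.asarray(bins, float) if np.ndim(bins) else np.linspace(0, 1, int(bins) + 1)
        return LinkLengthHistogram(
            bin_edges=edges,
            counts=np.zeros(len(edges) - 1, dtype=int),
            normalized=np.zeros(len(edges) - 1),
            empty=True,
        )
    if np.ndim(bins) == 0:
        edges = np.linspace(0.0, float(lengths.max()) or 1.0, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(lengths, bins=edges)
    widths = np.diff(edges)
    total = counts.sum()
    normalized = counts / (total * widths) if total > 0 else np.zeros_like(widths)
    return LinkLengthHistogram(
        bin_edges=edges, counts=counts, normalized=normalized, empty=total == 0
    )


def _skeleton_csgraph(skeleton: Skeleton):
    """Sparse 26-adjacency graph of skeleton voxels with physical step weights."""
    coords = np.argwhere(skeleton.data)
    n = len(coords)
    index = np.full(skeleton.data.shape, -1, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(n)
    steps = skeleton.geometry.zyx
    rows, cols, weights = [], [], []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)  # half the offsets; graph is symmetric
    ]
    shape = skeleton.data.shape
    for off in offsets:
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < shape), axis=1)
        src = np.arange(n)[ok]
        dst = index[tuple(shifted[ok].T)]
        hit = dst >= 0
        w = float(np.sqrt(((np.array(off) * steps) ** 2).sum()))
        rows.append(src[hit])
        cols.append(dst[hit])
        weights.append(np.full(hit.sum(), w))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    mat = coo_matrix(
        (np.concatenate([weights, weights]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    return coords, mat


def tortuosity(
    graph: NetworkGraph, skeleton: Skeleton, face_depth: float | None = None
) -> TortuosityResult:
    """Tortuosity xi of box-spanning backbone strands.

    For every Cartesian axis, skeleton voxels within ``face_depth`` of the two
    opposite box faces are the path terminals (thinning retreats strand ends
    by about the strand radius, so a shell rather than the literal face layer
    is used; ``None`` means one voxel).  From each upper-face voxel A the
    shortest along-skeleton path (physical step weights) to the set of
    lower-face voxels yields lambda and the Euclidean A-B distance
    lambda_Euc; the ratios are pooled over the three axes.
    """
    if skeleton.count() == 0:
        return TortuosityResult(
            xi_mean=None, xi_std=None, n_paths=0,
            per_axis={a: {"mean": None, "n": 0} for a in "zyx"},
            percolating=False,
        )
    coords, mat = _skeleton_csgraph(skeleton)
    steps = skeleton.geometry.zyx
    positions = (coords + 0.5) * steps
    shape = skeleton.data.shape

    ratios_all = []
    per_axis = {}
    for axis, name in enumerate("zyx"):
        depth_vox = (
            1 if face_depth is None else max(1, int(np.ceil(face_depth / steps[axis])))
        )
        top = np.flatnonzero(coords[:, axis] < depth_vox)
        bottom = np.flatnonzero(coords[:, axis] >= shape[axis] - depth_vox)
        both = set(top) & set(bottom)
        top = np.array([i for i in top if i not in both], dtype=np.int64)
        bottom = np.array([i for i in bottom if i not in both], dtype=np.int64)
        if len(top) == 0 or len(bottom) == 0:
            per_axis[name] = {"mean": None, "n": 0}
            continue
        dist, _, sources = dijkstra(
            mat, directed=False, indices=bottom, min_only=True,
            return_predecessors=True,
        )
        ratios = []
        for a in top:
            lam = dist[a]
            if not np.isfinite(lam) or lam <= 0:
                continue
            b = sources[a]
            euc = float(np.sqrt(((positions[a] - positions[b]) ** 2).sum()))
            if euc <= 0:
                continue
            ratios.append(lam / euc)
        if ratios:
            per_axis[name] = {"mean": float(np.mean(ratios)), "n": len(ratios)}
            ratios_all.extend(ratios)
        else:
            per_axis[name] = {"mean": None, "n": 0}

    if not ratios_all:
        return TortuosityResult(
            xi_mean=None, xi_std=None, n_paths=0, per_axis=per_axis,
            percolating=False,
        )
    arr = np.array(ratios_all)
    return TortuosityResult(
        xi_mean=float(arr.mean()),
        xi_std=float(arr.std()),
        n_paths=len(arr),
        per_axis=per_axis,
        percolating=True,
        xi_values=arr,
    )


def analyze(
    graph: NetworkGraph,
    skeleton: Skeleton,
    margin: float | None = None,
    bins=20,
    face_depth: float | None = None,
    sigma_um: float | None = None,
) -> dict:
    """Bundle summary, histogram and tortuosity into one report dict.

    ``margin`` defaults to 1.5 sigma.  Graph components are additionally
    reported separately (surviving clusters are independent network
    structures) and pooled.
    """
    if margin is None:
        margin = 1.5 * graph.sigma
    summary = summarize(graph, margin, sigma_um=sigma_um)
    hist = link_length_histogram(graph, bins=bins, margin=margin)
    tort = tortuosity(graph, skeleton, face_depth=face_depth)

    # per-component counts (no margin: components are a structural property)
    comp_of: dict[int, int] = {}
    parent = {nid: nid for nid in graph.nodes}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for l in graph.links.values():
        ru, rv = find(l.u), find(l.v)
        if ru != rv:
            parent[max(ru, rv)] = min(ru, rv)
    comp_nodes: dict[int, int] = {}
    for nid in graph.nodes:
        comp_of[nid] = find(nid)
        comp_nodes[comp_of[nid]] = comp_nodes.get(comp_of[nid], 0) + 1
    comp_links: dict[int, int] = {}
    for l in graph.links.values():
        comp_links[comp_of[l.u]] = comp_links.get(comp_of[l.u], 0) + 1
    components = [
        {"n_nodes": comp_nodes[c], "n_links": comp_links.get(c, 0)}
        for c in sorted(comp_nodes)
    ]

    return {
        "summary": summary.as_dict(),
        "histogram": {
            "bin_edges": hist.bin_edges.tolist(),
            "counts": hist.counts.tolist(),
            "normalized": hist.normalized.tolist(),
            "empty": bool(hist.empty),
        },
        "tortuosity": {
            "xi_mean": tort.xi_mean,
            "xi_std": tort.xi_std,
            "n_paths": tort.n_paths,
            "per_axis": tort.per_axis,
            "percolating": tort.percolating,
        },
        "n_components": len(components),
        "components": components,
    }
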