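"""End-to-end orchestration: configuration, the run loop, and overlay export.

``run`` executes preprocess -> skeletonize -> graphify (clean) -> netstats for
every input file and writes the full artifact set: node and link tables,
report JSON, histogram CSV, cleaned-skeleton TIFF, diagnostic overlays, and a
log of every parameter and per-stage count actually used.  Runs are fully
deterministic: identical configuration and inputs produce byte-identical
tables and reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .graphify import (
    CleaningParams,
    NetworkGraph,
    clean_graph,
    extract_graph,
    graph_to_skeleton,
)
from .netstats import analyze
from .preprocess import BinarizationParams, preprocess_stack
from .skeletonize import Skeleton, thin_volume
from .volume_io import (
    ImageStack,
    VoxelGeometry,
    default_psf,
    project_particles,
    read_coordinates,
    read_stack,
    write_stack,
)

__all__ = ["RunConfig", "run", "run_single", "render_overlays", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Everything a run needs; defaults follow the documented module defaults.

    Thresholds given as None are derived from the particle diameter sigma:
    closing semi-axes 0.25 sigma, hole threshold = voxel volume of one
    particle, side-chain threshold 1.5 sigma, node-collection threshold 0.9
    sigma, edge margin 1.5 sigma, tortuosity face shell 1.0 sigma.
    """

    inputs: list = field(default_factory=list)
    input_kind: str = "tiff"  # "tiff" | "coordinates"
    z_range: tuple | None = None  # (first, last) slice indices, inclusive
    voxel_size: tuple = (1.0, 1.0, 1.0)  # (dx, dy, dz), physical
    unit_label: str = "um"
    sigma: float = 1.0  # particle diameter in the same units
    binarization_method: str = "otsu"
    v_u: float = 0.5
    blur_voxels: float = 1.0
    closing_radii: float | None = None
    min_fraction: float = 0.01
    max_hole_voxels: int | None = None
    min_side_chain: float | None = None
    node_collect_dist: float | None = None
    max_clean_iterations: int = 10
    margin: float | None = None
    bins: int = 20
    use_psf: bool = False
    psf_sigma_xy: float | None = None
    psf_sigma_z: float | None = None
    point_emitters: bool = False
    face_depth: float | None = None
    outdir: str = "netskel_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_kind not in ("tiff", "coordinates"):
            raise ConfigError(f"input_kind must be 'tiff' or 'coordinates', got {self.input_kind!r}")
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if len(tuple(self.voxel_size)) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigError("voxel_size must be three positive numbers (dx, dy, dz)")
        if self.binarization_method not in ("otsu", "percentile"):
            raise ConfigError("binarization_method must be 'otsu' or 'percentile'")
        if not 0.0 <= self.v_u <= 1.0:
            raise ConfigError("v_u must lie in [0, 1]")
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ConfigError("min_fraction must lie in [0, 1]")
        if self.bins <= 0:
            raise ConfigError("bins must be a positive count")

    @property
    def geometry(self) -> VoxelGeometry:
        dx, dy, dz = self.voxel_size
        return VoxelGeometry(dx=dx, dy=dy, dz=dz, unit_label=self.unit_label)

    def resolved(self) -> dict:
        """All parameters with sigma-derived defaults filled in."""
        d = asdict(self)
        d["closing_radii"] = (
            self.closing_radii if self.closing_radii is not None else 0.25 * self.sigma
        )
        d["max_hole_voxels"] = (
            self.max_hole_voxels
            if self.max_hole_voxels is not None
            else int(np.ceil((np.pi / 6) * self.sigma**3 / self.geometry.voxel_volume))
        )
        d["min_side_chain"] = (
            self.min_side_chain if self.min_side_chain is not None else 1.5 * self.sigma
        )
        d["node_collect_dist"] = (
            self.node_collect_dist
            if self.node_collect_dist is not None
            else 0.9 * self.sigma
        )
        d["margin"] = self.margin if self.margin is not None else 1.5 * self.sigma
        d["face_depth"] = (
            self.face_depth if self.face_depth is not None else 1.0 * self.sigma
        )
        d["psf_sigma_xy"] = (
            self.psf_sigma_xy if self.psf_sigma_xy is not None else 0.21 * self.sigma
        )
        d["psf_sigma_z"] = (
            self.psf_sigma_z if self.psf_sigma_z is not None else 0.75 * self.sigma
        )
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config field(s): {sorted(unknown)}")
        for key in ("z_range", "voxel_size"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["voxel_size"] = list(self.voxel_size)
        d["z_range"] = list(self.z_range) if self.z_range else None
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _load_input(path: str | Path, config: RunConfig) -> ImageStack:
    geometry = config.geometry
    if config.input_kind == "tiff":
        stack = read_stack(path, geometry)
        if config.z_range is not None:
            z0, z1 = config.z_range
            stack = ImageStack(values=stack.values[z0 : z1 + 1], geometry=geometry)
        return stack
    particles = read_coordinates(path, sigma=config.sigma, unit_label=config.unit_label)
    psf = None
    if config.use_psf:
        r = config.resolved()
        psf = default_psf(geometry, r["psf_sigma_xy"], r["psf_sigma_z"])
    return project_particles(
        particles, geometry, psf=psf, point_emitters=config.point_emitters
    )


def run_single(
    stack: ImageStack, config: RunConfig, outdir: str | Path | None = None, label: str = "input"
) -> dict:
    """Run the full analysis on one stack; optionally write artifacts."""
    r = config.resolved()
    params = BinarizationParams(method=config.binarization_method, v_u=config.v_u)
    volume, cluster_labels, prep_report = preprocess_stack(
        stack,
        params=params,
        blur_widths=config.blur_voxels,
        closing_radii=r["closing_radii"],
        min_fraction=config.min_fraction,
        max_hole_voxels=r["max_hole_voxels"],
        sigma=config.sigma,
    )
    skeleton_raw = thin_volume(volume)
    graph = extract_graph(skeleton_raw, sigma=config.sigma)
    nodes_raw, links_raw = graph.n_nodes, graph.n_links
    cleaning = CleaningParams(
        min_side_chain=r["min_side_chain"],
        node_collect_dist=r["node_collect_dist"],
        max_iterations=config.max_clean_iterations,
    )
    graph = clean_graph(graph, cleaning)
    skeleton = graph_to_skeleton(graph, shape=stack.shape)
    report = analyze(
        graph,
        skeleton,
        margin=r["margin"],
        bins=config.bins,
        face_depth=r["face_depth"],
    )
    report["stages"] = {
        "material_voxels": volume.count(),
        "clusters_kept": prep_report.n_clusters_kept,
        "cluster_sizes": sorted(prep_report.cluster_sizes, reverse=True)[:20],
        "voxels_added_by_preprocessing": int(prep_report.added.sum()),
        "voxels_removed_by_preprocessing": int(prep_report.removed.sum()),
        "skeleton_voxels_raw": skeleton_raw.count(),
        "skeleton_voxels_clean": skeleton.count(),
        "n_nodes_raw": nodes_raw,
        "n_links_raw": links_raw,
        "n_nodes": graph.n_nodes,
        "n_links": graph.n_links,
    }
    report["thresholds"] = [
        {
            "slice": t.slice_index,
            "I_10": t.i_10,
            "I_90": t.i_90,
            "I_T": t.i_t,
            "degenerate": t.degenerate,
        }
        for t in prep_report.thresholds
    ]
    # analysis parameters only; file-system paths stay out of the report
    report["parameters"] = {
        k: v for k, v in r.items() if k not in ("outdir", "inputs")
    }
    report["version"] = __version__

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tables(graph, outdir, label)
        _write_report(report, outdir / f"{label}_report.json")
        _write_histogram_csv(report, outdir / f"{label}_histogram.csv")
        write_stack(skeleton.to_volume(), outdir / f"{label}_skeleton_clean.tif")
        render_overlays(stack, skeleton, graph, outdir, label=label)
        _write_binarization_overlay(stack, volume, prep_report, outdir, label)
    return {
        "report": report,
        "graph": graph,
        "skeleton": skeleton,
        "volume": volume,
    }


def run(config: RunConfig) -> dict:
    """Run the pipeline on every configured input; pool batch statistics."""
    if not config.inputs:
        raise ConfigError("no inputs configured (field: inputs)")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_used.yaml")
    per_file = {}
    for path in config.inputs:
        label = Path(path).stem
        stack = _load_input(path, config)
        result = run_single(stack, config, outdir=outdir, label=label)
        per_file[label] = result["report"]
    pooled = _pool_reports(per_file)
    _write_report(pooled, outdir / "pooled_report.json")
    return {"per_file": per_file, "pooled": pooled, "outdir": str(outdir)}


def _pool_reports(per_file: dict) -> dict:
    """Mean-over-files pooling of the scalar statistics."""

    def collect(path):
        vals = []
        for rep in per_file.values():
            v = rep
            for key in path:
                v = v[key]
            if v is not None:
                vals.append(v)
        return vals

    pooled = {"n_files": len(per_file), "files": sorted(per_file)}
    for name, path in [
        ("N_N", ("summary", "N_N")),
        ("N_L", ("summary", "N_L")),
        ("links_per_node", ("summary", "links_per_node")),
        ("rho_N_um", ("summary", "rho_N_um")),
        ("rho_L_um", ("summary", "rho_L_um")),
        ("rho_N_sigma", ("summary", "rho_N_sigma")),
        ("rho_L_sigma", ("summary", "rho_L_sigma")),
        ("xi_mean", ("tortuosity", "xi_mean")),
        ("xi_std", ("tortuosity", "xi_std")),
    ]:
        vals = collect(path)
        pooled[name] = {
            "mean": float(np.mean(vals)) if vals else None,
            "std": float(np.std(vals)) if vals else None,
            "n": len(vals),
        }
    return pooled


def _write_tables(graph: NetworkGraph, outdir: Path, label: str) -> None:
    deg = graph.degrees()
    steps = graph.geometry.zyx
    node_rows = []
    for nid in sorted(graph.nodes):
        n = graph.nodes[nid]
        # positions stored (z, y, x); tables use x, y, z columns
        node_rows.append(
            {
                "id": nid,
                "kind": n.kind,
                "x": n.position[2],
                "y": n.position[1],
                "z": n.position[0],
                "degree": deg[nid],
            }
        )
    pd.DataFrame(
        node_rows, columns=["id", "kind", "x", "y", "z", "degree"]
    ).to_csv(outdir / f"{label}_nodes.csv", index=False, float_format="%.6f")
    link_rows = [
        {
            "id": lid,
            "node_a": graph.links[lid].u,
            "node_b": graph.links[lid].v,
            "Lambda": graph.links[lid].length,
            "n_path_voxels": len(graph.links[lid].path),
        }
        for lid in sorted(graph.links)
    ]
    pd.DataFrame(
        link_rows, columns=["id", "node_a", "node_b", "Lambda", "n_path_voxels"]
    ).to_csv(outdir / f"{label}_links.csv", index=False, float_format="%.6f")


def _write_report(report: dict, path: Path) -> None:
    path.write_text(json.dumps(report, indent=1, sort_keys=True, default=float) + "\n")


def _write_histogram_csv(report: dict, path: Path) -> None:
    h = report["histogram"]
    edges = np.asarray(h["bin_edges"])
    centers = 0.5 * (edges[:-1] + edges[1:])
    df = pd.DataFrame(
        {
            "bin_center": centers,
            "count": h["counts"],
            "N_normalized": h["normalized"],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def _to_gray8(values: np.ndarray) -> np.ndarray:
    peak = values.max()
    if peak <= 0:
        return np.zeros(values.shape, dtype=np.uint8)
    return np.clip(values / peak * 255, 0, 255).astype(np.uint8)


def render_overlays(
    stack: ImageStack,
    skeleton: Skeleton,
    graph: NetworkGraph,
    outdir: str | Path,
    label: str = "input",
) -> list[Path]:
    """Write the skeleton/node overlay stack and three projections.

    Per-slice RGB TIFF: raw grayscale background with skeleton voxels green
    and branching-node voxels blue; plus maximum-intensity projections of the
    skeleton along each axis.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gray = _to_gray8(stack.values)
    rgb = np.stack([gray, gray, gray], axis=-1)
    sk = skeleton.data
    rgb[sk] = (0, 255, 0)
    branch = np.zeros(sk.shape, dtype=bool)
    for node in graph.nodes.values():
        if node.kind == "branching":
            for v in node.voxels:
                branch[tuple(v)] = True
    rgb[branch] = (0, 0, 255)
    paths = []
    overlay_path = outdir / f"{label}_skeleton_overlay.tif"
    tifffile.imwrite(overlay_path, rgb, photometric="rgb")
    paths.append(overlay_path)
    for axis, name in ((0, "z"), (1, "y"), (2, "x")):
        mip = (sk.max(axis=axis) * np.uint8(255)).astype(np.uint8)
        p = outdir / f"{label}_mip_{name}.tif"
        tifffile.imwrite(p, mip)
        paths.append(p)
    return paths


def _write_binarization_overlay(stack, volume, prep_report, outdir: Path, label: str) -> None:
    """Diagnostic overlays: material filter (green/red on raw) and the
    preprocessing diff (white = unchanged material, green = added, red = removed)."""
    gray = _to_gray8(stack.values)
    # binarization filter: green where material, red where not (scaled by intensity)
    rgb = np.zeros(gray.shape + (3,), dtype=np.uint8)
    rgb[..., 1] = np.where(volume.material, gray, 0)
    rgb[..., 0] = np.where(~volume.material, gray, 0)
    tifffile.imwrite(outdir / f"{label}_binarization_overlay.tif", rgb, photometric="rgb")

    diff = np.zeros(gray.shape + (3,), dtype=np.uint8)
    unchanged = volume.material & ~prep_report.added
    diff[unchanged] = (255, 255, 255)
    diff[prep_report.added] = (0, 255, 0)
    diff[prep_report.removed] = (255, 0, 0)
    tifffile.imwrite(outdir / f"{label}_preprocess_diff.tif", diff, photometric="rgb")
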