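"""Voronoi-tessellation density segmentation of localization tables.

Cells are clipped exactly to the ROI rectangle by augmenting the point
set with mirror images across the four ROI edges: each point's own
mirrors cut its cell at the edge lines, and mirrors can never claim
interior area, so the clipped cells tile the rectangle exactly.  The
mirroring is adaptive — only points whose raw cells cross the boundary
are mirrored — which keeps the second tessellation pass cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import QhullError, Voronoi, cKDTree

from .models import FluorophoreModel, LocalizationTable, RoiGeometry

log = logging.getLogger(__name__)

__all__ = [
    "DensityField",
    "ClusterAssignment",
    "merge_blinks",
    "compute_voronoi_densities",
    "segment_clusters",
]


@dataclass
class DensityField:
    """First-rank Voronoi density per localization (1 / clipped cell area)."""

    density: np.ndarray  # nm^-2 per localization; NaN where invalid
    cell_area: np.ndarray  # nm^2 per localization (duplicates share a cell)
    valid: np.ndarray  # False for degenerate inputs
    # segmentation internals: geometry on the deduplicated point set
    unique_points: np.ndarray
    unique_inverse: np.ndarray
    adjacency: np.ndarray  # (m, 2) unique-point index pairs sharing a Voronoi edge

    def __len__(self) -> int:
        return len(self.density)


@dataclass
class ClusterAssignment:
    """Per-localization cluster labels; -1 marks noise."""

    labels: np.ndarray
    n_clusters: int

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def _coords(locs) -> np.ndarray:
    if isinstance(locs, LocalizationTable):
        return locs.xy
    return np.asarray(locs, float).reshape(-1, 2)


def merge_blinks(
    locs: LocalizationTable, fluor: FluorophoreModel, merge_radius_nm: float
) -> LocalizationTable:
    """Merge re-blinks of the same molecule to their centroid.

    Localizations within ``merge_radius_nm`` of each other and separated
    by at most ``fluor.max_dark_time_frames`` frames are joined
    transitively (union-find over qualifying pairs).  Off by default in
    the pipeline.
    """
    if merge_radius_nm <= 0:
        raise ValueError("merge_radius_nm must be positive")
    df = locs.data
    if len(df) < 2:
        return locs

    xy = locs.xy
    frames = df["frame"].to_numpy()
    pairs = cKDTree(xy).query_pairs(merge_radius_nm, output_type="ndarray")
    if len(pairs):
        gap_ok = np.abs(frames[pairs[:, 0]] - frames[pairs[:, 1]]) <= fluor.max_dark_time_frames
        pairs = pairs[gap_ok]

    parent = np.arange(len(df))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    roots = np.array([find(i) for i in range(len(df))])
    _, group = np.unique(roots, return_inverse=True)
    ng = group.max() + 1

    out = (
        df.assign(_g=group)
        .groupby("_g", sort=True)
        .agg(
            x_nm=("x_nm", "mean"),
            y_nm=("y_nm", "mean"),
            frame=("frame", "min"),
            intensity=("intensity", "sum"),
            channel=("channel", "first"),
        )
        .reset_index(drop=True)
    )
    merged = locs.with_data(out)
    merged.meta = dict(locs.meta, n_merged=len(df) - ng)
    return merged


def _clipped_voronoi(points: np.ndarray, roi: RoiGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Exact ROI-clipped cell areas and shared-edge adjacency.

    Returns (areas[n], adjacency pairs on the input index set).
    """
    n = len(points)
    w, h = roi.width_nm, roi.height_nm

    def mirrors(p):
        # a point exactly on an edge is its own mirror there; skip those
        out = [
            (p * [-1.0, 1.0])[p[:, 0] > 0],
            np.column_stack([2.0 * w - p[:, 0], p[:, 1]])[p[:, 0] < w],
            (p * [1.0, -1.0])[p[:, 1] > 0],
            np.column_stack([p[:, 0], 2.0 * h - p[:, 1]])[p[:, 1] < h],
        ]
        return np.vstack(out)

    vor = Voronoi(points)

    def crossing(v: Voronoi) -> np.ndarray:
        flags = np.zeros(n, bool)
        verts = v.vertices
        for i in range(n):
            reg = v.regions[v.point_region[i]]
            if -1 in reg:
                flags[i] = True
                continue
            vv = verts[reg]
            if (
                (vv[:, 0] < 0).any()
                or (vv[:, 0] > w).any()
                or (vv[:, 1] < 0).any()
                or (vv[:, 1] > h).any()
            ):
                flags[i] = True
        return flags

    flagged = crossing(vor)
    if flagged.any():
        vor = Voronoi(np.vstack([points, mirrors(points[flagged])]))

    areas = np.empty(n)
    verts = vor.vertices
    for i in range(n):
        reg = vor.regions[vor.point_region[i]]
        vv = verts[reg]
        x, y = vv[:, 0], vv[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

    rp = vor.ridge_points
    keep = (rp[:, 0] < n) & (rp[:, 1] < n)
    adjacency = rp[keep]
    return areas, adjacency


def compute_voronoi_densities(locs, roi: RoiGeometry) -> DensityField:
    """First-rank Voronoi density for every localization.

    Cells are clipped to the ROI rectangle, so every cell is bounded and
    the clipped areas sum exactly to the ROI area.  Duplicate
    coordinates share one cell (and its density).  Fewer than 4 unique
    points, or a collinear point set, yields an all-invalid field that
    segments to pure noise.
    """
    pts = _coords(locs)
    n = len(pts)
    invalid = DensityField(
        density=np.full(n, np.nan),
        cell_area=np.full(n, np.nan),
        valid=np.zeros(n, bool),
        unique_points=np.empty((0, 2)),
        unique_inverse=np.zeros(n, int),
        adjacency=np.empty((0, 2), int),
    )
    if n == 0:
        return invalid

    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    if len(uniq) < 4:
        return invalid
    try:
        areas_u, adjacency = _clipped_voronoi(uniq, roi)
    except QhullError:
        log.warning("degenerate (collinear?) localization set; all flagged noise")
        return invalid

    areas = areas_u[inverse]
    return DensityField(
        density=1.0 / areas,
        cell_area=areas,
        valid=np.ones(n, bool),
        unique_points=uniq,
        unique_inverse=inverse,
        adjacency=adjacency,
    )


def segment_clusters(
    locs,
    densities: DensityField,
    roi: RoiGeometry,
    threshold_factor: float = 2.0,
    min_neighbors: int = 0,
    max_link_nm: float | None = 100.0,
    smooth_neighbors: bool = False,
    connectivity: str = "core-attach",
) -> ClusterAssignment:
    """Threshold densities and join cells sharing a Voronoi edge.

    Core localizations have density >= threshold_factor * (n_loc / ROI
    area), ties included.  Connectivity follows the tessellation: two
    localizations are linked when their Voronoi cells share an edge and,
    when ``max_link_nm`` is set (default 100 nm), their coordinates lie
    within that distance — the distance gate suppresses the spurious
    adjacency that cells of well-separated particles acquire across
    empty space.

    connectivity modes:
      * ``core-attach`` (default): connected components are built over
        all localizations; a component is a cluster iff it contains at
        least one core.  Boundary cells of a dense particle have large
        (low-density) cells and would otherwise be orphaned.
      * ``core-only``: only core-core links count and sub-threshold
        localizations are always noise.

    Components with fewer than 2 member localizations are noise.
    ``smooth_neighbors`` averages each density with its Voronoi
    neighbors before thresholding; ``min_neighbors`` additionally
    requires that many core Voronoi neighbors for core status.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    if connectivity not in ("core-attach", "core-only"):
        raise ValueError(f"unknown connectivity mode {connectivity!r}")
    n = len(densities.density)
    labels = np.full(n, -1, dtype=int)
    if n == 0 or not densities.valid.any():
        return ClusterAssignment(labels, 0)

    mean_density = n / roi.area_nm2
    threshold = threshold_factor * mean_density

    nu = len(densities.unique_points)
    inverse = densities.unique_inverse
    dens_u = np.empty(nu)
    dens_u[inverse] = densities.density  # duplicates share a value

    adj = densities.adjacency
    if smooth_neighbors and len(adj):
        deg = np.bincount(adj.ravel(), minlength=nu)
        acc = np.zeros(nu)
        np.add.at(acc, adj[:, 0], dens_u[adj[:, 1]])
        np.add.at(acc, adj[:, 1], dens_u[adj[:, 0]])
        dens_u = (dens_u + acc) / (1.0 + deg)

    with np.errstate(invalid="ignore"):
        core_u = dens_u >= threshold  # inclusive at the threshold

    if min_neighbors > 0 and len(adj):
        core_deg = np.zeros(nu, int)
        both = core_u[adj[:, 0]] & core_u[adj[:, 1]]
        np.add.at(core_deg, adj[both, 0], 1)
        np.add.at(core_deg, adj[both, 1], 1)
        core_u &= core_deg >= min_neighbors

    if not core_u.any():
        return ClusterAssignment(labels, 0)

    edges = adj
    if connectivity == "core-only" and len(edges):
        edges = edges[core_u[edges[:, 0]] & core_u[edges[:, 1]]]
    if max_link_nm is not None and len(edges):
        up = densities.unique_points
        d2 = ((up[edges[:, 0]] - up[edges[:, 1]]) ** 2).sum(1)
        edges = edges[d2 <= max_link_nm**2]

    graph = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(nu, nu)
    )
    _, comp_u = connected_components(graph, directed=False)

    # a component is a cluster iff it contains a core (core-attach) or,
    # in core-only mode, membership itself requires core status
    has_core = np.zeros(comp_u.max() + 1, bool)
    np.add.at(has_core, comp_u[core_u], True)
    member_u = has_core[comp_u] if connectivity == "core-attach" else core_u
    comp = np.where(member_u[inverse], comp_u[inverse], -1)

    # keep components with >= 2 member localizations; relabel contiguously
    # in order of first appearance so labeling is deterministic
    labels_out = np.full(n, -1, dtype=int)
    next_label = 0
    seen: dict[int, int] = {}
    sizes: dict[int, int] = {}
    for c in comp[comp >= 0]:
        sizes[c] = sizes.get(c, 0) + 1
    for i in range(n):
        c = comp[i]
        if c < 0 or sizes[c] < 2:
            continue
        if c not in seen:
            seen[c] = next_label
            next_label += 1
        labels_out[i] = seen[c]
    return ClusterAssignment(labels_out, next_label)
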