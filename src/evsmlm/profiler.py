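"""Cluster admission filtering, cargo estimation and morphometry.

Admission rules: candidate clusters in the small size class (20-100 nm
equivalent-circle diameter) are admitted when their localization count
lies in [small_min_factor * alpha, small_max_loc]; clusters above 100 nm
are admitted when the count lies in [large_min_loc, large_max_loc] and,
when a size cap is configured, the diameter does not exceed it.  All
bounds are inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .models import LocalizationTable

__all__ = [
    "ClusterFilterConfig",
    "Morphology",
    "CandidateCluster",
    "ParticleRecord",
    "estimate_cargo",
    "compute_morphology",
    "measure_clusters",
    "classify_and_filter",
]


@dataclass(frozen=True)
class ClusterFilterConfig:
    """Admission rules for candidate clusters.

    ``mouse_mode`` switches to the stricter small-cluster gate used for
    mouse plasma and tissue data: small range [30, 100] nm and a minimum
    of 2.5 x alpha localizations.
    """

    small_range_nm: tuple[float, float] = (20.0, 100.0)
    small_min_factor: float = 2.0
    small_max_loc: int = 2_000
    large_min_loc: int = 100
    large_max_loc: int = 15_000
    size_cap_nm: float | None = None
    mouse_mode: bool = False

    def __post_init__(self) -> None:
        if self.mouse_mode:
            object.__setattr__(self, "small_range_nm", (30.0, 100.0))
            object.__setattr__(self, "small_min_factor", 2.5)
        lo, hi = self.small_range_nm
        if not lo < hi:
            raise ValueError("small_range_nm lower bound must be < upper bound")
        if self.small_min_factor <= 0:
            raise ValueError("small_min_factor must be positive")
        if self.small_max_loc < 1 or self.large_min_loc < 1:
            raise ValueError("localization count bounds must be >= 1")
        if self.large_min_loc > self.large_max_loc:
            raise ValueError("large_min_loc must be <= large_max_loc")
        if self.size_cap_nm is not None and self.size_cap_nm < hi:
            raise ValueError("size_cap_nm must be >= the small range upper bound")


@dataclass(frozen=True)
class Morphology:
    diameter_nm: float
    circularity: float
    eccentricity: float
    feret_nm: float
    defined: bool


@dataclass(frozen=True)
class CandidateCluster:
    """A segmented cluster, measured but not yet admitted."""

    cluster_id: int
    n_loc: int
    centroid: tuple[float, float]
    morphology: Morphology


@dataclass(frozen=True)
class ParticleRecord:
    particle_id: int
    roi_id: str
    n_loc: int
    cargo_estimate: int
    diameter_nm: float
    circularity: float
    eccentricity: float
    feret_nm: float
    centroid: tuple[float, float]
    size_class: str  # "small" | "large"
    reporter_positive: bool | None = None


@dataclass(frozen=True)
class Rejection:
    cluster_id: int
    reason: str
    n_loc: int
    diameter_nm: float


def estimate_cargo(n_loc: int, alpha: float) -> int:
    """Molecules per cluster: round-half-up of n_loc / alpha, floored at 1.

    A detected particle implies at least one bound probe.
    """
    if n_loc < 1:
        raise ValueError("n_loc must be >= 1")
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    return max(1, math.floor(n_loc / alpha + 0.5))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) <= 64:
        d = points[:, None, :] - points[None, :, :]
        return float(np.sqrt((d**2).sum(-1)).max())
    d = 0.0
    for i in range(0, len(points), 512):
        diff = points[i : i + 512, None, :] - points[None, :, :]
        d = max(d, float((diff**2).sum(-1).max()))
    return float(np.sqrt(d))


def _hull_diameter(vertices: np.ndarray) -> float:
    """Maximum pairwise distance of a convex polygon (rotating calipers)."""
    m = len(vertices)
    if m <= 64:
        return _max_pairwise(vertices)
    best = 0.0
    j = 1
    for i in range(m):
        nxt = vertices[(i + 1) % m] - vertices[i]
        # advance the caliper while the antipodal point still moves away
        while True:
            cur = vertices[j % m]
            after = vertices[(j + 1) % m]
            step = after - cur
            if nxt[0] * step[1] - nxt[1] * step[0] > 0:
                j += 1
            else:
                break
        for k in (j % m, (j + 1) % m):
            best = max(best, float(((vertices[i] - vertices[k]) ** 2).sum()))
    return float(np.sqrt(best))


def compute_morphology(points: np.ndarray) -> Morphology:
    """Hull-based size and shape metrics for one cluster's localizations.

    diameter: equivalent-circle diameter 2*sqrt(hull_area/pi);
    circularity: 4*pi*area/perimeter^2 of the hull polygon;
    eccentricity: sqrt(1 - l2/l1) from the point-covariance eigenvalues;
    feret: maximum pairwise distance (auxiliary, not used for gating).

    Clusters with < 3 points or collinear points get diameter = max
    pairwise distance and NaN shape metrics (``defined=False``).
    """
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")

    if len(points) < 3:
        return Morphology(_max_pairwise(points), np.nan, np.nan, _max_pairwise(points), False)
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear / degenerate
        return Morphology(_max_pairwise(points), np.nan, np.nan, _max_pairwise(points), False)

    area = hull.volume  # 2-D: volume is area, area is perimeter
    perimeter = hull.area
    diameter = 2.0 * np.sqrt(area / np.pi)
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else np.nan
    feret = _hull_diameter(points[hull.vertices])  # vertices are CCW-ordered

    cov = np.cov(points.T)
    l2, l1 = np.linalg.eigvalsh(cov)
    eccentricity = float(np.sqrt(max(0.0, 1.0 - l2 / l1))) if l1 > 0 else np.nan
    return Morphology(float(diameter), float(circularity), eccentricity, feret, True)


def measure_clusters(
    locs: LocalizationTable | np.ndarray, labels: np.ndarray
) -> list[CandidateCluster]:
    """Morphology and counts for every non-noise cluster label."""
    xy = locs.xy if isinstance(locs, LocalizationTable) else np.asarray(locs, float)
    labels = np.asarray(labels)
    out = []
    for lab in np.unique(labels[labels >= 0]):
        pts = xy[labels == lab]
        out.append(
            CandidateCluster(
                cluster_id=int(lab),
                n_loc=len(pts),
                centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                morphology=compute_morphology(pts),
            )
        )
    return out


def classify_and_filter(
    clusters: list[CandidateCluster],
    filter_config: ClusterFilterConfig,
    alpha: float,
    roi_id: str = "roi0",
) -> tuple[list[ParticleRecord], list[Rejection]]:
    """Apply the admission rules; returns (admitted records, rejection log)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    lo, hi = filter_config.small_range_nm
    small_min = filter_config.small_min_factor * alpha

    admitted: list[ParticleRecord] = []
    rejections: list[Rejection] = []
    pid = 0
    for c in clusters:
        d = c.morphology.diameter_nm
        reason = None
        if d < lo:
            reason = "below_min_diameter"
        elif d <= hi:  # small size class, 100 nm inclusive
            size_class = "small"
            if c.n_loc < small_min:
                reason = "small_below_min_loc"
            elif c.n_loc > filter_config.small_max_loc:
                reason = "small_above_max_loc"
        else:
            size_class = "large"
            if filter_config.size_cap_nm is not None and d > filter_config.size_cap_nm:
                reason = "above_size_cap"
            elif c.n_loc < filter_config.large_min_loc:
                reason = "large_below_min_loc"
            elif c.n_loc > filter_config.large_max_loc:
                reason = "large_above_max_loc"

        if reason is not None:
            rejections.append(Rejection(c.cluster_id, reason, c.n_loc, d))
            continue
        admitted.append(
            ParticleRecord(
                particle_id=pid,
                roi_id=roi_id,
                n_loc=c.n_loc,
                cargo_estimate=estimate_cargo(c.n_loc, alpha),
                diameter_nm=d,
                circularity=c.morphology.circularity,
                eccentricity=c.morphology.eccentricity,
                feret_nm=c.morphology.feret_nm,
                centroid=c.centroid,
                size_class=size_class,
            )
        )
        pid += 1
    return admitted, rejections


def particles_to_frame(particles: list[ParticleRecord]) -> pd.DataFrame:
    """Flatten admitted particles into the emitted per-particle table."""
    return pd.DataFrame(
        [
            {
                "particle_id": p.particle_id,
                "roi_id": p.roi_id,
                "n_loc": p.n_loc,
                "cargo_estimate": p.cargo_estimate,
                "diameter_nm": p.diameter_nm,
                "circularity": p.circularity,
                "eccentricity": p.eccentricity,
                "feret_nm": p.feret_nm,
                "x_nm": p.centroid[0],
                "y_nm": p.centroid[1],
                "size_class": p.size_class,
                "reporter_positive": p.reporter_positive,
            }
            for p in particles
        ]
    )
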