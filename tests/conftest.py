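from __future__ import annotations

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from evsmlm.config import SimulationConfig, default_config
from evsmlm.models import (
    Distribution,
    NoiseModel,
    ParticleClassModel,
    ParticleGroundTruth,
    RoiGeometry,
)
from evsmlm.synthetic import _uniform_in_ellipse


@pytest.fixture
def roi_small() -> RoiGeometry:
    """A 10 x 10 um ROI that keeps tessellations cheap in unit tests."""
    return RoiGeometry(width_nm=10_000, height_nm=10_000, pixels_per_side=64, n_frames=1_000)


@pytest.fixture
def roi_default() -> RoiGeometry:
    return RoiGeometry()


def make_class(diameter=100.0, axial=1.0, cargo=20, labeling=1.0, reporter_prob=0.0):
    return ParticleClassModel(
        "EV",
        diameter_dist=Distribution("constant", (float(diameter),)),
        axial_ratio_dist=Distribution("constant", (float(axial),)),
        cargo_count_dist=Distribution("constant", (float(cargo),)),
        labeling_efficiency=labeling,
        reporter_prob=reporter_prob,
    )


def recovery_config(
    n_particles=100.0,
    background=1.0,
    diameter=100.0,
    cargo=20,
    reporter_prob=0.0,
    roi=None,
):
    """The standard parameter-recovery scenario: constant EV-class particles,
    alpha=10 probe, sigma_loc=10 nm, low background."""
    cfg = default_config()
    ev = make_class(diameter=diameter, cargo=cargo, reporter_prob=reporter_prob)
    cfg = replace(
        cfg,
        classes={**cfg.classes, "EV": ev},
        simulation=SimulationConfig(
            class_mix={"EV": float(n_particles)},
            noise=NoiseModel(background_loc_rate=background),
        ),
    )
    if roi is not None:
        cfg = replace(cfg, roi=roi)
    return cfg


def grid_truth(
    roi: RoiGeometry,
    seed: int,
    n_side: int = 6,
    diameter: float = 100.0,
    n_cargo: int = 20,
    jitter_nm: float = 400.0,
) -> list[ParticleGroundTruth]:
    """Particles on a jittered grid — guaranteed well-separated centroids."""
    rng = np.random.default_rng(seed)
    margin = 2_000.0
    xs = np.linspace(margin, roi.width_nm - margin, n_side)
    ys = np.linspace(margin, roi.height_nm - margin, n_side)
    out = []
    pid = 0
    for cx in xs:
        for cy in ys:
            c = (cx + rng.uniform(-jitter_nm, jitter_nm), cy + rng.uniform(-jitter_nm, jitter_nm))
            r = diameter / 2.0
            cargo = _uniform_in_ellipse(rng, n_cargo, c, r, r, 0.0)
            out.append(
                ParticleGroundTruth(
                    particle_id=pid,
                    class_name="EV",
                    centroid=c,
                    diameter_nm=diameter,
                    axial_ratio=1.0,
                    orientation=0.0,
                    cargo_molecules=cargo,
                )
            )
            pid += 1
    return out


def distance_oracle_labels(points: np.ndarray, radius_nm: float = 100.0) -> np.ndarray:
    """Brute-force oracle: connected components of the distance graph;
    components with >= 2 members are clusters, the rest noise."""
    n = len(points)
    pairs = cKDTree(points).query_pairs(radius_nm, output_type="ndarray")
    graph = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    sizes = Counter(comp)
    return np.array([c if sizes[c] >= 2 else -1 for c in comp])


def canonical_partition(labels) -> list[int]:
    """Relabel clusters by first appearance so partitions compare by equality."""
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab < 0:
            out.append(-1)
        else:
            out.append(mapping.setdefault(lab, len(mapping)))
    return out
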