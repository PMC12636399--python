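"""End-to-end convenience wrappers: simulate -> cluster -> filter -> summarize."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coloc as _coloc
from .config import PipelineConfig
from .models import LocalizationTable, ParticleGroundTruth
from .profiler import (
    CandidateCluster,
    ParticleRecord,
    Rejection,
    classify_and_filter,
    measure_clusters,
)
from .synthetic import emit_localizations, render_reporter_image, sample_particles
from .vorocluster import ClusterAssignment, compute_voronoi_densities, merge_blinks, segment_clusters

__all__ = ["PipelineResult", "SimulatedRoi", "simulate_roi", "process_localizations"]


@dataclass
class PipelineResult:
    particles: list[ParticleRecord]
    rejections: list[Rejection]
    assignment: ClusterAssignment
    clusters: list[CandidateCluster]
    positive_fraction: float = float("nan")


@dataclass
class SimulatedRoi:
    truth: list[ParticleGroundTruth]
    locs: LocalizationTable
    reporter_image: np.ndarray | None


def simulate_roi(
    config: PipelineConfig, seed: int, with_reporter: bool = False, roi_id: str = "roi0"
) -> SimulatedRoi:
    """Generate one synthetic ROI under the configured class mix."""
    truth = sample_particles(
        config.simulation.class_mix,
        config.roi,
        seed=seed,
        classes=config.classes,
        edge_margin_nm=config.simulation.edge_margin_nm,
    )
    locs = emit_localizations(
        truth,
        config.fluor,
        config.simulation.noise,
        config.roi,
        seed=seed + 1,
        blink_distribution=config.simulation.blink_distribution,
    )
    locs.roi_id = roi_id
    img = (
        render_reporter_image(truth, config.roi, config.coloc.psf_sigma_nm, seed=seed + 2)
        if with_reporter
        else None
    )
    return SimulatedRoi(truth, locs, img)


def process_localizations(
    locs: LocalizationTable,
    config: PipelineConfig,
    reporter_image: np.ndarray | None = None,
    roi_id: str | None = None,
) -> PipelineResult:
    """Run clustering, admission filtering and (optionally) colocalization."""
    roi_id = roi_id if roi_id is not None else locs.roi_id
    if config.clustering.merge_blinks:
        locs = merge_blinks(locs, config.fluor, config.clustering.merge_radius_nm)

    densities = compute_voronoi_densities(locs, config.roi)
    assignment = segment_clusters(
        locs,
        densities,
        config.roi,
        threshold_factor=config.clustering.threshold_factor,
        min_neighbors=config.clustering.min_neighbors,
        max_link_nm=config.clustering.max_link_nm,
        smooth_neighbors=config.clustering.smooth_neighbors,
        connectivity=config.clustering.connectivity,
    )
    clusters = measure_clusters(locs, assignment.labels)
    particles, rejections = classify_and_filter(
        clusters, config.filters, config.fluor.alpha, roi_id=roi_id
    )

    positive_fraction = float("nan")
    if reporter_image is not None and particles:
        mask = _coloc.binarize_reference(
            reporter_image,
            config.coloc.absolute_threshold,
            config.roi.pixel_size_nm,
            normalize=config.coloc.normalize,
        )
        shift = _coloc.align_channels(mask, particles, config.coloc.max_shift_nm)
        particles, positive_fraction = _coloc.flag_positive_particles(particles, mask, shift)

    return PipelineResult(particles, rejections, assignment, clusters, positive_fraction)
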