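"""Two-channel reporter colocalization.

The second (reporter) channel arrives as an already-reconstructed
intensity image.  It is max-normalized, binarized at an absolute
threshold (e.g. 0.3 for tissue, 0.4 for plasma preparations), coarsely
aligned to the SMLM channel by an integer-pixel translation, and
admitted particles are flagged positive when their centroid pixel falls
on the mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .models import RoiGeometry
from .profiler import ParticleRecord

log = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "binarize_reference",
    "align_channels",
    "flag_positive_particles",
]

#: shipped absolute thresholds for the reporter channel
TISSUE_THRESHOLD = 0.3
PLASMA_THRESHOLD = 0.4


@dataclass(frozen=True)
class BinaryMask:
    mask: np.ndarray  # boolean (n, n) grid
    threshold: float
    pixel_size_nm: float
    channel: str = "reporter"

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def binarize_reference(
    img: np.ndarray,
    absolute_threshold: float,
    pixel_size_nm: float,
    normalize: bool = True,
    channel: str = "reporter",
) -> BinaryMask:
    """Binarize a reporter-channel image at an absolute threshold.

    The image is divided by its maximum first (unless ``normalize`` is
    False for pre-normalized inputs); an all-zero image yields an empty
    mask.  Pixels at exactly the threshold are included.
    """
    if not 0.0 < absolute_threshold < 1.0:
        raise ValueError("absolute_threshold must lie in (0, 1)")
    img = np.asarray(img, float)
    if normalize:
        m = img.max()
        if m > 0:
            img = img / m
    return BinaryMask(img >= absolute_threshold, absolute_threshold, pixel_size_nm, channel)


def _centroid_pixels(particles: list[ParticleRecord], pixel_size_nm: float) -> np.ndarray:
    c = np.array([p.centroid for p in particles], float).reshape(-1, 2)
    cols = np.floor(c[:, 0] / pixel_size_nm).astype(int)
    rows = np.floor(c[:, 1] / pixel_size_nm).astype(int)
    return np.column_stack([rows, cols])


def _mask_hits(mask: np.ndarray, rc: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Hit flags for centroid pixels against a mask shifted by (dx, dy)."""
    rows = rc[:, 0] - dy
    cols = rc[:, 1] - dx
    inb = (rows >= 0) & (rows < mask.shape[0]) & (cols >= 0) & (cols < mask.shape[1])
    hits = np.zeros(len(rc), bool)
    hits[inb] = mask[rows[inb], cols[inb]]
    return hits


def align_channels(
    mask: BinaryMask,
    particles: list[ParticleRecord],
    max_shift_nm: float = 500.0,
    roi: RoiGeometry | None = None,
) -> tuple[int, int]:
    """Integer-pixel translation (dx, dy) aligning the mask to the particles.

    The returned shift is the correction to apply to the mask: a mask
    displaced by +2 pixels in x yields (-2, 0).  The search maximizes
    the count of particle centroids landing on true mask pixels within
    ``max_shift_nm``; ties break toward the smallest |shift| and then
    lexicographically on (dx, dy).  Saturation at the search boundary is
    logged.
    """
    px = mask.pixel_size_nm
    if not mask.mask.any() or not particles:
        log.warning("empty mask or particle set; returning zero shift")
        return (0, 0)
    s = int(np.floor(max_shift_nm / px))
    rc = _centroid_pixels(particles, px)

    candidates = []
    for dx in range(-s, s + 1):
        for dy in range(-s, s + 1):
            score = int(_mask_hits(mask.mask, rc, dx, dy).sum())
            candidates.append((-score, dx * dx + dy * dy, dx, dy))
    candidates.sort()
    _, _, dx, dy = candidates[0]
    if max(abs(dx), abs(dy)) == s:
        log.warning("alignment saturated at the +/-%d pixel search boundary", s)
    return (dx, dy)


def flag_positive_particles(
    particles: list[ParticleRecord],
    mask: BinaryMask,
    shift: tuple[int, int] = (0, 0),
) -> tuple[list[ParticleRecord], float]:
    """Set reporter positivity from centroid-pixel mask membership.

    The alignment shift is applied before lookup; centroids falling
    outside the image after shifting are negative.  Returns the flagged
    particles and the positive fraction (NaN when no particles).
    """
    if not particles:
        return [], float("nan")
    rc = _centroid_pixels(particles, mask.pixel_size_nm)
    hits = _mask_hits(mask.mask, rc, shift[0], shift[1])
    flagged = [replace(p, reporter_positive=bool(h)) for p, h in zip(particles, hits)]
    return flagged, float(hits.mean())
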