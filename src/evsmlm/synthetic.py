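"""Ground-truth simulator: particle fields, blinking localizations and
reporter-channel images.

Every stage is deterministic given (configuration, seed) so downstream
modules can be tested against known truth without any external data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import (
    DEFAULT_PARTICLE_CLASSES,
    FluorophoreModel,
    LocalizationTable,
    NoiseModel,
    ParticleClassModel,
    ParticleGroundTruth,
    RoiGeometry,
    empty_localization_table,
)

log = logging.getLogger(__name__)

__all__ = [
    "sample_particles",
    "emit_localizations",
    "render_reporter_image",
    "make_buffer_control",
]


def _uniform_in_ellipse(
    rng: np.random.Generator, n: int, centroid, a: float, b: float, theta: float
) -> np.ndarray:
    """n points uniform inside a rotated ellipse with semi-axes a, b."""
    r = np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    u = a * r * np.cos(phi)
    v = b * r * np.sin(phi)
    c, s = np.cos(theta), np.sin(theta)
    x = centroid[0] + u * c - v * s
    y = centroid[1] + u * s + v * c
    return np.column_stack([x, y])


def sample_particles(
    class_mix: dict[str, float],
    roi: RoiGeometry,
    seed: int,
    classes: dict[str, ParticleClassModel] | None = None,
    edge_margin_nm: float = 500.0,
) -> list[ParticleGroundTruth]:
    """Draw a ground-truth particle field.

    Per-class particle counts are Poisson with the requested expected
    count; centroids are uniform inside the ROI minus an edge margin;
    cargo molecules are uniform inside each particle's ellipse, thinned
    by the class labeling efficiency.
    """
    classes = classes if classes is not None else DEFAULT_PARTICLE_CLASSES
    for name, rate in class_mix.items():
        if rate < 0:
            raise ValueError(f"expected count for class {name!r} must be >= 0")
        if name not in classes:
            raise ValueError(f"unknown particle class {name!r}")

    rng = np.random.default_rng(seed)
    lo_x, hi_x = edge_margin_nm, roi.width_nm - edge_margin_nm
    lo_y, hi_y = edge_margin_nm, roi.height_nm - edge_margin_nm
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("edge margin leaves no interior for particle placement")

    particles: list[ParticleGroundTruth] = []
    pid = 0
    for name in sorted(class_mix):
        model = classes[name]
        n = rng.poisson(class_mix[name])
        for _ in range(n):
            cx = rng.uniform(lo_x, hi_x)
            cy = rng.uniform(lo_y, hi_y)
            diameter = float(model.diameter_dist.sample(rng, 1)[0])
            axial = max(1.0, float(model.axial_ratio_dist.sample(rng, 1)[0]))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            n_cargo = max(0, int(round(model.cargo_count_dist.sample(rng, 1)[0])))
            r = diameter / 2.0
            a, b = r * np.sqrt(axial), r / np.sqrt(axial)
            cargo = _uniform_in_ellipse(rng, n_cargo, (cx, cy), a, b, theta)
            if model.labeling_efficiency < 1.0 and n_cargo > 0:
                keep = rng.random(n_cargo) < model.labeling_efficiency
                cargo = cargo[keep]
            reporter = bool(rng.random() < model.reporter_prob)
            particles.append(
                ParticleGroundTruth(
                    particle_id=pid,
                    class_name=name,
                    centroid=(cx, cy),
                    diameter_nm=diameter,
                    axial_ratio=axial,
                    orientation=theta,
                    cargo_molecules=cargo,
                    reporter_positive=reporter,
                )
            )
            pid += 1
    return particles


def _truncated_poisson_rate(alpha: float) -> float:
    """Rate lam such that a Poisson(lam) conditioned on >=1 has mean alpha."""
    if alpha <= 1.0:
        return 1e-9

    def f(lam):
        return lam / (1.0 - np.exp(-lam)) - alpha

    return brentq(f, 1e-9, 10.0 * alpha)


def _blink_counts(
    rng: np.random.Generator, n: int, alpha: float, distribution: str
) -> np.ndarray:
    """Localizations emitted per labeled molecule; support {1,2,...}, mean alpha."""
    if distribution == "geometric":
        return rng.geometric(1.0 / alpha, n)
    if distribution == "poisson":
        lam = _truncated_poisson_rate(alpha)
        out = rng.poisson(lam, n)
        while np.any(out == 0):  # resample zeros: truncation at >= 1
            zero = out == 0
            out[zero] = rng.poisson(lam, int(zero.sum()))
        return out
    raise ValueError(f"unknown blink distribution {distribution!r}")


def emit_localizations(
    truth: list[ParticleGroundTruth],
    fluor: FluorophoreModel,
    noise: NoiseModel,
    roi: RoiGeometry,
    seed: int,
    blink_distribution: str = "geometric",
    channel: str = "ch0",
    intensity_photons: float = 1000.0,
) -> LocalizationTable:
    """Emit the localization table a particle field would produce.

    Each labeled molecule yields a random number of localizations with
    mean alpha; each localization is the molecule position plus
    isotropic Gaussian noise of sigma loc_precision_sigma_nm, assigned
    to a uniformly random frame.  Background clutter is added per the
    noise model.  Localizations falling outside the ROI are discarded
    (counted in ``meta['n_discarded']``).
    """
    rng = np.random.default_rng(seed)
    mols = (
        np.vstack([p.cargo_molecules for p in truth if len(p.cargo_molecules)])
        if any(len(p.cargo_molecules) for p in truth)
        else np.empty((0, 2))
    )

    n_signal = 0
    xs: list[np.ndarray] = []
    if len(mols):
        counts = _blink_counts(rng, len(mols), fluor.alpha, blink_distribution)
        n_signal = int(counts.sum())
        pos = np.repeat(mols, counts, axis=0)
        pos = pos + rng.normal(0.0, fluor.loc_precision_sigma_nm, pos.shape)
        xs.append(pos)

    n_bg = int(rng.poisson(noise.background_loc_rate * roi.area_um2))
    if n_bg:
        bg = np.column_stack(
            [rng.uniform(0.0, roi.width_nm, n_bg), rng.uniform(0.0, roi.height_nm, n_bg)]
        )
        if noise.false_loc_sigma > 0:
            bg = bg + rng.normal(0.0, noise.false_loc_sigma, bg.shape)
        xs.append(bg)

    if not xs:
        out = empty_localization_table(channel=channel)
        out.meta.update(n_emitted=0, n_background=0, n_discarded=0, seed=seed)
        return out

    pts = np.vstack(xs)
    frames = rng.integers(1, roi.n_frames + 1, len(pts))
    inside = (
        (pts[:, 0] >= 0)
        & (pts[:, 0] <= roi.width_nm)
        & (pts[:, 1] >= 0)
        & (pts[:, 1] <= roi.height_nm)
    )
    n_discarded = int((~inside).sum())
    if n_discarded:
        log.info("discarded %d out-of-ROI localizations", n_discarded)

    df = pd.DataFrame(
        {
            "x_nm": pts[inside, 0],
            "y_nm": pts[inside, 1],
            "frame": frames[inside],
            "intensity": np.full(int(inside.sum()), float(intensity_photons)),
            "channel": channel,
        }
    )
    out = LocalizationTable(df)
    out.meta.update(
        n_emitted=n_signal, n_background=n_bg, n_discarded=n_discarded, seed=seed
    )
    return out


def render_reporter_image(
    truth: list[ParticleGroundTruth],
    roi: RoiGeometry,
    psf_sigma_nm: float = 250.0,
    seed: int | None = None,
    amplitude_noise: float = 0.0,
) -> np.ndarray:
    """Render reporter-positive particles as a Gaussian-blob intensity image.

    Emulates an already-reconstructed second-channel image: one Gaussian
    of width psf_sigma_nm per reporter-positive particle, optional
    per-particle amplitude jitter, max-normalized to [0, 1].  Returns an
    all-zero image when no particle is reporter-positive.
    """
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma_nm must be positive")
    n = roi.pixels_per_side
    img = np.zeros((n, n))
    px = roi.pixel_size_nm
    rng = np.random.default_rng(seed)
    sigma_px = psf_sigma_nm / px
    half = max(2, int(np.ceil(4 * sigma_px)))
    for p in truth:
        if not p.reporter_positive:
            continue
        col = p.centroid[0] / px - 0.5  # Gaussian centre in pixel coords
        row = p.centroid[1] / px - 0.5
        amp = 1.0 + (amplitude_noise * abs(rng.normal()) if amplitude_noise else 0.0)
        c0, r0 = int(round(col)), int(round(row))
        cs = np.arange(max(0, c0 - half), min(n, c0 + half + 1))
        rs = np.arange(max(0, r0 - half), min(n, r0 + half + 1))
        if not len(cs) or not len(rs):
            continue
        gx = np.exp(-0.5 * ((cs - col) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((rs - row) / sigma_px) ** 2)
        img[np.ix_(rs, cs)] += amp * np.outer(gy, gx)
    m = img.max()
    if m > 0:
        img /= m
    return img


def make_buffer_control(
    roi: RoiGeometry, noise: NoiseModel, seed: int, channel: str = "ch0"
) -> LocalizationTable:
    """Particle-free (buffer only) ROI: background clutter and nothing else."""
    fluor = FluorophoreModel("none", alpha=1.0)
    return emit_localizations([], fluor, noise, roi, seed, channel=channel)
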