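"""Core domain types shared across the pipeline.

Coordinates are nanometres with the origin at the top-left corner of the
ROI and y increasing downward (image convention).  Pixel (row, col) spans
the half-open interval [col*px, (col+1)*px) x [row*px, (row+1)*px).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RoiGeometry",
    "FluorophoreModel",
    "FLUOROPHORE_REGISTRY",
    "Distribution",
    "ParticleClassModel",
    "DEFAULT_PARTICLE_CLASSES",
    "ParticleGroundTruth",
    "NoiseModel",
    "LocalizationTable",
]


@dataclass(frozen=True)
class RoiGeometry:
    """Geometry of one imaged region of interest.

    Defaults correspond to a 41 x 41 um field rendered on a 256 x 256
    pixel grid, acquired over 25,000 frames at 10 ms exposure.
    """

    width_nm: float = 41_000.0
    height_nm: float = 41_000.0
    pixels_per_side: int = 256
    n_frames: int = 25_000
    exposure_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0 or self.height_nm <= 0:
            raise ValueError("ROI side lengths must be positive")
        if self.pixels_per_side < 2:
            raise ValueError("pixels_per_side must be >= 2")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def pixel_size_nm(self) -> float:
        return self.width_nm / self.pixels_per_side

    @property
    def area_nm2(self) -> float:
        return self.width_nm * self.height_nm

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / 1e6


@dataclass(frozen=True)
class FluorophoreModel:
    """Blinking calibration for one fluorescent probe.

    ``alpha`` is the calibrated mean number of localizations emitted per
    probe over an acquisition; it converts localization counts into
    molecule counts.  ``max_dark_time_frames`` is the longest frame gap
    over which re-blinks are attributed to the same molecule (used only
    by the optional blink-merging stage).
    """

    probe_name: str
    alpha: float
    max_dark_time_frames: int = 50
    loc_precision_sigma_nm: float = 10.0

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if self.loc_precision_sigma_nm <= 0:
            raise ValueError("loc_precision_sigma_nm must be positive")
        if self.max_dark_time_frames < 0:
            raise ValueError("max_dark_time_frames must be >= 0")


#: Calibrated probes shipped with the package.  Alpha values are assay
#: calibration constants; dark time and localization precision are
#: configuration defaults, not calibrated truth.
FLUOROPHORE_REGISTRY: dict[str, FluorophoreModel] = {
    "SNA-AF647": FluorophoreModel("SNA-AF647", alpha=6),
    "antibody-AF647": FluorophoreModel("antibody-AF647", alpha=10),
    "antibody-CF568": FluorophoreModel("antibody-CF568", alpha=11),
    "ApoE-antibody-AF647": FluorophoreModel("ApoE-antibody-AF647", alpha=11),
}


@dataclass(frozen=True)
class Distribution:
    """Small seedable distribution spec used by the simulator.

    kinds:
      constant(value) | uniform(low, high) | uniform_int(low, high) —
      inclusive bounds | normal(mean, sd) | lognormal(median, sigma_log)
    """

    kind: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(size, float(self.params[0]))
        if self.kind == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size)
        if self.kind == "uniform_int":
            lo, hi = self.params
            return rng.integers(int(lo), int(hi) + 1, size).astype(float)
        if self.kind == "normal":
            mean, sd = self.params
            return rng.normal(mean, sd, size)
        if self.kind == "lognormal":
            median, sigma = self.params
            return rng.lognormal(np.log(median), sigma, size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    @property
    def mean(self) -> float:
        if self.kind == "constant":
            return float(self.params[0])
        if self.kind in ("uniform", "uniform_int"):
            return 0.5 * (self.params[0] + self.params[1])
        if self.kind == "normal":
            return float(self.params[0])
        if self.kind == "lognormal":
            median, sigma = self.params
            return float(median * np.exp(sigma**2 / 2))
        raise ValueError(self.kind)


def _dist(kind: str, *params: float) -> Distribution:
    return Distribution(kind, tuple(float(p) for p in params))


@dataclass(frozen=True)
class ParticleClassModel:
    """Synthetic generative model for one particle class."""

    class_name: str
    diameter_dist: Distribution
    axial_ratio_dist: Distribution
    cargo_count_dist: Distribution
    labeling_efficiency: float = 0.9
    reporter_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise ValueError("labeling_efficiency must lie in [0, 1]")
        if not 0.0 <= self.reporter_prob <= 1.0:
            raise ValueError("reporter_prob must lie in [0, 1]")


# Synthetic defaults, chosen so EVs are larger and circular, exomeres /
# supermeres smaller and elongated, and LPPs NVEP-sized but circular.
# These are simulation parameters, not measured truth.
DEFAULT_PARTICLE_CLASSES: dict[str, ParticleClassModel] = {
    "EV": ParticleClassModel(
        "EV",
        diameter_dist=_dist("lognormal", 90.0, 0.35),
        axial_ratio_dist=_dist("lognormal", 1.1, 0.08),
        cargo_count_dist=_dist("uniform_int", 10, 40),
    ),
    "exomere": ParticleClassModel(
        "exomere",
        diameter_dist=_dist("lognormal", 35.0, 0.30),
        axial_ratio_dist=_dist("lognormal", 1.8, 0.15),
        cargo_count_dist=_dist("uniform_int", 4, 12),
    ),
    "supermere": ParticleClassModel(
        "supermere",
        diameter_dist=_dist("lognormal", 25.0, 0.30),
        axial_ratio_dist=_dist("lognormal", 1.8, 0.15),
        cargo_count_dist=_dist("uniform_int", 4, 12),
    ),
    "LPP": ParticleClassModel(
        "LPP",
        diameter_dist=_dist("lognormal", 49.0, 0.25),
        axial_ratio_dist=_dist("lognormal", 1.1, 0.08),
        cargo_count_dist=_dist("uniform_int", 4, 12),
    ),
    # single stray molecules acting as clutter
    "background": ParticleClassModel(
        "background",
        diameter_dist=_dist("constant", 1.0),
        axial_ratio_dist=_dist("constant", 1.0),
        cargo_count_dist=_dist("constant", 1),
        labeling_efficiency=1.0,
    ),
}


@dataclass(frozen=True)
class ParticleGroundTruth:
    """Simulator truth for a single particle, used by recovery tests.

    The particle footprint is an ellipse whose area equals that of a
    circle of ``diameter_nm``: semi-axes a = (d/2)*sqrt(ar) and
    b = (d/2)/sqrt(ar) with ar the axial ratio.
    """

    particle_id: int
    class_name: str
    centroid: tuple[float, float]
    diameter_nm: float
    axial_ratio: float
    orientation: float
    cargo_molecules: np.ndarray  # (n, 2) nm positions of labeled molecules
    reporter_positive: bool = False

    @property
    def semi_axes(self) -> tuple[float, float]:
        r = self.diameter_nm / 2.0
        s = np.sqrt(self.axial_ratio)
        return r * s, r / s

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """True for points inside the particle ellipse."""
        a, b = self.semi_axes
        d = np.atleast_2d(points) - np.asarray(self.centroid)
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        u = d[:, 0] * c + d[:, 1] * s
        v = -d[:, 0] * s + d[:, 1] * c
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0 + tol


@dataclass(frozen=True)
class NoiseModel:
    """Background clutter model: spurious localizations per um^2 per ROI."""

    background_loc_rate: float = 0.0
    false_loc_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.background_loc_rate < 0:
            raise ValueError("background_loc_rate must be >= 0")
        if self.false_loc_sigma < 0:
            raise ValueError("false_loc_sigma must be >= 0")


@dataclass
class LocalizationTable:
    """One localization per row with ROI-level metadata.

    Columns: x_nm, y_nm, frame, intensity, channel (extra columns are
    preserved as opaque).  ``meta`` carries bookkeeping such as emitted /
    discarded counts from the simulator.
    """

    data: pd.DataFrame
    roi_id: str = "roi0"
    capture: str = ""
    detection: str = ""
    meta: dict = field(default_factory=dict)

    REQUIRED_COLUMNS = ("x_nm", "y_nm", "frame", "channel")

    def __post_init__(self) -> None:
        for col in self.REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"localization table missing column {col!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x_nm", "y_nm"]].to_numpy(float)

    def with_data(self, data: pd.DataFrame) -> "LocalizationTable":
        return replace(self, data=data)


def empty_localization_table(channel: str = "ch0", **kwargs) -> LocalizationTable:
    df = pd.DataFrame(
        {
            "x_nm": pd.Series(dtype=float),
            "y_nm": pd.Series(dtype=float),
            "frame": pd.Series(dtype=int),
            "intensity": pd.Series(dtype=float),
            "channel": pd.Series(dtype=str),
        }
    )
    return LocalizationTable(df, **kwargs)
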