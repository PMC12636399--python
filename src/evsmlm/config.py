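"""Pipeline configuration: defaults, YAML loading, validation, provenance."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .models import (
    DEFAULT_PARTICLE_CLASSES,
    FLUOROPHORE_REGISTRY,
    Distribution,
    FluorophoreModel,
    NoiseModel,
    ParticleClassModel,
    RoiGeometry,
)
from .profiler import ClusterFilterConfig

__all__ = ["PipelineConfig", "load_config", "default_config"]


@dataclass(frozen=True)
class ClusteringConfig:
    threshold_factor: float = 2.0
    min_neighbors: int = 0
    max_link_nm: float | None = 100.0
    smooth_neighbors: bool = False
    connectivity: str = "core-attach"
    merge_blinks: bool = False
    merge_radius_nm: float = 50.0

    def __post_init__(self) -> None:
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")
        if self.merge_radius_nm <= 0:
            raise ValueError("merge_radius_nm must be positive")


@dataclass(frozen=True)
class ColocConfig:
    absolute_threshold: float = 0.4  # plasma default; tissue uses 0.3
    max_shift_nm: float = 500.0
    normalize: bool = True
    psf_sigma_nm: float = 250.0

    def __post_init__(self) -> None:
        if not 0.0 < self.absolute_threshold < 1.0:
            raise ValueError("absolute_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class StatsConfig:
    dilution_factor: float = 1.0
    reference_volume_ul: float = 1.0
    test: str = "t_two_tailed"

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.reference_volume_ul <= 0:
            raise ValueError("reference_volume_ul must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    class_mix: dict[str, float] = field(default_factory=lambda: {"EV": 100.0})
    edge_margin_nm: float = 500.0
    blink_distribution: str = "geometric"
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(background_loc_rate=5.0))


@dataclass(frozen=True)
class PipelineConfig:
    roi: RoiGeometry = field(default_factory=RoiGeometry)
    fluorophores: dict[str, FluorophoreModel] = field(
        default_factory=lambda: dict(FLUOROPHORE_REGISTRY)
    )
    probe: str = "antibody-AF647"
    classes: dict[str, ParticleClassModel] = field(
        default_factory=lambda: dict(DEFAULT_PARTICLE_CLASSES)
    )
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    filters: ClusterFilterConfig = field(default_factory=ClusterFilterConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe not in self.fluorophores:
            raise ValueError(
                f"unknown probe {self.probe!r}; registry has {sorted(self.fluorophores)}"
            )
        for name in self.simulation.class_mix:
            if name not in self.classes:
                raise ValueError(f"class_mix references unknown class {name!r}")

    @property
    def fluor(self) -> FluorophoreModel:
        return self.fluorophores[self.probe]

    def provenance_lines(self) -> list[str]:
        """Human-readable log of every constant that encodes an assay default."""
        f = self.filters
        lines = [
            "probe alpha calibrations (mean localizations per probe): "
            + ", ".join(f"{n}={m.alpha:g}" for n, m in sorted(self.fluorophores.items())),
            f"active probe: {self.probe} (alpha={self.fluor.alpha:g})",
            f"ROI: {self.roi.width_nm:g} x {self.roi.height_nm:g} nm, "
            f"{self.roi.pixels_per_side} px/side, {self.roi.n_frames} frames "
            f"@ {self.roi.exposure_ms:g} ms",
            f"small-cluster gate: diameter {f.small_range_nm[0]:g}-{f.small_range_nm[1]:g} nm, "
            f"{f.small_min_factor:g} x alpha <= n_loc <= {f.small_max_loc}",
            f"large-cluster gate: {f.large_min_loc} <= n_loc <= {f.large_max_loc}"
            + (f", size cap {f.size_cap_nm:g} nm" if f.size_cap_nm else ""),
            f"mouse mode: {f.mouse_mode}",
            f"density threshold factor: {self.clustering.threshold_factor:g} x mean ROI "
            "density (tessellation-package convention; assumed, not calibrated)",
            f"adjacency max link: {self.clustering.max_link_nm} nm (assumed)",
            f"reporter absolute threshold: {self.coloc.absolute_threshold:g} "
            "(0.3 tissue / 0.4 plasma defaults)",
            f"concentration: particles_per_ul = count x dilution ({self.stats.dilution_factor:g}) "
            f"/ reference volume ({self.stats.reference_volume_ul:g} ul) (formula assumed)",
            "synthetic class parameters are simulation defaults, not measured truth",
        ]
        return lines


def default_config() -> PipelineConfig:
    return PipelineConfig()


def _dist_from_spec(spec) -> Distribution:
    if isinstance(spec, (int, float)):
        return Distribution("constant", (float(spec),))
    kind = spec["kind"]
    params = tuple(float(p) for p in spec["params"])
    return Distribution(kind, params)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML configuration, overlaying the shipped defaults.

    An empty (or missing) file yields the all-defaults configuration.
    Contradictory settings (unknown probe, inverted filter bounds,
    dilution < 1, ...) raise rather than being silently defaulted.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"configuration root must be a mapping, got {type(raw)}")
    if overrides:
        raw = {**raw, **overrides}

    cfg = default_config()

    if "roi" in raw:
        cfg = replace(cfg, roi=RoiGeometry(**raw["roi"]))
    if "fluorophores" in raw:
        reg = dict(cfg.fluorophores)
        for name, spec in raw["fluorophores"].items():
            base = reg.get(name)
            kwargs = dict(
                probe_name=name,
                alpha=spec.get("alpha", base.alpha if base else None),
                max_dark_time_frames=spec.get(
                    "max_dark_time_frames", base.max_dark_time_frames if base else 50
                ),
                loc_precision_sigma_nm=spec.get(
                    "loc_precision_sigma_nm", base.loc_precision_sigma_nm if base else 10.0
                ),
            )
            if kwargs["alpha"] is None:
                raise ValueError(f"new fluorophore {name!r} must define alpha")
            reg[name] = FluorophoreModel(**kwargs)
        cfg = replace(cfg, fluorophores=reg)
    if "classes" in raw:
        classes = dict(cfg.classes)
        for name, spec in raw["classes"].items():
            base = classes.get(name)
            classes[name] = ParticleClassModel(
                class_name=name,
                diameter_dist=_dist_from_spec(spec["diameter"])
                if "diameter" in spec
                else base.diameter_dist,
                axial_ratio_dist=_dist_from_spec(spec["axial_ratio"])
                if "axial_ratio" in spec
                else base.axial_ratio_dist,
                cargo_count_dist=_dist_from_spec(spec["cargo"])
                if "cargo" in spec
                else base.cargo_count_dist,
                labeling_efficiency=spec.get(
                    "labeling_efficiency", base.labeling_efficiency if base else 0.9
                ),
                reporter_prob=spec.get("reporter_prob", base.reporter_prob if base else 0.0),
            )
        cfg = replace(cfg, classes=classes)
    if "simulation" in raw:
        s = raw["simulation"]
        noise = (
            NoiseModel(**s["noise"]) if "noise" in s else cfg.simulation.noise
        )
        cfg = replace(
            cfg,
            simulation=SimulationConfig(
                class_mix={k: float(v) for k, v in s.get("class_mix", cfg.simulation.class_mix).items()},
                edge_margin_nm=s.get("edge_margin_nm", cfg.simulation.edge_margin_nm),
                blink_distribution=s.get("blink_distribution", cfg.simulation.blink_distribution),
                noise=noise,
            ),
        )
    if "clustering" in raw:
        cfg = replace(cfg, clustering=ClusteringConfig(**raw["clustering"]))
    if "filters" in raw:
        f = dict(raw["filters"])
        if "small_range_nm" in f:
            f["small_range_nm"] = tuple(f["small_range_nm"])
        cfg = replace(cfg, filters=ClusterFilterConfig(**f))
    if "coloc" in raw:
        cfg = replace(cfg, coloc=ColocConfig(**raw["coloc"]))
    if "stats" in raw:
        cfg = replace(cfg, stats=StatsConfig(**raw["stats"]))
    if "probe" in raw:
        cfg = replace(cfg, probe=raw["probe"])
    if "seed" in raw:
        cfg = replace(cfg, seed=int(raw["seed"]))

    # re-run cross-field validation after all sections are applied
    PipelineConfig.__post_init__(cfg)
    return cfg
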