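"""Per-ROI aggregation, concentration normalization and group comparisons.

The statistical unit is the ROI: condition summaries report mean +/- SEM
over ROI-level values (designs are typically n fractions x 5 ROIs).
Fraction-level nesting is recorded but not modeled; a caveat is logged
whenever more than one fraction contributes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .models import ParticleGroundTruth
from .profiler import ParticleRecord

log = logging.getLogger(__name__)

__all__ = [
    "ROISummary",
    "ConditionSummary",
    "ComparisonResult",
    "summarize_roi",
    "aggregate_condition",
    "compare_conditions",
    "significance_stars",
    "recovery_report",
    "RecoveryReport",
]

METRICS = ("particles_per_ul", "mean_cargo", "mean_diameter", "mean_circularity", "mean_eccentricity")


@dataclass(frozen=True)
class ROISummary:
    roi_id: str
    condition: str
    capture: str
    detection: str
    particles_detected: int
    particles_per_ul: float
    mean_cargo: float
    mean_diameter: float
    mean_circularity: float
    mean_eccentricity: float
    positive_fraction: float
    dilution_factor: float
    fraction_id: str = "f0"


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n_fractions: int
    n_rois: int
    means: dict[str, float]
    sems: dict[str, float]


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    groups: tuple[str, ...]
    test: str
    statistic: float
    p_value: float
    stars: str


def summarize_roi(
    particles: list[ParticleRecord],
    dilution_factor: float,
    reference_volume_ul: float = 1.0,
    roi_id: str = "roi0",
    condition: str = "",
    capture: str = "",
    detection: str = "",
    fraction_id: str = "f0",
) -> ROISummary:
    """One-ROI aggregate: particles_per_ul = count * dilution / reference volume.

    Metric means are NaN (undefined), not zero, when no particle was
    admitted.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if reference_volume_ul <= 0:
        raise ValueError("reference_volume_ul must be positive")
    n = len(particles)
    conc = n * dilution_factor / reference_volume_ul

    def m(vals):
        vals = np.asarray(vals, float)
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if len(vals) else float("nan")

    pos = [p.reporter_positive for p in particles if p.reporter_positive is not None]
    return ROISummary(
        roi_id=roi_id,
        condition=condition,
        capture=capture,
        detection=detection,
        particles_detected=n,
        particles_per_ul=conc,
        mean_cargo=m([p.cargo_estimate for p in particles]),
        mean_diameter=m([p.diameter_nm for p in particles]),
        mean_circularity=m([p.circularity for p in particles]),
        mean_eccentricity=m([p.eccentricity for p in particles]),
        positive_fraction=float(np.mean(pos)) if pos else float("nan"),
        dilution_factor=dilution_factor,
        fraction_id=fraction_id,
    )


def aggregate_condition(roi_summaries: list[ROISummary]) -> ConditionSummary:
    """Mean and SEM per metric over ROI-level values (SEM = sd / sqrt(n), ddof=1)."""
    if not roi_summaries:
        raise ValueError("need at least one ROI summary")
    conditions = {s.condition for s in roi_summaries}
    if len(conditions) > 1:
        raise ValueError(f"mixed conditions in one aggregate: {sorted(conditions)}")
    fractions = {s.fraction_id for s in roi_summaries}
    if len(fractions) > 1:
        log.info(
            "aggregating %d fractions as independent ROIs (no mixed model)", len(fractions)
        )
    n = len(roi_summaries)
    means, sems = {}, {}
    for metric in METRICS + ("positive_fraction",):
        vals = np.array([getattr(s, metric) for s in roi_summaries], float)
        vals = vals[~np.isnan(vals)]
        means[metric] = float(vals.mean()) if len(vals) else float("nan")
        sems[metric] = (
            float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) >= 2 else float("nan")
        )
    return ConditionSummary(
        condition=roi_summaries[0].condition,
        n_fractions=len(fractions),
        n_rois=n,
        means=means,
        sems=sems,
    )


def significance_stars(p: float) -> str:
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


def compare_conditions(
    groups: dict[str, np.ndarray],
    metric: str = "",
    test: str = "t_two_tailed",
) -> ComparisonResult:
    """Compare ROI-level metric values across conditions.

    tests: t_two_tailed (two-tailed Student's t, equal variances,
    2 groups), mann_whitney (2 groups), anova (one-way, >= 2 groups),
    anova_tukey (one-way ANOVA, p from the largest pairwise Tukey HSD
    contrast).
    """
    names = tuple(groups)
    vals = [np.asarray(groups[k], float) for k in names]
    if len(vals) < 2:
        raise ValueError("need at least two groups")
    for k, v in zip(names, vals):
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 ROI values")

    degenerate = all(v.std() == 0 for v in vals)
    if degenerate and len({float(v.mean()) for v in vals}) == 1:
        log.info("degenerate variance with equal means; p = 1 by convention")
        return ComparisonResult(metric, names, test, 0.0, 1.0, "ns")

    if test == "t_two_tailed":
        if len(vals) != 2:
            raise ValueError("t-test requires exactly two groups")
        stat, p = sps.ttest_ind(vals[0], vals[1], equal_var=True)
    elif test == "mann_whitney":
        if len(vals) != 2:
            raise ValueError("Mann-Whitney requires exactly two groups")
        stat, p = sps.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
    elif test == "anova":
        stat, p = sps.f_oneway(*vals)
    elif test == "anova_tukey":
        stat, _ = sps.f_oneway(*vals)
        res = sps.tukey_hsd(*vals)
        p = float(np.min(res.pvalue[~np.eye(len(vals), dtype=bool)]))
    else:
        raise ValueError(f"unknown test {test!r}")
    p = float(min(1.0, max(0.0, p)))
    return ComparisonResult(metric, names, test, float(stat), p, significance_stars(p))


@dataclass(frozen=True)
class RecoveryReport:
    matches: pd.DataFrame  # one row per matched (truth, detected) pair
    n_truth: int
    n_detected: int
    precision: float
    recall: float
    per_class: pd.DataFrame  # bias / RMSE of diameter & cargo per class

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RecoveryReport(precision={self.precision:.3f}, recall={self.recall:.3f}, "
            f"n_truth={self.n_truth}, n_detected={self.n_detected})"
        )


def recovery_report(
    particles: list[ParticleRecord],
    truth: list[ParticleGroundTruth],
    match_radius_nm: float = 100.0,
) -> RecoveryReport:
    """Greedy nearest-centroid matching of detections to ground truth.

    Pairs within ``match_radius_nm`` are matched closest-first, each
    truth particle and each detection used at most once.  Reports
    precision, recall and per-class bias / RMSE for diameter and cargo,
    plus positivity agreement where both sides carry a flag.
    """
    n_t, n_d = len(truth), len(particles)
    cols = [
        "truth_id", "particle_id", "class_name", "distance_nm",
        "true_diameter", "est_diameter", "true_cargo", "est_cargo",
        "true_positive_flag", "est_positive_flag",
    ]
    if n_t == 0 or n_d == 0:
        matches = pd.DataFrame(columns=cols)
        return RecoveryReport(
            matches, n_t, n_d,
            precision=0.0 if n_d else float("nan"),
            recall=0.0 if n_t else float("nan"),
            per_class=pd.DataFrame(),
        )

    t_xy = np.array([t.centroid for t in truth])
    d_xy = np.array([p.centroid for p in particles])
    pairs = cKDTree(t_xy).query_ball_tree(cKDTree(d_xy), match_radius_nm)
    cand = [
        (float(np.hypot(*(t_xy[i] - d_xy[j]))), i, j)
        for i, lst in enumerate(pairs)
        for j in lst
    ]
    cand.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    rows = []
    for dist, i, j in cand:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        t, p = truth[i], particles[j]
        rows.append(
            {
                "truth_id": t.particle_id,
                "particle_id": p.particle_id,
                "class_name": t.class_name,
                "distance_nm": dist,
                "true_diameter": t.diameter_nm,
                "est_diameter": p.diameter_nm,
                "true_cargo": len(t.cargo_molecules),
                "est_cargo": p.cargo_estimate,
                "true_positive_flag": t.reporter_positive,
                "est_positive_flag": p.reporter_positive,
            }
        )
    matches = pd.DataFrame(rows, columns=cols)

    per_class_rows = []
    for cls, grp in matches.groupby("class_name"):
        dd = grp["est_diameter"] - grp["true_diameter"]
        dc = grp["est_cargo"] - grp["true_cargo"]
        flagged = grp[grp["est_positive_flag"].notna()]
        per_class_rows.append(
            {
                "class_name": cls,
                "n_matched": len(grp),
                "diameter_bias": float(dd.mean()),
                "diameter_rmse": float(np.sqrt((dd**2).mean())),
                "cargo_bias": float(dc.mean()),
                "cargo_rmse": float(np.sqrt((dc**2).mean())),
                "positivity_agreement": float(
                    (flagged["est_positive_flag"].astype(bool) == flagged["true_positive_flag"]).mean()
                )
                if len(flagged)
                else float("nan"),
            }
        )
    return RecoveryReport(
        matches=matches,
        n_truth=n_t,
        n_detected=n_d,
        precision=len(matches) / n_d,
        recall=len(matches) / n_t,
        per_class=pd.DataFrame(per_class_rows),
    )
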