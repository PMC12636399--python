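"""Reading and writing of localization tables, truth sidecars and images."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .models import LocalizationTable, ParticleGroundTruth, RoiGeometry

log = logging.getLogger(__name__)

__all__ = [
    "read_localizations",
    "write_localizations",
    "write_truth",
    "read_truth",
    "write_image",
    "read_image",
]

#: column aliases per dialect, mapping file column -> native name
DIALECTS: dict[str, dict[str, str]] = {
    "native": {},
    "thunderstorm": {
        "x [nm]": "x_nm",
        "y [nm]": "y_nm",
        "frame": "frame",
        "intensity [photon]": "intensity",
        "channel": "channel",
    },
}

_MANDATORY = ("x_nm", "y_nm", "frame")


def read_localizations(
    path,
    dialect: str = "native",
    roi: RoiGeometry | None = None,
    sep: str = ",",
    channel: str = "ch0",
    **table_kwargs,
) -> LocalizationTable:
    """Read a delimited localization file.

    Unknown columns are preserved as opaque.  When ``roi`` is given,
    rows outside its bounds are counted, logged and dropped; the drop
    count is available as ``meta['n_out_of_bounds']``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    try:
        df = pd.read_csv(path, sep=sep)
    except ValueError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    df = df.rename(columns=DIALECTS[dialect])

    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(
                f"missing mandatory column {col!r} (dialect {dialect!r}) in {path}"
            )
    for col in ("x_nm", "y_nm", "frame"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"unparseable value in column {col!r} at data row {row}")
        df[col] = pd.to_numeric(df[col])
    if "intensity" not in df.columns:
        df["intensity"] = np.nan
    if "channel" not in df.columns:
        df["channel"] = channel

    n_oob = 0
    if roi is not None:
        inside = (
            (df["x_nm"] >= 0)
            & (df["x_nm"] <= roi.width_nm)
            & (df["y_nm"] >= 0)
            & (df["y_nm"] <= roi.height_nm)
        )
        n_oob = int((~inside).sum())
        if n_oob:
            log.warning("dropped %d out-of-bounds localizations from %s", n_oob, path)
            df = df[inside].reset_index(drop=True)

    table = LocalizationTable(df, **table_kwargs)
    table.meta["n_out_of_bounds"] = n_oob
    table.meta["source"] = str(path)
    return table


def write_localizations(table: LocalizationTable, path, sep: str = ",") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lead = [c for c in ("x_nm", "y_nm", "frame", "intensity", "channel") if c in table.data]
    cols = lead + [c for c in table.data.columns if c not in lead]
    table.data[cols].to_csv(path, sep=sep, index=False)
    return path


def write_truth(truth: list[ParticleGroundTruth], path, sep: str = ",") -> Path:
    """Write simulator ground truth as a flat sidecar table (one row per particle)."""
    rows = [
        {
            "particle_id": p.particle_id,
            "class_name": p.class_name,
            "x_nm": p.centroid[0],
            "y_nm": p.centroid[1],
            "diameter_nm": p.diameter_nm,
            "axial_ratio": p.axial_ratio,
            "orientation": p.orientation,
            "n_cargo": len(p.cargo_molecules),
            "reporter_positive": p.reporter_positive,
            "cargo_xy": ";".join(
                f"{x:.3f}:{y:.3f}" for x, y in np.atleast_2d(p.cargo_molecules)
            )
            if len(p.cargo_molecules)
            else "",
        }
        for p in truth
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        rows,
        columns=[
            "particle_id",
            "class_name",
            "x_nm",
            "y_nm",
            "diameter_nm",
            "axial_ratio",
            "orientation",
            "n_cargo",
            "reporter_positive",
            "cargo_xy",
        ],
    ).to_csv(path, sep=sep, index=False)
    return path


def read_truth(path, sep: str = ",") -> list[ParticleGroundTruth]:
    df = pd.read_csv(path, sep=sep, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        cargo = (
            np.array(
                [[float(v) for v in pair.split(":")] for pair in str(r["cargo_xy"]).split(";")]
            )
            if str(r["cargo_xy"])
            else np.empty((0, 2))
        )
        out.append(
            ParticleGroundTruth(
                particle_id=int(r["particle_id"]),
                class_name=str(r["class_name"]),
                centroid=(float(r["x_nm"]), float(r["y_nm"])),
                diameter_nm=float(r["diameter_nm"]),
                axial_ratio=float(r["axial_ratio"]),
                orientation=float(r["orientation"]),
                cargo_molecules=cargo,
                reporter_positive=str(r["reporter_positive"]).lower() in ("true", "1"),
            )
        )
    return out


def write_image(img: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, img.astype(np.float32))
    return path


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)
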