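"""Factorial simulation study of mal-angulated rotational osteotomies.

The default grid reproduces the study design exactly: two patient-derived
synthetic models (42° antetorsion / 6° retrotorsion), two osteotomy sites
(subtrochanteric 45/40 mm below the lesser trochanter, supracondylar 60/65
mm above the condyles), baseline plus mal-angulated planes (frontal and
sagittal, ±5/10/15/20/30°), and fragment rotations of 5–30° (external for
the antetorsion model, internal for the retrotorsion model).  That is 20
baseline runs, 80 mal-angulated planes, and 400 mal-angulated runs.

Summary cells pool the absolute HKA deviation over both models and both
tilt directions (n = 4 per cell, sample SD), mirroring the published
tables; a cell is flagged clinically relevant when mean + SD exceeds the
2° threshold established for osteotomy correction accuracy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .alignment import deviation_from_preop, measure_projected_hka
from .leg import (
    MODEL_1,
    MODEL_2,
    LegParameters,
    generate_synthetic_leg,
    jitter_landmarks,
)
from .osteotomy import (
    GRID_MAGNITUDES_DEG,
    GRID_ROTATIONS_DEG,
    PlaneAngulation,
    RotationSpec,
    apply_rotational_osteotomy,
    build_osteotomy_frame,
    make_baseline_plane,
    tilt_plane,
)

__all__ = [
    "ModelSpec",
    "GridConfig",
    "SimulationRecord",
    "run_grid",
    "summarize_table",
    "baseline_summary",
    "flag_relevant",
    "write_results_csv",
    "load_config",
]

RECORD_COLUMNS = [
    "model_id",
    "site",
    "plane",
    "direction",
    "magnitude_deg",
    "signed_magnitude_deg",
    "rotation_deg",
    "sense",
    "preop_hka_deg",
    "postop_hka_deg",
    "deviation_deg",
]


@dataclass(frozen=True)
class ModelSpec:
    """One study model: leg parameters plus its per-site study settings."""

    model_id: str
    params: LegParameters
    rotation_sense: str
    subtrochanteric_level_mm: float
    supracondylar_level_mm: float

    def level_for(self, site: str) -> float:
        if site == "subtrochanteric":
            return self.subtrochanteric_level_mm
        if site == "supracondylar":
            return self.supracondylar_level_mm
        raise ValueError(f"unknown site: {site!r}")


def _default_models() -> tuple:
    return (
        ModelSpec("model1", MODEL_1, "external", 45.0, 60.0),
        ModelSpec("model2", MODEL_2, "internal", 40.0, 65.0),
    )


@dataclass(frozen=True)
class GridConfig:
    """Configuration of the factorial grid; defaults match the study design."""

    models: tuple = field(default_factory=_default_models)
    sites: tuple = ("subtrochanteric", "supracondylar")
    angulation_planes: tuple = ("frontal", "sagittal")
    magnitudes_deg: tuple = GRID_MAGNITUDES_DEG
    directions: tuple = ("plus", "minus")
    rotations_deg: tuple = GRID_ROTATIONS_DEG
    projection_mode: str = "knee_anchored"
    rotation_axis: str = "plane_normal"
    relevance_threshold_deg: float = 2.0
    jitter_sigma_mm: float = 0.0
    jitter_seed: int = 0


@dataclass(frozen=True)
class SimulationRecord:
    """Outcome of one simulated rotational osteotomy."""

    model_id: str
    site: str
    plane: str  # 'baseline', 'frontal' or 'sagittal'
    direction: str  # 'plus', 'minus' or '' for baseline
    magnitude_deg: float
    signed_magnitude_deg: float
    rotation_deg: float
    sense: str
    preop_hka_deg: float
    postop_hka_deg: float
    deviation_deg: float


def run_grid(config: GridConfig = GridConfig()) -> list[SimulationRecord]:
    """Run every simulation of the factorial grid, in deterministic order.

    Returns one record per (model × site × plane × rotation), baseline
    planes included (``plane == 'baseline'``).
    """
    records: list[SimulationRecord] = []
    for model in config.models:
        lm = generate_synthetic_leg(model.params)
        if config.jitter_sigma_mm > 0.0:
            lm = jitter_landmarks(lm, config.jitter_sigma_mm, config.jitter_seed)
        pre = measure_projected_hka(lm, config.projection_mode, reference=lm)
        for site in config.sites:
            frame = build_osteotomy_frame(lm, site, model.level_for(site))
            planes = [("baseline", "", 0.0, make_baseline_plane(frame))]
            for ang_plane in config.angulation_planes:
                for mag in config.magnitudes_deg:
                    for direction in config.directions:
                        ang = PlaneAngulation(ang_plane, mag, direction)
                        planes.append(
                            (ang_plane, direction, mag, tilt_plane(frame, ang))
                        )
            for plane_kind, direction, mag, plane in planes:
                for theta in config.rotations_deg:
                    rot = RotationSpec(theta, model.rotation_sense)
                    rotated = apply_rotational_osteotomy(
                        lm, plane, frame, rot, rotation_axis=config.rotation_axis
                    )
                    post = measure_projected_hka(
                        rotated, config.projection_mode, reference=lm
                    )
                    signed = mag if direction != "minus" else -mag
                    records.append(
                        SimulationRecord(
                            model_id=model.model_id,
                            site=site,
                            plane=plane_kind,
                            direction=direction,
                            magnitude_deg=mag,
                            signed_magnitude_deg=signed,
                            rotation_deg=theta,
                            sense=model.rotation_sense,
                            preop_hka_deg=pre.hka_valgus_deg,
                            postop_hka_deg=post.hka_valgus_deg,
                            deviation_deg=deviation_from_preop(pre, post),
                        )
                    )
    return records


def records_frame(records) -> pd.DataFrame:
    """Records as a DataFrame with a stable column order."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df[RECORD_COLUMNS]


def flag_relevant(mean_deg: float, sd_deg: float, threshold_deg: float = 2.0) -> bool:
    """Clinical relevance rule: mean + SD strictly greater than the threshold."""
    return bool(mean_deg + sd_deg > threshold_deg)


def summarize_table(records, threshold_deg: float = 2.0) -> pd.DataFrame:
    """Pool mal-angulated records into table cells.

    One row per (site, plane, |magnitude|, rotation) with the mean and
    sample standard deviation of the absolute HKA deviation over both
    models and both tilt directions, plus the relevance flag.
    """
    df = records_frame(records)
    mal = df[df["plane"] != "baseline"]
    if mal.empty:
        raise ValueError("no mal-angulated records to summarise")
    grouped = (
        mal.groupby(["site", "plane", "magnitude_deg", "rotation_deg"])[
            "deviation_deg"
        ]
        .agg(mean_deg="mean", sd_deg=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    grouped["sd_deg"] = grouped["sd_deg"].fillna(0.0)
    grouped["relevant"] = grouped["mean_deg"] + grouped["sd_deg"] > threshold_deg
    return grouped.sort_values(
        ["site", "plane", "magnitude_deg", "rotation_deg"]
    ).reset_index(drop=True)


def baseline_summary(records) -> dict:
    """Pooled mean ± SD of the absolute HKA change over all baseline runs."""
    df = records_frame(records)
    base = df[df["plane"] == "baseline"]["deviation_deg"]
    if base.empty:
        raise ValueError("no baseline records")
    return {
        "mean_deg": float(base.mean()),
        "sd_deg": float(base.std(ddof=1)) if len(base) > 1 else 0.0,
        "n": int(len(base)),
    }


def cell(table: pd.DataFrame, site: str, plane: str, magnitude: float, rotation: float):
    """Select one summary cell; raises KeyError if absent."""
    sel = table[
        (table["site"] == site)
        & (table["plane"] == plane)
        & (table["magnitude_deg"] == magnitude)
        & (table["rotation_deg"] == rotation)
    ]
    if sel.empty:
        raise KeyError((site, plane, magnitude, rotation))
    return sel.iloc[0]


def _wide_table(table: pd.DataFrame, site: str) -> pd.DataFrame:
    """Publication-style wide layout: rows plane × magnitude, columns the
    rotations, cells ``mean ± sd`` with ``*`` marking relevant cells."""
    sub = table[table["site"] == site]
    rotations = sorted(sub["rotation_deg"].unique())
    rows = []
    for mag in sorted(sub["magnitude_deg"].unique()):
        for plane in ("sagittal", "frontal"):
            row = {"angulation": f"+/-{mag:g}", "plane": plane}
            for rot in rotations:
                c = cell(table, site, plane, mag, rot)
                mark = "*" if c["relevant"] else ""
                row[f"rot{rot:g}"] = f"{c['mean_deg']:.2f} +/- {c['sd_deg']:.2f}{mark}"
            rows.append(row)
    return pd.DataFrame(rows)


def write_results_csv(records, table: pd.DataFrame, out_dir) -> list[Path]:
    """Write the per-run records and the summary tables to *out_dir*.

    Produces ``records.csv`` (one row per simulation, grid order),
    ``summary_long.csv`` (machine-readable cells) and one
    ``summary_<site>.csv`` per site in the publication layout.  Output is
    byte-reproducible for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    p = out / "records.csv"
    records_frame(records).to_csv(p, index=False, float_format="%.6f")
    paths.append(p)

    p = out / "summary_long.csv"
    table.to_csv(p, index=False, float_format="%.6f")
    paths.append(p)

    for site in table["site"].unique():
        p = out / f"summary_{site}.csv"
        _wide_table(table, site).to_csv(p, index=False)
        paths.append(p)
    return paths


def load_config(path) -> GridConfig:
    """Load a :class:`GridConfig` from a YAML file.

    Any omitted key keeps its default.  Model entries are mappings with the
    leg parameters under ``params`` plus ``rotation_sense`` and the two
    per-site levels.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    if "models" in doc:
        models = []
        for m in doc["models"]:
            models.append(
                ModelSpec(
                    model_id=m["model_id"],
                    params=LegParameters(**m["params"]),
                    rotation_sense=m.get("rotation_sense", "external"),
                    subtrochanteric_level_mm=m.get("subtrochanteric_level_mm", 45.0),
                    supracondylar_level_mm=m.get("supracondylar_level_mm", 60.0),
                )
            )
        kwargs["models"] = tuple(models)
    for key in (
        "sites",
        "angulation_planes",
        "magnitudes_deg",
        "directions",
        "rotations_deg",
    ):
        if key in doc:
            kwargs[key] = tuple(doc[key])
    for key in (
        "projection_mode",
        "rotation_axis",
        "relevance_threshold_deg",
        "jitter_sigma_mm",
        "jitter_seed",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    return GridConfig(**kwargs)
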