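"""Readers and writers for the interchange formats.

Tabular data travel as UTF-8 comma-separated CSV with a header row and "."
decimals; section geometry travels as GeoJSON (coordinates in µm — the files
are planar, not geographic); results are JSON with explicit units.  All
readers validate schema up front and identify the offending row on error;
write→read round-trips preserve values to full float precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, mapping, shape

from .spatial import SectionPattern
from .spiketrain import SpikeTrain

POINT_COLUMNS = ("section_id", "rat_id", "hemisphere", "x_um", "y_um", "neun", "cfos", "gad")
SPIKE_COLUMNS = ("cell_id", "rat_id", "condition", "sweep", "t_s")
COUNT_COLUMNS = ("rat_id", "region", "hemisphere", "treatment", "area_mm2", "count")
VEP_COLUMNS = ("sweep", "t_s", "v")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Section point patterns: CSV + GeoJSON
# ---------------------------------------------------------------------------


def write_points(
    sections: Iterable[SectionPattern], points_path, geometry_path
) -> None:
    """Write sections to a points CSV and a GeoJSON geometry file."""
    sections = list(sections)
    frames = []
    features = []
    for s in sections:
        df = s.points.copy()
        df.insert(0, "section_id", s.section_id)
        df.insert(1, "rat_id", s.rat_id)
        df.insert(2, "hemisphere", s.hemisphere)
        frames.append(df[list(POINT_COLUMNS)])
        features.append(
            {
                "type": "Feature",
                "properties": {"section_id": s.section_id, "kind": "region"},
                "geometry": mapping(s.region),
            }
        )
        features.append(
            {
                "type": "Feature",
                "properties": {"section_id": s.section_id, "kind": "lateral_edge"},
                "geometry": mapping(LineString(s.lateral_edge)),
            }
        )
    pd.concat(frames, ignore_index=True).to_csv(points_path, index=False)
    geo = {
        "type": "FeatureCollection",
        "crs_note": "planar coordinates in micrometres, not geographic",
        "features": features,
    }
    Path(geometry_path).write_text(json.dumps(geo))


def read_points(points_path, geometry_path) -> list[SectionPattern]:
    """Read sections back from the points CSV + GeoJSON geometry pair.

    Raises with the section id / row index when a column is missing, a
    section lacks geometry, or a point falls outside its region polygon.
    """
    df = pd.read_csv(points_path)
    _require_columns(df, POINT_COLUMNS, "points")
    geo = json.loads(Path(geometry_path).read_text())
    regions: dict[str, Polygon] = {}
    edges: dict[str, np.ndarray] = {}
    for feat in geo.get("features", []):
        sid = str(feat["properties"]["section_id"])
        kind = feat["properties"]["kind"]
        g = shape(feat["geometry"])
        if kind == "region":
            regions[sid] = g
        elif kind == "lateral_edge":
            edges[sid] = np.asarray(g.coords, dtype=float)
    sections = []
    for sid, sub in df.groupby("section_id", sort=False):
        sid = str(sid)
        if sid not in regions or sid not in edges:
            raise ValueError(f"no geometry found for section_id '{sid}'")
        region = regions[sid]
        pts = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        ok = shapely.covers(
            shapely.buffer(region, 1e-6),
            shapely.points(pts[:, 0], pts[:, 1]),
        )
        if not ok.all():
            bad = sub.index[~ok].tolist()
            raise ValueError(
                f"section '{sid}': points outside region polygon at rows {bad}"
            )
        sections.append(
            SectionPattern(
                section_id=sid,
                rat_id=str(sub["rat_id"].iloc[0]),
                hemisphere=str(sub["hemisphere"].iloc[0]),
                region=region,
                lateral_edge=edges[sid],
                points=sub[["x_um", "y_um", "neun", "cfos", "gad"]].reset_index(
                    drop=True
                ),
            )
        )
    return sections


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


def write_spikes(trains: Iterable[SpikeTrain], path) -> None:
    rows = []
    durations = {}
    for tr in trains:
        durations[(tr.cell_id, tr.condition)] = tr.sweep_duration
        for i, sweep in enumerate(tr.sweeps):
            for t in sweep:
                rows.append(
                    {
                        "cell_id": tr.cell_id,
                        "rat_id": tr.rat_id,
                        "condition": tr.condition,
                        "sweep": i,
                        "t_s": t,
                        "sweep_duration_s": tr.sweep_duration,
                        "n_sweeps": len(tr.sweeps),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spikes(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    _require_columns(df, SPIKE_COLUMNS, "spikes")
    trains = []
    for (cell, cond), sub in df.groupby(["cell_id", "condition"], sort=False):
        duration = (
            float(sub["sweep_duration_s"].iloc[0])
            if "sweep_duration_s" in sub
            else float(np.ceil(sub["t_s"].max()))
        )
        n_sweeps = (
            int(sub["n_sweeps"].iloc[0])
            if "n_sweeps" in sub
            else int(sub["sweep"].max()) + 1
        )
        sweeps = [np.empty(0) for _ in range(n_sweeps)]
        for sw, swsub in sub.groupby("sweep"):
            sweeps[int(sw)] = np.sort(swsub["t_s"].to_numpy(dtype=float))
        trains.append(
            SpikeTrain(
                cell_id=str(cell),
                rat_id=str(sub["rat_id"].iloc[0]),
                condition=str(cond),
                sweeps=sweeps,
                sweep_duration=duration,
            )
        )
    return trains


# ---------------------------------------------------------------------------
# Count tables and VEP sweeps
# ---------------------------------------------------------------------------


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, "counts")
    if (df["area_mm2"] <= 0).any():
        bad = df.index[df["area_mm2"] <= 0].tolist()
        raise ValueError(f"non-positive area at rows {bad}")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_vep(sweeps, path) -> None:
    rows = []
    for s in sweeps:
        t = np.arange(s.voltage.size) / s.sampling_rate
        rows.append(
            pd.DataFrame(
                {"sweep": s.sweep_index, "t_s": t, "v": s.voltage,
                 "condition": s.condition}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_vep(
    path, sampling_rate: float = 20_000.0, stim_onset: float = 0.1,
    stim_duration: float = 0.3,
):
    from .vep import VepSweep

    df = pd.read_csv(path)
    _require_columns(df, VEP_COLUMNS, "VEP")
    sweeps = []
    for sw, sub in df.groupby("sweep", sort=True):
        sub = sub.sort_values("t_s")
        cond = str(sub["condition"].iloc[0]) if "condition" in sub else "control"
        sweeps.append(
            VepSweep(
                voltage=sub["v"].to_numpy(dtype=float),
                sampling_rate=sampling_rate,
                stim_onset=stim_onset,
                stim_duration=stim_duration,
                sweep_index=int(sw),
                condition=cond,
            )
        )
    return sweeps


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(_to_jsonable(config_dict), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(payload: dict, path, config_dict: dict | None = None,
                  seed: int | None = None) -> None:
    """Write a result JSON with provenance (config hash, seed, version)."""
    from . import __version__

    out = {
        "provenance": {
            "fosmap_version": __version__,
            "config_hash": config_hash(config_dict or {}),
            "seed": seed,
        },
        "results": _to_jsonable(payload),
    }
    Path(path).write_text(json.dumps(out, indent=2))
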