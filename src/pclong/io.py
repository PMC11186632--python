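"""Readers and writers for the package's plain-text formats.

Tracks and point patterns travel as CSV, decay series as CSV, repertoires
as AIRR-style Rearrangement TSV plus a sample-metadata CSV, cluster masks as
a CSV of occupied bins with a JSON header. Readers validate schemas and
report offending lines; writers round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decay import DecaySeries
from .spatial import ClusterMask, PointPattern
from .tracks import Track

__all__ = [
    "read_points", "write_points",
    "read_tracks", "write_tracks",
    "read_decay", "write_decay",
    "read_airr", "write_airr",
    "read_sample_metadata",
    "write_mask", "read_mask",
    "load_yaml_config",
]

_AIRR_REQUIRED = ("sequence_id", "v_call", "junction_aa", "duplicate_count")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(
                f"{path}: unparseable numeric in column {col!r} at line {line}"
            )
        df[col] = converted
    return df


# --------------------------------------------------------- point patterns

def write_points(pattern: PointPattern, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# extent: " + ",".join(f"{e:g}" for e in pattern.extent) + "\n")
        pattern.to_frame().to_csv(fh, index=False)


def read_points(path, extent=None) -> PointPattern:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# extent:"):
            extent = tuple(float(v) for v in first.split(":", 1)[1].split(","))
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    coord_cols = [c for c in ("x_um", "y_um", "z_um") if c in df.columns]
    _require_columns(df, ["x_um", "y_um", "subset"], path)
    df = _numeric(df, coord_cols, path)
    positions = df[coord_cols].to_numpy(dtype=float)
    if extent is None:
        extent = tuple(np.ceil(positions.max(axis=0))) if len(df) else (1.0,) * len(coord_cols)
    return PointPattern(positions, df["subset"].to_numpy(), extent)


# ----------------------------------------------------------------- tracks

def write_tracks(tracks, path) -> None:
    rows = []
    for tr in tracks:
        d = tr.positions.shape[1]
        for j in range(tr.n_frames):
            row = {"track_id": tr.track_id, "t_min": tr.t[j],
                   "x_um": tr.positions[j, 0], "y_um": tr.positions[j, 1]}
            if d == 3:
                row["z_um"] = tr.positions[j, 2]
            row["ch_yfp"] = tr.ch_yfp[j]
            row["ch_tomato"] = tr.ch_tomato[j]
            if "phenotype" in tr.metadata:
                row["phenotype"] = tr.metadata["phenotype"]
            if "subset" in tr.metadata:
                row["subset"] = tr.metadata["subset"]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["track_id", "t_min", "x_um", "y_um", "ch_yfp", "ch_tomato"], path)
    coord_cols = [c for c in ("x_um", "y_um", "z_um") if c in df.columns]
    df = _numeric(df, ["t_min", *coord_cols, "ch_yfp", "ch_tomato"], path)
    out = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        t = grp["t_min"].to_numpy()
        if np.unique(t).size != t.size:
            raise ValueError(f"{path}: track {tid!r} has duplicate frame times")
        meta = {}
        for key in ("phenotype", "subset"):
            if key in grp.columns:
                meta[key] = grp[key].iloc[0]
        out.append(
            Track(
                track_id=str(tid),
                t=t,
                positions=grp[coord_cols].to_numpy(),
                ch_yfp=grp["ch_yfp"].to_numpy(),
                ch_tomato=grp["ch_tomato"].to_numpy(),
                metadata=meta,
            )
        )
    return out


# ------------------------------------------------------------------ decay

def write_decay(series: DecaySeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_decay(path) -> DecaySeries:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["day", "count"], path)
    df = _numeric(df, ["day", "count"], path)
    meta = {}
    for key in ("tissue", "age_group"):
        if key in df.columns and df[key].nunique() == 1:
            meta[key] = df[key].iloc[0]
    return DecaySeries(
        timepoints=df["day"].to_numpy(),
        counts=df["count"].to_numpy(),
        replicate_ids=df["replicate_id"].to_numpy() if "replicate_id" in df.columns else None,
        metadata=meta,
    )


# ------------------------------------------------------------- repertoire

def write_airr(rearrangements: pd.DataFrame, path) -> None:
    rearrangements.to_csv(path, sep="\t", index=False)


def read_airr(path) -> pd.DataFrame:
    """Read an AIRR-style Rearrangement TSV; header-only files yield an
    empty table."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, _AIRR_REQUIRED, path)
    numeric = [c for c in ("duplicate_count", "mutation_count", "v_sequence_length")
               if c in df.columns]
    return _numeric(df, numeric, path)


def read_sample_metadata(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "mouse_id"], path)
    return df


# ------------------------------------------------------------------ masks

def write_mask(mask: ClusterMask, csv_path, json_path) -> None:
    header = {
        "origin": list(mask.origin),
        "bin_size": mask.bin_size,
        "grid_shape": list(mask.grid_shape),
        "connectivity": "full",
        "cluster_counts": {str(k): v for k, v in mask.cluster_counts.items()},
    }
    Path(json_path).write_text(json.dumps(header, indent=2, sort_keys=True))
    rows = [
        {**{f"bin_{ax}": b for ax, b in zip("xyz", bins)}, "cluster_id": cid}
        for bins, cid in sorted(mask.bin_clusters.items())
    ]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_mask(csv_path, json_path) -> ClusterMask:
    header = json.loads(Path(json_path).read_text())
    mask = ClusterMask(
        origin=tuple(header["origin"]),
        bin_size=float(header["bin_size"]),
        grid_shape=tuple(header["grid_shape"]),
        cluster_counts={int(k): v for k, v in header["cluster_counts"].items()},
    )
    df = pd.read_csv(csv_path)
    bin_cols = [c for c in ("bin_x", "bin_y", "bin_z") if c in df.columns]
    for _, row in df.iterrows():
        mask.bin_clusters[tuple(int(row[c]) for c in bin_cols)] = int(row["cluster_id"])
    return mask


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
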