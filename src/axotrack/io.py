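"""File formats and configuration.

Track tables use the TrackMate CSV-export column dialect: a spots table
with TRACK_ID, FRAME, POSITION_T, POSITION_X, POSITION_Y, MEAN_INTENSITY
(plus optional CHANNEL / REPLICATE / MOVIE labels), an edges table of
frame-to-frame displacements, and a tracks summary table. Real TrackMate
exports carry three repeated sub-header rows under the header; the reader
drops them when present, the writer emits clean single-header CSV.

Units are normalized at this boundary and nowhere else: frames 0-based,
times in seconds, positions in µm, intensities in AU.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bleach import IntensityTrace
from .kinetics import KineticsConfig
from .simulate import AxonGeometry, SimTraceConfig, SimTrackConfig, TraceSet
from .tracks import Track, TrackSet

__all__ = ["read_tracks", "write_tracks", "read_traces", "write_traces",
           "write_kymograph", "PipelineConfig", "write_manifest"]

SPOT_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_T", "POSITION_X",
                "POSITION_Y", "MEAN_INTENSITY"]


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV table, dropping TrackMate's repeated sub-header rows."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    # TrackMate exports repeat the header as up to 3 non-numeric rows
    if "FRAME" in df.columns:
        numeric = pd.to_numeric(df["FRAME"], errors="coerce")
        df = df[numeric.notna()].reset_index(drop=True)
    return df


def read_tracks(path: str | Path, frame_rate: float | None = None) -> TrackSet:
    """Read a spots table into a validated TrackSet.

    Distinct errors name the problem: missing columns, non-monotone frames
    within a track, duplicated (track, frame) rows. When POSITION_T is
    absent it is derived from FRAME and ``frame_rate`` (an explicit
    warning would be logged by the CLI layer).
    """
    df = _read_table(path)
    missing = [c for c in SPOT_COLUMNS if c not in df.columns
               and c not in ("POSITION_T", "POSITION_Y", "MEAN_INTENSITY")]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if "POSITION_T" not in df.columns:
        if frame_rate is None:
            raise ValueError("POSITION_T absent and no frame_rate given")
        df["POSITION_T"] = df["FRAME"].astype(float) / frame_rate
    for c in ("POSITION_Y", "MEAN_INTENSITY"):
        if c not in df.columns:
            df[c] = 0.0
    for c in ("CHANNEL", "REPLICATE", "MOVIE"):
        if c not in df.columns:
            df[c] = {"CHANNEL": "ch0", "REPLICATE": "rep0", "MOVIE": "movie0"}[c]
    if df.duplicated(subset=["TRACK_ID", "FRAME"]).any():
        dups = df[df.duplicated(subset=["TRACK_ID", "FRAME"])]["TRACK_ID"].unique()
        raise ValueError(f"duplicated (track, frame) rows in track(s) {dups.tolist()}")
    tracks = []
    inferred_rate = None
    for tid, g in df.groupby("TRACK_ID", sort=True):
        g = g.sort_index()
        frames = g["FRAME"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) <= 0):
            g = g.sort_values("FRAME")
            frames = g["FRAME"].to_numpy(dtype=np.int64)
            if np.any(np.diff(frames) <= 0):
                raise ValueError(f"non-monotone frames within track {tid}")
        tr = Track(
            track_id=int(tid), frames=frames,
            t=g["POSITION_T"].to_numpy(dtype=float),
            x=g["POSITION_X"].to_numpy(dtype=float),
            y=g["POSITION_Y"].to_numpy(dtype=float),
            intensity=g["MEAN_INTENSITY"].to_numpy(dtype=float),
            channel=str(g["CHANNEL"].iloc[0]), replicate=str(g["REPLICATE"].iloc[0]),
            movie=str(g["MOVIE"].iloc[0]))
        tracks.append(tr)
        inferred_rate = 1.0 / tr.dt
    return TrackSet(tracks=tracks,
                    frame_rate=frame_rate or inferred_rate or 2.0)


def write_tracks(trackset: TrackSet, out_dir: str | Path, stem: str = "tracks") -> dict:
    """Write spots, edges and tracks-summary tables (plus ground truth).

    Returns the mapping of table name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spots = trackset.to_spots_frame()
    paths = {"spots": out_dir / f"{stem}_spots.csv"}
    spots.to_csv(paths["spots"], index=False)

    edge_rows, track_rows = [], []
    for tr in trackset:
        dx = np.diff(tr.x)
        dt = np.diff(tr.t)
        edge_rows.append(pd.DataFrame({
            "TRACK_ID": tr.track_id,
            "SPOT_SOURCE_FRAME": tr.frames[:-1],
            "SPOT_TARGET_FRAME": tr.frames[1:],
            "DISPLACEMENT": np.abs(dx),
            "SPEED": np.abs(dx) / dt,
        }))
        track_rows.append({
            "TRACK_ID": tr.track_id, "NUMBER_SPOTS": len(tr),
            "TRACK_DURATION": tr.duration,
            "TRACK_DISPLACEMENT": abs(tr.net_displacement),
            "TOTAL_DISTANCE_TRAVELED": tr.path_length,
            "TRACK_MEAN_SPEED": abs(tr.net_displacement) / tr.duration,
        })
    paths["edges"] = out_dir / f"{stem}_edges.csv"
    (pd.concat(edge_rows, ignore_index=True) if edge_rows
     else pd.DataFrame()).to_csv(paths["edges"], index=False)
    paths["tracks"] = out_dir / f"{stem}_tracks.csv"
    pd.DataFrame(track_rows).to_csv(paths["tracks"], index=False)
    if trackset.ground_truth is not None:
        paths["ground_truth"] = out_dir / f"{stem}_ground_truth.csv"
        trackset.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths


def write_traces(traceset: TraceSet, out_dir: str | Path, stem: str = "traces") -> dict:
    """Write bleaching traces as long-format CSV plus ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for tr in traceset:
        frames.append(pd.DataFrame({
            "spot_id": tr.spot_id,
            "frame": np.arange(len(tr)),
            "t": tr.t,
            "intensity": tr.values,
        }))
    paths = {"traces": out_dir / f"{stem}.csv",
             "ground_truth": out_dir / f"{stem}_ground_truth.csv"}
    pd.concat(frames, ignore_index=True).to_csv(paths["traces"], index=False)
    traceset.ground_truth.to_csv(paths["ground_truth"], index=False)
    return paths


def read_traces(path: str | Path, frame_rate: float = 30.0,
                background: float | None = None) -> list[IntensityTrace]:
    """Read long-format trace CSV (spot_id, frame, t, intensity)."""
    df = pd.read_csv(path)
    need = {"frame", "intensity"}
    if not need.issubset(df.columns):
        raise ValueError(f"missing required column(s): {sorted(need - set(df.columns))}")
    if "spot_id" not in df.columns:
        df["spot_id"] = 0
    traces = []
    for sid, g in df.groupby("spot_id", sort=True):
        g = g.sort_values("frame")
        rate = frame_rate
        if "t" in g.columns and len(g) > 1:
            dt = np.diff(g["t"].to_numpy(dtype=float))
            if np.all(dt > 0):
                rate = 1.0 / float(np.median(dt))
        traces.append(IntensityTrace(spot_id=int(sid),
                                     values=g["intensity"].to_numpy(dtype=float),
                                     frame_rate=rate, background=background))
    return traces


def write_kymograph(image: np.ndarray, path: str | Path) -> Path:
    """Write a kymograph as single-page float32 TIFF."""
    import tifffile
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


@dataclass
class PipelineConfig:
    """One structured YAML config drives every stage.

    Defaults trace to the imaging regime the package emulates:
    2-Hz track acquisition, 0.1 µm/s pause threshold, 10-µm motile
    filter, 30-Hz bleaching at ~26 AU per fluorophore, a 500-µm groove
    with a 110-µm window, mean retrograde speed 1.76 µm/s.
    """

    seed: int = 0
    geometry: dict = field(default_factory=lambda: dict(
        groove_length=500.0, window_start=0.0, window_end=110.0))
    tracks: dict = field(default_factory=dict)    # SimTrackConfig overrides
    traces: dict = field(default_factory=dict)    # SimTraceConfig overrides
    kinetics: dict = field(default_factory=dict)  # KineticsConfig overrides
    coloc: dict = field(default_factory=lambda: dict(
        max_separation=0.5, min_overlap_fraction=0.5, min_overlap_frames=3))
    arrival: dict = field(default_factory=dict)   # ArrivalModelConfig overrides
    stats: dict = field(default_factory=lambda: dict(alpha=0.05, adjustment="holm"))
    output_dir: str = "axotrack_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path

    def track_config(self) -> SimTrackConfig:
        geo = AxonGeometry(**self.geometry)
        return SimTrackConfig(geometry=geo, seed=self.seed, **self.tracks)

    def trace_config(self) -> SimTraceConfig:
        return SimTraceConfig(seed=self.seed, **self.traces)

    def kinetics_config(self) -> KineticsConfig:
        return KineticsConfig(**self.kinetics)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(config: PipelineConfig, out_dir: str | Path,
                   stage: str, outputs: dict) -> Path:
    """Write a run manifest: config hash, seed, stage, package version."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "config": asdict(config),
        "outputs": {k: str(v) for k, v in outputs.items()},
        "version": __version__,
    }
    path = out_dir / f"manifest_{stage}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
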