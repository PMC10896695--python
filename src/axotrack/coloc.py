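"""Two-channel track colocalization.

Tracks from two simultaneously imaged channels are matched when they are
co-visible long enough and stay within a sub-diffraction separation for
most of their co-visible interval. Matching is one-to-one and greedy by
ascending mean separation (deterministic ties by track ids) — at typical
axonal track densities assignment conflicts are rare, so greedy matching
and globally optimal matching coincide in practice.

Defaults: max_separation 0.5 µm, min_overlap_fraction 0.5,
min_overlap_frames 3. All three are exposed because imaging conditions
(channel registration, density) legitimately move them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticsConfig, track_summary
from .tracks import TrackSet

__all__ = ["ColocalizationMatch", "ColocalizationSummary",
           "match_tracks", "summarize_colocalization"]


@dataclass(frozen=True)
class ColocalizationMatch:
    """A matched A/B track pair with overlap and separation statistics."""

    track_id_a: int
    track_id_b: int
    overlap_frames: int
    overlap_fraction: float   # of the shorter track
    mean_separation: float    # µm, over co-visible frames


def _points_frame(ts: TrackSet, tag: str) -> pd.DataFrame:
    rows = []
    for tr in ts:
        rows.append(pd.DataFrame({
            "movie": tr.movie, "id": tr.track_id, "frame": tr.frames,
            "x": tr.x, "y": tr.y, "n": len(tr)}))
    if not rows:
        return pd.DataFrame(columns=["movie", "id", "frame", "x", "y", "n"])
    out = pd.concat(rows, ignore_index=True)
    return out.rename(columns={c: f"{c}_{tag}" for c in ("id", "x", "y", "n")})


def match_tracks(set_a: TrackSet, set_b: TrackSet, max_separation: float = 0.5,
                 min_overlap_fraction: float = 0.5,
                 min_overlap_frames: int = 3) -> list[ColocalizationMatch]:
    """One-to-one matches between channels sharing a frame clock.

    A pair is a candidate when the channels overlap for at least
    ``min_overlap_frames`` frames and the fraction of co-visible frames
    with separation below ``max_separation`` is at least
    ``min_overlap_fraction``. Candidates are assigned greedily by
    ascending mean separation, ties by (id_a, id_b).
    """
    if not np.isclose(set_a.frame_rate, set_b.frame_rate):
        raise ValueError(
            f"frame rates differ: {set_a.frame_rate} vs {set_b.frame_rate} Hz")
    pa, pb = _points_frame(set_a, "a"), _points_frame(set_b, "b")
    if pa.empty or pb.empty:
        return []
    joined = pa.merge(pb, on=["movie", "frame"])
    if joined.empty:
        return []
    sep = np.hypot(joined["x_a"] - joined["x_b"], joined["y_a"] - joined["y_b"])
    joined = joined.assign(sep=sep, close=sep < max_separation)
    g = joined.groupby(["id_a", "id_b"]).agg(
        overlap=("frame", "size"), close=("close", "sum"),
        mean_sep=("sep", "mean"), n_a=("n_a", "first"), n_b=("n_b", "first"))
    g = g[g["overlap"] >= min_overlap_frames]
    g = g[g["close"] / g["overlap"] >= min_overlap_fraction]
    g = g.reset_index().sort_values(["mean_sep", "id_a", "id_b"],
                                    kind="mergesort")
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for row in g.itertuples(index=False):
        if row.id_a in used_a or row.id_b in used_b:
            continue
        used_a.add(row.id_a)
        used_b.add(row.id_b)
        shorter = min(row.n_a, row.n_b)
        matches.append(ColocalizationMatch(
            track_id_a=int(row.id_a), track_id_b=int(row.id_b),
            overlap_frames=int(row.overlap),
            overlap_fraction=float(row.overlap / shorter),
            mean_separation=float(row.mean_sep)))
    return matches


@dataclass
class ColocalizationSummary:
    """Colocalized fraction and per-subgroup speed statistics."""

    n_a: int
    n_b: int
    n_matched: int
    percent_of_a: float
    percent_of_b: float
    speeds: pd.DataFrame  # rows: A-only / B-only / matched

    def summary(self) -> str:
        lines = [
            f"Colocalization: {self.n_matched} matched pairs",
            f"  channel A: {self.n_a} motile tracks -> {self.percent_of_a:.1f}% colocalized",
            f"  channel B: {self.n_b} motile tracks -> {self.percent_of_b:.1f}% colocalized",
            self.speeds.to_string(index=False),
        ]
        return "\n".join(lines)


def summarize_colocalization(matches: list[ColocalizationMatch],
                             set_a: TrackSet, set_b: TrackSet,
                             config: KineticsConfig | None = None
                             ) -> ColocalizationSummary:
    """Percent colocalization against each channel plus subgroup speeds.

    Percentages use each channel's motile-track count as denominator;
    speeds (mean ± SEM of track net speeds) are reported for A-only,
    B-only and matched subgroups. The matched subgroup's speed is taken
    from channel A's member of each pair.
    """
    config = config or KineticsConfig()
    sum_a = {tr.track_id: track_summary(tr, config) for tr in set_a}
    sum_b = {tr.track_id: track_summary(tr, config) for tr in set_b}
    motile_a = {i for i, s in sum_a.items() if s.passed_motile_filter}
    motile_b = {i for i, s in sum_b.items() if s.passed_motile_filter}
    matched_a = {m.track_id_a for m in matches}
    matched_b = {m.track_id_b for m in matches}
    n_a, n_b, n_m = len(motile_a), len(motile_b), len(matches)

    def speed_row(label: str, speeds: list[float]) -> dict:
        arr = np.asarray(speeds, dtype=float)
        return {"group": label, "n": len(arr),
                "mean_speed": float(arr.mean()) if arr.size else float("nan"),
                "sem": float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")}

    rows = [
        speed_row("A_only", [sum_a[i].mean_speed for i in motile_a - matched_a]),
        speed_row("B_only", [sum_b[i].mean_speed for i in motile_b - matched_b]),
        speed_row("matched", [sum_a[m.track_id_a].mean_speed for m in matches]),
    ]
    return ColocalizationSummary(
        n_a=n_a, n_b=n_b, n_matched=n_m,
        percent_of_a=100.0 * n_m / n_a if n_a else 0.0,
        percent_of_b=100.0 * n_m / n_b if n_b else 0.0,
        speeds=pd.DataFrame(rows))
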