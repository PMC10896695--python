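"""Per-track and per-population transport kinetics.

Implements the metrics used throughout axonal-transport quantification:
net speed (end-to-end displacement over duration), run length,
instantaneous velocity (windowed central difference), pause detection at
the 0.1 µm/s threshold, percent pausing, the 10-µm motile filter,
directionality, motile-event frequency per movie, and the first-arrival
time after label onset.

Sign convention: retrograde motion has negative axial velocity
(x decreases toward the cell body).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import Track, TrackSet

__all__ = [
    "KineticsConfig",
    "PauseEvent",
    "KineticsSummary",
    "instantaneous_velocity",
    "detect_pauses",
    "track_summary",
    "population_summary",
    "event_frequency",
    "first_arrival_time",
]


@dataclass(frozen=True)
class KineticsConfig:
    """Thresholds of the kinetics pipeline.

    pause_speed_threshold : µm/s — instantaneous speed below which a
        particle counts as paused (default 0.1).
    motile_min_displacement : µm — net displacement a track must exceed
        to enter population statistics (default 10).
    velocity_window : frames — width of the central-difference window
        (odd; default 3, i.e. a 1-s baseline at 2 Hz).
    min_pause_duration : s — shortest run of sub-threshold frames that
        counts as a pause (default 1.0; suppresses single-frame
        threshold crossings).
    speed_definition : "net" (displacement / duration, default) or
        "path" (summed |dx| / duration).
    """

    pause_speed_threshold: float = 0.1
    motile_min_displacement: float = 10.0
    velocity_window: int = 3
    min_pause_duration: float = 1.0
    speed_definition: str = "net"

    def __post_init__(self) -> None:
        if self.pause_speed_threshold <= 0 or self.motile_min_displacement <= 0:
            raise ValueError("thresholds must be positive")
        if self.velocity_window < 1 or self.velocity_window % 2 == 0:
            raise ValueError("velocity_window must be a positive odd integer")
        if self.min_pause_duration <= 0:
            raise ValueError("min_pause_duration must be positive")
        if self.speed_definition not in ("net", "path"):
            raise ValueError("speed_definition must be 'net' or 'path'")


@dataclass(frozen=True)
class PauseEvent:
    """One pause: maximal sub-threshold interval of a track."""

    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class KineticsSummary:
    """Derived metrics for one track."""

    track_id: int
    direction: str
    mean_speed: float
    path_speed: float
    run_length: float
    duration: float
    n_pauses: int
    mean_pause_duration: float
    percent_pausing: float
    max_instantaneous_speed: float
    passed_motile_filter: bool
    movie: str
    replicate: str

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "track_id", "direction", "mean_speed", "path_speed", "run_length",
            "duration", "n_pauses", "mean_pause_duration", "percent_pausing",
            "max_instantaneous_speed", "passed_motile_filter", "movie", "replicate")}


def instantaneous_velocity(track: Track, config: KineticsConfig | None = None) -> np.ndarray:
    """Signed per-frame velocity (µm/s) by windowed central difference.

    v_i = (x_{i+w} - x_{i-w}) / (t_{i+w} - t_{i-w}) with
    w = (velocity_window - 1) / 2; the first/last w points use one-sided
    differences over the same span. Negative = retrograde.
    """
    config = config or KineticsConfig()
    n = len(track)
    if n < config.velocity_window:
        raise ValueError(
            f"track {track.track_id}: {n} points < velocity window {config.velocity_window}")
    w = (config.velocity_window - 1) // 2
    x, t = track.x, track.t
    v = np.empty(n)
    if w == 0:
        v[:-1] = np.diff(x) / np.diff(t)
        v[-1] = v[-2]
        return v
    core = slice(w, n - w)
    v[core] = (x[2 * w:] - x[:n - 2 * w]) / (t[2 * w:] - t[:n - 2 * w])
    for i in range(w):  # one-sided ends over the same span
        span = min(2 * w, n - 1 - i)
        v[i] = (x[i + span] - x[i]) / (t[i + span] - t[i])
        j = n - 1 - i
        span = min(2 * w, j)
        v[j] = (x[j] - x[j - span]) / (t[j] - t[j - span])
    return v


def detect_pauses(track: Track, config: KineticsConfig | None = None) -> list[PauseEvent]:
    """Maximal runs of sub-threshold instantaneous speed lasting long enough.

    A frame is paused when |v| < pause_speed_threshold; runs shorter than
    min_pause_duration are discarded. Because the windowed velocity at a
    pause boundary mixes paused and moving displacement, each detected
    run is dilated by the window radius (w frames) on both sides before
    its duration is measured — undoing the erosion the smoothing window
    necessarily applies to a sub-threshold interval. Dilated runs that
    touch merge into one event; events are clamped to the track's span.
    """
    config = config or KineticsConfig()
    v = instantaneous_velocity(track, config)
    paused = np.abs(v) < config.pause_speed_threshold
    dt = track.dt
    w = (config.velocity_window - 1) // 2
    n = len(paused)
    # raw maximal sub-threshold runs as [first_frame, last_frame]
    raw: list[list[int]] = []
    i = 0
    while i < n:
        if paused[i]:
            j = i
            while j + 1 < n and paused[j + 1]:
                j += 1
            raw.append([i - w, j + w])  # de-erode by the window radius
            i = j + 1
        else:
            i += 1
    # merge overlapping dilated runs, clamp to the track
    merged: list[list[int]] = []
    for a, b in raw:
        a, b = max(a, 0), min(b, n - 1)
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    events: list[PauseEvent] = []
    for a, b in merged:
        duration = (b - a + 1) * dt
        if duration >= config.min_pause_duration:
            events.append(PauseEvent(start=float(track.t[a]),
                                     end=float(track.t[a]) + duration))
    return events


def track_summary(track: Track, config: KineticsConfig | None = None) -> KineticsSummary:
    """All per-track metrics.

    mean_speed is |net displacement| / duration (the start-to-end
    convention); path_speed (summed |dx| / duration) is always reported
    alongside. Direction is the sign of the net displacement when its
    magnitude passes the motile filter, else "stationary".
    """
    config = config or KineticsConfig()
    if track.duration <= 0:
        raise ValueError(f"track {track.track_id}: zero duration")
    net = track.net_displacement
    run_length = abs(net)
    mean_speed = run_length / track.duration
    path_speed = track.path_length / track.duration
    motile = run_length >= config.motile_min_displacement
    if not motile:
        direction = "stationary"
    else:
        direction = "retrograde" if net < 0 else "anterograde"
    pauses = detect_pauses(track, config) if len(track) >= config.velocity_window else []
    paused_time = sum(p.duration for p in pauses)
    paused_time = min(paused_time, track.duration)
    v = instantaneous_velocity(track, config) if len(track) >= config.velocity_window \
        else np.diff(track.x) / np.diff(track.t)
    reported = path_speed if config.speed_definition == "path" else mean_speed
    return KineticsSummary(
        track_id=track.track_id,
        direction=direction,
        mean_speed=reported,
        path_speed=path_speed,
        run_length=run_length,
        duration=track.duration,
        n_pauses=len(pauses),
        mean_pause_duration=paused_time / len(pauses) if pauses else 0.0,
        percent_pausing=100.0 * paused_time / track.duration,
        max_instantaneous_speed=float(np.max(np.abs(v))),
        passed_motile_filter=bool(motile),
        movie=track.movie,
        replicate=track.replicate,
    )


@dataclass
class PopulationSummary:
    """Per-track table plus group aggregates for one track set."""

    per_track: pd.DataFrame
    aggregates: pd.DataFrame
    direction_fractions: dict[str, float]
    n_motile: int
    status: str = "ok"

    def summary(self) -> str:
        lines = [f"Population: {len(self.per_track)} tracks, {self.n_motile} motile"]
        if self.status != "ok":
            lines.append(f"  status: {self.status}")
        for d, f in self.direction_fractions.items():
            lines.append(f"  {d}: {100 * f:.1f}%")
        if not self.aggregates.empty:
            lines.append(self.aggregates.to_string())
        return "\n".join(lines)


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def population_summary(trackset: TrackSet,
                       config: KineticsConfig | None = None) -> PopulationSummary:
    """Per-track metrics plus aggregates over motile tracks.

    Aggregates report mean ± SEM both over tracks and over replicate
    means (the latter is what replicate-level statistics consume).
    Direction fractions are over all tracks; speed/pause aggregates are
    over tracks passing the motile filter.
    """
    config = config or KineticsConfig()
    rows = [track_summary(tr, config).as_dict() for tr in trackset]
    per_track = pd.DataFrame(rows)
    if per_track.empty:
        return PopulationSummary(per_track, pd.DataFrame(), {}, 0, status="empty")
    counts = per_track["direction"].value_counts(normalize=True)
    fractions = {d: float(counts.get(d, 0.0))
                 for d in ("retrograde", "anterograde", "stationary")}
    motile = per_track[per_track["passed_motile_filter"]]
    if motile.empty:
        return PopulationSummary(per_track, pd.DataFrame(), fractions, 0,
                                 status="all tracks filtered out")
    metrics = ["mean_speed", "path_speed", "run_length", "percent_pausing",
               "mean_pause_duration"]
    agg_rows = []
    for m in metrics:
        vals = motile[m].to_numpy(dtype=float)
        rep_means = motile.groupby("replicate")[m].mean().to_numpy(dtype=float)
        agg_rows.append({
            "metric": m,
            "mean_over_tracks": float(vals.mean()), "sem_over_tracks": _sem(vals),
            "n_tracks": len(vals),
            "mean_over_replicates": float(rep_means.mean()),
            "sem_over_replicates": _sem(rep_means), "n_replicates": len(rep_means),
        })
    return PopulationSummary(per_track, pd.DataFrame(agg_rows), fractions, len(motile))


def event_frequency(trackset: TrackSet, movie_duration: float | None = None,
                    direction: str = "retrograde",
                    config: KineticsConfig | None = None) -> float:
    """Motile events per minute in the given direction.

    Counts tracks passing the motile filter per movie, divides by the
    movie duration in minutes, and averages over movies. Movies with no
    tracks contribute zero only if they appear in the set; absent movies
    cannot be counted.
    """
    config = config or KineticsConfig()
    duration = movie_duration if movie_duration is not None else trackset.movie_duration
    if duration is None or duration <= 0:
        raise ValueError("movie_duration must be positive")
    minutes = duration / 60.0
    per_movie: dict[str, int] = {m: 0 for m in trackset.movies}
    for tr in trackset:
        s = track_summary(tr, config)
        if s.passed_motile_filter and s.direction == direction:
            per_movie[tr.movie] += 1
    if not per_movie:
        return 0.0
    return float(np.mean([c / minutes for c in per_movie.values()]))


def first_arrival_time(trackset: TrackSet, direction: str = "retrograde",
                       config: KineticsConfig | None = None) -> float | None:
    """Minutes from label onset to the first motile track in the window.

    Requires the set's clock to start at label onset (t = 0). Returns
    None when no qualifying track exists ("not observed").
    """
    config = config or KineticsConfig()
    best: float | None = None
    for tr in trackset:
        s = track_summary(tr, config)
        if s.passed_motile_filter and s.direction == direction:
            t0 = float(tr.t[0]) / 60.0
            if best is None or t0 < best:
                best = t0
    return best
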