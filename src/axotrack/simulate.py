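"""Seeded synthetic data with the statistical structure of axonal-transport movies.

Three generators:

* :func:`simulate_tracks` — particles moving through a microfluidic groove
  under a two-state run/pause process, observed at 2 Hz inside a ~110-µm
  imaging window with Gaussian localization noise. Supports the
  label-onset experiment in which motile particles start from the distal
  (axonal) end at t = 0 so that first-arrival times are meaningful.
* :func:`simulate_bleach_traces` — 30-Hz intensity traces of immobilized
  spots containing n molecules x c tagged copies x labeling efficiency
  fluorophores, each contributing a ~26 AU plateau until its exponential
  bleaching time.
* :func:`simulate_dual_channel` — two track sets in which a configured
  fraction of channel-A particles carries a channel-B partner on the same
  trajectory.

Every generator records per-particle ground truth and is bit-reproducible
from its seed. Sub-streams are derived deterministically from the
top-level seed via ``numpy.random.SeedSequence``.

Defaults emulate the imaging regime the package targets: a 500-µm groove,
2-Hz acquisition, retrograde speeds truncated to 0.3–5.0 µm/s around a
1.76 µm/s mean, visible run lengths of mean 35 µm (defocus censoring,
flagged in ground truth, not detachment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bleach import IntensityTrace
from .tracks import Track, TrackSet

__all__ = [
    "AxonGeometry",
    "SimTrackConfig",
    "SimTraceConfig",
    "TraceSet",
    "simulate_tracks",
    "simulate_bleach_traces",
    "simulate_dual_channel",
    "render_kymograph",
]


@dataclass(frozen=True)
class AxonGeometry:
    """Groove geometry in µm. x = 0 is the somatodendritic end."""

    groove_length: float = 500.0
    window_start: float = 0.0
    window_end: float = 110.0

    def __post_init__(self) -> None:
        if not (0 <= self.window_start < self.window_end <= self.groove_length):
            raise ValueError(
                "require 0 <= window_start < window_end <= groove_length; "
                f"got [{self.window_start}, {self.window_end}] in {self.groove_length}")

    @property
    def window_width(self) -> float:
        return self.window_end - self.window_start


@dataclass
class SimTrackConfig:
    """Parameters of the track generator.

    direction_mix is (retrograde, anterograde, stationary) fractions.
    Speeds are drawn per track from a normal truncated to
    [speed_min, speed_max]; runs alternate with exponential pauses
    (entry rate ``pause_entry_rate`` per second of running,
    mean duration ``pause_mean_duration``).
    """

    geometry: AxonGeometry = field(default_factory=AxonGeometry)
    frame_rate: float = 2.0
    n_tracks: int = 50
    n_movies: int = 1
    direction_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)
    speed_mean: float = 1.76
    speed_sd: float = 0.8
    speed_min: float = 0.3
    speed_max: float = 5.0
    pause_entry_rate: float = 0.05
    pause_mean_duration: float = 4.0
    localization_sd: float = 0.05
    visible_length_mean: float = 35.0
    label_onset: bool = False
    movie_duration: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        mix = np.asarray(self.direction_mix, dtype=float)
        if mix.size != 3 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("direction_mix must be 3 non-negative fractions summing to 1")
        if not self.speed_min < self.speed_max:
            raise ValueError("require speed_min < speed_max")
        if min(self.pause_entry_rate, self.pause_mean_duration,
               self.localization_sd, self.visible_length_mean) < 0:
            raise ValueError("rates, durations and sds must be >= 0")
        if self.n_tracks < 0 or self.n_movies < 1:
            raise ValueError("n_tracks >= 0 and n_movies >= 1 required")
        if self.movie_duration <= 0:
            raise ValueError("movie_duration must be positive")


def _draw_speed(cfg: SimTrackConfig, rng: np.random.Generator) -> float:
    a = (cfg.speed_min - cfg.speed_mean) / cfg.speed_sd if cfg.speed_sd > 0 else 0.0
    b = (cfg.speed_max - cfg.speed_mean) / cfg.speed_sd if cfg.speed_sd > 0 else 0.0
    if cfg.speed_sd == 0:
        return cfg.speed_mean
    return float(stats.truncnorm.rvs(a, b, loc=cfg.speed_mean, scale=cfg.speed_sd,
                                     random_state=rng))


def _motion_breakpoints(cfg: SimTrackConfig, speed_signed: float, t0: float,
                        x0: float, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-linear trajectory: breakpoint times, positions, running flags.

    Alternates exponential run intervals (rate = pause_entry_rate) with
    exponential pauses (mean = pause_mean_duration), starting in the
    running state, until the movie ends or the particle leaves the groove.
    """
    t_end = cfg.movie_duration
    times = [t0]
    xs = [x0]
    running = [True]
    t, x = t0, x0
    state_run = True
    L = cfg.geometry.groove_length
    while t < t_end and 0.0 <= x <= L:
        if state_run:
            dur = rng.exponential(1.0 / cfg.pause_entry_rate) \
                if cfg.pause_entry_rate > 0 else t_end - t + 1.0
        else:
            dur = rng.exponential(cfg.pause_mean_duration) \
                if cfg.pause_mean_duration > 0 else 0.0
        dur = min(dur, t_end - t)
        if state_run:
            x = x + speed_signed * dur
        t = t + dur
        times.append(t)
        xs.append(x)
        running.append(not state_run)
        state_run = not state_run
        if dur <= 0:
            break
    return np.asarray(times), np.asarray(xs), np.asarray(running)


def _true_tracks(cfg: SimTrackConfig, rng: np.random.Generator) -> list[dict]:
    """Generate noiseless particle trajectories sampled at the frame clock.

    Each entry carries the frames/times/true positions of the visible
    stretch plus the ground-truth row for that particle.
    """
    geo = cfg.geometry
    dt = 1.0 / cfg.frame_rate
    n_frames_total = int(np.floor(cfg.movie_duration / dt)) + 1
    all_t = np.arange(n_frames_total) * dt
    out = []
    labels = np.array(["retrograde", "anterograde", "stationary"])
    for i in range(cfg.n_tracks):
        movie = f"movie{rng.integers(cfg.n_movies)}"
        direction = str(rng.choice(labels, p=np.asarray(cfg.direction_mix, dtype=float)))
        speed = _draw_speed(cfg, rng)
        if direction == "stationary":
            speed_signed = 0.0
        elif direction == "retrograde":
            speed_signed = -speed
        else:
            speed_signed = speed
        if cfg.label_onset:
            t0 = 0.0
            x0 = geo.groove_length
        else:
            t0 = float(rng.uniform(0.0, cfg.movie_duration))
            x0 = float(rng.uniform(geo.window_start, geo.window_end))
        vis_len = float(rng.exponential(cfg.visible_length_mean)) \
            if cfg.visible_length_mean > 0 else np.inf
        bt, bx, brun = _motion_breakpoints(cfg, speed_signed, t0, x0, rng)
        sel = all_t >= t0 - 1e-12
        tf = all_t[sel]
        frames = np.nonzero(sel)[0]
        xf = np.interp(tf, bt, bx)
        path = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(xf)))])
        visible = (xf >= geo.window_start) & (xf <= geo.window_end) & (path <= vis_len)
        row = {
            "track_id": -1, "movie": movie, "direction": direction,
            "speed": speed if direction != "stationary" else 0.0,
            "start_time": t0, "start_x": x0, "visible_length": vis_len,
            "censored_by_visibility": False, "emitted": False,
            "true_pause_fraction": np.nan, "first_visible_t": np.nan,
        }
        if not np.any(visible):
            out.append({"frames": None, "gt": row})
            continue
        # first contiguous visible stretch (monotone runs leave the window once)
        first = int(np.argmax(visible))
        after = np.nonzero(~visible[first:])[0]
        last = first + (int(after[0]) if after.size else visible.size - first)
        frames_v = frames[first:last]
        if len(frames_v) < 2:
            out.append({"frames": None, "gt": row})
            continue
        tv = tf[first:last]
        xv = xf[first:last]
        row["emitted"] = True
        row["censored_by_visibility"] = bool(path[last - 1] >= vis_len - 1e-9)
        row["first_visible_t"] = float(tv[0])
        row["true_pause_fraction"] = _paused_fraction(bt, brun, tv[0], tv[-1])
        out.append({"frames": frames_v, "t": tv, "x": xv, "gt": row})
    return out


def _paused_fraction(bt: np.ndarray, brun: np.ndarray, t_a: float, t_b: float) -> float:
    """Ground-truth fraction of [t_a, t_b] spent in the paused state."""
    if t_b <= t_a:
        return 0.0
    paused = 0.0
    for k in range(len(bt) - 1):
        # interval k runs iff brun[k] is True entering it
        seg_a, seg_b = bt[k], bt[k + 1]
        lo, hi = max(seg_a, t_a), min(seg_b, t_b)
        if hi > lo and not brun[k]:
            paused += hi - lo
    if bt[-1] < t_b and len(bt) >= 2:
        if not brun[-1]:
            paused += t_b - max(bt[-1], t_a)
    return paused / (t_b - t_a)


def simulate_tracks(config: SimTrackConfig) -> TrackSet:
    """Generate a seeded TrackSet under the two-state run/pause model.

    Ground truth (one row per generated particle, emitted or not) is
    attached as ``TrackSet.ground_truth``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    raw = _true_tracks(config, rng)
    tracks, gt_rows = [], []
    tid = 0
    for item in raw:
        row = item["gt"]
        if item["frames"] is not None:
            x = item["x"] + rng.normal(0.0, config.localization_sd, size=len(item["x"]))
            y = rng.normal(0.0, config.localization_sd, size=len(item["x"]))
            inten = np.full(len(item["x"]), 52.0) + rng.normal(0, 4.0, size=len(item["x"]))
            row = dict(row, track_id=tid)
            tracks.append(Track(
                track_id=tid, frames=item["frames"], t=item["t"], x=x, y=y,
                intensity=inten, movie=row["movie"]))
            tid += 1
        gt_rows.append(row)
    return TrackSet(
        tracks=tracks, frame_rate=config.frame_rate,
        movie_duration=config.movie_duration, label_onset=config.label_onset,
        ground_truth=pd.DataFrame(gt_rows))


@dataclass
class SimTraceConfig:
    """Parameters of the bleaching-trace generator.

    A spot holds n molecules (n ~ molecule_count_pmf), each with
    ``copies_per_molecule`` taggable copies, each copy labeled with
    probability ``labeling_efficiency``. Every labeled fluorophore
    contributes an intensity plateau (drawn once from
    N(step_intensity_mean, step_intensity_sd), floored at 1 AU) that
    switches off at an exponential bleaching time of rate
    ``bleach_rate``.
    """

    n_traces: int = 300
    frame_rate: float = 30.0
    n_frames: int = 900
    molecule_count_pmf: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.15})
    copies_per_molecule: int = 2
    labeling_efficiency: float = 0.9
    step_intensity_mean: float = 26.0
    step_intensity_sd: float = 4.0
    bleach_rate: float = 0.1
    noise_sd: float = 6.0
    background: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.molecule_count_pmf:
            raise ValueError("molecule_count_pmf must be non-empty")
        probs = np.array(list(self.molecule_count_pmf.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("molecule_count_pmf must sum to 1 (tolerance 1e-9)")
        if any(int(k) < 1 for k in self.molecule_count_pmf):
            raise ValueError("molecule counts must be >= 1")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise ValueError("labeling_efficiency must be in [0, 1]")
        if min(self.step_intensity_mean, self.step_intensity_sd,
               self.background, self.noise_sd) < 0:
            raise ValueError("intensities and sds must be >= 0")
        if self.frame_rate <= 0 or self.n_frames < 10 or self.n_traces < 1:
            raise ValueError("invalid acquisition parameters")
        if self.copies_per_molecule < 1 or self.bleach_rate <= 0:
            raise ValueError("copies_per_molecule >= 1 and bleach_rate > 0 required")


@dataclass
class TraceSet:
    """Synthetic bleaching traces plus their per-trace ground truth."""

    traces: list[IntensityTrace]
    ground_truth: pd.DataFrame
    config: SimTraceConfig

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)


def simulate_bleach_traces(config: SimTraceConfig) -> TraceSet:
    """Generate seeded bleaching traces with recorded fluorophore truth."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    counts = np.array(sorted(config.molecule_count_pmf), dtype=int)
    probs = np.array([config.molecule_count_pmf[int(k)] for k in counts], dtype=float)
    probs = probs / probs.sum()
    t = np.arange(config.n_frames) / config.frame_rate
    traces, gt = [], []
    for sid in range(config.n_traces):
        n_mol = int(rng.choice(counts, p=probs))
        n_fluor = int(rng.binomial(n_mol * config.copies_per_molecule,
                                   config.labeling_efficiency))
        amps = np.maximum(rng.normal(config.step_intensity_mean,
                                     config.step_intensity_sd, size=n_fluor), 1.0)
        bleach_t = rng.exponential(1.0 / config.bleach_rate, size=n_fluor)
        signal = np.full(config.n_frames, config.background, dtype=float)
        for a, tb in zip(amps, bleach_t):
            signal += a * (t < tb)
        if config.noise_sd > 0:
            signal = signal + rng.normal(0.0, config.noise_sd, size=config.n_frames)
        traces.append(IntensityTrace(spot_id=sid, values=signal,
                                     frame_rate=config.frame_rate,
                                     background=config.background))
        gt.append({
            "spot_id": sid, "n_molecules": n_mol, "n_fluorophores": n_fluor,
            "total_intensity": float(amps.sum()),
            "bleach_times": ";".join(f"{v:.4f}" for v in sorted(bleach_t)),
            "step_sizes": ";".join(f"{v:.4f}" for v in amps),
        })
    return TraceSet(traces=traces, ground_truth=pd.DataFrame(gt), config=config)


def simulate_dual_channel(config_a: SimTrackConfig, config_b: SimTrackConfig,
                          coloc_fraction: float, seed: int = 0
                          ) -> tuple[TrackSet, TrackSet]:
    """Two-channel track sets with a configured colocalized fraction.

    ``round(coloc_fraction * n_A)`` channel-A particles get a channel-B
    partner sharing their true trajectory (each channel adds its own
    localization noise); the remaining ``config_b.n_tracks`` B particles
    are independent, with B's own speed/direction distributions.
    Ground-truth pairing is recorded in both sets' tables
    (``partner_id`` column).
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_a, rng_b, rng_p = (np.random.default_rng(s) for s in ss)

    raw_a = _true_tracks(config_a, rng_a)
    emitted_a = [it for it in raw_a if it["frames"] is not None]
    n_pairs = int(round(coloc_fraction * len(emitted_a)))

    tracks_a, gt_a = [], []
    for tid, item in enumerate(emitted_a):
        x = item["x"] + rng_a.normal(0.0, config_a.localization_sd, size=len(item["x"]))
        y = rng_a.normal(0.0, config_a.localization_sd, size=len(item["x"]))
        tracks_a.append(Track(track_id=tid, frames=item["frames"], t=item["t"],
                              x=x, y=y, channel="A", movie=item["gt"]["movie"]))
        gt_a.append(dict(item["gt"], track_id=tid, partner_id=-1))

    tracks_b, gt_b = [], []
    bid = 0
    # partners: first n_pairs A particles (order is already random)
    for tid in range(n_pairs):
        item = emitted_a[tid]
        x = item["x"] + rng_p.normal(0.0, config_b.localization_sd, size=len(item["x"]))
        y = rng_p.normal(0.0, config_b.localization_sd, size=len(item["x"]))
        tracks_b.append(Track(track_id=bid, frames=item["frames"], t=item["t"],
                              x=x, y=y, channel="B", movie=item["gt"]["movie"]))
        gt_a[tid]["partner_id"] = bid
        gt_b.append(dict(item["gt"], track_id=bid, partner_id=tid))
        bid += 1
    raw_b = _true_tracks(config_b, rng_b)
    for item in raw_b:
        if item["frames"] is None:
            continue
        x = item["x"] + rng_b.normal(0.0, config_b.localization_sd, size=len(item["x"]))
        y = rng_b.normal(0.0, config_b.localization_sd, size=len(item["x"]))
        tracks_b.append(Track(track_id=bid, frames=item["frames"], t=item["t"],
                              x=x, y=y, channel="B", movie=item["gt"]["movie"]))
        gt_b.append(dict(item["gt"], track_id=bid, partner_id=-1))
        bid += 1

    set_a = TrackSet(tracks=tracks_a, frame_rate=config_a.frame_rate,
                     movie_duration=config_a.movie_duration,
                     ground_truth=pd.DataFrame(gt_a))
    set_b = TrackSet(tracks=tracks_b, frame_rate=config_b.frame_rate,
                     movie_duration=config_b.movie_duration,
                     ground_truth=pd.DataFrame(gt_b))
    return set_a, set_b


def render_kymograph(trackset: TrackSet, geometry: AxonGeometry,
                     psf_sd: float = 0.2, background_noise_sd: float = 0.0,
                     pixel_size: float = 0.1, seed: int = 0) -> np.ndarray:
    """Render a kymograph image: rows = frames, columns = binned positions.

    Each visible spot contributes a 1-D Gaussian intensity profile of
    width ``psf_sd`` (µm) centred on its position; sloped lines in the
    image therefore have slope equal to particle speed. Deterministic
    given ``seed`` (used only for the optional background noise).
    """
    if psf_sd <= 0:
        raise ValueError("psf_sd must be positive")
    if len(trackset) == 0 and trackset.movie_duration is None:
        raise ValueError("empty trackset without movie_duration")
    duration = trackset.movie_duration
    if duration is None:
        duration = max(tr.t[-1] for tr in trackset)
    n_frames = int(np.floor(duration * trackset.frame_rate)) + 1
    centers = np.arange(geometry.window_start + pixel_size / 2,
                        geometry.window_end, pixel_size)
    img = np.zeros((n_frames, len(centers)))
    for tr in trackset:
        amp = np.where(tr.intensity > 0, tr.intensity, 50.0)
        for f, x, a in zip(tr.frames, tr.x, amp):
            if 0 <= f < n_frames:
                img[f] += a * np.exp(-0.5 * ((centers - x) / psf_sd) ** 2)
    if background_noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, background_noise_sd, size=img.shape)
    return img
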