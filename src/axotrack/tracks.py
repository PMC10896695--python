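"""Core containers for single-particle tracks.

Coordinate convention (shared by every module): x = 0 at the somatodendritic
end of the microfluidic groove, x = groove_length at the axonal end.
Retrograde transport (toward the cell body) therefore means decreasing x.
Times are in seconds, positions in micrometres, intensities in arbitrary
units (AU); frames are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = ["Track", "TrackSet"]

#: Relative tolerance on the uniformity of the frame interval.
_DT_RTOL = 1e-6


@dataclass
class Track:
    """Ordered time/position/intensity samples for one particle in one channel.

    Parameters
    ----------
    track_id : int
        Identifier, unique within a :class:`TrackSet`.
    frames : ndarray of int
        0-based acquisition frame of each sample; strictly increasing.
    t : ndarray of float
        Time of each sample in seconds (``frames / frame_rate``).
    x : ndarray of float
        Position along the axon axis in µm.
    y : ndarray of float, optional
        Transverse position in µm (zeros when the axis is collapsed).
    intensity : ndarray of float, optional
        Spot intensity in AU.
    channel, replicate, movie : str
        Acquisition metadata labels.
    """

    track_id: int
    frames: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray | None = None
    intensity: np.ndarray | None = None
    channel: str = "ch0"
    replicate: str = "rep0"
    movie: str = "movie0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.zeros_like(self.x) if self.y is None else np.asarray(self.y, dtype=float)
        if self.intensity is None:
            self.intensity = np.zeros_like(self.x)
        else:
            self.intensity = np.asarray(self.intensity, dtype=float)
        n = len(self.frames)
        if n < 2:
            raise ValueError(f"track {self.track_id}: needs >= 2 points, got {n}")
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.intensity) == n):
            raise ValueError(f"track {self.track_id}: field lengths disagree")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")
        dts = np.diff(self.t) / np.diff(self.frames)
        if dts.size and not np.allclose(dts, dts[0], rtol=_DT_RTOL, atol=1e-9):
            raise ValueError(f"track {self.track_id}: non-uniform frame interval")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return float((self.t[-1] - self.t[0]) / (self.frames[-1] - self.frames[0]))

    @property
    def duration(self) -> float:
        """Track time span in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def net_displacement(self) -> float:
        """Signed end-minus-start displacement along the axon (µm)."""
        return float(self.x[-1] - self.x[0])

    @property
    def path_length(self) -> float:
        """Sum of absolute frame-to-frame axial displacements (µm)."""
        return float(np.sum(np.abs(np.diff(self.x))))

    def flipped(self) -> "Track":
        """Return a copy with the axial coordinate negated (direction swap)."""
        return Track(
            track_id=self.track_id, frames=self.frames.copy(), t=self.t.copy(),
            x=-self.x, y=self.y.copy(), intensity=self.intensity.copy(),
            channel=self.channel, replicate=self.replicate, movie=self.movie,
        )


@dataclass
class TrackSet:
    """A collection of tracks from one experiment plus acquisition metadata.

    ``ground_truth`` is populated by the simulators (one row per generated
    particle, including particles never seen in the window) and round-trips
    through the CSV writers unchanged.
    """

    tracks: list[Track] = field(default_factory=list)
    frame_rate: float = 2.0
    movie_duration: float | None = None
    label_onset: bool = False
    ground_truth: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    @property
    def movies(self) -> list[str]:
        return sorted({tr.movie for tr in self.tracks})

    def to_spots_frame(self) -> pd.DataFrame:
        """Flatten to a per-spot table in the TrackMate column dialect."""
        rows = []
        for tr in self.tracks:
            rows.append(pd.DataFrame({
                "TRACK_ID": tr.track_id,
                "FRAME": tr.frames,
                "POSITION_T": tr.t,
                "POSITION_X": tr.x,
                "POSITION_Y": tr.y,
                "MEAN_INTENSITY": tr.intensity,
                "CHANNEL": tr.channel,
                "REPLICATE": tr.replicate,
                "MOVIE": tr.movie,
            }))
        if not rows:
            return pd.DataFrame(columns=[
                "TRACK_ID", "FRAME", "POSITION_T", "POSITION_X", "POSITION_Y",
                "MEAN_INTENSITY", "CHANNEL", "REPLICATE", "MOVIE"])
        return pd.concat(rows, ignore_index=True)

    def flipped(self) -> "TrackSet":
        """Coordinate-flipped copy (retrograde and anterograde swap)."""
        return TrackSet(
            tracks=[tr.flipped() for tr in self.tracks],
            frame_rate=self.frame_rate,
            movie_duration=self.movie_duration,
            label_onset=self.label_onset,
            ground_truth=None if self.ground_truth is None else self.ground_truth.copy(),
        )
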