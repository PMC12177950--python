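"""Trajectory containers and track-table I/O.

Positions are stored in micrometres and time in seconds throughout the
package; pixel-to-micron conversion happens once, when a tracker emits
coordinates. Frame indices are 0-based.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "TrajectorySet",
    "read_tracks",
    "write_tracks",
    "filter_min_length",
    "TrackFormatError",
    "TrackValidationError",
]


class TrackFormatError(ValueError):
    """Raised when a track table is structurally malformed."""


class TrackValidationError(ValueError):
    """Raised when track-table contents violate trajectory invariants."""


@dataclass(frozen=True)
class Trajectory:
    """One molecule's sampled path: positions x(k), y(k) at frame indices k.

    Parameters
    ----------
    track_id : int
        Integer label, unique within a :class:`TrajectorySet`.
    frames : ndarray of int
        Strictly increasing 0-based frame indices.
    x, y : ndarray of float
        Positions in micrometres.
    frame_time : float
        Frame interval Delta-t in seconds.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_time: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(frames) == len(x) == len(y)):
            raise TrackValidationError(
                f"track {self.track_id}: frames/x/y lengths differ"
            )
        if len(frames) < 1:
            raise TrackValidationError(f"track {self.track_id}: empty trajectory")
        if np.any(np.diff(frames) <= 0):
            raise TrackValidationError(
                f"track {self.track_id}: frame indices not strictly increasing"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise TrackValidationError(f"track {self.track_id}: non-finite position")
        if not self.frame_time > 0:
            raise TrackValidationError("frame_time must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(l, 2) array of [x, y] in micrometres."""
        return np.column_stack([self.x, self.y])

    @property
    def is_contiguous(self) -> bool:
        """True when frames have no gaps (required by the MSD estimators)."""
        return len(self.frames) == self.frames[-1] - self.frames[0] + 1


@dataclass
class TrajectorySet:
    """A collection of trajectories sharing acquisition parameters."""

    trajectories: list[Trajectory]
    pixel_size: float = 0.176
    frame_time: float = 0.1
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise TrackValidationError("duplicate track_id in TrajectorySet")
        for t in self.trajectories:
            if not np.isclose(t.frame_time, self.frame_time):
                raise TrackValidationError(
                    f"track {t.track_id}: frame_time differs from set frame_time"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for t in self.trajectories:
            frames.append(
                pd.DataFrame(
                    {
                        "track_id": t.track_id,
                        "frame": t.frames,
                        "x_um": t.x,
                        "y_um": t.y,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(columns=["track_id", "frame", "x_um", "y_um"])
        return pd.concat(frames, ignore_index=True)


_HEADER_RE = re.compile(
    r"#\s*pixel_size_um=(?P<px>[-+0-9.eE]+)\s+frame_time_s=(?P<dt>[-+0-9.eE]+)"
)

_COLUMN_ALIASES = {"track_id": "track_id", "frame": "frame", "x_um": "x_um",
                   "y_um": "y_um", "x": "x_um", "y": "y_um"}


def read_tracks(path) -> TrajectorySet:
    """Read a track-table CSV/TSV into a :class:`TrajectorySet`.

    The expected layout is a metadata header line
    ``# pixel_size_um=<f> frame_time_s=<f>`` followed by columns
    ``track_id,frame,x_um,y_um`` (comma- or tab-separated).
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    pixel_size, frame_time = 0.176, 0.1
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            m = _HEADER_RE.match(line)
            if m:
                pixel_size = float(m.group("px"))
                frame_time = float(m.group("dt"))
            body_start = i + 1
        else:
            break
    body = "\n".join(lines[body_start:])
    sep = "\t" if ("\t" in lines[body_start] if body_start < len(lines) else False) else ","
    df = pd.read_csv(io.StringIO(body), sep=sep, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    df = df.rename(columns={c: _COLUMN_ALIASES.get(c, c) for c in df.columns})
    for col in ("track_id", "frame", "x_um", "y_um"):
        if col not in df.columns:
            raise TrackFormatError(f"missing required column: {col}")
    trajectories = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        if grp["frame"].duplicated().any():
            raise TrackValidationError(
                f"track {tid}: duplicate frame index in table"
            )
        trajectories.append(
            Trajectory(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(dtype=np.int64),
                x=grp["x_um"].to_numpy(dtype=float),
                y=grp["y_um"].to_numpy(dtype=float),
                frame_time=frame_time,
            )
        )
    return TrajectorySet(
        trajectories, pixel_size=pixel_size, frame_time=frame_time,
        provenance=f"read_tracks:{path}",
    )


def write_tracks(tset: TrajectorySet, path) -> None:
    """Write a :class:`TrajectorySet` as the package's track-table CSV.

    ``read_tracks(write_tracks(s))`` round-trips bit-identically for
    finite coordinates (values are written with ``repr`` precision).
    """
    df = tset.to_dataframe()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# pixel_size_um={tset.pixel_size!r} frame_time_s={tset.frame_time!r}\n"
        )
        fh.write("track_id,frame,x_um,y_um\n")
        for row in df.itertuples(index=False):
            fh.write(f"{int(row.track_id)},{int(row.frame)},{row.x_um!r},{row.y_um!r}\n")


def filter_min_length(tset: TrajectorySet, min_frames: int = 20) -> TrajectorySet:
    """Keep only trajectories strictly longer than ``min_frames`` frames.

    The default of 20 frames (2 s at a 100 ms frame time) excludes short
    tracks whose MSD estimates are noise-dominated; "longer than" is a
    strict inequality, so the default keeps lengths >= 21.
    """
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    kept = [t for t in tset.trajectories if len(t) > min_frames]
    return TrajectorySet(
        kept, pixel_size=tset.pixel_size, frame_time=tset.frame_time,
        provenance=tset.provenance,
    )
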