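"""Spot detection and frame-to-frame linking.

Detection is difference-of-Gaussians (DoG) band-pass filtering, local
maxima above a response threshold, and quadratic subpixel refinement on
the 3x3 DoG neighborhood. Linking solves, per consecutive frame pair,
the minimum-total-squared-displacement one-to-one assignment among
candidate pairs closer than the gate distance (default 0.88 um = 5
pixels); unassigned spots start or terminate tracks. No gap closing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .imaging import Movie
from .trajectories import Trajectory, TrajectorySet

__all__ = [
    "Spot",
    "LinkConfig",
    "dog_detect",
    "apply_filters",
    "link",
    "track_movie",
]


@dataclass(frozen=True)
class Spot:
    """One detected fluorescent spot (positions in um, subpixel)."""

    frame: int
    x: float
    y: float
    sum_intensity: float
    quality: float

    def __post_init__(self):
        if self.sum_intensity < 0:
            raise ValueError("sum_intensity must be non-negative")


@dataclass(frozen=True)
class LinkConfig:
    """Detection and linking parameters.

    ``dog_sigma_small``/``dog_sigma_large`` are the band-pass scales in
    um (defaults scale the classic 1.0/1.6-pixel pair by the pixel
    size); ``detection_threshold`` is in DoG response units (counts);
    ``max_disp`` is the per-frame gate in um; ``mask`` an optional
    polygon (list of (x_um, y_um) vertices) restricting analysis to a
    flake interior.
    """

    max_disp: float = 0.88
    min_sum_intensity: float = 0.0
    dog_sigma_small: float = 1.0 * 0.176
    dog_sigma_large: float = 1.6 * 0.176
    detection_threshold: float = 15.0
    pixel_size: float = 0.176
    mask: np.ndarray | None = None

    def __post_init__(self):
        if not 0 < self.dog_sigma_small < self.dog_sigma_large:
            raise ValueError("need 0 < dog_sigma_small < dog_sigma_large")
        if self.max_disp <= 0:
            raise ValueError("max_disp must be positive")
        if self.mask is not None:
            m = np.asarray(self.mask, float)
            if m.ndim != 2 or m.shape[1] != 2 or len(m) < 3:
                raise ValueError("mask must be an (n>=3, 2) polygon vertex array")
            object.__setattr__(self, "mask", m)


def _parabola_vertex(f0: float, f1: float, f2: float) -> float:
    """Vertex offset in [-0.5, 0.5] of the parabola through three equally
    spaced samples centered on f1; 0 when the triple is not a maximum."""
    denom = f0 - 2.0 * f1 + f2
    if denom >= 0:
        return 0.0
    off = 0.5 * (f0 - f2) / denom
    return off if abs(off) <= 0.5 else 0.0


def _quadratic_refine(patch: np.ndarray) -> tuple[float, float]:
    """Subpixel offset of the maximum of a 3x3 patch.

    Fits a separable quadratic to the log of the response along each
    axis through the peak — exact for a Gaussian-shaped peak, and close
    to it for a DoG response. Falls back to a quadratic on the raw
    values when the neighborhood is not strictly positive; offsets are
    clamped to +/-0.5 px (saddles fall back to the integer maximum).
    """
    row = patch[1, :]
    col = patch[:, 1]
    dx = (_parabola_vertex(*np.log(row)) if np.all(row > 0)
          else _parabola_vertex(*row))
    dy = (_parabola_vertex(*np.log(col)) if np.all(col > 0)
          else _parabola_vertex(*col))
    return float(dx), float(dy)


def dog_detect(image: np.ndarray, config: LinkConfig) -> list[Spot]:
    """Detect spots in one image (2D array of camera counts).

    Local maxima of the DoG-filtered image above ``detection_threshold``
    are refined to subpixel via a quadratic fit; ``sum_intensity`` is
    the background-subtracted count sum over a disk of radius
    ceil(2 * dog_sigma_small / pixel_size) pixels (background = image
    median). Returned positions are in um; ``frame`` is left 0 (callers
    tracking a movie overwrite it).
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("dog_detect expects a single 2D image")
    s_small = config.dog_sigma_small / config.pixel_size
    s_large = config.dog_sigma_large / config.pixel_size
    support = int(np.ceil(4 * s_large))
    if min(img.shape) <= 2 * support + 1 and min(img.shape) < 7:
        raise ValueError("image smaller than DoG kernel support")
    dog = (ndimage.gaussian_filter(img, s_small)
           - ndimage.gaussian_filter(img, s_large))
    maxf = ndimage.maximum_filter(dog, size=3, mode="nearest")
    peaks = (dog >= maxf) & (dog > config.detection_threshold)
    # exclude the one-pixel border: the 3x3 refinement needs a full patch
    peaks[0, :] = peaks[-1, :] = False
    peaks[:, 0] = peaks[:, -1] = False
    ys, xs = np.nonzero(peaks)
    background = float(np.median(img))
    radius = int(np.ceil(2 * s_small))
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disk = (yy * yy + xx * xx) <= radius * radius
    spots = []
    ny, nx = img.shape
    for iy, ix in zip(ys, xs):
        dx, dy = _quadratic_refine(dog[iy - 1:iy + 2, ix - 1:ix + 2])
        # pixel-center convention: pixel (iy, ix) is centered at
        # (ix + 0.5, iy + 0.5) px
        x_um = (ix + dx + 0.5) * config.pixel_size
        y_um = (iy + dy + 0.5) * config.pixel_size
        y0, y1 = max(0, iy - radius), min(ny, iy + radius + 1)
        x0, x1 = max(0, ix - radius), min(nx, ix + radius + 1)
        sub = img[y0:y1, x0:x1] - background
        dsk = disk[(y0 - iy + radius):(y1 - iy + radius),
                   (x0 - ix + radius):(x1 - ix + radius)]
        sum_int = float(max(np.sum(sub[dsk]), 0.0))
        spots.append(Spot(frame=0, x=x_um, y=y_um,
                          sum_intensity=sum_int, quality=float(dog[iy, ix])))
    return spots


def _point_in_polygon(x: float, y: float, poly: np.ndarray) -> bool:
    # even-odd ray casting
    inside = False
    n = len(poly)
    for i in range(n):
        x0, y0 = poly[i]
        x1, y1 = poly[(i + 1) % n]
        if (y0 > y) != (y1 > y):
            xc = x0 + (y - y0) / (y1 - y0) * (x1 - x0)
            if x < xc:
                inside = not inside
    return inside


def apply_filters(spots: list[Spot], config: LinkConfig) -> list[Spot]:
    """Drop spots below the sum-intensity threshold or outside the mask
    polygon (boundary cropping)."""
    out = []
    for s in spots:
        if s.sum_intensity < config.min_sum_intensity:
            continue
        if config.mask is not None and not _point_in_polygon(s.x, s.y, config.mask):
            continue
        out.append(s)
    return out


def link(spots_by_frame: dict[int, list[Spot]], config: LinkConfig,
         frame_time: float = 0.1) -> TrajectorySet:
    """Link spots across consecutive frames into trajectories.

    Per frame pair, candidate pairs within ``max_disp`` enter a
    rectangular assignment problem with squared-distance cost, solved
    exactly; unmatched spots terminate or start tracks. Spots within a
    frame are processed in a deterministic order (descending quality,
    then x, y) so results are reproducible.
    """
    if not spots_by_frame:
        return TrajectorySet([], frame_time=frame_time,
                             pixel_size=config.pixel_size)
    frames_sorted = sorted(spots_by_frame)
    ordered = {
        f: sorted(spots_by_frame[f], key=lambda s: (-s.quality, s.x, s.y))
        for f in frames_sorted
    }
    # active track id per spot index in the previous frame
    tracks: dict[int, list[Spot]] = {}
    next_id = 0
    prev_ids: list[int] = []
    prev_frame = None
    for f in frames_sorted:
        cur = ordered[f]
        cur_ids = [-1] * len(cur)
        if prev_frame is not None and f == prev_frame + 1 and prev_ids and cur:
            prev_spots = ordered[prev_frame]
            px = np.array([s.x for s in prev_spots])
            py = np.array([s.y for s in prev_spots])
            cx = np.array([s.x for s in cur])
            cy = np.array([s.y for s in cur])
            d2 = (px[:, None] - cx[None, :]) ** 2 + (py[:, None] - cy[None, :]) ** 2
            gate2 = config.max_disp**2
            cost = np.where(d2 <= gate2, d2, np.inf)
            # drop all-inf rows/cols so the assignment is feasible
            rows = np.where(np.isfinite(cost).any(axis=1))[0]
            cols = np.where(np.isfinite(cost).any(axis=0))[0]
            if len(rows) and len(cols):
                sub = cost[np.ix_(rows, cols)]
                # large-but-finite padding keeps linear_sum_assignment happy
                big = 1e6 * max(gate2, 1.0)
                ri, ci = optimize.linear_sum_assignment(
                    np.where(np.isfinite(sub), sub, big))
                for r, c in zip(ri, ci):
                    if np.isfinite(sub[r, c]):
                        cur_ids[cols[c]] = prev_ids[rows[r]]
        for i, s in enumerate(cur):
            s = Spot(frame=f, x=s.x, y=s.y,
                     sum_intensity=s.sum_intensity, quality=s.quality)
            if cur_ids[i] == -1:
                cur_ids[i] = next_id
                tracks[next_id] = []
                next_id += 1
            tracks[cur_ids[i]].append(s)
        prev_ids = cur_ids
        prev_frame = f
    trajs = []
    for tid in sorted(tracks):
        pts = tracks[tid]
        trajs.append(Trajectory(
            track_id=tid,
            frames=np.array([p.frame for p in pts]),
            x=np.array([p.x for p in pts]),
            y=np.array([p.y for p in pts]),
            frame_time=frame_time,
        ))
    return TrajectorySet(trajs, frame_time=frame_time,
                         pixel_size=config.pixel_size,
                         provenance="tracking.link")


def track_movie(movie: Movie, config: LinkConfig | None = None) -> TrajectorySet:
    """Detect, filter and link across a whole movie.

    Output coordinates are um using the movie's pixel size; the returned
    set carries the movie's frame time.
    """
    if config is None:
        config = LinkConfig(pixel_size=movie.config.pixel_size)
    elif config.pixel_size != movie.config.pixel_size:
        raise ValueError("LinkConfig.pixel_size disagrees with the movie")
    spots_by_frame: dict[int, list[Spot]] = {}
    for f in range(movie.n_frames):
        det = dog_detect(movie.frames[f], config)
        det = apply_filters(det, config)
        spots_by_frame[f] = [
            Spot(frame=f, x=s.x, y=s.y, sum_intensity=s.sum_intensity,
                 quality=s.quality)
            for s in det
        ]
    return link(spots_by_frame, config, frame_time=movie.config.frame_time)
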