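"""Nuclear movement in time-lapse movies of differentiating myotubes.

Detections are linked frame-to-frame by greedy mutual nearest neighbours
within a maximum link distance, and each track is summarised by the
percentage of time intervals in which the nucleus is in motion and the
average velocity over the moving intervals only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["NucleusTrack", "MotionMetrics", "LinkResult", "link_tracks",
           "motion_metrics", "tracks_from_truth"]

#: µm a nucleus must move between frames to count as "in motion"; roughly
#: the centroid-localization noise floor of the synthetic movies
DEFAULT_MOTION_THRESHOLD = 0.5


@dataclass
class NucleusTrack:
    track_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)  # µm

    def append(self, frame: int, xy: tuple[float, float]) -> None:
        if self.frames and frame <= self.frames[-1]:
            raise ValueError("frames must be strictly increasing")
        self.frames.append(frame)
        self.positions.append((float(xy[0]), float(xy[1])))

    def displacements(self) -> np.ndarray:
        """Per-interval displacement magnitudes (µm/frame interval)."""
        pos = np.asarray(self.positions)
        if len(pos) < 2:
            return np.empty(0)
        return np.linalg.norm(np.diff(pos, axis=0), axis=1)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MotionMetrics:
    track_id: int
    pct_time_in_motion: float   # %
    avg_velocity: float         # µm/min over moving intervals; NaN if none
    n_intervals: int
    velocity_defined: bool


@dataclass
class LinkResult:
    tracks: list[NucleusTrack]
    ambiguity_count: int  # detections with >1 candidate inside the link radius


def link_tracks(frames, max_link_distance: float) -> LinkResult:
    """Link per-frame detections into tracks.

    ``frames`` is a sequence (one entry per movie frame) of (n, 2) arrays
    or DataFrames with columns ``x_um, y_um``.  Consecutive frames are
    linked greedily: candidate pairs within ``max_link_distance`` are
    assigned in order of increasing distance (ties by lowest detection
    index), each detection used at most once.  Unlinked detections start
    new tracks; tracks without a match terminate.  Detections with more
    than one in-radius candidate are tallied as ambiguities.
    """
    if len(frames) < 2:
        raise ValueError("at least two frames are required")
    coords = [_as_xy(f) for f in frames]

    tracks: list[NucleusTrack] = []
    active: dict[int, NucleusTrack] = {}  # index in current frame -> track
    for i, pt in enumerate(coords[0]):
        tr = NucleusTrack(track_id=len(tracks))
        tr.append(0, pt)
        tracks.append(tr)
        active[i] = tr

    n_ambiguous = 0
    for f in range(1, len(coords)):
        prev, cur = coords[f - 1], coords[f]
        links, amb = _greedy_links(prev, cur, max_link_distance)
        n_ambiguous += amb
        new_active: dict[int, NucleusTrack] = {}
        for i_prev, j_cur in links:
            if i_prev in active:
                active[i_prev].append(f, cur[j_cur])
                new_active[j_cur] = active[i_prev]
        linked_cur = {j for _, j in links}
        for j in range(len(cur)):
            if j not in linked_cur:
                tr = NucleusTrack(track_id=len(tracks))
                tr.append(f, cur[j])
                tracks.append(tr)
                new_active[j] = tr
        active = new_active
    return LinkResult(tracks, n_ambiguous)


def _as_xy(f) -> np.ndarray:
    if isinstance(f, pd.DataFrame):
        return f[["x_um", "y_um"]].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(f, dtype=float)).reshape(-1, 2)


def _greedy_links(prev: np.ndarray, cur: np.ndarray, max_dist: float):
    if len(prev) == 0 or len(cur) == 0:
        return [], 0
    d = np.linalg.norm(prev[:, None, :] - cur[None, :, :], axis=2)
    in_radius = d <= max_dist
    amb = int(np.sum(in_radius.sum(axis=1) > 1)) + int(np.sum(in_radius.sum(axis=0) > 1))
    ii, jj = np.nonzero(in_radius)
    order = sorted(range(len(ii)), key=lambda k: (d[ii[k], jj[k]], ii[k], jj[k]))
    used_prev: set[int] = set()
    used_cur: set[int] = set()
    links = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_prev or j in used_cur:
            continue
        links.append((i, j))
        used_prev.add(i)
        used_cur.add(j)
    return links, amb


def motion_metrics(
    track: NucleusTrack,
    motion_threshold: float = DEFAULT_MOTION_THRESHOLD,
    frame_interval_min: float = 20.0,
) -> MotionMetrics:
    """Time-in-motion percentage and average velocity of one track.

    An interval counts as "in motion" iff its displacement exceeds
    ``motion_threshold`` (µm).  The average velocity is the mean of
    displacement/interval over the moving intervals only; with no moving
    interval it is undefined (NaN, flagged) and the percentage is 0.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    disp = track.displacements()
    if disp.size == 0:
        raise ValueError("track needs at least two positions")
    moving = disp > motion_threshold
    pct = 100.0 * float(moving.mean())
    if moving.any():
        vel = float(np.mean(disp[moving]) / frame_interval_min)
        return MotionMetrics(track.track_id, pct, vel, disp.size, True)
    return MotionMetrics(track.track_id, 0.0, float("nan"), disp.size, False)


def tracks_from_truth(truth: pd.DataFrame) -> list[NucleusTrack]:
    """Convert a truth-track table (track_id, frame, x_um, y_um) to tracks."""
    out = []
    for tid, grp in truth.sort_values(["track_id", "frame"]).groupby("track_id"):
        tr = NucleusTrack(track_id=int(tid))
        for _, row in grp.iterrows():
            tr.append(int(row["frame"]), (row["x_um"], row["y_um"]))
        out.append(tr)
    return out
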