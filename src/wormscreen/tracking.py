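"""Track linking and population behavioural endpoints.

Detections are linked frame-to-frame by greedy nearest-neighbour
assignment into per-animal tracks, from which the population endpoints
are computed: the coiler score (percentage of tracked frames with
circularity above the coil threshold, pooled over animals), the
duration-weighted average crawling speed, and fold-of-control
normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import COIL_THRESHOLD, Detection


@dataclass
class Track:
    """One worm's linked detections (at most one per frame)."""

    track_id: int
    detections: list[Detection]
    fps: float

    def __post_init__(self) -> None:
        frames = [d.frame_index for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def duration(self) -> float:
        """Tracked time in seconds: (last - first frame) / fps."""
        if len(self.detections) < 2:
            return 0.0
        return (self.detections[-1].frame_index - self.detections[0].frame_index) / self.fps

    @property
    def path_length(self) -> float:
        """Sum of consecutive centroid-to-centroid distances, px."""
        total = 0.0
        for a, b in zip(self.detections, self.detections[1:]):
            total += math.dist(a.centroid, b.centroid)
        return total

    @property
    def speed(self) -> float:
        """Distance travelled over time tracked, px/s."""
        if self.duration == 0:
            raise ValueError("track too short to define a speed")
        return self.path_length / self.duration


@dataclass
class PopulationResult:
    n_tracks: int
    coiler_score: float  # % of frames
    mean_speed: float  # px/s
    frames_used: int
    frames_dropped: int


@dataclass
class NormalizedScore:
    raw: float
    control_mean: float
    normalized: float = field(init=False)

    def __post_init__(self) -> None:
        self.normalized = self.raw / self.control_mean


def link_tracks(
    detections_per_frame: list[list[Detection]],
    max_disp: float,
    max_gap: int = 2,
    fps: float = 2.0,
) -> list[Track]:
    """Greedy nearest-neighbour linking of detections into tracks.

    Open tracks are matched to the current frame's detections in order of
    increasing distance; matches beyond ``max_disp`` (scaled by the gap
    length in frames) are refused, unmatched detections seed new tracks,
    and a track unmatched for more than ``max_gap`` frames is closed.
    Greedy (rather than optimal) assignment can swap identities during
    close encounters, which leaves the pooled coiler score and weighted
    speed unchanged.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    next_id = 0
    open_tracks: list[dict] = []  # {"track": Track, "last_frame": int}
    finished: list[Track] = []

    for frame_index, dets in enumerate(detections_per_frame):
        # close stale tracks
        still_open = []
        for entry in open_tracks:
            if frame_index - entry["last_frame"] > max_gap + 1:
                finished.append(entry["track"])
            else:
                still_open.append(entry)
        open_tracks = still_open

        unmatched = list(range(len(dets)))
        if open_tracks and unmatched:
            pairs = []
            for ti, entry in enumerate(open_tracks):
                last = entry["track"].detections[-1].centroid
                gap = frame_index - entry["last_frame"]
                for di in unmatched:
                    d = math.dist(last, dets[di].centroid)
                    if d <= max_disp * gap:
                        pairs.append((d, ti, di))
            pairs.sort()
            used_tracks: set[int] = set()
            used_dets: set[int] = set()
            for d, ti, di in pairs:
                if ti in used_tracks or di in used_dets:
                    continue
                open_tracks[ti]["track"].detections.append(dets[di])
                open_tracks[ti]["last_frame"] = frame_index
                used_tracks.add(ti)
                used_dets.add(di)
            unmatched = [di for di in unmatched if di not in used_dets]

        for di in unmatched:
            open_tracks.append(
                {
                    "track": Track(track_id=next_id, detections=[dets[di]], fps=fps),
                    "last_frame": frame_index,
                }
            )
            next_id += 1

    finished.extend(entry["track"] for entry in open_tracks)
    finished.sort(key=lambda t: t.track_id)
    return finished


def coiler_score(
    tracks: list[Track],
    coil_threshold: float = COIL_THRESHOLD,
    per_animal: bool = False,
) -> float:
    """Percentage of tracked frames with circularity above the threshold.

    Frames are pooled across all animals in the population by default;
    ``per_animal=True`` instead averages each track's own percentage.
    """
    if not tracks:
        raise ValueError("no tracks")
    if per_animal:
        percentages = []
        for t in tracks:
            n = len(t.detections)
            if n == 0:
                continue
            coil = sum(d.circularity > coil_threshold for d in t.detections)
            percentages.append(100.0 * coil / n)
        if not percentages:
            raise ValueError("no tracked frames")
        return float(np.mean(percentages))
    total = sum(len(t.detections) for t in tracks)
    if total == 0:
        raise ValueError("no tracked frames")
    coil = sum(
        d.circularity > coil_threshold for t in tracks for d in t.detections
    )
    return 100.0 * coil / total


def average_speed(tracks: list[Track]) -> float:
    """Duration-weighted mean of per-track speeds, px/s.

    Equals total path length / total tracked time.
    """
    usable = [t for t in tracks if t.duration > 0]
    if not usable:
        raise ValueError("no tracks with positive duration")
    total_path = sum(t.path_length for t in usable)
    total_time = sum(t.duration for t in usable)
    return total_path / total_time


def normalize_to_control(
    test_scores: "list[float]", control_scores: "list[float]"
) -> list[NormalizedScore]:
    """Each test score as a fold of the control-group mean."""
    if not control_scores:
        raise ValueError("control scores are empty")
    control_mean = float(np.mean(control_scores))
    if control_mean == 0:
        raise ValueError(
            "control mean is zero; fold-change undefined — report raw scores instead"
        )
    return [NormalizedScore(raw=s, control_mean=control_mean) for s in test_scores]


def population_result(
    tracks: list[Track],
    frames_dropped: int = 0,
    coil_threshold: float = COIL_THRESHOLD,
) -> PopulationResult:
    """Bundle the population endpoints for one recording."""
    frames_used = sum(len(t.detections) for t in tracks)
    return PopulationResult(
        n_tracks=len(tracks),
        coiler_score=coiler_score(tracks, coil_threshold),
        mean_speed=average_speed(tracks),
        frames_used=frames_used,
        frames_dropped=frames_dropped,
    )
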