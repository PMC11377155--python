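"""Frame-to-frame single-cell tracking with live/dead calling.

Cells detected on the analysis start frame receive tentative IDs. Between
consecutive frames, regions are matched one-to-one when centroid distance,
relative area change and relative mean-intensity change all pass the gates;
among admissible pairs the assignment greedily takes ascending cost

    cost = (d / max_displacement)^2 + (|dA| / A_prev)^2 + (|dI| / I_prev)^2

(ties broken by lower previous tentative ID). Tracks whose cells coalesce
into one region are deleted as inaccurate; tracks shorter than 5 frames are
discarded; survivors are renumbered contiguously.

Death is called at the first frame where the area falls to half or less of
the previous frame (inclusive), the mean intensity drops strictly below the
mode's detection threshold, or — survival_v2 only — the node count reaches
0. A cell that simply vanishes from detection before the movie ends is dead
at its first missing frame (a sub-threshold cell produces no detection,
which is how an intensity collapse manifests). A cell alive on the last
frame is right-censored there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import DetectorParams, MatchGates
from .detection import CellBodyRegion
from .errors import ValidationError


@dataclass
class Observation:
    frame_index: int
    region: CellBodyRegion
    ratio: Optional[float] = None
    n_nodes: Optional[int] = None


@dataclass
class Track:
    """One cell's observations from the analysis start frame onward."""

    tentative_id: int
    observations: List[Observation] = field(default_factory=list)
    final_id: Optional[int] = None
    group: Optional[str] = None          # inclusion_positive | inclusion_negative | converter
    death_frame: Optional[int] = None
    censored: bool = False
    n_frames_total: Optional[int] = None  # movie length, for censoring logic

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    @property
    def first_frame(self) -> int:
        return self.observations[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.observations[-1].frame_index

    def areas(self) -> np.ndarray:
        return np.array([o.region.area_px2 for o in self.observations], dtype=float)

    def means(self, channel: str) -> np.ndarray:
        return np.array(
            [o.region.mean_intensity[channel] for o in self.observations], dtype=float
        )

    def centroids(self) -> np.ndarray:
        return np.array(
            [[o.region.y, o.region.x] for o in self.observations], dtype=float
        )


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------

def match_cost(prev: CellBodyRegion, nxt: CellBodyRegion, gates: MatchGates) -> float:
    d = np.hypot(prev.y - nxt.y, prev.x - nxt.x)
    da = abs(nxt.area_px2 - prev.area_px2) / prev.area_px2
    channel = prev.detection_channel
    mp = prev.mean_intensity[channel]
    di = abs(nxt.mean_intensity[channel] - mp) / mp
    return (d / gates.max_displacement_px) ** 2 + da ** 2 + di ** 2


def _admissible(prev: CellBodyRegion, nxt: CellBodyRegion, gates: MatchGates) -> bool:
    if np.hypot(prev.y - nxt.y, prev.x - nxt.x) > gates.max_displacement_px:
        return False
    if abs(nxt.area_px2 - prev.area_px2) / prev.area_px2 > gates.max_area_change_fraction:
        return False
    channel = prev.detection_channel
    mp = prev.mean_intensity[channel]
    if abs(nxt.mean_intensity[channel] - mp) / mp > gates.max_intensity_change_fraction:
        return False
    return True


def match_frames(
    prev: Sequence[CellBodyRegion],
    nxt: Sequence[CellBodyRegion],
    gates: MatchGates,
) -> Tuple[List[Tuple[int, int]], List[int], List[int]]:
    """One-to-one partial matching between consecutive frames.

    Returns ``(pairs, unmatched_prev, unmatched_next)`` where pairs are
    ``(prev_index, next_index)``. Only gate-admissible pairs are considered;
    among them the greedy ascending-cost order (ties to the lower previous
    index) assigns each region at most once.
    """
    candidates = []
    for i, p in enumerate(prev):
        for j, q in enumerate(nxt):
            if _admissible(p, q, gates):
                candidates.append((match_cost(p, q, gates), i, j))
    candidates.sort()
    used_prev: Set[int] = set()
    used_next: Set[int] = set()
    pairs: List[Tuple[int, int]] = []
    for cost, i, j in candidates:
        if i in used_prev or j in used_next:
            continue
        used_prev.add(i)
        used_next.add(j)
        pairs.append((i, j))
    unmatched_prev = [i for i in range(len(prev)) if i not in used_prev]
    unmatched_next = [j for j in range(len(nxt)) if j not in used_next]
    return pairs, unmatched_prev, unmatched_next


def detect_merge(
    prev: Sequence[CellBodyRegion],
    nxt: Sequence[CellBodyRegion],
    gates: MatchGates,
) -> Set[int]:
    """Indices of previous-frame regions whose cells coalesced into one region.

    When two or more previous cells are distance-admissible to exactly one
    and the same next-frame region, their masks have merged and all the
    involved tracks are inaccurate. (Distance is the relevant gate here: a
    merged region fails the area gate by construction.)
    """
    reachable: Dict[int, List[int]] = {}
    for i, p in enumerate(prev):
        within = [
            j for j, q in enumerate(nxt)
            if np.hypot(p.y - q.y, p.x - q.x) <= gates.max_displacement_px
        ]
        reachable[i] = within
    merged: Set[int] = set()
    by_target: Dict[int, List[int]] = {}
    for i, targets in reachable.items():
        if len(targets) == 1:
            by_target.setdefault(targets[0], []).append(i)
    for target, sources in by_target.items():
        if len(sources) >= 2:
            merged.update(sources)
    return merged


# --------------------------------------------------------------------------
# track assembly
# --------------------------------------------------------------------------

def track_cells(
    per_frame_detections: Sequence[Sequence[CellBodyRegion]],
    params: DetectorParams,
    gates: MatchGates = MatchGates(),
    start_frame: int = 0,
) -> List[Track]:
    """Link detections into retained, renumbered tracks.

    Only cells present on the analysis start frame seed tracks; a track ends
    at its first unmatched frame; merged tracks are deleted outright; tracks
    observed for fewer than ``params.min_track_frames`` frames are
    discarded. Survivors get contiguous final IDs 1..K in tentative-ID
    order.
    """
    if not per_frame_detections or all(len(d) == 0 for d in per_frame_detections):
        raise ValidationError("no detections to track")
    n_frames = len(per_frame_detections)
    if n_frames < params.min_track_frames:
        raise ValidationError(
            f"need detections for >= {params.min_track_frames} frames, got {n_frames}"
        )

    tracks: List[Track] = []
    active: List[Track] = []
    for tid, region in enumerate(per_frame_detections[start_frame], start=1):
        obs = Observation(start_frame, region, region.ratio, region.n_nodes)
        t = Track(tentative_id=tid, observations=[obs], n_frames_total=n_frames)
        tracks.append(t)
        active.append(t)
    deleted: Set[int] = set()

    for frame in range(start_frame + 1, n_frames):
        if not active:
            break
        prev_regions = [t.observations[-1].region for t in active]
        next_regions = list(per_frame_detections[frame])
        merged = detect_merge(prev_regions, next_regions, gates)
        for idx in merged:
            deleted.add(active[idx].tentative_id)
        pairs, unmatched_prev, _ = match_frames(prev_regions, next_regions, gates)
        still_active = []
        matched = {i: j for i, j in pairs}
        for idx, track in enumerate(active):
            if track.tentative_id in deleted:
                continue
            j = matched.get(idx)
            if j is None:
                continue  # track ends here (first missing frame)
            region = next_regions[j]
            track.observations.append(
                Observation(frame, region, region.ratio, region.n_nodes)
            )
            still_active.append(track)
        active = still_active

    retained = [
        t for t in tracks
        if t.tentative_id not in deleted and t.n_observations >= params.min_track_frames
    ]
    for k, track in enumerate(sorted(retained, key=lambda t: t.tentative_id), start=1):
        track.final_id = k
    return retained


# --------------------------------------------------------------------------
# death calling
# --------------------------------------------------------------------------

def call_death(
    track: Track,
    params: DetectorParams,
    n_frames: Optional[int] = None,
) -> Tuple[Optional[int], bool]:
    """First death frame of a track, or censoring at the last frame.

    Criteria, checked in frame order (death is absorbing):
    area(t) <= (1 - death_area_drop_fraction) * area(t-1)  [inclusive];
    mean(t) strictly below the mode's detection-channel threshold;
    survival_v2 only: n_nodes(t) == 0. A track whose last observation
    precedes the final movie frame is dead at the first missing frame.
    The result is stored on the track and returned as
    ``(death_frame or None, censored)``.
    """
    if track.n_observations < 2:
        raise ValidationError("call_death requires a track with >= 2 observations")
    if n_frames is None:
        n_frames = track.n_frames_total
    if n_frames is None:
        raise ValidationError("movie length unknown: pass n_frames")

    channel = track.observations[0].region.detection_channel
    threshold = params.death_intensity_threshold(channel)
    keep_fraction = 1.0 - params.death_area_drop_fraction

    death: Optional[int] = None
    prev_area = track.observations[0].region.area_px2
    for k, obs in enumerate(track.observations):
        frame = obs.frame_index
        if params.mode == "survival_v2" and obs.n_nodes is not None and obs.n_nodes == 0:
            death = frame
            break
        if k > 0:
            if obs.region.area_px2 <= keep_fraction * prev_area:
                death = frame
                break
            if obs.region.mean_intensity[channel] < threshold:
                death = frame
                break
        prev_area = obs.region.area_px2

    if death is None and track.last_frame < n_frames - 1:
        death = track.last_frame + 1  # vanished from detection mid-movie

    track.death_frame = death
    track.censored = death is None
    return death, track.censored
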