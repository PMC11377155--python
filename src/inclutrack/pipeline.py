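"""End-to-end survival pipelines and ground-truth evaluation.

``run_survival_analysis`` chains detection, tracking, group assignment and
death calling for one two-channel stack. In the seeded and spontaneous
modes, inclusion-positive neurons are detected and tracked on GFP (a track
is inclusion-positive when its start-frame inclusion/cell ratio exceeds the
mode's gate; the seeded secondary filter drops tracks whose ratio or mean
GFP ever leaves the printed bounds) and inclusion-negative neurons on RFP,
excluding RFP tracks that duplicate an inclusion-positive GFP track. In
survival_v2 all neurons are tracked on RFP with per-frame node counts.

The evaluation helpers compare pipeline output against the simulator's
ground truth: per-frame detection precision/recall, death-call accuracy
(within +/-1 frame, over planted deaths at or after the 5-frame retention
horizon) and the pooled per-frame hazard estimate with its binomial CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import GFP, RFP, DetectorParams, MatchGates
from .detection import (
    CellBodyRegion,
    annotate_regions,
    classify_inclusion_positive,
    detect_cell_bodies,
    detect_neurite_mask,
)
from .errors import ValidationError
from .simulate import GroundTruth
from .stack import FrameStack
from .survival import SurvivalRecord, tracks_to_survival_records
from .tracking import Track, call_death, track_cells


def detect_frames(
    stack: FrameStack,
    channel: str,
    params: DetectorParams,
    with_ratio: bool = False,
    with_nodes: bool = False,
) -> List[List[CellBodyRegion]]:
    """Cell-body detections for every frame, optionally annotated in place."""
    out = []
    for t in range(stack.n_frames):
        regions = detect_cell_bodies(stack, t, channel, params)
        if with_ratio or with_nodes:
            mask = detect_neurite_mask(stack, t, params, channel) if with_nodes else None
            annotate_regions(stack, t, regions, params,
                             neurite_mask=mask)
            if not with_ratio:
                for r in regions:
                    r.ratio = None
        out.append(regions)
    return out


def _passes_secondary(track: Track, params: DetectorParams) -> bool:
    ratios = [o.ratio for o in track.observations if o.ratio is not None]
    means = track.means(GFP)
    if not ratios:
        return True
    return (max(ratios) < params.secondary_ratio_max
            and means.max() < params.secondary_mean_gfp_max)


def run_survival_analysis(
    stack: FrameStack,
    params: DetectorParams,
    gates: MatchGates = MatchGates(),
    frame_interval_h: Optional[float] = None,
) -> Tuple[List[Track], List[SurvivalRecord]]:
    """Full tracking and death calling for one stack; returns tracks + records."""
    if frame_interval_h is None:
        diffs = np.diff(stack.times_h)
        frame_interval_h = float(diffs[0]) if len(diffs) else 6.0

    tracks: List[Track] = []
    if params.mode == "survival_v2":
        detections = detect_frames(stack, RFP, params, with_nodes=True)
        tracks = track_cells(detections, params, gates)
        for track in tracks:
            track.group = "all"
            call_death(track, params)
    else:
        gfp_detections = detect_frames(stack, GFP, params, with_ratio=True)
        gfp_tracks = track_cells(gfp_detections, params, gates)
        positives: List[Track] = []
        for track in gfp_tracks:
            start_ratio = track.observations[0].ratio or 0.0
            if not classify_inclusion_positive(start_ratio, params):
                continue
            if params.mode == "seeded" and not _passes_secondary(track, params):
                continue
            track.group = "inclusion_positive"
            call_death(track, params)
            positives.append(track)

        rfp_detections = detect_frames(stack, RFP, params)
        rfp_tracks = track_cells(rfp_detections, params, gates)
        taken = np.array([[t.observations[0].region.y, t.observations[0].region.x]
                          for t in positives]).reshape(-1, 2)
        negatives: List[Track] = []
        for track in rfp_tracks:
            y, x = track.observations[0].region.y, track.observations[0].region.x
            if len(taken) and np.hypot(taken[:, 0] - y, taken[:, 1] - x).min() <= 5.0:
                continue  # same cell already tracked as inclusion-positive on GFP
            track.group = "inclusion_negative"
            call_death(track, params)
            negatives.append(track)
        tracks = positives + negatives
        for k, track in enumerate(tracks, start=1):
            track.final_id = k

    records = tracks_to_survival_records(tracks, frame_interval_h)
    return tracks, records


# --------------------------------------------------------------------------
# ground-truth evaluation
# --------------------------------------------------------------------------

@dataclass
class DetectionScore:
    precision: float
    recall: float
    n_true: int
    n_detected: int
    n_matched: int


def evaluate_detection(
    per_frame_detections: Sequence[Sequence[CellBodyRegion]],
    gt: GroundTruth,
    match_radius_px: float = 8.0,
) -> DetectionScore:
    """Per-frame centroid matching of detections against rendered cells.

    Recall counts ground-truth cells on frames where they are alive (the
    shrunken death-frame rendering is allowed, not required, to be
    detected); precision counts detections within the match radius of any
    rendered cell, dying ones included.
    """
    n_true = n_det = n_match_recall = n_match_precision = 0
    for t, regions in enumerate(per_frame_detections):
        rows = gt.frames[gt.frames.frame == t]
        rendered = rows[["y", "x"]].to_numpy(dtype=float).reshape(-1, 2)
        alive = rows[rows.alive][["y", "x"]].to_numpy(dtype=float).reshape(-1, 2)
        centroids = np.array([[r.y, r.x] for r in regions]).reshape(-1, 2)
        n_true += len(alive)
        n_det += len(centroids)
        if len(centroids) and len(rendered):
            d = np.hypot(centroids[:, None, 0] - rendered[None, :, 0],
                         centroids[:, None, 1] - rendered[None, :, 1])
            n_match_precision += int((d.min(axis=1) <= match_radius_px).sum())
        if len(centroids) and len(alive):
            d = np.hypot(alive[:, None, 0] - centroids[None, :, 0],
                         alive[:, None, 1] - centroids[None, :, 1])
            n_match_recall += int((d.min(axis=1) <= match_radius_px).sum())
    precision = n_match_precision / n_det if n_det else 1.0
    recall = n_match_recall / n_true if n_true else 1.0
    return DetectionScore(precision=precision, recall=recall,
                          n_true=n_true, n_detected=n_det,
                          n_matched=n_match_recall)


def match_tracks_to_truth(
    tracks: Sequence[Track],
    gt: GroundTruth,
    match_radius_px: float = 8.0,
) -> Dict[int, int]:
    """Map track tentative_id -> ground-truth cell_id via start-frame position."""
    start = gt.frames[gt.frames.frame == gt.frames.frame.min()]
    ids = start.cell_id.to_numpy()
    pos = start[["y", "x"]].to_numpy(dtype=float)
    mapping: Dict[int, int] = {}
    for track in tracks:
        y, x = track.observations[0].region.y, track.observations[0].region.x
        if not len(pos):
            continue
        d = np.hypot(pos[:, 0] - y, pos[:, 1] - x)
        j = int(np.argmin(d))
        if d[j] <= match_radius_px:
            mapping[track.tentative_id] = int(ids[j])
    return mapping


@dataclass
class DeathCallScore:
    fraction_within_1_frame: float
    n_planted_deaths: int
    n_called_within_1: int
    spurious_death_fraction: float
    n_always_alive: int


def evaluate_death_calls(
    tracks: Sequence[Track],
    gt: GroundTruth,
    min_track_frames: int = 5,
    match_radius_px: float = 8.0,
) -> DeathCallScore:
    """Accuracy of called deaths against the planted schedule.

    Planted deaths earlier than ``min_track_frames`` are outside the
    tracker's design horizon (such tracks are discarded by the 5-frame rule)
    and excluded from the denominator.
    """
    mapping = match_tracks_to_truth(tracks, gt, match_radius_px)
    truth = gt.cells.set_index("cell_id")
    n_deaths = n_within = n_alive = n_spurious = 0
    for track in tracks:
        cell_id = mapping.get(track.tentative_id)
        if cell_id is None:
            continue
        true_death = truth.loc[cell_id, "death_frame"]
        if not pd.isna(true_death):
            true_death = int(true_death)
            if true_death < min_track_frames:
                continue
            n_deaths += 1
            if track.death_frame is not None and abs(track.death_frame - true_death) <= 1:
                n_within += 1
        else:
            n_alive += 1
            if track.death_frame is not None:
                n_spurious += 1
    return DeathCallScore(
        fraction_within_1_frame=n_within / n_deaths if n_deaths else 1.0,
        n_planted_deaths=n_deaths,
        n_called_within_1=n_within,
        spurious_death_fraction=n_spurious / n_alive if n_alive else 0.0,
        n_always_alive=n_alive,
    )


@dataclass
class HazardEstimate:
    hazard: float
    ci_low: float
    ci_high: float
    n_deaths: int
    n_exposures: int


def estimate_per_frame_hazard(
    tracks: Sequence[Track],
    truncation_frame: int = 0,
) -> HazardEstimate:
    """Pooled per-frame death hazard from called deaths and at-risk exposures.

    A track dead at frame d contributes its at-risk frame transitions and
    one death; a censored track contributes transitions up to its last
    frame. ``truncation_frame`` removes immortal time: tracks retained under
    the 5-frame rule are by construction death-free before frame
    ``min_track_frames``, so counting those transitions as exposure biases
    the hazard low — pass ``min_track_frames - 1`` to condition on survival
    to that frame. The 95% CI is the exact (Clopper-Pearson) binomial
    interval.
    """
    deaths = exposures = 0
    for track in tracks:
        start = max(track.first_frame, truncation_frame)
        if track.death_frame is not None:
            if track.death_frame <= truncation_frame:
                continue
            deaths += 1
            exposures += track.death_frame - start
        else:
            exposures += max(0, track.last_frame - start)
    if exposures == 0:
        raise ValidationError("no at-risk exposure among tracks")
    low, high = proportion_confint(deaths, exposures, alpha=0.05, method="beta")
    return HazardEstimate(hazard=deaths / exposures, ci_low=float(low),
                          ci_high=float(high), n_deaths=deaths,
                          n_exposures=exposures)
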