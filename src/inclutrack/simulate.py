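"""Synthetic two-channel inclusion-neuron time-lapse with per-cell ground truth.

The generator emulates the live-imaging experiment the trackers were built
for: sparsely RFP-labeled induced neurons imaged every 6 h for 10 days at a
10X objective (0.8 um/px), with diffuse or punctate GFP reporting
alpha-synuclein. Cells are adherent (stationary apart from small Gaussian
jitter), a configurable fraction carries a bright somatic inclusion rendered
``inclusion_intensity_offset`` counts above the soma mean, and death is a
per-frame Bernoulli hazard that depends on inclusion status. A dying cell is
rendered one last time at ``death_area_shrink_factor`` times its previous
area and disappears (falls below every detection threshold) thereafter.

Optional extras: per-field neurite-type inclusion segments that elongate
over time (population-based readout, not assigned to cells), per-cell
neurites rendered into the RFP channel for node counting, and LIPID / P62 /
HOECHST marker channels with planted inclusion-subtype labels and
intact-versus-fragmented nuclei.

Intensities are placed inside the printed detection ranges (soma GFP mean
~80-135 over a background of ~20, RFP ~300-450) so the published thresholds
apply to the rendered images without rescaling; frames are written as 16-bit
TIFF, the common container for 12-bit cameras.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .config import GFP, RFP, LIPID, P62, HOECHST
from .errors import FormatError, PlacementError, ValidationError
from .stack import FrameStack

SUBTYPES = ("TypeI", "TypeIIa", "TypeIIb", "mixed")
# (lipid_positive, p62_positive) for each planted subtype
_SUBTYPE_MARKERS = {
    "TypeI": (True, False),
    "TypeIIa": (False, True),
    "TypeIIb": (False, False),
    "mixed": (True, True),
}
# compass directions (dy, dx) used for neurites and neurite-type inclusions;
# axis-aligned / 45-degree rendering keeps geodesic length equal to the
# Euclidean endpoint distance, so gate semantics are unambiguous
_DIRECTIONS = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)], dtype=float
)
_DIRECTIONS /= np.linalg.norm(_DIRECTIONS, axis=1, keepdims=True)


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment; defaults are the study conditions."""

    frame_width_px: int = 512
    frame_height_px: int = 512
    n_frames: int = 40                  # 10 days at 6 h cadence
    frame_interval_h: float = 6.0
    microns_per_pixel: float = 0.8
    n_cells: int = 50
    inclusion_fraction: float = 0.5
    inclusion_onset_max_frame: int = 0  # onset uniform in [0, this]
    hazard_with_inclusion: float = 0.02
    hazard_without_inclusion: float = 0.005
    soma_diameter_px_range: Tuple[float, float] = (16.0, 24.0)
    soma_gfp_mean_range: Tuple[float, float] = (80.0, 135.0)
    soma_rfp_mean_range: Tuple[float, float] = (300.0, 450.0)
    inclusion_intensity_offset: float = 100.0
    inclusion_area_fraction: float = 0.08
    background_mean: float = 20.0
    noise_sd: float = 3.0
    jitter_sd_px: float = 1.0
    death_area_shrink_factor: float = 0.4
    # population neurite-type inclusion segments (rendered in GFP)
    neurite_inclusion_rate: float = 0.0     # expected new segments per frame
    neurite_inclusion_growth_px_per_frame: float = 2.0
    neurite_seg_len_init_px: Tuple[float, float] = (20.0, 28.0)
    neurite_seg_len_max_px: float = 80.0
    neurite_seg_gfp_range: Tuple[float, float] = (85.0, 120.0)
    # per-cell neurites (rendered in RFP) for node counting / survival_v2
    render_cell_neurites: bool = False
    neurites_per_cell_range: Tuple[int, int] = (2, 4)
    neurite_len_px_range: Tuple[float, float] = (15.0, 25.0)
    neurite_width_px: int = 3
    neurite_rfp_intensity: float = 350.0
    # marker channels (LIPID / P62 / HOECHST) with planted subtype labels
    render_markers: bool = False
    marker_intensity: float = 200.0
    marker_background: float = 10.0
    nucleus_radius_px: float = 6.0
    nucleus_fragment_radius_px: float = 2.0
    subtype_probs: Tuple[float, float, float, float] = (0.125, 0.60, 0.25, 0.025)
    # converter cells: lipid-positive inclusion turns lipid-negative mid-movie
    converter_fraction: float = 0.0
    converter_switch_frame: Optional[int] = None
    min_separation_px: Optional[float] = None  # default: soma diameter max + 30
    bit_depth_max: int = 65535
    seed: int = 0

    def validate(self) -> None:
        c = self
        if c.n_frames < 5:
            raise ValidationError("n_frames must be >= 5 (5-frame tracking rule)")
        if c.frame_width_px < 32 or c.frame_height_px < 32:
            raise ValidationError("frame_width_px/frame_height_px must be >= 32")
        if c.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        for name in ("inclusion_fraction", "hazard_with_inclusion",
                     "hazard_without_inclusion", "converter_fraction"):
            v = getattr(c, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("soma_diameter_px_range", "soma_gfp_mean_range",
                     "soma_rfp_mean_range", "neurite_seg_len_init_px",
                     "neurite_len_px_range", "neurites_per_cell_range",
                     "neurite_seg_gfp_range"):
            lo, hi = getattr(c, name)
            if not (0 <= lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 <= min <= max, got {(lo, hi)}")
        if not 0.0 < c.death_area_shrink_factor < 1.0:
            raise ValidationError("death_area_shrink_factor must be in (0, 1)")
        if not 0.0 < c.inclusion_area_fraction < 1.0:
            raise ValidationError("inclusion_area_fraction must be in (0, 1)")
        for name in ("background_mean", "noise_sd", "inclusion_intensity_offset",
                     "frame_interval_h", "microns_per_pixel"):
            if getattr(c, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        hi_intensity = max(
            c.soma_gfp_mean_range[1] + c.inclusion_intensity_offset,
            c.soma_rfp_mean_range[1], c.marker_intensity, c.neurite_rfp_intensity,
        )
        if hi_intensity > c.bit_depth_max:
            raise ValidationError(
                f"configured intensities exceed bit_depth_max={c.bit_depth_max}"
            )
        if abs(sum(c.subtype_probs) - 1.0) > 1e-9:
            raise ValidationError("subtype_probs must sum to 1")

    @property
    def separation_px(self) -> float:
        if self.min_separation_px is not None:
            return float(self.min_separation_px)
        return self.soma_diameter_px_range[1] + 30.0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        data = json.loads(Path(path).read_text())
        for key, value in list(data.items()):
            if isinstance(value, list):
                data[key] = tuple(value)
        return cls(**data)


@dataclass
class GroundTruth:
    """Per-cell schedule and per-frame geometry of a simulated experiment.

    ``cells``: one row per cell with cell_id, group
    (inclusion_positive / inclusion_negative / converter), soma radius and
    channel means, inclusion_onset_frame / death_frame (nullable),
    lipid_positive / p62_positive / subtype, n_neurites.

    ``frames``: one row per rendered cell-frame with position, the radius and
    exact pixel area actually rendered, inclusion geometry and node count.

    ``neurite_segments``: one row per neurite-type inclusion segment per
    frame (endpoints, Euclidean length, mean GFP, class).
    """

    cells: pd.DataFrame
    frames: pd.DataFrame
    neurite_segments: pd.DataFrame
    n_frames: int
    frame_shape: Tuple[int, int]
    microns_per_pixel: float = 0.8

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: int) -> pd.Series:
        return self.cells.set_index("cell_id").loc[cell_id]

    def frames_of(self, cell_id: int) -> pd.DataFrame:
        return self.frames[self.frames.cell_id == cell_id].sort_values("frame")

    def validate(self) -> None:
        if len(self.cells):
            death = self.cells.death_frame.dropna()
            if len(death) and not ((death >= 1) & (death < self.n_frames)).all():
                raise ValidationError("death_frame must lie within [1, n_frames)")
            onset = self.cells.inclusion_onset_frame.dropna()
            if len(onset) and not ((onset >= 0) & (onset < self.n_frames)).all():
                raise ValidationError("inclusion_onset_frame must lie within [0, n_frames)")
        if len(self.frames):
            if self.frames.frame.min() < 0 or self.frames.frame.max() >= self.n_frames:
                raise ValidationError("frames table has out-of-range frame indices")


def soma_pixels(row: pd.Series, shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of the soma disk rendered for one ground-truth frame row."""
    return draw_disk((row.y, row.x), row.radius_px, shape=shape)


def inclusion_pixels(row: pd.Series, shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of the somatic inclusion disk for one frame row (may be empty)."""
    if not row.has_inclusion or row.incl_radius_px <= 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    return draw_disk((row.incl_y, row.incl_x), row.incl_radius_px, shape=shape)


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _place_cells(rng, config: SimConfig) -> np.ndarray:
    """Rejection-sample (y, x) home positions with a minimum pairwise distance."""
    n = config.n_cells
    margin = config.soma_diameter_px_range[1] / 2 + 3
    if config.render_cell_neurites:
        margin += config.neurite_len_px_range[1] + 2
    lo_y, hi_y = margin, config.frame_height_px - margin
    lo_x, hi_x = margin, config.frame_width_px - margin
    if n and (hi_y <= lo_y or hi_x <= lo_x):
        raise PlacementError("field too small for the configured soma size")
    sep2 = config.separation_px ** 2
    homes: list = []
    attempts = 0
    while len(homes) < n:
        attempts += 1
        if attempts > 2000 * max(n, 1):
            raise PlacementError(
                f"could not place {n} cells with separation {config.separation_px:.0f}px "
                f"in a {config.frame_width_px}x{config.frame_height_px} field"
            )
        cand = np.array([rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x)])
        if all(((cand - h) ** 2).sum() >= sep2 for h in homes):
            homes.append(cand)
    return np.array(homes).reshape(n, 2)


def _sample_cells(rng, config: SimConfig) -> pd.DataFrame:
    n = config.n_cells
    d_lo, d_hi = config.soma_diameter_px_range
    radius = rng.uniform(d_lo, d_hi, n) / 2.0
    gfp = rng.uniform(*config.soma_gfp_mean_range, n)
    rfp = rng.uniform(*config.soma_rfp_mean_range, n)

    n_incl = int(round(config.inclusion_fraction * n))
    order = rng.permutation(n)
    has_inclusion = np.zeros(n, bool)
    has_inclusion[order[:n_incl]] = True
    onset = np.full(n, pd.NA, dtype=object)
    for i in np.flatnonzero(has_inclusion):
        onset[i] = int(rng.integers(0, config.inclusion_onset_max_frame + 1))

    n_conv = int(round(config.converter_fraction * n_incl))
    converter = np.zeros(n, bool)
    converter[order[:n_conv]] = True  # converters are inclusion-positive by construction

    subtype = np.array(
        [rng.choice(SUBTYPES, p=config.subtype_probs) if has_inclusion[i] else "none"
         for i in range(n)], dtype=object)
    # converters must start lipid-positive to have a lipid state to lose
    subtype[converter] = "TypeI"
    lipid = np.array([_SUBTYPE_MARKERS.get(s, (False, False))[0] for s in subtype])
    p62 = np.array([_SUBTYPE_MARKERS.get(s, (False, False))[1] for s in subtype])

    # per-frame Bernoulli death hazard, inclusion-status dependent
    death = np.full(n, pd.NA, dtype=object)
    u = rng.random((n, config.n_frames))
    for i in range(n):
        for t in range(1, config.n_frames):
            incl_now = has_inclusion[i] and t >= onset[i]
            h = config.hazard_with_inclusion if incl_now else config.hazard_without_inclusion
            if u[i, t] < h:
                death[i] = t
                break

    group = np.where(converter, "converter",
                     np.where(has_inclusion, "inclusion_positive", "inclusion_negative"))
    n_neur = (rng.integers(config.neurites_per_cell_range[0],
                           config.neurites_per_cell_range[1] + 1, n)
              if config.render_cell_neurites else np.zeros(n, int))
    return pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "group": group,
        "soma_radius_px": radius,
        "gfp_mean": gfp,
        "rfp_mean": rfp,
        "inclusion_onset_frame": pd.array(onset, dtype="Int64"),
        "death_frame": pd.array(death, dtype="Int64"),
        "subtype": subtype,
        "lipid_positive": lipid,
        "p62_positive": p62,
        "n_neurites": n_neur,
    })


def _thick_line_coords(p0, p1, half_width: int, shape):
    """Pixel coords of a line of width 2*half_width+1 (dilated Bresenham line)."""
    rr0, cc0 = draw_line(int(round(p0[0])), int(round(p0[1])),
                         int(round(p1[0])), int(round(p1[1])))
    rs, cs = [], []
    for dy in range(-half_width, half_width + 1):
        for dx in range(-half_width, half_width + 1):
            rs.append(rr0 + dy)
            cs.append(cc0 + dx)
    rr = np.concatenate(rs)
    cc = np.concatenate(cs)
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    flat = np.unique(rr[keep] * shape[1] + cc[keep])
    return flat // shape[1], flat % shape[1]


def _classify_segment(length_px: float, mean_gfp: float) -> str:
    """Gate logic for neurite-type inclusion classes (mirrors the detector)."""
    if length_px > 30.0 and mean_gfp > 60.0:
        return "long"
    if 20.0 <= length_px <= 30.0 and mean_gfp > 80.0:
        return "short_thick"
    return "rejected"


def simulate_experiment(config: SimConfig) -> Tuple[FrameStack, GroundTruth]:
    """Render the configured experiment; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, W = config.frame_height_px, config.frame_width_px
    shape = (H, W)
    T = config.n_frames

    cells = _sample_cells(rng, config)
    homes = _place_cells(rng, config)
    jitter = rng.normal(0.0, config.jitter_sd_px, size=(T, config.n_cells, 2))
    if config.n_cells:
        jitter[0] = 0.0

    # per-cell fixed inclusion offset direction and neurite directions
    incl_angle = rng.uniform(0, 2 * math.pi, config.n_cells)
    neur_dirs = []
    for i in range(config.n_cells):
        k = int(cells.n_neurites.iloc[i])
        idx = rng.choice(len(_DIRECTIONS), size=k, replace=False) if k else []
        neur_dirs.append(_DIRECTIONS[list(idx)])
    neur_lens = [
        rng.uniform(*config.neurite_len_px_range, size=len(d)) for d in neur_dirs
    ]

    switch_frame = config.converter_switch_frame
    if switch_frame is None:
        switch_frame = T // 2

    channel_names = [GFP, RFP]
    if config.render_markers:
        channel_names += [LIPID, P62, HOECHST]
    arrays = {name: np.zeros((T, H, W), dtype=np.uint16) for name in channel_names}

    frame_rows = []
    seg_rows = []
    segments: list = []  # active neurite-type inclusion segments
    next_seg_id = 1
    sep_guard = config.soma_diameter_px_range[1] / 2 + config.neurite_seg_len_max_px + 6

    for t in range(T):
        planes = {}
        for name in channel_names:
            bg = config.marker_background if name in (LIPID, P62, HOECHST) \
                else config.background_mean
            planes[name] = rng.normal(bg, config.noise_sd, size=shape)

        # ---- neurite-type inclusion segments (population, GFP) ----------
        if config.neurite_inclusion_rate > 0:
            for _ in range(rng.poisson(config.neurite_inclusion_rate)):
                placed = False
                for _attempt in range(50):
                    anchor = np.array([rng.uniform(10, H - 10), rng.uniform(10, W - 10)])
                    direction = _DIRECTIONS[rng.integers(len(_DIRECTIONS))]
                    length = rng.uniform(*config.neurite_seg_len_init_px)
                    end = anchor + direction * config.neurite_seg_len_max_px
                    far_from_somas = config.n_cells == 0 or (
                        np.min(np.linalg.norm(homes - anchor, axis=1)) > sep_guard
                        and np.min(np.linalg.norm(homes - end, axis=1)) > sep_guard
                    )
                    inside = (0 <= end[0] < H) and (0 <= end[1] < W)
                    far_from_segs = all(
                        np.linalg.norm(np.array(s["anchor"]) - anchor) > 2 * config.neurite_seg_len_max_px
                        for s in segments
                    )
                    if far_from_somas and inside and far_from_segs:
                        segments.append({
                            "seg_id": next_seg_id, "anchor": tuple(anchor),
                            "dir": direction, "length": length,
                            "gfp": rng.uniform(*config.neurite_seg_gfp_range),
                        })
                        next_seg_id += 1
                        placed = True
                        break
                if not placed:
                    continue
        for seg in segments:
            p0 = np.array(seg["anchor"])
            p1 = p0 + seg["dir"] * seg["length"]
            rr, cc = draw_line(int(round(p0[0])), int(round(p0[1])),
                               int(round(p1[0])), int(round(p1[1])))
            keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            planes[GFP][rr[keep], cc[keep]] = rng.normal(
                seg["gfp"], config.noise_sd, size=keep.sum())
            length = float(np.linalg.norm(p1 - p0))
            seg_rows.append({
                "frame": t, "seg_id": seg["seg_id"],
                "y0": p0[0], "x0": p0[1], "y1": p1[0], "x1": p1[1],
                "length_px": length, "mean_gfp": seg["gfp"],
                "klass": _classify_segment(length, seg["gfp"]),
            })
            seg["length"] = min(
                seg["length"] + config.neurite_inclusion_growth_px_per_frame,
                config.neurite_seg_len_max_px,
            )

        # ---- cells ------------------------------------------------------
        for i in range(config.n_cells):
            row = cells.iloc[i]
            death = row.death_frame
            dead_now = (death is not pd.NA) and t == death
            gone = (death is not pd.NA) and t > death
            center = homes[i] + jitter[t, i]
            r = float(row.soma_radius_px)
            if dead_now:
                # half-pixel safety margin keeps the discretized disk area at
                # or below shrink_factor times the previous frame's area
                r = max(1.5, r * math.sqrt(config.death_area_shrink_factor) - 0.5)

            onset = row.inclusion_onset_frame
            incl_now = (onset is not pd.NA) and t >= onset and not gone
            alive = not (dead_now or gone)

            # nucleus renders independently of the soma (persists after death)
            if config.render_markers:
                if (death is pd.NA) or t < death:
                    rr, cc = draw_disk(tuple(center), config.nucleus_radius_px, shape=shape)
                    planes[HOECHST][rr, cc] = rng.normal(
                        config.marker_intensity, config.noise_sd, size=len(rr))
                else:  # fragmented nucleus from the death frame onward
                    for dy, dx in ((-4, -3), (3, -2), (1, 4)):
                        rr, cc = draw_disk(
                            (center[0] + dy, center[1] + dx),
                            config.nucleus_fragment_radius_px, shape=shape)
                        planes[HOECHST][rr, cc] = rng.normal(
                            config.marker_intensity, config.noise_sd, size=len(rr))

            if gone:
                continue

            # neurites into RFP while the cell is alive (nodes drop to 0 at death)
            n_nodes = 0
            if config.render_cell_neurites and alive:
                half_w = max(0, (config.neurite_width_px - 1) // 2)
                for direction, nlen in zip(neur_dirs[i], neur_lens[i]):
                    p0 = center + direction * (r + 1)
                    p1 = center + direction * (r + 1 + nlen)
                    rr, cc = _thick_line_coords(p0, p1, half_w, shape)
                    planes[RFP][rr, cc] = rng.normal(
                        config.neurite_rfp_intensity, config.noise_sd, size=len(rr))
                n_nodes = len(neur_dirs[i])

            rr, cc = draw_disk(tuple(center), r, shape=shape)
            planes[GFP][rr, cc] = rng.normal(row.gfp_mean, config.noise_sd, size=len(rr))
            planes[RFP][rr, cc] = rng.normal(row.rfp_mean, config.noise_sd, size=len(rr))
            area = len(rr)

            incl_r = incl_x = incl_y = 0.0
            lipid_on = False
            if incl_now:
                incl_r = r * math.sqrt(config.inclusion_area_fraction)
                offset_d = max(0.0, r - incl_r - 1.5)
                incl_y = center[0] + offset_d * math.sin(incl_angle[i])
                incl_x = center[1] + offset_d * math.cos(incl_angle[i])
                ir, ic = draw_disk((incl_y, incl_x), incl_r, shape=shape)
                planes[GFP][ir, ic] = rng.normal(
                    row.gfp_mean + config.inclusion_intensity_offset,
                    config.noise_sd, size=len(ir))
                if config.render_markers:
                    lipid_on = bool(row.lipid_positive) and not (
                        row.group == "converter" and t >= switch_frame)
                    if lipid_on:
                        planes[LIPID][ir, ic] = rng.normal(
                            config.marker_intensity, config.noise_sd, size=len(ir))
                    if row.p62_positive:
                        planes[P62][ir, ic] = rng.normal(
                            config.marker_intensity, config.noise_sd, size=len(ir))

            frame_rows.append({
                "cell_id": int(row.cell_id), "frame": t,
                "x": center[1], "y": center[0], "radius_px": r, "area_px2": area,
                "alive": alive, "has_inclusion": bool(incl_now),
                "incl_x": incl_x, "incl_y": incl_y, "incl_radius_px": incl_r,
                "n_nodes": int(n_nodes), "lipid_on": lipid_on,
            })

        for name in channel_names:
            arrays[name][t] = np.clip(
                planes[name], 0, config.bit_depth_max).astype(np.uint16)

    frames_df = pd.DataFrame(frame_rows, columns=[
        "cell_id", "frame", "x", "y", "radius_px", "area_px2", "alive",
        "has_inclusion", "incl_x", "incl_y", "incl_radius_px", "n_nodes", "lipid_on",
    ])
    segs_df = pd.DataFrame(seg_rows, columns=[
        "frame", "seg_id", "y0", "x0", "y1", "x1", "length_px", "mean_gfp", "klass",
    ])
    stack = FrameStack(
        channels=arrays,
        times_h=np.arange(T, dtype=float) * config.frame_interval_h,
    )
    gt = GroundTruth(
        cells=cells, frames=frames_df, neurite_segments=segs_df,
        n_frames=T, frame_shape=shape, microns_per_pixel=config.microns_per_pixel,
    )
    gt.validate()
    return stack, gt


# --------------------------------------------------------------------------
# ground-truth round trip
# --------------------------------------------------------------------------

_GT_META = "gt_meta.json"


def write_ground_truth(gt: GroundTruth, path) -> Path:
    """CSV tables (cells / frames / neurite segments) plus a JSON summary."""
    gt.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    gt.cells.to_csv(path / "cells.csv", index=False)
    gt.frames.to_csv(path / "frames.csv", index=False)
    gt.neurite_segments.to_csv(path / "neurite_segments.csv", index=False)
    meta = {
        "n_frames": gt.n_frames,
        "frame_shape": list(gt.frame_shape),
        "microns_per_pixel": gt.microns_per_pixel,
        "n_cells": gt.n_cells,
    }
    (path / _GT_META).write_text(json.dumps(meta, indent=1))
    return path


def read_ground_truth(path) -> GroundTruth:
    path = Path(path)
    meta_path = path / _GT_META
    if not meta_path.exists():
        raise FormatError(f"no {_GT_META} in {path}")
    meta = json.loads(meta_path.read_text())
    try:
        cells = pd.read_csv(
            path / "cells.csv",
            dtype={"inclusion_onset_frame": "Int64", "death_frame": "Int64"},
        )
        frames = pd.read_csv(path / "frames.csv")
        segs = pd.read_csv(path / "neurite_segments.csv")
    except (FileNotFoundError, ValueError) as exc:
        raise FormatError(f"invalid ground-truth directory {path}: {exc}") from exc
    expected = {"cell_id", "group", "soma_radius_px", "gfp_mean", "rfp_mean",
                "inclusion_onset_frame", "death_frame", "subtype",
                "lipid_positive", "p62_positive", "n_neurites"}
    if len(cells.columns) and not expected.issubset(cells.columns):
        raise FormatError(
            f"cells.csv schema mismatch: missing {sorted(expected - set(cells.columns))}"
        )
    gt = GroundTruth(
        cells=cells, frames=frames, neurite_segments=segs,
        n_frames=int(meta["n_frames"]),
        frame_shape=tuple(meta["frame_shape"]),
        microns_per_pixel=float(meta["microns_per_pixel"]),
    )
    gt.validate()
    return gt
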