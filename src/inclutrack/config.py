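"""Detector parameter presets and frame-to-frame matching gates.

Three named parameter sets drive the tracking pipeline:

``seeded``
    PFF-seeded inclusion model. Inclusion-positive neurons are detected and
    tracked on GFP (cell body: mean intensity > 60, bounding-box sides
    6-30 px); inclusion-negative neurons on RFP (> 250, 10-30 px). Somatic
    inclusion pixels are those at or above the cell-body mean + 70 (a
    "flexible" per-cell, per-frame threshold); a cell is inclusion-positive
    when the inclusion/cell-body area ratio exceeds 0.015. A secondary filter
    (ratio < 0.4 and mean GFP < 150) removes rounded dying cells with bright
    GFP that masquerade as inclusion-positive.

``spontaneous``
    Spontaneous inclusion model. GFP cell bodies: > 40, 15-30 px; inclusion
    pixels are an absolute gate (>= 160); positive when ratio > 0.02. RFP
    cell bodies: > 180, 10-40 px.

``survival_v2``
    RFP-based neuron detection with heavier morphological clean-up (5 cycles
    of erosion then dilation on the start frame, 4 thereafter, chosen to
    eliminate thin linear neurite areas from the cell-body mask), an
    intensity threshold of 160, and a node-count death criterion: a cell
    whose number of attached thin linear objects (nodes) reaches 0 is dead.

Boundary semantics are literal throughout: "greater than" / "above" /
"below" / "less than" are strict; "X or higher" and printed <= / >= are
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

from .errors import ValidationError

# Channel names used across the package.
GFP = "GFP"
RFP = "RFP"
LIPID = "LIPID"
P62 = "P62"
HOECHST = "HOECHST"

MODES = ("seeded", "spontaneous", "survival_v2")


@dataclass(frozen=True)
class DetectorParams:
    """Complete gate set for one algorithm variant.

    Fields not used by a mode are ``None``. All pixel gates are in raw pixels
    of the analysis image; intensity gates are in the raw (arbitrary) counts
    of the acquisition, the same units the simulator renders.
    """

    mode: str
    microns_per_pixel: float = 0.8

    # --- cell-body gates, per detection channel ---------------------------
    gfp_intensity_min: Optional[float] = None       # strict >
    gfp_side_px: Optional[Tuple[int, int]] = None   # inclusive bbox sides
    rfp_intensity_min: Optional[float] = None       # strict >
    rfp_side_px: Optional[Tuple[int, int]] = None

    # --- somatic inclusion gates -----------------------------------------
    inclusion_offset_over_cell_mean: Optional[float] = None  # >= mean + offset
    inclusion_abs_intensity_min: Optional[float] = None      # >= absolute
    inclusion_ratio_min: Optional[float] = None              # strict >

    # --- seeded-only secondary filter (both strict) -----------------------
    secondary_ratio_max: Optional[float] = None
    secondary_mean_gfp_max: Optional[float] = None

    # --- neurite-type inclusion gates (seeded) ----------------------------
    neurite_short_len_px: Optional[Tuple[float, float]] = None  # inclusive
    neurite_short_gfp_min: Optional[float] = None               # strict >
    neurite_long_len_px_min: Optional[float] = None             # strict >
    neurite_long_gfp_min: Optional[float] = None                # strict >
    neurite_inclusion_intensity_floor: float = 60.0  # pixel gate for candidate objects

    # --- survival_v2 ------------------------------------------------------
    survival_intensity_threshold: Optional[float] = None  # strict > for detection;
                                                          # death when mean < value

    # --- morphology -------------------------------------------------------
    opening_cycles_first: int = 1   # erosion/dilation cycles on the start frame
    opening_cycles_later: int = 1   # cycles on subsequent frames
    connectivity: int = 2           # 2 = 8-connected components

    # --- neurite mask / node counting ------------------------------------
    neurite_smooth_px: int = 3
    neurite_intensity_threshold: float = 150.0
    neurite_opening_cycles: int = 1
    node_collar_px: int = 3

    # --- shared tracking constants ----------------------------------------
    min_track_frames: int = 5
    death_area_drop_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.microns_per_pixel <= 0:
            raise ValidationError("microns_per_pixel must be positive")
        for name in ("gfp_side_px", "rfp_side_px", "neurite_short_len_px"):
            pair = getattr(self, name)
            if pair is not None and not (0 < pair[0] <= pair[1]):
                raise ValidationError(f"{name} must be an ordered positive pair, got {pair}")
        for name in (
            "gfp_intensity_min", "rfp_intensity_min", "inclusion_offset_over_cell_mean",
            "inclusion_abs_intensity_min", "survival_intensity_threshold",
        ):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if not 0 < self.death_area_drop_fraction <= 1:
            raise ValidationError("death_area_drop_fraction must be in (0, 1]")
        if self.min_track_frames < 2:
            raise ValidationError("min_track_frames must be >= 2")
        if self.opening_cycles_first < 0 or self.opening_cycles_later < 0:
            raise ValidationError("opening cycle counts must be >= 0")

    # ------------------------------------------------------------------ api

    @classmethod
    def seeded(cls, **overrides) -> "DetectorParams":
        """Seeded (PFF) model preset."""
        base = cls(
            mode="seeded",
            gfp_intensity_min=60.0,
            gfp_side_px=(6, 30),
            inclusion_offset_over_cell_mean=70.0,
            inclusion_ratio_min=0.015,
            secondary_ratio_max=0.4,
            secondary_mean_gfp_max=150.0,
            rfp_intensity_min=250.0,
            rfp_side_px=(10, 30),
            neurite_short_len_px=(20.0, 30.0),
            neurite_short_gfp_min=80.0,
            neurite_long_len_px_min=30.0,
            neurite_long_gfp_min=60.0,
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def spontaneous(cls, **overrides) -> "DetectorParams":
        """Spontaneous model preset."""
        base = cls(
            mode="spontaneous",
            gfp_intensity_min=40.0,
            gfp_side_px=(15, 30),
            inclusion_abs_intensity_min=160.0,
            inclusion_ratio_min=0.02,
            rfp_intensity_min=180.0,
            rfp_side_px=(10, 40),
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def survival_v2(cls, **overrides) -> "DetectorParams":
        """RFP-based survival tracker with node-count death criterion."""
        base = cls(
            mode="survival_v2",
            survival_intensity_threshold=160.0,
            opening_cycles_first=5,
            opening_cycles_later=4,
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def from_mode(cls, mode: str, **overrides) -> "DetectorParams":
        try:
            factory = {
                "seeded": cls.seeded,
                "spontaneous": cls.spontaneous,
                "survival_v2": cls.survival_v2,
            }[mode]
        except KeyError:
            raise ValidationError(f"unknown mode {mode!r}") from None
        return factory(**overrides)

    # ---------------------------------------------------------------- gates

    def cellbody_gate(self, channel: str) -> Tuple[float, Optional[Tuple[int, int]]]:
        """Return ``(intensity_min, side_px_bounds)`` for a detection channel.

        ``side_px_bounds`` is ``None`` when the mode applies no bounding-box
        gate on that channel (survival_v2 relies on morphology instead).
        """
        if self.mode == "survival_v2":
            if channel != RFP:
                raise ValidationError("survival_v2 detects on the RFP channel only")
            return float(self.survival_intensity_threshold), None
        if channel == GFP:
            if self.gfp_intensity_min is None:
                raise ValidationError(f"mode {self.mode!r} has no GFP cell-body gate")
            return float(self.gfp_intensity_min), self.gfp_side_px
        if channel == RFP:
            if self.rfp_intensity_min is None:
                raise ValidationError(f"mode {self.mode!r} has no RFP cell-body gate")
            return float(self.rfp_intensity_min), self.rfp_side_px
        raise ValidationError(f"no cell-body gate for channel {channel!r}")

    def death_intensity_threshold(self, channel: str) -> float:
        """Threshold under which a tracked cell's mean intensity means death.

        survival_v2 prints 160; the other variants reuse their detection-gate
        value for the tracked channel (exposed here so it can be overridden).
        """
        if self.mode == "survival_v2":
            return float(self.survival_intensity_threshold)
        return self.cellbody_gate(channel)[0]

    def opening_cycles(self, is_start_frame: bool) -> int:
        return self.opening_cycles_first if is_start_frame else self.opening_cycles_later

    def px_to_um(self, px: float) -> float:
        return px * self.microns_per_pixel

    def um_to_px(self, um: float) -> float:
        return um / self.microns_per_pixel


@dataclass(frozen=True)
class MatchGates:
    """Admissibility gates for frame-to-frame cell matching.

    A previous/next region pair is admissible when the centroid displacement,
    the relative area change and the relative mean-intensity change all stay
    within these bounds. Defaults reject cross-cell jumps on fields where
    cells sit more than two gate radii apart while tolerating the small
    positional jitter of adherent neurons.
    """

    max_displacement_px: float = 15.0
    max_area_change_fraction: float = 0.5
    max_intensity_change_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "max_displacement_px", "max_area_change_fraction", "max_intensity_change_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
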