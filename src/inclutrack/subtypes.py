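"""Inclusion subtype classification and nucleus-integrity scoring.

Inclusions are subtyped by marker co-labeling: Type I is lipid-positive /
p62-negative (membrane- and lipid-rich), Type IIa lipid-negative /
p62-positive, Type IIb lipid-negative / p62-negative; the rare double-
positive combination is labeled ``mixed`` rather than forced into a type.
Marker positivity is operationalized as the fraction of inclusion pixels
above a per-channel intensity threshold reaching ``min_overlap_fraction``
(inclusive, default 0.5).

Nucleus integrity uses the Hoechst area gate: an intact nucleus is a single
component of at least 60 um^2; two or more components each below 60 um^2 are
a fragmented (presumed apoptotic) nucleus; anything else is excluded from
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .detection import CellBodyRegion, InclusionRegion
from .errors import ValidationError
from .stack import FrameStack

MIN_NUCLEUS_AREA_UM2 = 60.0

SUBTYPE_TABLE: Dict[Tuple[bool, bool], str] = {
    (True, False): "TypeI",
    (False, True): "TypeIIa",
    (False, False): "TypeIIb",
    (True, True): "mixed",
}


@dataclass
class SubtypeCall:
    lipid_positive: bool
    p62_positive: bool
    subtype: str
    location: str = "soma"               # soma | neurite
    ubiquitin_positive: Optional[bool] = None
    warning: Optional[str] = None


@dataclass
class NucleusCall:
    state: str                           # intact | fragmented | excluded
    largest_fragment_area_um2: float
    n_components: int


def marker_positivity(
    inclusion: InclusionRegion,
    stack: FrameStack,
    marker_channel: str,
    marker_threshold: float,
    min_overlap_fraction: float = 0.5,
) -> bool:
    """Positive iff the marker-covered fraction of inclusion pixels is >= the cutoff."""
    if inclusion.coords is None or len(inclusion.coords) == 0:
        raise ValidationError("inclusion has no pixel coordinates")
    image = stack.frame(marker_channel, inclusion.frame_index).astype(float)
    rr, cc = inclusion.coords[:, 0], inclusion.coords[:, 1]
    covered = float(np.mean(image[rr, cc] > marker_threshold))
    return covered >= min_overlap_fraction


def classify_location(
    inclusion: InclusionRegion,
    soma_masks: Sequence[np.ndarray],
    neurite_mask: Optional[np.ndarray] = None,
) -> Tuple[str, Optional[str]]:
    """Pixel-majority rule: soma if most inclusion pixels lie in any cell body.

    Returns ``(location, warning)``; an inclusion overlapping neither mask is
    called neurite with a warning flag.
    """
    if inclusion.coords is None or len(inclusion.coords) == 0:
        raise ValidationError("inclusion has no pixel coordinates")
    rr, cc = inclusion.coords[:, 0], inclusion.coords[:, 1]
    n = len(rr)
    in_soma = np.zeros(n, dtype=bool)
    for mask in soma_masks:
        in_soma |= mask[rr, cc]
    if in_soma.sum() * 2 > n:
        return "soma", None
    in_neurite = neurite_mask[rr, cc].any() if neurite_mask is not None else False
    if not in_neurite and not in_soma.any():
        return "neurite", "overlaps no mask"
    return "neurite", None


def classify_subtype(lipid_positive: bool, p62_positive: bool) -> str:
    return SUBTYPE_TABLE[(bool(lipid_positive), bool(p62_positive))]


def call_subtype(
    inclusion: InclusionRegion,
    stack: FrameStack,
    lipid_channel: str = "LIPID",
    p62_channel: str = "P62",
    marker_threshold: float = 100.0,
    min_overlap_fraction: float = 0.5,
    soma_masks: Optional[Sequence[np.ndarray]] = None,
) -> SubtypeCall:
    """Full marker call for one inclusion (convenience wrapper)."""
    lipid = marker_positivity(
        inclusion, stack, lipid_channel, marker_threshold, min_overlap_fraction)
    p62 = marker_positivity(
        inclusion, stack, p62_channel, marker_threshold, min_overlap_fraction)
    location, warning = ("soma", None)
    if soma_masks is not None:
        location, warning = classify_location(inclusion, soma_masks)
    return SubtypeCall(
        lipid_positive=lipid, p62_positive=p62,
        subtype=classify_subtype(lipid, p62),
        location=location, warning=warning,
    )


def classify_nucleus(
    component_areas_px2: Sequence[float],
    microns_per_pixel: float,
) -> NucleusCall:
    """Intact / fragmented / excluded call from Hoechst component areas.

    Intact: exactly one component at or above 60 um^2. Fragmented: two or
    more components, each below 60 um^2. Everything else (no signal, a
    single sub-gate speck, or mixtures) is excluded.
    """
    areas_um2 = np.asarray(component_areas_px2, dtype=float) * microns_per_pixel ** 2
    n = len(areas_um2)
    largest = float(areas_um2.max()) if n else 0.0
    big = areas_um2 >= MIN_NUCLEUS_AREA_UM2
    if n == 1 and big[0]:
        state = "intact"
    elif n >= 2 and not big.any():
        state = "fragmented"
    else:
        state = "excluded"
    return NucleusCall(state=state, largest_fragment_area_um2=largest, n_components=n)


def nucleus_components_near(
    hoechst_mask: np.ndarray,
    center_yx: Tuple[float, float],
    radius_px: float,
    connectivity: int = 2,
) -> list:
    """Areas (px^2) of Hoechst components whose centroid lies within a disk
    around a soma centroid — the operational cell-to-nucleus association."""
    from skimage.measure import label as sk_label, regionprops

    labels = sk_label(hoechst_mask, connectivity=connectivity)
    areas = []
    for prop in regionprops(labels):
        dy = prop.centroid[0] - center_yx[0]
        dx = prop.centroid[1] - center_yx[1]
        if np.hypot(dy, dx) <= radius_px:
            areas.append(int(prop.area))
    return areas


def crosstab_marker_vs_viability(
    marker_positive: Sequence[bool],
    nucleus_states: Sequence[str],
    exact_test: bool = False,
):
    """2x2 counts of {marker+, marker-} x {intact, fragmented} with row proportions.

    Cells whose nucleus call is ``excluded`` are dropped. Returns
    ``(table, proportions)`` or ``(table, proportions, p_value)`` when
    ``exact_test`` is requested (Fisher).
    """
    if len(marker_positive) != len(nucleus_states):
        raise ValidationError("marker and nucleus sequences differ in length")
    rows = [
        (bool(m), s) for m, s in zip(marker_positive, nucleus_states)
        if s in ("intact", "fragmented")
    ]
    if not rows:
        raise ValidationError("no cells with both a marker call and a scored nucleus")
    table = pd.DataFrame(
        0, index=["marker_pos", "marker_neg"], columns=["intact", "fragmented"]
    )
    for m, s in rows:
        table.loc["marker_pos" if m else "marker_neg", s] += 1
    totals = table.sum(axis=1)
    proportions = table.div(totals.replace(0, np.nan), axis=0)
    if exact_test:
        _, p = fisher_exact(table.values)
        return table, proportions, float(p)
    return table, proportions
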