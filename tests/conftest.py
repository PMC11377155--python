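"""Shared fixtures: small simulated movies and hand-built frame images."""

import numpy as np
import pytest

from inclutrack import (
    GFP,
    RFP,
    DetectorParams,
    FrameStack,
    SimConfig,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def seeded_params():
    return DetectorParams.seeded()


@pytest.fixture(scope="session")
def spontaneous_params():
    return DetectorParams.spontaneous()


@pytest.fixture(scope="session")
def v2_params():
    return DetectorParams.survival_v2()


@pytest.fixture(scope="session")
def small_movie():
    """20 cells, 20 frames, default intensities; moderate hazard."""
    config = SimConfig(n_cells=20, n_frames=20, seed=11)
    stack, gt = simulate_experiment(config)
    return config, stack, gt


@pytest.fixture(scope="session")
def neurite_movie():
    """Cells with rendered neurites for node counting (survival_v2 regime)."""
    config = SimConfig(
        n_cells=10, n_frames=12, seed=23, render_cell_neurites=True,
        inclusion_fraction=0.0, hazard_without_inclusion=0.02,
    )
    stack, gt = simulate_experiment(config)
    return config, stack, gt


@pytest.fixture(scope="session")
def marker_movie():
    """All-inclusion movie with LIPID / P62 / HOECHST channels rendered."""
    config = SimConfig(
        n_cells=16, n_frames=8, seed=31, inclusion_fraction=1.0,
        render_markers=True, hazard_with_inclusion=0.0,
    )
    stack, gt = simulate_experiment(config)
    return config, stack, gt


def make_frame_stack(gfp=None, rfp=None, n_frames=1, shape=(64, 64),
                     background=20.0, interval_h=6.0):
    """Stack from explicit 2D frames (repeated if a single frame is given)."""
    def expand(frames):
        if frames is None:
            return np.full((n_frames, *shape), background, dtype=float)
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = np.repeat(frames[None], n_frames, axis=0)
        return frames

    channels = {GFP: expand(gfp), RFP: expand(rfp)}
    nf = channels[GFP].shape[0]
    return FrameStack(channels=channels,
                      times_h=np.arange(nf, dtype=float) * interval_h)


def paint_soma(frame, center, half_side, value):
    """Square soma of side 2*half_side+1 centered at (row, col)."""
    r, c = center
    frame[r - half_side:r + half_side + 1, c - half_side:c + half_side + 1] = value
    return frame
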