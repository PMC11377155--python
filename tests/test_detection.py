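"""Detection gates, boundary semantics and morphology against pixel oracles."""

import numpy as np
import pytest

from inclutrack import (
    GFP,
    RFP,
    DetectorParams,
    ModeError,
    ValidationError,
    binarize_and_open,
    classify_inclusion_positive,
    count_nodes,
    detect_cell_bodies,
    detect_neurite_inclusions,
    detect_neurite_mask,
    detect_soma_inclusions,
    secondary_filter,
    skeleton_geodesic_length,
)
from inclutrack.detection import CellBodyRegion

from conftest import make_frame_stack, paint_soma


# --------------------------------------------------------------------------
# independent pixel-level morphology oracle (shift-based, no library calls)
# --------------------------------------------------------------------------

def _shift_erode(mask):
    out = mask.copy()
    padded = np.pad(mask, 1, constant_values=False)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            out &= padded[1 + dy:1 + dy + mask.shape[0], 1 + dx:1 + dx + mask.shape[1]]
    return out


def _shift_dilate(mask):
    out = np.zeros_like(mask)
    padded = np.pad(mask, 1, constant_values=False)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            out |= padded[1 + dy:1 + dy + mask.shape[0], 1 + dx:1 + dx + mask.shape[1]]
    return out


def _oracle_open(image, threshold, n_cycles):
    mask = image > threshold
    for _ in range(n_cycles):
        mask = _shift_erode(mask)
    for _ in range(n_cycles):
        mask = _shift_dilate(mask)
    return mask & (image > threshold)


class TestBinarizeAndOpen:
    def test_all_below_threshold_gives_empty_mask(self):
        assert not binarize_and_open(np.full((32, 32), 10.0), 50.0, 3).any()

    def test_zero_cycles_is_plain_threshold(self):
        rng = np.random.default_rng(0)
        image = rng.uniform(0, 100, (32, 32))
        np.testing.assert_array_equal(
            binarize_and_open(image, 50.0, 0), image > 50.0)

    def test_line_removed_disk_retained_one_cycle(self):
        """A 2-px-wide line vanishes under one opening cycle; a disk survives."""
        image = np.zeros((64, 64))
        image[10:12, 5:60] = 100.0                     # 2-px-wide line
        yy, xx = np.mgrid[:64, :64]
        disk = (yy - 40) ** 2 + (xx - 32) ** 2 <= 10 ** 2
        image[disk] = 100.0
        result = binarize_and_open(image, 50.0, 1)
        oracle = _oracle_open(image, 50.0, 1)
        np.testing.assert_array_equal(result, oracle)
        assert not result[10:12, 5:60].any()
        assert result[disk].sum() > 0.8 * disk.sum()

    @pytest.mark.parametrize("cycles", [1, 2, 4, 5])
    def test_matches_pixel_oracle_on_random_images(self, cycles):
        rng = np.random.default_rng(cycles)
        for _ in range(5):
            image = rng.uniform(0, 100, (48, 48))
            # add structure so masks are not pure salt
            image[10:30, 10:30] += 40
            result = binarize_and_open(image, 60.0, cycles)
            oracle = _oracle_open(image, 60.0, cycles)
            np.testing.assert_array_equal(result, oracle)
            assert not (result & ~(image > 60.0)).any()  # subset of threshold

    def test_opening_pass_is_idempotent_on_opened_masks(self):
        rng = np.random.default_rng(3)
        image = rng.uniform(0, 100, (48, 48))
        image[5:40, 5:40] += 30
        once = binarize_and_open(image, 55.0, 2)
        again = binarize_and_open(once.astype(float) * 100, 50.0, 2)
        np.testing.assert_array_equal(once, again)

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValidationError, match="2D"):
            binarize_and_open(np.zeros((4, 4, 4)), 1.0, 1)


# --------------------------------------------------------------------------
# cell-body gates
# --------------------------------------------------------------------------

def _one_soma_stack(half_side, value, channel=GFP, shape=(64, 64)):
    frame = np.full(shape, 20.0)
    paint_soma(frame, (32, 32), half_side, value)
    if channel == GFP:
        return make_frame_stack(gfp=frame, rfp=None, shape=shape)
    return make_frame_stack(gfp=None, rfp=frame, shape=shape)


class TestCellBodyGates:
    def test_in_gate_soma_detected_seeded(self, seeded_params):
        stack = _one_soma_stack(half_side=9, value=100.0)  # 19x19 bbox
        regions = detect_cell_bodies(stack, 0, GFP, seeded_params)
        assert len(regions) == 1
        assert regions[0].area_px2 >= 300

    def test_oversized_bbox_rejected(self, seeded_params):
        frame = np.full((64, 64), 20.0)
        frame[10:45, 20:40] = 100.0  # 35 x 20 bbox fails the 30 px max
        stack = make_frame_stack(gfp=frame)
        assert detect_cell_bodies(stack, 0, GFP, seeded_params) == []

    def test_gfp_gate_differs_between_modes(self, seeded_params, spontaneous_params):
        stack = _one_soma_stack(half_side=9, value=50.0)  # mean 50: 40 < 50 < 60
        assert detect_cell_bodies(stack, 0, GFP, seeded_params) == []
        assert len(detect_cell_bodies(stack, 0, GFP, spontaneous_params)) == 1

    def test_intensity_gate_is_strict(self, seeded_params):
        stack = _one_soma_stack(half_side=9, value=60.0)
        assert detect_cell_bodies(stack, 0, GFP, seeded_params) == []
        stack = _one_soma_stack(half_side=9, value=60.5)
        assert len(detect_cell_bodies(stack, 0, GFP, seeded_params)) == 1

    def test_rfp_gate_values(self, seeded_params, spontaneous_params):
        stack = _one_soma_stack(half_side=7, value=200.0, channel=RFP)
        assert detect_cell_bodies(stack, 0, RFP, seeded_params) == []     # needs >250
        assert len(detect_cell_bodies(stack, 0, RFP, spontaneous_params)) == 1  # >180

    def test_spontaneous_min_side_is_15(self, spontaneous_params):
        stack = _one_soma_stack(half_side=6, value=100.0)  # 13x13 bbox
        assert detect_cell_bodies(stack, 0, GFP, spontaneous_params) == []
        stack = _one_soma_stack(half_side=7, value=100.0)  # 15x15 bbox
        assert len(detect_cell_bodies(stack, 0, GFP, spontaneous_params)) == 1

    def test_gate_soundness_remeasured(self, small_movie, seeded_params):
        """Every returned region satisfies its gates when re-measured."""
        _, stack, _ = small_movie
        gate, sides = seeded_params.cellbody_gate(GFP)
        for t in (0, 5):
            for region in detect_cell_bodies(stack, t, GFP, seeded_params):
                image = stack.frame(GFP, t).astype(float)
                rr, cc = region.pixel_coords()
                assert image[rr, cc].mean() > gate
                assert sides[0] <= region.bbox_width_px <= sides[1]
                assert sides[0] <= region.bbox_length_px <= sides[1]

    def test_unknown_channel_and_frame_errors(self, small_movie, seeded_params):
        _, stack, _ = small_movie
        with pytest.raises(ValidationError):
            detect_cell_bodies(stack, 0, "LIPID", seeded_params)
        with pytest.raises(ValidationError):
            detect_cell_bodies(stack, stack.n_frames, GFP, seeded_params)


# --------------------------------------------------------------------------
# somatic inclusions
# --------------------------------------------------------------------------

def _soma_with_blob(soma_value, blob_value, blob_px=18, half_side=9):
    frame = np.full((64, 64), 20.0)
    paint_soma(frame, (32, 32), half_side, soma_value)
    rows, cols = np.divmod(np.arange(blob_px), 6)
    frame[26 + rows, 26 + cols] = blob_value
    return make_frame_stack(gfp=frame)


class TestSomaInclusions:
    def test_uniform_soma_has_no_inclusion(self, seeded_params):
        stack = _one_soma_stack(half_side=9, value=100.0)
        cell = detect_cell_bodies(stack, 0, GFP, seeded_params)[0]
        inclusions, ratio = detect_soma_inclusions(stack, 0, cell, seeded_params)
        assert inclusions == [] and ratio == 0.0

    def test_ratio_matches_pixel_count_oracle(self, seeded_params):
        """A planted blob is returned and the ratio equals the exact pixel count."""
        stack = _soma_with_blob(100.0, 250.0, blob_px=18)
        cell = detect_cell_bodies(stack, 0, GFP, seeded_params)[0]
        inclusions, ratio = detect_soma_inclusions(stack, 0, cell, seeded_params)
        image = stack.frame(GFP, 0)
        rr, cc = cell.pixel_coords()
        mean = image[rr, cc].mean()
        oracle = int((image[rr, cc] >= mean + 70.0).sum())
        assert sum(i.area_px2 for i in inclusions) == oracle == 18
        assert ratio == pytest.approx(oracle / cell.area_px2)

    def test_flexible_threshold_tracks_the_cell_mean(self, seeded_params):
        """Raising the soma mean hides a blob that a dimmer soma reveals."""
        bright = _soma_with_blob(160.0, 220.0)
        cell = detect_cell_bodies(bright, 0, GFP,
                                  DetectorParams.seeded(secondary_mean_gfp_max=1e9))[0]
        _, ratio_bright = detect_soma_inclusions(bright, 0, cell, seeded_params)
        dim = _soma_with_blob(100.0, 220.0)
        cell = detect_cell_bodies(dim, 0, GFP, seeded_params)[0]
        _, ratio_dim = detect_soma_inclusions(dim, 0, cell, seeded_params)
        assert ratio_bright == 0.0 and ratio_dim > 0.0

    def test_spontaneous_gate_is_absolute_and_inclusive(self, spontaneous_params):
        stack = _soma_with_blob(100.0, 150.0, half_side=9)
        cell = detect_cell_bodies(stack, 0, GFP, spontaneous_params)[0]
        _, ratio = detect_soma_inclusions(stack, 0, cell, spontaneous_params)
        assert ratio == 0.0  # 150 < 160
        stack = _soma_with_blob(100.0, 160.0, half_side=9)
        cell = detect_cell_bodies(stack, 0, GFP, spontaneous_params)[0]
        inclusions, ratio = detect_soma_inclusions(stack, 0, cell, spontaneous_params)
        assert ratio > 0.0 and len(inclusions) >= 1  # 160 >= 160


class TestPositivityAndSecondaryFilter:
    @pytest.mark.parametrize("ratio, mode, expected", [
        (0.02, "seeded", True),
        (0.015, "seeded", False),        # "above 0.015" is strict
        (0.02, "spontaneous", False),    # "above 0.02" is strict
        (0.021, "spontaneous", True),
    ])
    def test_ratio_gate_boundaries(self, ratio, mode, expected):
        params = DetectorParams.from_mode(mode)
        assert classify_inclusion_positive(ratio, params) is expected

    def _cell(self, mean_gfp):
        return CellBodyRegion(
            region_id=1, frame_index=0, bbox=(0, 0, 10, 10),
            mask=np.ones((10, 10), bool), centroid=(5.0, 5.0), area_px2=100,
            bbox_length_px=10, bbox_width_px=10,
            mean_intensity={GFP: mean_gfp}, detection_channel=GFP,
        )

    @pytest.mark.parametrize("ratio, mean_gfp, keep", [
        (0.3, 140.0, True),
        (0.45, 100.0, False),   # ratio gate fails
        (0.1, 150.0, False),    # "below 150" is strict
        (0.4, 100.0, False),    # "less than 0.4" is strict
    ])
    def test_secondary_filter_boundaries(self, seeded_params, ratio, mean_gfp, keep):
        assert secondary_filter(self._cell(mean_gfp), ratio, seeded_params) is keep

    def test_secondary_filter_rejects_non_seeded_mode(self, spontaneous_params):
        with pytest.raises(ModeError):
            secondary_filter(self._cell(100.0), 0.1, spontaneous_params)


# --------------------------------------------------------------------------
# neurite-type inclusions
# --------------------------------------------------------------------------

def _line_stack(length_px, value, width=1):
    frame = np.full((96, 96), 20.0)
    frame[40:40 + width, 10:10 + length_px + 1] = value
    return make_frame_stack(gfp=frame, shape=(96, 96))


class TestNeuriteInclusions:
    @pytest.mark.parametrize("length, value, expected_class", [
        (25, 85.0, "short_thick"),
        (35, 65.0, "long"),
        (25, 70.0, None),     # fails short gate (80) and long length (>30)
        (35, 55.0, None),     # long length but fails the 60 gate
    ])
    def test_length_and_intensity_gates(self, seeded_params, length, value,
                                        expected_class):
        stack = _line_stack(length, value)
        empty_mask = np.zeros((96, 96), bool)
        objects, total = detect_neurite_inclusions(stack, 0, empty_mask, seeded_params)
        if expected_class is None:
            assert objects == [] and total == 0.0
        else:
            assert len(objects) == 1
            assert objects[0].neurite_class == expected_class
            assert objects[0].length_px == pytest.approx(length, abs=1.0)
            assert total == pytest.approx(length, abs=1.0)

    def test_objects_overlapping_cell_bodies_excluded(self, seeded_params):
        stack = _line_stack(35, 90.0)
        mask = np.zeros((96, 96), bool)
        mask[38:43, 20:30] = True  # covers part of the line
        objects, _ = detect_neurite_inclusions(stack, 0, mask, seeded_params)
        assert objects == []

    def test_skeleton_length_of_straight_lines(self):
        mask = np.zeros((40, 40), bool)
        mask[5, 5:36] = True  # 31 pixels -> geodesic 30
        assert skeleton_geodesic_length(mask) == pytest.approx(30.0)
        diag = np.eye(21, dtype=bool)
        assert skeleton_geodesic_length(diag) == pytest.approx(20 * np.sqrt(2))
        single = np.zeros((5, 5), bool)
        single[2, 2] = True
        assert skeleton_geodesic_length(single) == 0.0


# --------------------------------------------------------------------------
# neurite mask and node counting
# --------------------------------------------------------------------------

class TestNeuriteMaskAndNodes:
    def test_blank_frame_gives_empty_mask(self, v2_params):
        stack = make_frame_stack(rfp=np.full((64, 64), 20.0))
        assert not detect_neurite_mask(stack, 0, v2_params).any()

    def test_mask_covers_rendered_polyline(self, neurite_movie, v2_params):
        _, stack, gt = neurite_movie
        mask = detect_neurite_mask(stack, 0, v2_params)
        # reconstruct union of soma disks; neurite pixels = mask minus somata
        from inclutrack.simulate import soma_pixels
        soma = np.zeros(stack.frame_shape, bool)
        for _, row in gt.frames[gt.frames.frame == 0].iterrows():
            rr, cc = soma_pixels(row, stack.frame_shape)
            soma[rr, cc] = True
        assert (mask & ~soma).sum() > 0

    def test_determinism(self, neurite_movie, v2_params):
        _, stack, _ = neurite_movie
        m1 = detect_neurite_mask(stack, 0, v2_params)
        m2 = detect_neurite_mask(stack, 0, v2_params)
        np.testing.assert_array_equal(m1, m2)

    def test_node_counts_match_ground_truth(self, neurite_movie, v2_params):
        _, stack, gt = neurite_movie
        regions = detect_cell_bodies(stack, 0, RFP, v2_params)
        mask = detect_neurite_mask(stack, 0, v2_params)
        truth = gt.cells.set_index("cell_id")
        f0 = gt.frames[gt.frames.frame == 0]
        matched = 0
        for region in regions:
            d = np.hypot(f0.y - region.y, f0.x - region.x)
            row = f0.iloc[int(np.argmin(d))]
            expected = int(truth.loc[row.cell_id, "n_neurites"])
            assert count_nodes(region, mask, v2_params.node_collar_px) == expected
            matched += 1
        assert matched >= 8

    def test_soma_without_neurites_has_zero_nodes(self, v2_params):
        frame = np.full((64, 64), 20.0)
        paint_soma(frame, (32, 32), 9, 300.0)
        stack = make_frame_stack(rfp=frame)
        region = detect_cell_bodies(stack, 0, RFP, v2_params)[0]
        mask = detect_neurite_mask(stack, 0, v2_params)
        assert count_nodes(region, mask, v2_params.node_collar_px) == 0

    def test_detached_component_contributes_nothing(self, v2_params):
        frame = np.full((96, 96), 20.0)
        paint_soma(frame, (30, 30), 9, 300.0)
        frame[80:83, 10:60] = 300.0  # far-away linear object
        stack = make_frame_stack(rfp=frame, shape=(96, 96))
        region = detect_cell_bodies(stack, 0, RFP, v2_params)[0]
        mask = detect_neurite_mask(stack, 0, v2_params)
        assert count_nodes(region, mask, v2_params.node_collar_px) == 0
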