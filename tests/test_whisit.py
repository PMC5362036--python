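"""Compartment masks, intensity ratio, classification, time-lapse episodes."""

import numpy as np
import pytest

from memloc import (CellGeometry, CompartmentParams, MemlocError, classify,
                    cytosol_interior, dispersal_episodes, mean_intensity,
                    measure_cell, measure_timeseries, membrane_ring,
                    outline_of, split_compartments)
from memloc.simcell import _render_cell, apply_optics
from conftest import chebyshev_ring_oracle, random_mask


def square_mask(n, size=20):
    m = np.zeros((size, size), dtype=bool)
    m[4:4 + n, 4:4 + n] = True
    return m


class TestMembraneRing:
    def test_12x12_square_ring_and_interior_counts(self):
        mask = square_mask(12)
        ring = membrane_ring(mask, 4)
        oracle = chebyshev_ring_oracle(mask, 4)
        np.testing.assert_array_equal(ring, oracle)
        assert ring.sum() == 128      # 144 minus the surviving 4x4 interior
        assert cytosol_interior(mask, ring).sum() == 16

    def test_zero_width_ring_is_empty(self):
        assert membrane_ring(square_mask(12), 0).sum() == 0

    def test_ring_swallows_thin_cell(self):
        mask = square_mask(5)
        ring = membrane_ring(mask, 4)
        assert (ring == mask).all()
        with pytest.raises(MemlocError) as exc:
            cytosol_interior(mask, ring)
        assert exc.value.code == "cell_too_thin"

    def test_empty_ring_leaves_interior_equal_to_mask(self):
        mask = square_mask(8)
        interior = cytosol_interior(mask, np.zeros_like(mask))
        np.testing.assert_array_equal(interior, mask)

    @pytest.mark.parametrize("width", [1, 2, 4])
    def test_erosion_equals_bruteforce_chebyshev_on_random_masks(self, width):
        rng = np.random.default_rng(width)
        for _ in range(67):  # ~200 masks across the three widths
            mask = random_mask(rng)
            if not mask.any():
                continue
            np.testing.assert_array_equal(
                membrane_ring(mask, width),
                chebyshev_ring_oracle(mask, width))

    def test_partition_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = random_mask(rng)
            if not mask.any():
                continue
            ring = membrane_ring(mask, 4)
            interior = mask & ~ring
            assert not (ring & interior).any()
            np.testing.assert_array_equal(ring | interior, mask)


class TestMeanIntensity:
    def test_uniform_value(self):
        img = np.full((6, 6), 5.0)
        assert mean_intensity(img, square_mask(3, 6)) == 5.0

    def test_arithmetic_mean(self):
        img = np.zeros((3, 3))
        img[0, :3] = [2, 4, 6]
        mask = np.zeros((3, 3), bool)
        mask[0, :3] = True
        assert mean_intensity(img, mask) == 4.0

    def test_constant_background_subtracted(self):
        params = CompartmentParams(background_mode="constant",
                                   background_value=3.0)
        img = np.full((6, 6), 5.0)
        assert mean_intensity(img, square_mask(3, 6), params) == 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(MemlocError) as exc:
            mean_intensity(np.ones((4, 4)), np.zeros((4, 4), bool))
        assert exc.value.code == "empty_compartment"


class TestClassify:
    @pytest.mark.parametrize("ratio,expected", [
        (0.70, "cytosolic"),   # boundary value is cytosolic
        (0.71, "membrane"),
        (0.0, "cytosolic"),
        (1.0, "membrane"),
    ])
    def test_threshold_convention(self, ratio, expected):
        assert classify(ratio, 0.7) == expected


def render_cell_image(mode="cytosolic", membrane_fraction=None, noise=False,
                      seed=0, psf=2.0, background=100.0):
    geom = CellGeometry("c", (40.0, 40.0), 45.0, 15.0, 0.3, mode,
                        membrane_fraction if membrane_fraction is not None
                        else (1.0 if mode == "membrane" else 0.0))
    if mode == "mixed":
        geom = CellGeometry("c", (40.0, 40.0), 45.0, 15.0, 0.3, "mixed",
                            membrane_fraction)
    canvas = np.zeros((80, 80))
    _render_cell(geom, 1000.0, 1.5, canvas)
    img = apply_optics(canvas, psf, background, poisson=noise,
                       read_sd=20.0 if noise else 0.0, seed=seed)
    return img, outline_of(geom)


class TestMeasureCell:
    def test_uniform_image_ratio_is_one_and_membrane_class(self):
        outline = outline_of(CellGeometry("u", (20, 20), 30, 15, 0.0))
        m = measure_cell(np.full((40, 40), 9.0), outline,
                         CompartmentParams())
        assert m.ratio == 1.0
        assert m.label == "membrane"  # 1.0 > 0.7

    def test_noiseless_membrane_cell_ratio_above_one(self, default_params):
        img, outline = render_cell_image("membrane")
        m = measure_cell(img, outline, default_params, 0.066)
        assert m.ratio > 1.0
        assert m.label == "membrane"

    def test_noiseless_cytosolic_cell_ratio_below_threshold(self,
                                                            default_params):
        img, outline = render_cell_image("cytosolic")
        m = measure_cell(img, outline, default_params, 0.066)
        assert m.ratio < 0.7
        assert m.label == "cytosolic"

    def test_ratio_scale_invariant(self):
        img, outline = render_cell_image(background=0.0)
        params = CompartmentParams()  # background none
        base = measure_cell(img, outline, params).ratio
        for c in (0.25, 3.0, 117.0):
            scaled = measure_cell(img * c, outline, params).ratio
            assert abs(scaled - base) < 1e-9

    def test_ratio_strictly_increasing_in_membrane_fraction(self,
                                                            default_params):
        ratios = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            img, outline = render_cell_image("mixed", membrane_fraction=f)
            ratios.append(measure_cell(img, outline, default_params).ratio)
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_border_cell_flagged(self, default_params):
        geom = CellGeometry("b", (22.4, 40.0), 45.0, 15.0, 0.0)
        outline = outline_of(geom)
        m = measure_cell(np.full((80, 80), 50.0), outline, CompartmentParams())
        assert "border" in m.flags
        assert not m.valid

    def test_too_thin_cell_flagged_not_dropped(self):
        from memloc import CellOutline
        thin = CellOutline("t", np.array(
            [[9.5, 9.5], [14.5, 9.5], [14.5, 14.5], [9.5, 14.5]]))  # 5x5 px
        m = measure_cell(np.ones((30, 30)), thin, CompartmentParams())
        assert "too_thin" in m.flags
        assert m.ratio is None


class TestDispersalEpisodes:
    def test_worked_seven_frame_trace(self):
        trace = [0.9, 0.9, 0.6, 0.65, 0.6, 0.9, 0.95]
        episodes = dispersal_episodes(trace, 3.0)
        assert len(episodes) == 1
        ep = episodes[0]
        assert ep.onset_time_min == 6.0
        assert ep.duration_min == 9.0
        assert ep.frame_span == (2, 4)

    def test_all_membrane_no_episode(self):
        assert dispersal_episodes([0.9, 1.1, 0.8], 3.0) == []

    def test_single_frame_dip_debounced(self):
        assert dispersal_episodes([0.9, 0.5, 0.9, 0.9], 3.0) == []

    def test_gap_breaks_run(self):
        episodes = dispersal_episodes([0.6, 0.6, None, 0.6, 0.6], 3.0)
        assert [e.frame_span for e in episodes] == [(0, 1), (3, 4)]

    def test_trailing_episode_closed_at_end(self):
        episodes = dispersal_episodes([0.9, 0.6, 0.6], 5.0)
        assert episodes[0].frame_span == (1, 2)
        assert episodes[0].duration_min == 10.0
        assert episodes[0].onset_time_min == 5.0
        # duration = (last - first + 1) * interval
        first, last = episodes[0].frame_span
        assert episodes[0].duration_min == (last - first + 1) * 5.0


class TestMeasureTimeseries:
    def test_membrane_dispersal_return_cycle(self, default_params):
        # f schedule: membrane -> dispersed (2 frames) -> membrane
        frames, outlines = [], []
        for f in (1.0, 0.0, 0.0, 1.0):
            img, outline = render_cell_image("mixed", membrane_fraction=f)
            frames.append(img)
            outlines.append([outline])
        measurements, episodes = measure_timeseries(
            frames, outlines, default_params, 3.0, 0.066)
        assert len(measurements) == 4
        assert [e.frame_span for e in episodes["c"]] == [(1, 2)]
        assert episodes["c"][0].onset_time_min == 3.0
        assert episodes["c"][0].duration_min == 6.0

    def test_missing_cell_breaks_episode_and_flags(self, default_params):
        img, outline = render_cell_image("cytosolic")
        frames = [img, img, img]
        outlines = [[outline], [], [outline]]  # vanishes in frame 1
        measurements, episodes = measure_timeseries(
            frames, outlines, default_params, 3.0)
        assert episodes["c"] == []  # runs of length 1 are debounced
        assert all("gap" in m.flags for m in measurements)
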