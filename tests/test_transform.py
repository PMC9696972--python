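"""Unit and property tests for the SIM-LBP per-pixel stages and transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simlbp.transform import (
    BinaryPairSet,
    ComparisonPairSet,
    ConfigError,
    PixelWindow3x3,
    TransformConfig,
    binarize_pairs,
    compute_comparison_pairs,
    compute_feature_coefficients,
    extract_window,
    flatten_clockwise,
    sim_lbp_pixel,
    sim_lbp_transform,
    sim_lbp_transform_naive,
    symmetric_split,
    weighted_pixel_value,
)

windows = st.builds(
    PixelWindow3x3,
    SL=st.tuples(*[st.integers(0, 255)] * 3),
    SC=st.tuples(*[st.integers(0, 255)] * 3),
    SR=st.tuples(*[st.integers(0, 255)] * 3),
)

bitpairs = st.tuples(*[st.tuples(st.integers(0, 1), st.integers(0, 1))] * 3)


class TestExtractWindow:
    def test_single_pixel_replicates(self):
        w = extract_window(np.array([[7]], dtype=np.uint8), 0, 0, "replicate")
        assert w.SL == w.SC == w.SR == (7, 7, 7)

    def test_interior_window_ignores_padding(self, worked_image):
        for pad in ("replicate", "reflect", "zero", "crop"):
            w = extract_window(worked_image, 1, 1, pad)
            assert (w.SL, w.SC, w.SR) == ((10, 40, 70), (20, 50, 80), (30, 60, 90))

    def test_zero_padding_at_corner(self, worked_image):
        w = extract_window(worked_image, 0, 0, "zero")
        assert w.SL == (0, 0, 0)
        assert w.SC == (0, 10, 40)
        assert w.SR == (0, 20, 50)

    def test_out_of_range_and_crop_border_raise(self, worked_image):
        with pytest.raises(IndexError):
            extract_window(worked_image, 3, 0, "replicate")
        with pytest.raises(IndexError):
            extract_window(worked_image, 0, 1, "crop")


class TestComparisonPairs:
    def test_constant_window_gives_zero_pairs(self):
        w = PixelWindow3x3(SL=(50,) * 3, SC=(50,) * 3, SR=(50,) * 3)
        pairs = compute_comparison_pairs(w)
        assert pairs.ordered == ((0, 0),) * 6

    def test_worked_window(self, worked_window):
        pairs = compute_comparison_pairs(worked_window, "neighbor_minus_center")
        assert pairs.vpairs == ((-10, 10),) * 3
        assert pairs.hpairs == ((-30, 30),) * 3

    @given(windows)
    def test_sign_conventions_are_negations(self, w):
        nmc = compute_comparison_pairs(w, "neighbor_minus_center").ordered
        cmn = compute_comparison_pairs(w, "center_minus_neighbor").ordered
        assert all((x, y) == (-u, -v) for (x, y), (u, v) in zip(nmc, cmn))


class TestFeatureCoefficients:
    def test_zero_pairs_use_fallback(self):
        pairs = ComparisonPairSet(vpairs=((0, 0),) * 3, hpairs=((0, 0),) * 3)
        assert compute_feature_coefficients(pairs, fallback=0.0).fcv == (0.0,) * 6
        assert compute_feature_coefficients(pairs, fallback=3.5).fcv == (3.5,) * 6

    def test_symmetric_pair_has_variance_100_and_zero_mean(self):
        pairs = ComparisonPairSet(vpairs=((-10, 10),) * 3, hpairs=((-10, 10),) * 3)
        co = compute_feature_coefficients(pairs)
        assert co.sigma2 == (100.0,) * 6
        assert co.fcv == (0.0,) * 6

    def test_asymmetric_pair_mean_over_population_variance(self):
        # pair (2, 8): mean 5, population variance ((2-8)/2)^2 = 9 -> 5/9
        pairs = ComparisonPairSet(vpairs=((2, 8), (0, 0), (0, 0)), hpairs=((0, 0),) * 3)
        co = compute_feature_coefficients(pairs)
        assert co.fcv[0] == pytest.approx(5 / 9)
        assert co.sigma2[0] == 9.0

    def test_center_pixel_mode_copies_anchor_intensities(self, worked_window):
        pairs = compute_comparison_pairs(worked_window)
        co = compute_feature_coefficients(pairs, "center_pixel", worked_window)
        assert co.fcv == (20, 50, 80, 40, 50, 60)

    def test_global_sum_replicates_the_total(self):
        pairs = ComparisonPairSet(vpairs=((2, 8), (-10, 10), (0, 0)), hpairs=((0, 0),) * 3)
        co = compute_feature_coefficients(pairs, "global_sum", fallback=1.0)
        # terms: 5/9, 0, 1, 1, 1, 1
        total = 5 / 9 + 4.0
        assert all(f == pytest.approx(total) for f in co.fcv)

    def test_unknown_mode_rejected(self):
        pairs = ComparisonPairSet(vpairs=((0, 0),) * 3, hpairs=((0, 0),) * 3)
        with pytest.raises(ConfigError):
            compute_feature_coefficients(pairs, "nope")


class TestBinarize:
    def test_ties_map_to_one(self):
        pairs = ComparisonPairSet(vpairs=((0, 0),) * 3, hpairs=((0, 0),) * 3)
        co = compute_feature_coefficients(pairs)
        bp = binarize_pairs(pairs, co)
        assert bp.vbp == bp.hbp == ((1, 1),) * 3

    def test_sign_test_per_element(self, worked_window):
        pairs = compute_comparison_pairs(worked_window)
        bp = binarize_pairs(pairs, compute_feature_coefficients(pairs))
        assert bp.vbp == ((0, 1),) * 3
        assert bp.hbp == ((0, 1),) * 3

    def test_coefficient_above_both_elements(self):
        from simlbp.transform import FeatureCoefficients

        pairs = ComparisonPairSet(vpairs=((5, 5), (0, 0), (0, 0)), hpairs=((0, 0),) * 3)
        co = FeatureCoefficients(fcv=(6, 0, 0, 0, 0, 0), sigma2=(0,) * 6)
        assert binarize_pairs(pairs, co).vbp[0] == (0, 0)

    @given(windows)
    def test_flipping_sign_convention_complements_non_tie_bits(self, w):
        """With the thresholds held at zero, negating every difference must
        complement exactly the bits whose difference is non-zero."""
        from simlbp.transform import FeatureCoefficients

        zero = FeatureCoefficients(fcv=(0.0,) * 6, sigma2=(0.0,) * 6)
        nmc = compute_comparison_pairs(w, "neighbor_minus_center")
        cmn = compute_comparison_pairs(w, "center_minus_neighbor")
        b1 = binarize_pairs(nmc, zero)
        b2 = binarize_pairs(cmn, zero)
        for (x, y), p, q in zip(nmc.ordered, b1.vbp + b1.hbp, b2.vbp + b2.hbp):
            assert (p[0] == q[0]) == (x == 0)
            assert (p[1] == q[1]) == (y == 0)


class TestSplitAndFlatten:
    def test_all_zero_pairs(self):
        bp = BinaryPairSet(vbp=((0, 0),) * 3, hbp=((0, 0),) * 3)
        sm = symmetric_split(bp)
        assert not sm.vertical.any() and not sm.horizontal.any() and not sm.merged.any()

    def test_worked_placement_and_or(self):
        bp = BinaryPairSet(vbp=((0, 1),) * 3, hbp=((0, 1),) * 3)
        sm = symmetric_split(bp)
        assert sm.vertical.tolist() == [[0, 0, 1], [0, 0, 1], [0, 0, 1]]
        assert sm.horizontal.tolist() == [[0, 0, 0], [0, 0, 0], [1, 1, 1]]
        assert sm.merged.tolist() == [[0, 0, 1], [0, 0, 1], [1, 1, 1]]

    def test_single_bit_survives_or(self):
        bp = BinaryPairSet(vbp=((1, 0), (0, 0), (0, 0)), hbp=((0, 0),) * 3)
        assert symmetric_split(bp).merged.tolist() == [[1, 0, 0], [0, 0, 0], [0, 0, 0]]

    @given(bitpairs, bitpairs)
    def test_split_structure_invariants(self, vbp, hbp):
        sm = symmetric_split(BinaryPairSet(vbp=vbp, hbp=hbp))
        assert not sm.vertical[:, 1].any()      # centre column empty
        assert not sm.horizontal[1, :].any()    # middle row empty
        assert sm.merged[1, 1] == 0
        assert np.array_equal(sm.merged, np.logical_or(sm.vertical, sm.horizontal))

    def test_flatten_clockwise_walk(self):
        assert flatten_clockwise([[0, 0, 1], [0, 0, 1], [1, 1, 1]]) == (0, 0, 1, 1, 1, 1, 1, 0)
        assert flatten_clockwise(np.zeros((3, 3))) == (0,) * 8
        assert flatten_clockwise([[0, 0, 0], [0, 1, 0], [0, 0, 0]]) == (0,) * 8


class TestWeightedPixelValue:
    @pytest.mark.parametrize("order", ["lsb_at_top_left", "msb_at_top_left"])
    def test_extremes(self, order):
        assert weighted_pixel_value((0,) * 8, order) == 0
        assert weighted_pixel_value((1,) * 8, order) == 255

    def test_worked_code_is_124(self):
        assert weighted_pixel_value((0, 0, 1, 1, 1, 1, 1, 0), "lsb_at_top_left") == 124

    def test_single_bit_endianness(self):
        bits = (1, 0, 0, 0, 0, 0, 0, 0)
        assert weighted_pixel_value(bits, "lsb_at_top_left") == 1
        assert weighted_pixel_value(bits, "msb_at_top_left") == 128

    @given(st.tuples(*[st.integers(0, 1)] * 8))
    def test_bit_orders_are_mirror_images(self, bits):
        assert weighted_pixel_value(bits, "lsb_at_top_left") == weighted_pixel_value(
            bits[::-1], "msb_at_top_left"
        )
        assert 0 <= weighted_pixel_value(bits) <= 255


class TestSimLbpPixel:
    def test_constant_window_forced_to_255(self):
        w = PixelWindow3x3(SL=(50,) * 3, SC=(50,) * 3, SR=(50,) * 3)
        assert sim_lbp_pixel(w, TransformConfig()) == 255

    def test_worked_window_full_pipeline(self, worked_window):
        assert sim_lbp_pixel(worked_window, TransformConfig()) == 124


class TestSimLbpTransform:
    def test_constant_image_transforms_to_all_255(self):
        img = np.full((5, 5), 50, dtype=np.uint8)
        assert np.array_equal(sim_lbp_transform(img), np.full((5, 5), 255))

    def test_crop_on_worked_image(self, worked_image):
        out = sim_lbp_transform(worked_image, TransformConfig(padding="crop"))
        assert out.tolist() == [[124]]

    def test_purity_and_non_destructive(self, worked_image):
        before = worked_image.copy()
        a = sim_lbp_transform(worked_image)
        b = sim_lbp_transform(worked_image)
        assert np.array_equal(a, b)
        assert np.array_equal(worked_image, before)

    @pytest.mark.parametrize("pad,expected", [
        ("replicate", (6, 7)), ("reflect", (6, 7)), ("zero", (6, 7)), ("crop", (4, 5)),
    ])
    def test_output_size_contract(self, pad, expected):
        img = np.arange(42, dtype=np.uint8).reshape(6, 7)
        assert sim_lbp_transform(img, TransformConfig(padding=pad)).shape == expected

    def test_crop_agrees_with_replicate_on_interior(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (12, 9), dtype=np.int64).astype(np.uint8)
        crop = sim_lbp_transform(img, TransformConfig(padding="crop"))
        repl = sim_lbp_transform(img, TransformConfig(padding="replicate"))
        assert np.array_equal(crop, repl[1:-1, 1:-1])

    def test_small_image_with_crop_rejected(self):
        with pytest.raises(ValueError):
            sim_lbp_transform(np.zeros((2, 5), dtype=np.uint8), TransformConfig(padding="crop"))

    @settings(deadline=None, max_examples=10)
    @given(st.integers(0, 2**31 - 1))
    def test_vectorised_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (int(rng.integers(4, 16)), int(rng.integers(4, 16))),
                           dtype=np.int64).astype(np.uint8)
        cfg = TransformConfig(
            sign_convention=rng.choice(["neighbor_minus_center", "center_minus_neighbor"]),
            coefficient_mode=rng.choice(["pair_mean_over_variance", "global_sum", "center_pixel"]),
            bit_order=rng.choice(["lsb_at_top_left", "msb_at_top_left"]),
            padding=rng.choice(["replicate", "reflect", "zero", "crop"]),
        )
        assert np.array_equal(sim_lbp_transform(img, cfg), sim_lbp_transform_naive(img, cfg))

    def test_additive_shift_invariance_difference_modes(self):
        rng = np.random.default_rng(11)
        img = rng.integers(60, 200, (16, 16), dtype=np.int64).astype(np.uint8)
        for mode in ("pair_mean_over_variance", "global_sum"):
            cfg = TransformConfig(coefficient_mode=mode)
            base = sim_lbp_transform(img, cfg)
            for c in (-40, 25):
                assert np.array_equal(sim_lbp_transform(img + np.int64(c), cfg), base)

    def test_center_pixel_mode_is_not_shift_invariant(self):
        # the literal printed thresholds depend on absolute intensities
        rng = np.random.default_rng(12)
        img = rng.integers(60, 200, (16, 16), dtype=np.int64).astype(np.uint8)
        cfg = TransformConfig(coefficient_mode="center_pixel")
        assert not np.array_equal(
            sim_lbp_transform(img + np.int64(40), cfg), sim_lbp_transform(img, cfg)
        )
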