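import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from _oracles import haralick_by_pair_enumeration
from dwigrade.radiomics import (GLCM_DIRECTIONS, HARALICK_NAMES,
                                RadiomicsConfig, extract_sequence,
                                feature_names, first_order_features,
                                gabor_features, glcm, haralick_features,
                                kirsch_features)


class TestFirstOrder:
    def test_constant_patch_convention(self, make_patch):
        f = first_order_features(make_patch(np.full((32, 32), 7.0)))
        assert np.array_equal(f, [7.0, 0.0, 0.0, 0.0])

    def test_symmetric_four_pixels(self, make_patch):
        mask = np.zeros((32, 32), bool)
        mask[0, :4] = True
        px = np.zeros((32, 32))
        px[0, 2:4] = 10.0
        f = first_order_features(make_patch(px, mask))
        assert f[0] == pytest.approx(5.0)
        assert f[1] == pytest.approx(5.0)       # population sd
        assert f[2] == pytest.approx(0.0)       # symmetric

    def test_skewness_matches_moment_oracle(self, make_patch):
        rng = np.random.default_rng(17)
        x = rng.exponential(2.0, 1024)
        f = first_order_features(make_patch(x.reshape(32, 32)))
        m = x.mean()
        m2 = ((x - m) ** 2).mean()
        m3 = ((x - m) ** 3).mean()
        m4 = ((x - m) ** 4).mean()
        assert f[2] == pytest.approx(m3 / m2 ** 1.5, rel=1e-12)
        assert f[3] == pytest.approx(m4 / m2 ** 2 - 3.0, rel=1e-12)

    def test_mask_restriction(self, make_patch):
        px = np.full((32, 32), 3949.0)
        mask = np.zeros((32, 32), bool)
        mask[10:12, 10:12] = True
        px[mask] = 2.0
        f = first_order_features(make_patch(px, mask))
        assert f[0] == pytest.approx(2.0)


class TestHaralick:
    def test_constant_patch_single_glcm_entry(self, make_patch):
        f = haralick_features(make_patch(np.full((32, 32), 4.0)), (0, 1))
        by_name = dict(zip(HARALICK_NAMES, f))
        assert by_name["energy"] == pytest.approx(1.0)
        assert by_name["contrast"] == pytest.approx(0.0)
        assert by_name["entropy"] == pytest.approx(0.0)
        assert by_name["maximum_probability"] == pytest.approx(1.0)

    def test_checkerboard_matches_hand_oracle(self, make_patch):
        """2x2 checkerboard at 2 gray levels, horizontal offset: every one
        of the 18 statistics equals the pair-enumeration oracle."""
        px = np.zeros((32, 32))
        px[:2, :2] = [[0, 1], [1, 0]]
        mask = np.zeros((32, 32), bool)
        mask[:2, :2] = True
        config = RadiomicsConfig(n_gray_levels=2)
        patch = make_patch(px, mask)
        f = haralick_features(patch, (0, 1), config)
        P_oracle, f_oracle = haralick_by_pair_enumeration(px, mask, (0, 1), 2)
        assert np.allclose(glcm(patch, (0, 1), config), P_oracle)
        assert np.allclose(glcm(patch, (0, 1), config),
                           [[0.0, 0.5], [0.5, 0.0]])
        assert np.allclose(f, f_oracle, atol=1e-12)

    def test_vector_length_per_direction(self, make_patch):
        patch = make_patch(np.random.default_rng(0).random((32, 32)))
        for d in GLCM_DIRECTIONS:
            assert haralick_features(patch, d).shape == (18,)

    @pytest.mark.parametrize("trial", range(0, 100, 1))
    def test_random_patches_match_pair_enumeration_oracle(self, make_patch, trial):
        rng = np.random.default_rng(1000 + trial)
        px32 = np.zeros((32, 32))
        mask32 = np.zeros((32, 32), bool)
        px32[:8, :8] = rng.uniform(0, 100, (8, 8))
        mask32[:8, :8] = rng.random((8, 8)) < 0.8
        if mask32.sum() < 4:
            mask32[:2, :2] = True
        patch = make_patch(px32, mask32)
        config = RadiomicsConfig(n_gray_levels=8)
        for d in GLCM_DIRECTIONS:
            _, expected = haralick_by_pair_enumeration(px32, mask32, d, 8)
            got = haralick_features(patch, d, config) \
                if np.any(expected) else None
            if got is not None:
                assert np.max(np.abs(got - expected)) <= 1e-10

    def test_glcm_normalized(self, make_patch):
        rng = np.random.default_rng(5)
        patch = make_patch(rng.random((32, 32)),
                           rng.random((32, 32)) < 0.7)
        for d in GLCM_DIRECTIONS:
            assert glcm(patch, d).sum() == pytest.approx(1.0)

    def test_no_valid_pairs_warns_and_zeroes(self, make_patch):
        mask = np.zeros((32, 32), bool)
        mask[0, 0] = True
        patch = make_patch(np.ones((32, 32)), mask)
        with pytest.warns(UserWarning):
            f = haralick_features(patch, (0, 1))
        assert np.array_equal(f, np.zeros(18))


class TestKirsch:
    def test_constant_patch_zero_response(self, make_patch):
        f = kirsch_features(make_patch(np.full((32, 32), 9.0)))
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_vertical_edge_favors_horizontal_gradient_kernels(self, make_patch):
        px = np.zeros((32, 32))
        px[:, 16:] = 10.0
        f = kirsch_features(make_patch(px))
        # ring positions 2/6 are the east/west kernels; 0/4 north/south
        assert f[2] > f[0] and f[2] > f[4]
        assert f[6] > f[0] and f[6] > f[4]

    def test_quarter_rotation_permutes_two_compass_steps(self, make_patch):
        rng = np.random.default_rng(3)
        px = rng.random((32, 32)) * 10
        f = kirsch_features(make_patch(px))
        f_rot = kirsch_features(make_patch(np.rot90(px)))
        assert np.allclose(f_rot, np.roll(f, -2), rtol=1e-10)


class TestGabor:
    def test_vector_length(self, make_patch):
        f = gabor_features(make_patch(np.random.default_rng(0).random((32, 32))))
        assert f.shape == (12,)

    def test_constant_patch_near_zero(self, make_patch):
        f = gabor_features(make_patch(np.full((32, 32), 11.0)))
        assert np.all(np.abs(f) <= 1e-6)

    def test_grating_peaks_at_matched_orientation_and_scale(self, make_patch):
        x = np.arange(32)
        grating = 5.0 + np.broadcast_to(np.sin(2 * np.pi * x / 4.0), (32, 32))
        f = gabor_features(make_patch(np.array(grating)))
        names = feature_names()[-12:]
        assert names[int(np.argmax(f))] == "gabor_o0_w4"


class TestSequence:
    def test_length_and_block_structure(self, make_patch):
        patch = make_patch(np.random.default_rng(1).random((32, 32)) * 50)
        seq = extract_sequence(patch)
        assert len(seq.values) == 96
        assert np.allclose(seq.values[:4], first_order_features(patch))
        off = 4
        for d in GLCM_DIRECTIONS:
            assert np.allclose(seq.values[off:off + 18],
                               haralick_features(patch, d))
            off += 18
        assert np.allclose(seq.values[off:off + 8], kirsch_features(patch))
        assert np.allclose(seq.values[off + 8:], gabor_features(patch))

    def test_deterministic(self, make_patch):
        patch = make_patch(np.random.default_rng(2).random((32, 32)))
        assert np.array_equal(extract_sequence(patch).values,
                              extract_sequence(patch).values)

    def test_invariant_to_fill_value(self, make_patch):
        """All 96 features must depend on in-mask pixels only."""
        rng = np.random.default_rng(6)
        mask = np.zeros((32, 32), bool)
        mask[8:24, 6:26] = True
        px = rng.uniform(100, 900, (32, 32))
        filled_a, filled_b = px.copy(), px.copy()
        filled_a[~mask] = 3949.0
        filled_b[~mask] = 0.0
        seq_a = extract_sequence(make_patch(filled_a, mask))
        seq_b = extract_sequence(make_patch(filled_b, mask))
        assert np.array_equal(seq_a.values, seq_b.values)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(arrays(np.float64, (32, 32), elements=st.floats(0, 1000)),
           st.integers(0, 2 ** 31 - 1))
    def test_property_finite_96_vector(self, px, mask_seed):
        from dwigrade.zoning import ZonePatch
        mask = np.random.default_rng(mask_seed).random((32, 32)) < 0.6
        if not mask.any():
            mask[0, 0] = True
        patch = ZonePatch(pixels=px, mask=mask, modality="ADC",
                          patient_id="T", slice_index=0, zone_id=1)
        seq = extract_sequence(patch)
        assert len(seq.values) == 96
        assert np.all(np.isfinite(seq.values))

    def test_feature_names_block_sizes(self):
        names = feature_names()
        assert len(names) == 96
        assert sum(n.startswith("fo_") for n in names) == 4
        assert sum(n.startswith("haralick_") for n in names) == 72
        assert sum(n.startswith("kirsch_") for n in names) == 8
        assert sum(n.startswith("gabor_") for n in names) == 12
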