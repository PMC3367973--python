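import numpy as np
import pytest
from scipy import integrate

from faasym.misreg import (
    count_diff_voxels,
    count_f_voxels,
    f_critical,
    f_ratio_map,
    hemispheric_kappa,
    kappa_overlap,
    map_stats_to_reference,
    mask_variance,
    normalized_f_sum,
    subject_fa_mask,
    symmetrize_variance,
    FMap,
    VarianceMap,
)
from faasym.volio import BinaryMask, VolumetricImage, make_grid_affine


SHAPE = (9, 7, 7)
AFFINE = make_grid_affine(SHAPE, 4.0)


def _mask(data):
    return BinaryMask(np.asarray(data, dtype=np.uint8), AFFINE)


def _random_masks(n, seed, shape=SHAPE):
    rng = np.random.default_rng(seed)
    return [
        BinaryMask((rng.uniform(size=shape) > 0.5).astype(np.uint8),
                   make_grid_affine(shape, 4.0))
        for _ in range(n)
    ]


class TestKappaOverlap:
    def test_subset_gives_one(self):
        b = np.zeros(SHAPE); b[2:4, 2:4, 2:4] = 1
        t = np.zeros(SHAPE); t[1:5, 1:5, 1:5] = 1
        assert kappa_overlap(_mask(b), _mask(t)) == 1.0

    def test_disjoint_gives_zero(self):
        b = np.zeros(SHAPE); b[0, 0, 0] = 1
        t = np.zeros(SHAPE); t[5, 5, 5] = 1
        assert kappa_overlap(_mask(b), _mask(t)) == 0.0

    def test_partial_overlap_fraction(self):
        b = np.zeros(SHAPE); b.ravel()[:10] = 1
        t = np.zeros(SHAPE); t.ravel()[6:20] = 1
        assert kappa_overlap(_mask(b), _mask(t)) == pytest.approx(0.4)

    def test_empty_mask_flagged_missing(self):
        assert kappa_overlap(_mask(np.zeros(SHAPE)), _mask(np.ones(SHAPE))) is None

    def test_brute_force_oracle_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            b = (rng.uniform(size=(4, 4, 4)) > 0.5).astype(np.uint8)
            t = (rng.uniform(size=(4, 4, 4)) > 0.5).astype(np.uint8)
            if b.sum() == 0:
                continue
            inter = sum(
                1
                for i in range(4) for j in range(4) for k in range(4)
                if b[i, j, k] == 1 and t[i, j, k] == 1
            )
            expected = inter / b.sum()
            aff = make_grid_affine((4, 4, 4), 4.0)  # not flip-closed use ok here
            got = kappa_overlap(BinaryMask(b, aff), BinaryMask(t, aff))
            assert got == pytest.approx(expected, abs=1e-12)


class TestMaskVariance:
    def test_identical_masks_zero_variance(self):
        masks = [_mask(np.ones(SHAPE))] * 3
        assert np.all(mask_variance(masks).data == 0)

    def test_closed_form_half_occupancy(self):
        data = [np.zeros(SHAPE) for _ in range(4)]
        for d in data[:2]:
            d[3, 3, 3] = 1
        v = mask_variance([_mask(d) for d in data])
        # values (1,1,0,0): unbiased variance = 0.25 * 4/3
        assert v.data[3, 3, 3] == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_brute_force_oracle(self):
        masks = _random_masks(5, 11, shape=(4, 4, 4))
        v = mask_variance(masks)
        stack = np.stack([m.data.astype(float) for m in masks])
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    vals = stack[:, i, j, k]
                    mean = vals.sum() / 5
                    expected = ((vals - mean) ** 2).sum() / 4
                    assert abs(v.data[i, j, k] - expected) < 1e-12

    def test_single_mask_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            mask_variance([_mask(np.ones(SHAPE))])


class TestSymmetrizeVariance:
    def test_symmetric_input_doubles(self):
        data = np.random.default_rng(0).uniform(size=SHAPE)
        data = 0.5 * (data + data[::-1])
        v = VarianceMap(data, AFFINE, 4)
        vs = symmetrize_variance(v)
        assert np.allclose(vs.data, 2 * data)

    def test_point_value_appears_at_both_sides(self):
        data = np.zeros(SHAPE)
        data[1, 3, 3] = 0.4  # off-midline column
        vs = symmetrize_variance(VarianceMap(data, AFFINE, 4))
        assert vs.data[1, 3, 3] == pytest.approx(0.4)
        assert vs.data[7, 3, 3] == pytest.approx(0.4)
        assert np.array_equal(vs.data, vs.data[::-1])


class TestFMaps:
    def test_equal_maps_ratio_one(self):
        v = VarianceMap(np.full(SHAPE, 0.2), AFFINE, 4)
        f = f_ratio_map(v, v)
        assert np.allclose(f.data, 1.0)

    def test_reciprocal_identity(self):
        rng = np.random.default_rng(5)
        a = VarianceMap(rng.uniform(0.05, 0.3, SHAPE), AFFINE, 4)
        b = VarianceMap(rng.uniform(0.05, 0.3, SHAPE), AFFINE, 4)
        fab = f_ratio_map(a, b).data
        fba = f_ratio_map(b, a).data
        assert np.allclose(fab * fba, 1.0)

    def test_zero_handling(self):
        a = np.zeros(SHAPE); b = np.zeros(SHAPE)
        a[0, 0, 0] = 0.4; b[0, 0, 0] = 0.1   # 4.0
        a[1, 1, 1] = 0.3                      # x/0 -> sentinel
        f = f_ratio_map(VarianceMap(a, AFFINE, 4), VarianceMap(b, AFFINE, 4))
        assert f.data[0, 0, 0] == pytest.approx(4.0)
        assert f.data[1, 1, 1] > 100  # capped sentinel, counts as suprathreshold
        assert f.data[2, 2, 2] == 0.0  # 0/0 excluded
        assert f.nonzero_count() == 2


class TestFCritical:
    def test_median_is_one(self):
        for d in (3, 10, 17):
            assert f_critical(d, d, 0.5) == pytest.approx(1.0, abs=1e-9)

    def test_quadrature_oracle(self):
        """Check the upper-p quantile against direct integration of the
        F(10, 10) density."""
        from scipy import stats

        fc = f_critical(10, 10, 0.05)
        tail, _ = integrate.quad(lambda x: stats.f.pdf(x, 10, 10), fc, np.inf)
        assert tail == pytest.approx(0.05, abs=1e-3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            f_critical(0, 10, 0.05)
        with pytest.raises(ValueError):
            f_critical(10, 10, 1.5)


class TestNormalizedFSum:
    def _fmap(self, values):
        data = np.zeros(SHAPE)
        data.ravel()[: len(values)] = values
        return FMap(data, AFFINE, "m", "n", 4)

    def test_no_suprathreshold_is_zero(self):
        assert normalized_f_sum(self._fmap([1.0, 2.0, 0.5]), 2.27) == 0.0

    def test_hand_counted_example(self):
        # values {3, 1, 0.5, 0}: one suprathreshold (3), three nonzero
        assert normalized_f_sum(self._fmap([3.0, 1.0, 0.5, 0.0]), 2.27) == pytest.approx(1.0)

    def test_scaling_monotone(self):
        f = self._fmap([3.0, 1.0, 0.5])
        f10 = self._fmap([30.0, 10.0, 5.0])
        assert normalized_f_sum(f10, 2.27) > normalized_f_sum(f, 2.27)

    def test_empty_support_flagged(self):
        assert normalized_f_sum(self._fmap([]), 2.27) is None

    def test_brute_force_oracle_random(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            data = rng.uniform(0, 4, (4, 4, 4)) * (rng.uniform(size=(4, 4, 4)) > 0.3)
            f = FMap(data, make_grid_affine((4, 4, 4), 4.0), "m", "n", 5)
            fc = 2.27
            total = nz = 0.0
            for i in range(4):
                for j in range(4):
                    for k in range(4):
                        v = data[i, j, k]
                        if v != 0:
                            nz += 1
                        if v > fc:
                            total += v
            assert normalized_f_sum(f, fc) == pytest.approx(total / nz, abs=1e-12)


class TestHemisphericKappa:
    def test_mirror_symmetric_masks_give_one(self):
        data = np.zeros(SHAPE)
        data[2:7, 2:5, 2:5] = 1
        data = np.maximum(data, data[::-1])
        assert hemispheric_kappa([_mask(data)]) == 1.0

    def test_no_mirror_overlap_gives_zero(self):
        data = np.zeros(SHAPE)
        data[0:2, 0:3, 0:3] = 1           # left block
        data[7:9, 4:7, 4:7] = 1           # right block, mirrored elsewhere
        assert hemispheric_kappa([_mask(data)]) == 0.0

    def test_constructed_ratio(self):
        """|I| = 30 and |Delta| = 10 on the half grid -> kappa = 0.75."""
        data = np.zeros(SHAPE)
        # 30 voxels present on both sides
        both = [(i, j, k) for i in (1, 2) for j in range(5) for k in range(3)]
        for (i, j, k) in both:
            data[i, j, k] = 1
            data[8 - i, j, k] = 1
        # 10 voxels on the left only
        only = [(3, j, k) for j in range(5) for k in range(2)]
        for (i, j, k) in only:
            data[i, j, k] = 1
        assert hemispheric_kappa([_mask(data)]) == pytest.approx(0.75)

    def test_brute_force_oracle_multi_subject(self):
        masks = _random_masks(5, 21)
        got = hemispheric_kappa(masks)
        # explicit-loop recomputation (midline column index 4 excluded)
        nx = SHAPE[0]
        d_sum = i_sum = 0.0
        for m in masks:
            for i in range(nx // 2):
                for j in range(SHAPE[1]):
                    for k in range(SHAPE[2]):
                        L = m.data[i, j, k]
                        R = m.data[nx - 1 - i, j, k]
                        d_sum += abs(int(L) - int(R))
                        i_sum += int(L) * int(R)
        assert got == pytest.approx(i_sum / (i_sum + d_sum), abs=1e-12)


class TestCounts:
    def test_count_f_monotone_in_threshold(self):
        data = np.random.default_rng(2).uniform(0, 5, SHAPE)
        f = FMap(data, AFFINE, "m", "n", 4)
        assert count_f_voxels(f, 1.0) >= count_f_voxels(f, 2.27) >= count_f_voxels(f, 4.0)

    def test_identical_variances_zero_count(self):
        v = VarianceMap(np.full(SHAPE, 0.1), AFFINE, 4)
        assert count_f_voxels(f_ratio_map(v, v), 2.27) == 0

    def test_diff_count_partition_identity(self):
        rng = np.random.default_rng(9)
        b = (rng.uniform(size=SHAPE) > 0.6).astype(np.uint8)
        t = (rng.uniform(size=SHAPE) > 0.6).astype(np.uint8)
        bm, tm = _mask(b), _mask(t)
        inter = int((b & t).sum())
        assert count_diff_voxels(bm, tm) + inter == int(b.sum())

    def test_subset_gives_zero_diff(self):
        b = np.zeros(SHAPE); b[2, 2, 2] = 1
        t = np.ones(SHAPE)
        assert count_diff_voxels(_mask(b), _mask(t)) == 0


class TestSubjectFaMask:
    def test_strict_threshold_and_external_mask(self):
        data = np.full(SHAPE, 0.2)
        data[4, 4, 4] = 0.35
        img = VolumetricImage(data, AFFINE)
        m = subject_fa_mask(img, 0.2)
        assert m.count() == 1  # 0.2 itself excluded (strict >)
        ext = _mask(np.zeros(SHAPE))
        assert subject_fa_mask(img, 0.2, ext).count() == 0


class TestMapStatsToReference:
    def test_identical_templates_identity(self, small_templates):
        fa, _ = small_templates
        data = np.zeros(fa.shape, dtype=np.uint8)
        data[10:12, 10:12, 10:12] = 1
        mask = BinaryMask(data, fa.affine)
        out = map_stats_to_reference(mask, fa, fa)
        assert np.array_equal(out.data, mask.data)

    def test_translated_template_moves_mask(self, small_templates):
        from faasym.register import RegistrationConfig
        from faasym.volio import resample

        fa, _ = small_templates
        t = np.eye(4)
        t[1, 3] = -4.0  # reference content moved +4 mm in y
        ref = resample(fa, fa.shape, fa.affine, transform=t)
        data = np.zeros(fa.shape, dtype=np.uint8)
        data[8:12, 8:12, 14:18] = 1
        mask = BinaryMask(data, fa.affine)
        out = map_stats_to_reference(
            mask, fa, ref, RegistrationConfig(max_iterations=6))
        assert set(np.unique(out.data)) <= {0, 1}
        c_in = np.argwhere(mask.data).mean(axis=0)
        c_out = np.argwhere(out.data).mean(axis=0)
        # centroid shift ~ +1 voxel in y (4 mm), within 1 voxel
        assert c_out[1] - c_in[1] == pytest.approx(1.0, abs=1.0)
        assert abs(c_out[0] - c_in[0]) < 1.0
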