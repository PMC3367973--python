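import numpy as np
import pytest
from scipy import ndimage

from faasym.tbss_lite import (
    ProjectionRecord,
    project_to_skeleton,
    skeleton_paired_test,
    skeletonize,
    thicken_tbss_mask,
)
from faasym.volio import VolumetricImage


class TestSkeletonize:
    def test_tube_skeleton_thin_and_on_axis(self, tube_template):
        spec, fa = tube_template
        sk = skeletonize(fa)
        # two mirrored tubes, axis length 120 mm / 4 mm = 31 voxels each
        assert 0.8 * 62 <= len(sk) <= 1.2 * 62
        aff = fa.affine
        wx = aff[0, 0] * sk.voxels[:, 0] + aff[0, 3]
        wz = aff[2, 2] * sk.voxels[:, 2] + aff[2, 3]
        dist_vox = np.sqrt((np.abs(wx) - 20.0) ** 2 + wz**2) / 4.0
        assert dist_vox.max() <= 1.0
        # thinness: most skeleton voxels have at most 2 neighbours
        m = sk.as_mask().data.astype(float)
        kern = np.ones((3, 3, 3)); kern[1, 1, 1] = 0
        nb = ndimage.convolve(m, kern, mode="constant")[m > 0]
        assert (nb <= 2).mean() >= 0.9

    def test_all_voxels_above_threshold(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa, fa_threshold=0.2)
        assert np.all(sk.mean_fa > 0.2)
        assert np.allclose(np.linalg.norm(sk.tract_dir, axis=1), 1.0)

    def test_symmetric_input_symmetric_skeleton(self, small_templates):
        fa, _ = small_templates
        sk = skeletonize(fa)
        m = sk.as_mask().data
        assert np.array_equal(m, m[::-1])

    def test_empty_threshold_rejected(self, tube_template):
        _, fa = tube_template
        with pytest.raises(ValueError, match="threshold"):
            skeletonize(fa, fa_threshold=0.99)


class TestProjection:
    def test_mean_image_projects_to_itself(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        rec = project_to_skeleton(fa, sk, 3.0)
        assert np.allclose(rec.values, sk.mean_fa)
        assert np.array_equal(rec.source_vox, sk.voxels)

    def test_shifted_subject_moves_sources_not_values(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        shifted = VolumetricImage(np.roll(fa.data, 2, axis=0), fa.affine)
        rec = project_to_skeleton(shifted, sk, 3.0)
        preserved = np.abs(rec.values - sk.mean_fa) < 0.05
        assert preserved.mean() >= 0.9
        assert np.median(rec.source_vox[:, 0] - sk.voxels[:, 0]) == pytest.approx(2.0)

    def test_projected_value_at_least_centre_value(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        rng = np.random.default_rng(0)
        subject = VolumetricImage(
            np.clip(fa.data + 0.05 * rng.standard_normal(fa.shape), 0, 1), fa.affine)
        rec = project_to_skeleton(subject, sk, 3.0)
        centre = subject.data[tuple(sk.voxels.T)]
        assert np.all(rec.values >= centre - 1e-12)

    def test_small_radius_rejected(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        with pytest.raises(ValueError, match="radius"):
            project_to_skeleton(fa, sk, 0.5)


def _records(values_matrix, skeleton):
    return [
        ProjectionRecord(values=row, source_vox=skeleton.voxels.copy(),
                         search_radius=3.0)
        for row in values_matrix
    ]


class TestPairedPermutationTest:
    def test_zero_differences_nothing_significant(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        vals = np.tile(sk.mean_fa, (6, 1))
        res = skeleton_paired_test(_records(vals, sk), _records(vals, sk),
                                   n_permutations=200, seed=1)
        assert res.significant.sum() == 0

    def test_p_values_within_permutation_bounds(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        rng = np.random.default_rng(3)
        a = np.tile(sk.mean_fa, (8, 1)) + 0.01 * rng.standard_normal((8, len(sk)))
        b = np.tile(sk.mean_fa, (8, 1)) + 0.01 * rng.standard_normal((8, len(sk)))
        nperm = 300
        res = skeleton_paired_test(_records(a, sk), _records(b, sk),
                                   n_permutations=nperm, seed=2)
        assert np.all(res.p_fwe >= 1.0 / (nperm + 1) - 1e-12)
        assert np.all(res.p_fwe <= 1.0)

    def test_deterministic_given_seed(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        rng = np.random.default_rng(4)
        a = np.tile(sk.mean_fa, (6, 1)) + 0.02 * rng.standard_normal((6, len(sk)))
        b = np.tile(sk.mean_fa, (6, 1))
        r1 = skeleton_paired_test(_records(a, sk), _records(b, sk), 200, seed=5)
        r2 = skeleton_paired_test(_records(a, sk), _records(b, sk), 200, seed=5)
        assert np.array_equal(r1.p_fwe, r2.p_fwe)

    def test_few_permutations_warn(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        vals = np.tile(sk.mean_fa, (4, 1))
        with pytest.warns(UserWarning, match="permutations"):
            skeleton_paired_test(_records(vals, sk), _records(vals, sk),
                                 n_permutations=50, seed=0)


class TestThickening:
    def test_unanimous_backprojection_probability_one(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        vals = np.tile(sk.mean_fa, (5, 1))
        recs = _records(vals, sk)
        sig = np.zeros(len(sk), dtype=bool)
        sig[:4] = True
        thick = thicken_tbss_mask(recs, sig, sk, threshold=0.1)
        marked = tuple(sk.voxels[:4].T)
        assert np.all(thick.probability[marked] == 1.0)
        assert thick.mask.count() == 4

    def test_threshold_monotone(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        rng = np.random.default_rng(6)
        recs = []
        for _ in range(10):
            jitter = rng.integers(-1, 2, size=sk.voxels.shape)
            src = np.clip(sk.voxels + jitter, 0, np.asarray(sk.grid_shape) - 1)
            recs.append(ProjectionRecord(sk.mean_fa.copy(), src, 3.0))
        sig = np.ones(len(sk), dtype=bool)
        loose = thicken_tbss_mask(recs, sig, sk, threshold=0.0).mask.data
        strictm = thicken_tbss_mask(recs, sig, sk, threshold=0.2).mask.data
        assert np.all(strictm <= loose)

    def test_boundary_probability_excluded_strictly(self, tube_template):
        """One subject of ten marks a voxel: probability 0.1, excluded by
        the strict > 0.1 rule."""
        _, fa = tube_template
        sk = skeletonize(fa)
        recs = []
        for s in range(10):
            src = sk.voxels.copy()
            if s > 0:  # nine subjects project the first voxel elsewhere
                src[0] = [0, 0, 0]
            recs.append(ProjectionRecord(sk.mean_fa.copy(), src, 3.0))
        sig = np.zeros(len(sk), dtype=bool)
        sig[0] = True
        thick = thicken_tbss_mask(recs, sig, sk, threshold=0.1)
        v0 = tuple(sk.voxels[0])
        assert thick.probability[v0] == pytest.approx(0.1)
        assert thick.mask.data[v0] == 0

    def test_no_significant_voxels_flagged_empty(self, tube_template):
        _, fa = tube_template
        sk = skeletonize(fa)
        recs = _records(np.tile(sk.mean_fa, (3, 1)), sk)
        thick = thicken_tbss_mask(recs, np.zeros(len(sk), dtype=bool), sk)
        assert thick.empty
        assert thick.mask.count() == 0
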