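"""Simplified skeleton-based reference analysis (TBSS-style).

The mean normalised FA volume is reduced to a thin centre-of-tract
skeleton; each subject's FA is projected onto the skeleton by searching
for the maximum FA in the plane perpendicular to the local tract
direction; paired original-vs-flipped differences on the skeleton are
tested with a sign-flip max-statistic permutation test (familywise error
control); and significant skeleton voxels are projected back into each
subject to build the "thickened" volumetric mask used when comparing
skeleton results with voxel-based statistics.

Tract geometry is taken from the Hessian of the smoothed mean FA: the
eigenvector with the smallest-magnitude eigenvalue is the tract
direction, and the two remaining (most negative curvature) eigenvectors
span the cross-tract plane.  A voxel belongs to the skeleton when its FA
exceeds the threshold and is a local maximum along both cross-tract
eigen-directions, which thins tubes to their axis and sheets to their
mid-plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import BinaryMask, VolumetricImage, smooth_array

__all__ = [
    "Skeleton",
    "ProjectionRecord",
    "ThickenedMask",
    "SkeletonTestResult",
    "skeletonize",
    "project_to_skeleton",
    "skeleton_paired_test",
    "thicken_tbss_mask",
]

DEFAULT_FA_THRESHOLD = 0.2
DEFAULT_PROBABILITY_THRESHOLD = 0.1
DEFAULT_N_PERMUTATIONS = 5000


@dataclass(eq=False)
class Skeleton:
    """Thin centre-of-tract voxel set on the template grid."""

    voxels: np.ndarray  # (N, 3) int indices
    tract_dir: np.ndarray  # (N, 3) unit tract direction (voxel coords)
    perp1: np.ndarray  # (N, 3) first cross-tract direction
    perp2: np.ndarray  # (N, 3) second cross-tract direction
    mean_fa: np.ndarray  # (N,) mean-FA value at each skeleton voxel
    grid_shape: tuple
    affine: np.ndarray

    def __len__(self) -> int:
        return self.voxels.shape[0]

    def as_mask(self) -> BinaryMask:
        m = np.zeros(self.grid_shape, dtype=np.uint8)
        m[tuple(self.voxels.T)] = 1
        return BinaryMask(m, self.affine, "skeleton")


@dataclass(eq=False)
class ProjectionRecord:
    """Per skeleton voxel: the projected FA value and its source voxel."""

    values: np.ndarray  # (N,)
    source_vox: np.ndarray  # (N, 3) int indices in template space
    search_radius: float


@dataclass(eq=False)
class ThickenedMask:
    """Thresholded back-projection probability map."""

    mask: BinaryMask
    probability: np.ndarray
    threshold: float
    empty: bool = False


@dataclass(eq=False)
class SkeletonTestResult:
    significant: np.ndarray  # (N,) bool
    t: np.ndarray
    p_fwe: np.ndarray
    alpha: float


def _hessian_eig(f: np.ndarray, candidates: np.ndarray):
    """Eigen-decomposition of the Hessian at candidate voxels.

    Returns eigenvalues ascending and eigenvectors (columns) for each
    candidate.  Works in voxel units (isotropic-enough template grids).
    """
    gx, gy, gz = np.gradient(f)
    hxx, hxy, hxz = np.gradient(gx)
    _, hyy, hyz = np.gradient(gy)
    _, _, hzz = np.gradient(gz)
    idx = tuple(candidates.T)
    H = np.empty((candidates.shape[0], 3, 3))
    H[:, 0, 0] = hxx[idx]
    H[:, 1, 1] = hyy[idx]
    H[:, 2, 2] = hzz[idx]
    H[:, 0, 1] = H[:, 1, 0] = hxy[idx]
    H[:, 0, 2] = H[:, 2, 0] = hxz[idx]
    H[:, 1, 2] = H[:, 2, 1] = hyz[idx]
    evals, evecs = np.linalg.eigh(H)
    return evals, evecs


def skeletonize(
    mean_fa: VolumetricImage,
    fa_threshold: float = DEFAULT_FA_THRESHOLD,
    smooth_fwhm_mm: float | None = None,
) -> Skeleton:
    """Extract the centre-of-tract skeleton of a mean FA volume.

    A voxel is retained when FA > ``fa_threshold`` and the (smoothed) FA
    is a local maximum along both cross-tract Hessian eigen-directions.
    """
    if smooth_fwhm_mm is None:
        smooth_fwhm_mm = 2.0 * float(np.mean(mean_fa.voxel_size))
    f = smooth_array(mean_fa.data, smooth_fwhm_mm, mean_fa.voxel_size)
    cand = np.argwhere(mean_fa.data > fa_threshold)
    if cand.size == 0:
        raise ValueError(
            f"no voxels above FA threshold {fa_threshold}; review the threshold"
        )
    evals, evecs = _hessian_eig(f, cand)
    # tract direction: eigenvector with smallest |curvature| (FA changes
    # least along the tract); the other two span the cross-tract plane
    order = np.argsort(np.abs(evals), axis=1)
    rows = np.arange(cand.shape[0])[:, None]
    tract = evecs[rows, :, order[:, 0:1]][:, 0, :]
    perp1 = evecs[rows, :, order[:, 1:2]][:, 0, :]
    perp2 = evecs[rows, :, order[:, 2:3]][:, 0, :]
    ridge = evals[:, 0] < 0  # genuinely negative principal curvature

    # centre-of-tract criterion: discrete local maximum against every
    # 26-neighbour except those within 45 degrees of the tract direction
    # (along-tract variation must not veto a cross-tract ridge)
    fpad = np.pad(f, 1, mode="edge")
    centre = f[tuple(cand.T)]
    keep = ridge.copy()
    eps = 1e-12
    offsets = np.array(
        [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ],
        dtype=float,
    )
    unit = offsets / np.linalg.norm(offsets, axis=1, keepdims=True)
    align = np.abs(unit @ tract.T)  # (26, N) |cos| to tract direction
    cos45 = np.cos(np.pi / 4.0) + 1e-9
    for o, ou, al in zip(offsets.astype(int), unit, align):
        nb = fpad[tuple((cand + 1 + o).T)]
        test = al <= cos45  # neighbour lies off the tract cone
        keep &= ~test | (centre + eps >= nb)
    if not keep.any():
        raise ValueError("skeletonization produced no voxels; review thresholds")
    return Skeleton(
        voxels=cand[keep],
        tract_dir=tract[keep],
        perp1=perp1[keep],
        perp2=perp2[keep],
        mean_fa=mean_fa.data[tuple(cand[keep].T)],
        grid_shape=mean_fa.shape,
        affine=mean_fa.affine,
    )


def _sample_at(volume: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(volume, coords, order=1, mode="grid-constant", cval=0.0)


def project_to_skeleton(
    subject_fa: VolumetricImage, skeleton: Skeleton, search_radius: float = 3.0
) -> ProjectionRecord:
    """Project a subject's normalised FA onto the skeleton.

    For each skeleton voxel the maximum FA within ``search_radius`` voxels
    in the cross-tract plane is recorded together with its source voxel;
    ties are broken toward the skeleton voxel (samples are visited in
    order of increasing distance and replaced only on strict improvement).
    """
    if search_radius < 1:
        raise ValueError("search radius must be at least 1 voxel")
    if subject_fa.shape != skeleton.grid_shape:
        raise ValueError("subject FA must live on the skeleton's template grid")
    n = len(skeleton)
    angles = np.arange(8) * (np.pi / 8.0)
    radii = np.arange(0.5, search_radius + 1e-9, 0.5)
    # offsets ordered by increasing |r| so the nearest max wins ties
    offs = [np.zeros((1, n, 3))]
    for r in radii:
        for a in angles:
            d = np.cos(a) * skeleton.perp1 + np.sin(a) * skeleton.perp2
            offs.append((r * d)[None])
            offs.append((-r * d)[None])
    offsets = np.concatenate(offs, axis=0)  # (S, N, 3)
    pts = skeleton.voxels[None].astype(float) + offsets
    vals = _sample_at(subject_fa.data, pts.reshape(-1, 3).T).reshape(
        offsets.shape[0], n
    )
    best = np.zeros(n, dtype=int)
    best_val = vals[0].copy()
    for s in range(1, vals.shape[0]):
        better = vals[s] > best_val
        best[better] = s
        best_val[better] = vals[s][better]
    src = pts[best, np.arange(n)]
    src = np.clip(
        np.rint(src).astype(int), 0, np.asarray(skeleton.grid_shape) - 1
    )
    return ProjectionRecord(values=best_val, source_vox=src, search_radius=search_radius)


def skeleton_paired_test(
    records_orig,
    records_flipped,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    alpha: float = 0.05,
    seed: int = 0,
) -> SkeletonTestResult:
    """Paired t-test on the skeleton with sign-flip max-statistic
    familywise correction (one-sided, left-greater-than-right).

    Permutation p-values lie in [1/(n_perm+1), 1]; a voxel is significant
    when its corrected p is at most alpha and its t is positive.
    """
    if len(records_orig) != len(records_flipped):
        raise ValueError("paired record lists must have equal length")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse null")
    x = np.stack([r.values for r in records_orig])
    y = np.stack([r.values for r in records_flipped])
    d = x - y  # (n_subj, n_vox)
    ns = d.shape[0]
    t_obs = _paired_t(d.mean(axis=0), (d * d).sum(axis=0), ns)

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_permutations, ns))
    ssq = (d * d).sum(axis=0)  # invariant under sign flips
    means = signs @ d / ns
    t_perm = _paired_t(means, ssq[None, :], ns)
    max_t = t_perm.max(axis=1)
    p_fwe = (1 + (max_t[:, None] >= t_obs[None, :]).sum(axis=0)) / (
        n_permutations + 1
    )
    significant = (p_fwe <= alpha) & (t_obs > 0)
    return SkeletonTestResult(significant=significant, t=t_obs, p_fwe=p_fwe, alpha=alpha)


def _paired_t(mean, ssq, n):
    var = (ssq - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t = np.asarray(t)
    t[~np.isfinite(t)] = 0.0
    return t


def thicken_tbss_mask(
    records,
    significant: np.ndarray,
    skeleton: Skeleton,
    threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
) -> ThickenedMask:
    """Back-project significant skeleton voxels into each subject and
    threshold the group-mean occupancy probability (strictly > threshold).

    ``records`` are the per-subject projection records used in the test;
    each significant skeleton voxel marks its per-subject source voxel.
    An empty significant set yields a valid, flagged, empty mask.
    """
    significant = np.asarray(significant, dtype=bool)
    prob = np.zeros(skeleton.grid_shape, dtype=np.float64)
    nsub = len(records)
    if nsub == 0:
        raise ValueError("need at least one projection record")
    if significant.any():
        for rec in records:
            m = np.zeros(skeleton.grid_shape, dtype=np.float64)
            src = rec.source_vox[significant]
            m[tuple(src.T)] = 1.0
            prob += m
        prob /= nsub
    mask = BinaryMask(
        (prob > threshold).astype(np.uint8), skeleton.affine, f"tbss-thick>{threshold}"
    )
    return ThickenedMask(
        mask=mask, probability=prob, threshold=threshold, empty=not significant.any()
    )
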