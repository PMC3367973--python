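"""Misregistration quantification from binary FA masks.

After spatial normalisation, an FA mask (FA strictly above a threshold)
is free of microstructural information and reflects only morphology, so
residual between-subject or between-hemisphere mask disagreement measures
misregistration.  This module implements:

* ``kappa_overlap`` - weighted overlap between an FA-VBS statistical mask
  and the thickened skeleton-statistics mask (fraction of FA-VBS findings
  confirmed by the skeleton reference);
* ``mask_variance`` / ``symmetrize_variance`` - voxelwise unbiased sample
  variance of the per-subject masks, and its left+right hemispheric sum;
* ``f_ratio_map`` / ``f_critical`` / ``normalized_f_sum`` - variance-ratio
  (F) maps between registration approaches, the critical F quantile, and
  the normalized sum of suprathreshold F values;
* ``hemispheric_kappa`` - per-approach left/right overlap coefficient
  kappa_thr from subject-wise difference and intersection maps;
* ``count_f_voxels`` / ``count_diff_voxels`` - the voxel-count diagnostics
  N^F (voxels susceptible to misregistration relative to the reference
  approach) and N^Diff (FA-VBS findings absent from the skeleton mask).

All thresholds are strict inequalities (mask > thr, F > F_c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .register import RegistrationConfig, apply_transform, nonlinear_register
from .volio import BinaryMask, VolumetricImage, is_flip_closed, world_x_coordinates

__all__ = [
    "VarianceMap",
    "FMap",
    "MisregSummary",
    "subject_fa_mask",
    "map_stats_to_reference",
    "kappa_overlap",
    "mask_variance",
    "symmetrize_variance",
    "f_ratio_map",
    "f_critical",
    "normalized_f_sum",
    "hemispheric_kappa",
    "count_f_voxels",
    "count_diff_voxels",
]

FA_MASK_THRESHOLDS = (0.2, 0.3, 0.4, 0.5)
# x/0 voxels (misregistration present in m, absent in n) are capped here.
# Finite F ratios of binary-mask variances are bounded by ~N_S^2/4(N_S-1),
# so this sentinel is far above any attainable finite value.
F_INF_SENTINEL = 1e3


@dataclass(eq=False)
class VarianceMap:
    """Voxelwise variance of registered FA masks over subjects."""

    data: np.ndarray
    affine: np.ndarray
    n_subjects: int
    symmetrized: bool = False


@dataclass(eq=False)
class FMap:
    """Voxelwise variance ratio F_{m/n} between two approaches."""

    data: np.ndarray
    affine: np.ndarray
    numerator: str
    denominator: str
    n_subjects: int

    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.data))


@dataclass(eq=False)
class MisregSummary:
    """Collected diagnostics for a set of registration approaches."""

    kappa: dict = field(default_factory=dict)  # approach -> kappa_m (or per thr)
    kappa_thr: dict = field(default_factory=dict)  # approach -> {thr: value}
    normalized_f: dict = field(default_factory=dict)  # "m/n" -> value
    n_f: dict = field(default_factory=dict)  # approach -> N^F
    n_diff: dict = field(default_factory=dict)  # approach -> N^Diff


def subject_fa_mask(
    fa_norm: VolumetricImage, thr: float = 0.2, external_mask: BinaryMask | None = None
) -> BinaryMask:
    """FA mask M_k^m: normalised FA strictly above ``thr``, optionally
    restricted to an external analysis FA mask."""
    m = fa_norm.data > thr
    if external_mask is not None:
        m = m & (external_mask.data > 0)
    return BinaryMask(m.astype(np.uint8), fa_norm.affine, f"fa>{thr}")


def map_stats_to_reference(
    stat_mask: BinaryMask,
    template_m: VolumetricImage,
    template_ref: VolumetricImage,
    config: RegistrationConfig | None = None,
) -> BinaryMask:
    """Transport a statistical mask from approach space to reference space.

    The deformation is estimated by registering the approach's customized
    template to the reference-space template, then applied to the mask
    with nearest-neighbour resampling (mask stays binary).  When the two
    templates coincide (self-contained synthetic runs) the mapping is the
    identity.
    """
    if template_m.same_grid(template_ref) and np.allclose(
        template_m.data, template_ref.data, atol=1e-9
    ):
        return BinaryMask(stat_mask.data.copy(), stat_mask.affine, stat_mask.provenance)
    result = nonlinear_register(template_m, template_ref, None, config)
    moved = apply_transform(
        stat_mask.as_image(), None, result.warp, order="nearest"
    )
    return BinaryMask(
        (moved.data > 0.5).astype(np.uint8), template_ref.affine, stat_mask.provenance
    )


def kappa_overlap(b_mask: BinaryMask, thick_mask: BinaryMask, mode: str = "fraction"):
    """Weighted overlap kappa_m between the FA-VBS mask B_m and the
    thickened skeleton mask T.

    ``fraction`` mode (default): |B_m and T| / |B_m| - the fraction of
    FA-VBS findings confirmed by the skeleton reference; 1 means every
    FA-VBS voxel lies inside T, 0 means the masks are disjoint.
    ``jaccard`` mode normalizes by |B_m or T| instead.
    Returns None (flagged missing) when B_m is empty.
    """
    if b_mask.shape != thick_mask.shape:
        raise ValueError("masks must share a grid")
    b = b_mask.data > 0
    t = thick_mask.data > 0
    nb = int(b.sum())
    if nb == 0:
        return None
    inter = int((b & t).sum())
    if mode == "fraction":
        return inter / nb
    if mode == "jaccard":
        union = int((b | t).sum())
        return inter / union
    raise ValueError("mode must be 'fraction' or 'jaccard'")


def mask_variance(masks) -> VarianceMap:
    """Voxelwise unbiased sample variance of subject FA masks.

    For binary inputs this equals p*(1-p) * N_S/(N_S-1) with p the
    voxelwise occupancy fraction.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 subjects")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError("masks must share a grid")
    stack = np.stack([np.asarray(m.data, dtype=np.float64) for m in masks])
    var = stack.var(axis=0, ddof=1)
    return VarianceMap(var, masks[0].affine, n_subjects=len(masks))


def symmetrize_variance(vmap: VarianceMap) -> VarianceMap:
    """V_sym(x,y,z) = V(x,y,z) + V(-x,y,z): hemispheric sum of variances."""
    if not is_flip_closed(vmap.data.shape, vmap.affine):
        raise ValueError("variance map grid is not flip-closed")
    vs = vmap.data + vmap.data[::-1, :, :]
    return VarianceMap(vs, vmap.affine, vmap.n_subjects, symmetrized=True)


def f_ratio_map(v_m: VarianceMap, v_n: VarianceMap, name_m="m", name_n="n") -> FMap:
    """Voxelwise ratio of two (symmetrized) variance maps.

    0/0 voxels are set to 0 and excluded from the nonzero support; x/0
    voxels with x > 0 are capped at a large sentinel and always count as
    suprathreshold.
    """
    if v_m.data.shape != v_n.data.shape:
        raise ValueError("variance maps must share a grid")
    if v_m.n_subjects != v_n.n_subjects:
        raise ValueError("variance maps must come from the same cohort size")
    num = v_m.data
    den = v_n.data
    out = np.zeros_like(num)
    both = den > 0
    out[both] = num[both] / den[both]
    out[(den == 0) & (num > 0)] = F_INF_SENTINEL
    return FMap(out, v_m.affine, name_m, name_n, v_m.n_subjects)


def f_critical(df1: int, df2: int, p: float) -> float:
    """Upper-p critical value of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not (0 < p < 1):
        raise ValueError("p must lie in (0, 1)")
    return float(stats.f.isf(p, df1, df2))


def normalized_f_sum(fmap: FMap, f_c: float) -> float:
    """Sum of F values strictly above F_c, divided by the number of
    nonzero voxels of the F map.  Undefined (None) without nonzero
    support."""
    nz = fmap.nonzero_count()
    if nz == 0:
        return None
    supra = fmap.data[fmap.data > f_c]
    return float(supra.sum() / nz)


def hemispheric_kappa(
    subject_masks, mode: str = "ratio"
) -> float:
    """Left/right overlap coefficient kappa_thr for one approach.

    Each subject's FA mask is split at the midline; the right half is
    mirrored onto the left half-grid.  Delta_k = |L_k - R_k| marks voxels
    covered by exactly one hemisphere, I_k = L_k * R_k voxels covered by
    both.  With group means Delta-bar and I-bar,

        kappa = sum(I-bar) / (sum(I-bar) + sum(Delta-bar))

    which is 1 for perfectly mirror-symmetric masks (no misregistration)
    and 0 when the mirrored hemispheres never overlap.  ``mode='dice'``
    uses 2*sum(I-bar) / (2*sum(I-bar) + sum(Delta-bar)) instead.
    The midline column (its own mirror image) is excluded.
    """
    if len(subject_masks) < 1:
        raise ValueError("need at least 1 subject mask")
    shape = subject_masks[0].shape
    affine = subject_masks[0].affine
    if not is_flip_closed(shape, affine):
        raise ValueError("masks must live on a flip-closed grid")
    xs = world_x_coordinates(shape, affine)
    tol = 1e-6 * max(1.0, float(np.abs(xs).max()))
    left_cols = np.where(xs < -tol)[0]
    d_sum = np.zeros((left_cols.size,) + shape[1:])
    i_sum = np.zeros_like(d_sum)
    for m in subject_masks:
        data = np.asarray(m.data, dtype=np.float64)
        flipped = data[::-1, :, :]
        L = data[left_cols, :, :]
        R = flipped[left_cols, :, :]
        d_sum += np.abs(L - R)
        i_sum += L * R
    n = len(subject_masks)
    d_bar = d_sum / n
    i_bar = i_sum / n
    si, sd = float(i_bar.sum()), float(d_bar.sum())
    if si + sd == 0:
        return None
    if mode == "ratio":
        return si / (si + sd)
    if mode == "dice":
        return 2 * si / (2 * si + sd)
    raise ValueError("mode must be 'ratio' or 'dice'")


def count_f_voxels(fmap: FMap, f_c: float) -> int:
    """N^F: number of voxels with F strictly above the critical value."""
    return int(np.count_nonzero(fmap.data > f_c))


def count_diff_voxels(b_mask: BinaryMask, thick_mask: BinaryMask) -> int:
    """N^Diff: FA-VBS voxels not present in the thickened skeleton mask."""
    if b_mask.shape != thick_mask.shape:
        raise ValueError("masks must share a grid")
    return int(np.count_nonzero((b_mask.data > 0) & (thick_mask.data == 0)))
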