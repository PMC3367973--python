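"""Synthetic FA/b0 phantom cohorts with known ground truth.

The phantom emulates the data configuration of a hemispheric-asymmetry
study: a left-right symmetric brain (ellipsoid) containing high-FA tube
"tracts" on a low-FA background, and a complementary-contrast b0 volume
(bright CSF ventricles, near-uniform mid-intensity parenchyma, dark
exterior) whose poor interior white-matter contrast reproduces the known
weakness of b0-driven registration in central WM.

Subjects are generated from the template by a smooth random low-frequency
cosine-basis warp (the same family the registration engine estimates, so
recovery is well-posed), a small random affine jitter, an optional
systematic left-hemisphere shape bias, an optional seeded left>right FA
increment inside one tract, and additive Gaussian noise clipped to the
valid FA range.  Every piece of ground truth (dense displacement field,
affine, asymmetry mask) is stored on the sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .register import (
    DctWarp,
    affine_matrix_from_params,
    displacement_field,
)
from .volio import (
    BinaryMask,
    VolumetricImage,
    flip_lr,
    make_grid_affine,
    write_volume,
)

__all__ = [
    "Tube",
    "PhantomSpec",
    "SubjectSample",
    "generate_symmetric_template",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
]


@dataclass(eq=False)
class Tube:
    """A straight tube tract primitive: world-mm segment + radius + FA."""

    p0: tuple
    p1: tuple
    radius_mm: float
    fa: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fa <= 1.0):
            raise ValueError("tube FA must be in [0, 1]")
        if self.radius_mm <= 0:
            raise ValueError("tube radius must be positive")


@dataclass(eq=False)
class PhantomSpec:
    """Study conditions for a synthetic cohort.

    The x dimension of ``grid_shape`` must be odd so the midline voxel
    column lies exactly on the world x = 0 symmetry plane.
    """

    grid_shape: tuple = (49, 57, 49)
    voxel_size_mm: float | tuple = 3.0
    tract_set: list | None = None  # None -> default brain-like tract set
    background_fa: float = 0.05
    b0_contrast: dict = field(
        default_factory=lambda: {"csf": 1.0, "gm": 0.6, "wm": 0.6, "background": 0.05}
    )
    asymmetry_roi: tuple | None = None  # (tract index, delta FA on left copy)
    texture_amplitude: float = 0.08  # parenchymal FA variation (identifiability)
    texture_scale_mm: float = 10.0
    warp_amplitude_mm: float = 2.0
    hemi_shape_bias_mm: float = 0.0
    affine_jitter_mm: float = 0.8
    affine_jitter_rad: float = 0.005
    affine_jitter_scale: float = 0.01
    noise_sigma: float = 0.02
    seed: int = 0
    hard_mode: bool = False  # sample warp frequencies beyond the registration basis

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if self.grid_shape[0] % 2 == 0:
            raise ValueError(
                "grid x dimension must be odd (midline column convention)"
            )
        if not (0.0 <= self.background_fa <= 0.15):
            raise ValueError("background_fa must be in [0, 0.15]")
        if self.warp_amplitude_mm < 0 or self.noise_sigma < 0:
            raise ValueError("warp amplitude and noise sigma must be >= 0")
        if self.asymmetry_roi is not None:
            idx, dfa = self.asymmetry_roi
            if dfa < 0:
                raise ValueError("asymmetry delta FA must be >= 0")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.voxel_size_mm, dtype=float), (3,)
        ).copy()

    @property
    def affine(self) -> np.ndarray:
        return make_grid_affine(self.grid_shape, self.voxel_size)

    @property
    def half_extent(self) -> np.ndarray:
        """Half field of view per axis in mm."""
        return (np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size

    def tracts(self) -> list:
        if self.tract_set is not None:
            return list(self.tract_set)
        return default_tract_set(self)


def default_tract_set(spec: PhantomSpec) -> list:
    """Brain-like default tracts, scaled to the field of view.

    Tube 0: a superior-inferior projection-like bundle in the left
    hemisphere (mirrored by template symmetrization); tube 1: an
    anterior-posterior association-like bundle; tube 2: a left-right
    commissural bundle crossing the midline.
    """
    ex, ey, ez = spec.half_extent
    r = max(2.8 * float(np.mean(spec.voxel_size)), 0.12 * min(ex, ey, ez))
    return [
        Tube((-0.40 * ex, -0.10 * ey, -0.55 * ez), (-0.40 * ex, 0.00, 0.55 * ez), r, 0.70),
        Tube((-0.42 * ex, -0.55 * ey, 0.25 * ez), (-0.42 * ex, 0.55 * ey, 0.25 * ez), r, 0.60),
        Tube((-0.55 * ex, 0.15 * ey, 0.40 * ez), (0.55 * ex, 0.15 * ey, 0.40 * ez), r, 0.65),
    ]


@dataclass(eq=False)
class SubjectSample:
    """One synthetic subject: FA + b0 volumes plus full ground truth."""

    fa: VolumetricImage
    b0: VolumetricImage
    true_warp: np.ndarray  # dense displacement, (3, nx, ny, nz), mm
    true_affine: np.ndarray  # 4x4 jitter matrix (subject world -> template world domain)
    asym_mask: BinaryMask


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


def _world_grids(spec: PhantomSpec):
    aff = spec.affine
    idx = [np.arange(n, dtype=float) for n in spec.grid_shape]
    wx = aff[0, 0] * idx[0] + aff[0, 3]
    wy = aff[1, 1] * idx[1] + aff[1, 3]
    wz = aff[2, 2] * idx[2] + aff[2, 3]
    return np.meshgrid(wx, wy, wz, indexing="ij")


def _brain_mask(spec: PhantomSpec, wx, wy, wz) -> np.ndarray:
    ax, ay, az = 0.84 * spec.half_extent
    return (wx / ax) ** 2 + (wy / ay) ** 2 + (wz / az) ** 2 <= 1.0


def _tube_distance(tube: Tube, wx, wy, wz) -> np.ndarray:
    """Distance (mm) from each voxel to the tube's axis segment."""
    p0 = np.asarray(tube.p0, dtype=float)
    p1 = np.asarray(tube.p1, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 <= 0:
        raise ValueError("degenerate tube segment")
    vx, vy, vz = wx - p0[0], wy - p0[1], wz - p0[2]
    t = (vx * d[0] + vy * d[1] + vz * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    qx = vx - t * d[0]
    qy = vy - t * d[1]
    qz = vz - t * d[2]
    return np.sqrt(qx**2 + qy**2 + qz**2)


def _tube_mask(tube: Tube, wx, wy, wz) -> np.ndarray:
    return _tube_distance(tube, wx, wy, wz) <= tube.radius_mm


def _tube_profile(tube: Tube, wx, wy, wz) -> np.ndarray:
    """Radial FA weighting: 1 on the axis, cosine taper to 0 at the tube
    radius.  FA is highest at the tract core, as in real white matter,
    which gives the skeletonization a well-defined ridge while keeping a
    broad high-FA core so FA masks at every analysis threshold (0.2-0.5)
    retain non-trivial support."""
    rho = _tube_distance(tube, wx, wy, wz)
    return np.where(
        rho <= tube.radius_mm, np.cos(0.5 * np.pi * rho / tube.radius_mm), 0.0
    )


def generate_symmetric_template(
    spec: PhantomSpec,
) -> tuple[VolumetricImage, VolumetricImage]:
    """Build the exactly flip-symmetric FA and b0 template pair.

    Symmetry is enforced by taking the voxelwise maximum of the
    constructed volume and its left-right mirror, which preserves tube
    interiors exactly (a tube placed in one hemisphere simply appears in
    both).
    """
    wx, wy, wz = _world_grids(spec)
    brain = _brain_mask(spec, wx, wy, wz)
    he = spec.half_extent
    fa = np.where(brain, spec.background_fa, 0.0)
    if spec.texture_amplitude > 0:
        # smooth, flip-symmetric parenchymal FA variation: real FA images
        # carry structure throughout the brain, which is what makes a
        # deformation identifiable away from the major tracts
        from scipy import ndimage as _ndi

        trng = np.random.default_rng(np.random.SeedSequence(
            entropy=int(spec.seed), spawn_key=(97,)
        ))
        g = _ndi.gaussian_filter(
            trng.standard_normal(spec.grid_shape),
            spec.texture_scale_mm / spec.voxel_size / 2.355,
        )
        g = 0.5 * (g + g[::-1, :, :])
        g = g / max(g.std(), 1e-12)
        fa = np.where(
            brain,
            np.clip(fa + spec.texture_amplitude * g, 0.01, 0.19),
            0.0,
        )
    for tube in spec.tracts():
        for p in (tube.p0, tube.p1):
            if np.any(np.abs(np.asarray(p, dtype=float)) > he + 1e-9):
                raise ValueError(
                    f"tube endpoint {p} lies outside the grid field of view "
                    f"(half extents {he})"
                )
        w = _tube_profile(tube, wx, wy, wz) * brain
        fa = np.maximum(fa, spec.background_fa + (tube.fa - spec.background_fa) * w)
        fa = np.where(brain, fa, 0.0)

    c = spec.b0_contrast
    b0 = np.where(brain, c["gm"], c["background"])
    # two mirrored ventricle-like bright CSF blobs near the centre
    ex, ey, ez = he
    for sx in (-1.0, 1.0):
        vent = (
            ((wx - sx * 0.18 * ex) / (0.14 * ex)) ** 2
            + ((wy + 0.05 * ey) / (0.30 * ey)) ** 2
            + ((wz - 0.15 * ez) / (0.18 * ez)) ** 2
        ) <= 1.0
        b0 = np.where(vent & brain, c["csf"], b0)
    # white matter compartment: tubes get the WM b0 level (deliberately
    # close to GM, i.e. poor interior contrast)
    for tube in spec.tracts():
        m = _tube_mask(tube, wx, wy, wz) & brain
        b0 = np.where(m, c["wm"], b0)

    aff = spec.affine
    fa_img = VolumetricImage(fa, aff, "template")
    b0_img = VolumetricImage(b0, aff, "template")
    fa_img = fa_img.copy_with(np.maximum(fa_img.data, flip_lr(fa_img).data))
    b0_img = b0_img.copy_with(np.maximum(b0_img.data, flip_lr(b0_img).data))
    return fa_img, b0_img


def asymmetry_roi_mask(spec: PhantomSpec) -> BinaryMask:
    """Template-space mask of the seeded left>right FA increment region."""
    if spec.asymmetry_roi is None:
        return BinaryMask(np.zeros(spec.grid_shape, dtype=np.uint8), spec.affine, "asym:none")
    idx, _dfa = spec.asymmetry_roi
    tracts = spec.tracts()
    if not (0 <= idx < len(tracts)):
        raise ValueError("asymmetry_roi tract index out of range")
    wx, wy, wz = _world_grids(spec)
    brain = _brain_mask(spec, wx, wy, wz)
    tube = tracts[idx]
    m = _tube_mask(tube, wx, wy, wz) & brain
    mirr = m[::-1, :, :]
    left = wx < -1e-9  # strictly left of the midline column
    roi = (m | mirr) & left
    return BinaryMask(roi.astype(np.uint8), spec.affine, f"asym:tract{idx}")


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------


def _random_warp_coeffs(rng, dims) -> np.ndarray:
    c = rng.standard_normal((3,) + tuple(dims))
    # damp the highest frequencies a little so fields stay brain-like
    for ax, k in enumerate(dims):
        w = 1.0 / (1.0 + np.arange(k))
        shape = [1, 1, 1, 1]
        shape[ax + 1] = k
        c = c * w.reshape(shape)
    return c


def _hemi_bias_field(spec: PhantomSpec) -> np.ndarray:
    """Systematic, smooth left-hemisphere displacement (mm), identical for
    every subject; produces a reproducible left-vs-right shape difference.

    The bump is centred on the left projection tract and decays well
    before the brain boundary, mimicking an interior anatomical asymmetry
    (deep white matter shape) that carries no signature in the b0
    boundary/ventricle contrast but is visible to FA-driven registration.
    """
    u = np.zeros((3,) + spec.grid_shape)
    if spec.hemi_shape_bias_mm == 0:
        return u
    wx, wy, wz = _world_grids(spec)
    ex, ey, ez = spec.half_extent
    bump = np.exp(
        -((wx + 0.40 * ex) ** 2) / (2 * (0.24 * ex) ** 2)
        - ((wy + 0.05 * ey) ** 2) / (2 * (0.45 * ey) ** 2)
        - (wz**2) / (2 * (0.45 * ez) ** 2)
    )
    u[0] = spec.hemi_shape_bias_mm * bump
    u[2] = 0.4 * spec.hemi_shape_bias_mm * bump
    return u


def _jacobian_ok(u: np.ndarray, voxel_size) -> bool:
    """Check det(I + du/dx) > 0 everywhere (warp invertibility)."""
    vs = np.asarray(voxel_size, dtype=float)
    J = np.empty(u.shape[1:] + (3, 3))
    for a in range(3):
        g = np.gradient(u[a], *vs)
        for b in range(3):
            J[..., a, b] = g[b]
    J += np.eye(3)
    return bool(np.linalg.det(J).min() > 0)


def generate_subject(
    template_fa: VolumetricImage,
    template_b0: VolumetricImage,
    spec: PhantomSpec,
    subject_seed,
    on_bad_jacobian: str = "resample",
) -> SubjectSample:
    """Deform the template pair into one synthetic subject.

    The FA asymmetry increment (if any) is applied to the left ROI before
    warping; the identical warp + affine jitter is applied to FA and b0;
    additive Gaussian noise is drawn last and FA is clipped to [0, 1].
    Fully reproducible given ``subject_seed``.
    """
    rng = np.random.default_rng(subject_seed)
    grid = spec.grid_shape
    vs = spec.voxel_size
    aff = spec.affine

    fa0 = template_fa.data.copy()
    roi = asymmetry_roi_mask(spec)
    if spec.asymmetry_roi is not None:
        _idx, dfa = spec.asymmetry_roi
        fa0 = np.clip(fa0 + dfa * roi.data, 0.0, 1.0)
    fa_src = template_fa.copy_with(fa0)

    warp_dims = (9, 11, 9) if spec.hard_mode else (4, 5, 4)
    bias = _hemi_bias_field(spec)
    for attempt in range(6):
        coeffs = _random_warp_coeffs(rng, warp_dims)
        warp = DctWarp(coeffs[0], coeffs[1], coeffs[2], grid, aff)
        u = displacement_field(warp)
        peak = float(np.abs(u).max())
        if spec.warp_amplitude_mm == 0 or peak == 0:
            u = np.zeros_like(u)
            warp = DctWarp.zero(grid, aff, warp_dims)
        else:
            scale = spec.warp_amplitude_mm / peak
            u = u * scale
            warp = DctWarp(
                coeffs[0] * scale, coeffs[1] * scale, coeffs[2] * scale, grid, aff
            )
        u_total = u + bias
        if _jacobian_ok(u_total, vs):
            break
        if on_bad_jacobian == "error":
            raise ValueError("sampled warp has non-positive Jacobian")
    else:
        raise ValueError("could not sample an invertible warp in 6 attempts")

    # affine jitter (small; recovered later by the affine pre-registration)
    p = np.zeros(12)
    p[0:3] = rng.normal(0.0, 1.0, 3) * spec.affine_jitter_mm
    p[3:6] = rng.normal(0.0, 1.0, 3) * spec.affine_jitter_rad
    p[6:9] = 1.0 + rng.normal(0.0, 1.0, 3) * spec.affine_jitter_scale
    jitter = affine_matrix_from_params(p)

    # pull-back: subject(v) = template(A^-1 M (A v + u_total(v)))
    fa_img = _pullback(fa_src, jitter, u_total, aff, grid)
    b0_img = _pullback(template_b0, jitter, u_total, aff, grid)

    if spec.noise_sigma > 0:
        fa_img = fa_img.copy_with(
            np.clip(fa_img.data + rng.normal(0, spec.noise_sigma, grid), 0.0, 1.0)
        )
        b0_img = b0_img.copy_with(
            np.clip(b0_img.data + rng.normal(0, spec.noise_sigma, grid), 0.0, None)
        )
    else:
        fa_img = fa_img.copy_with(np.clip(fa_img.data, 0.0, 1.0))

    fa_img.space_tag = "native"
    b0_img.space_tag = "native"
    return SubjectSample(
        fa=fa_img,
        b0=b0_img,
        true_warp=u_total,
        true_affine=jitter,
        asym_mask=roi,
    )


def _pullback(img: VolumetricImage, m: np.ndarray, u: np.ndarray, aff, grid):
    from scipy import ndimage

    idx = np.stack(
        np.meshgrid(*(np.arange(n, dtype=float) for n in grid), indexing="ij")
    )
    world = np.einsum("ab,bxyz->axyz", aff[:3, :3], idx) + aff[:3, 3].reshape(
        3, 1, 1, 1
    )
    world = world + u
    world = np.einsum("ab,bxyz->axyz", m[:3, :3], world) + m[:3, 3].reshape(3, 1, 1, 1)
    inv = np.linalg.inv(aff)
    vox = np.einsum("ab,bxyz->axyz", inv[:3, :3], world) + inv[:3, 3].reshape(
        3, 1, 1, 1
    )
    out = ndimage.map_coordinates(img.data, vox, order=1, mode="grid-constant", cval=0.0)
    return VolumetricImage(out, np.asarray(aff), img.space_tag)


def generate_cohort(
    spec: PhantomSpec, n_subjects: int, seed: int | None = None
) -> tuple[list[SubjectSample], dict]:
    """Generate a cohort plus a ground-truth manifest.

    Per-subject seeds are spawned deterministically from the master seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (variance undefined below)")
    master = spec.seed if seed is None else seed
    fa_t, b0_t = generate_symmetric_template(spec)
    subjects = []
    manifest: dict = {
        "seed": int(master),
        "n_subjects": int(n_subjects),
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": list(map(float, spec.voxel_size)),
        "warp_amplitude_mm": float(spec.warp_amplitude_mm),
        "hemi_shape_bias_mm": float(spec.hemi_shape_bias_mm),
        "noise_sigma": float(spec.noise_sigma),
        "asymmetry_roi": None
        if spec.asymmetry_roi is None
        else [int(spec.asymmetry_roi[0]), float(spec.asymmetry_roi[1])],
        "subjects": [],
    }
    for k in range(n_subjects):
        sseq = np.random.SeedSequence(entropy=int(master), spawn_key=(k,))
        subj = generate_subject(fa_t, b0_t, spec, sseq)
        subjects.append(subj)
        manifest["subjects"].append(
            {
                "index": k,
                "max_displacement_mm": float(np.abs(subj.true_warp).max()),
                "affine_translation_mm": subj.true_affine[:3, 3].tolist(),
            }
        )
    return subjects, manifest


def write_cohort(subjects, manifest, out_dir) -> None:
    """Persist FA/b0 volumes, asymmetry masks and the manifest."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, s in enumerate(subjects):
        write_volume(s.fa, out / f"sub-{k:02d}_fa.nii.gz")
        write_volume(s.b0, out / f"sub-{k:02d}_b0.nii.gz")
        write_volume(s.asym_mask.as_image(), out / f"sub-{k:02d}_asym.nii.gz")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
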