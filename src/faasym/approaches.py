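"""The four spatial-registration approaches for FA asymmetry analysis.

Every subject contributes an FA and a b0 volume.  All subjects are first
affine-registered to a common symmetric b0 reference (the b0 channel
drives the affine; the same transformation is applied to the FA map).
On top of that, four nonlinear strategies are available:

* ``i``   - whole-brain registration driven by the b0 (T2) contrast, no
  selection mask; the estimated warp is applied to the FA map.
* ``ii``  - whole-brain registration driven by the FA contrast, with a
  brain selection mask applied to the source before smoothing.
* ``iii`` - separate-hemisphere FA registration: the left hemisphere is
  registered with the right side zeroed; the volume is then flipped and
  the (mirrored) right hemisphere registered the same way; the output is
  assembled from the two half-registrations with a one-voxel cross-fade
  on the shared midline column.
* ``iv``  - the multi-contrast combination: approach (i) followed by
  approach (iii) on its output.

Each approach builds its own left-right symmetrized customized template
iteratively (module :mod:`faasym.template`) with the same registration it
later applies.  Flipped normalised maps are produced by running the
identical machinery on the mirrored input, preserving the paired design
in which registration error affects both arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .register import (
    RegistrationConfig,
    affine_register,
    apply_transform,
    nonlinear_register,
)
from .template import build_template
from .volio import (
    VolumetricImage,
    flip_lr,
    hemisphere_masks,
    smooth_array,
)

__all__ = [
    "APPROACH_IDS",
    "ApproachConfig",
    "NormalisedSubject",
    "ApproachResult",
    "run_approach",
]

APPROACH_IDS = ("i", "ii", "iii", "iv")


@dataclass(eq=False)
class ApproachConfig:
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    template_tolerance_pct: float = 2.0
    template_max_iters: int = 3
    brain_b0_threshold: float = 0.3  # on 4 mm-smoothed b0 intensity
    include_flipped: bool = True

    def template_registration(self) -> RegistrationConfig:
        """Template construction registers with the base smoothing stage
        only; the half-FWHM refinement is reserved for the final subject
        normalisation (the evolving blurred average carries no detail the
        refinement could lock onto, and a single stage converges)."""
        import dataclasses

        return dataclasses.replace(self.registration, refine=False)


@dataclass(eq=False)
class NormalisedSubject:
    fa_norm: VolumetricImage
    fa_flipped_norm: VolumetricImage | None
    transforms: dict
    approach: str


@dataclass(eq=False)
class ApproachResult:
    approach: str
    subjects: list
    templates: dict  # stage name -> VolumetricImage
    template_builds: dict = field(default_factory=dict)  # stage -> TemplateBuildResult


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _brain_mask_from_b0(b0: VolumetricImage, threshold: float) -> np.ndarray:
    sm = smooth_array(b0.data, 4.0, b0.voxel_size)
    return (sm > threshold).astype(np.float64)


def _affine_stage(cohort, reference_b0: VolumetricImage, config: ApproachConfig):
    """Affine-register every subject's b0 to the reference and transport
    the FA (and b0) onto the reference grid."""
    aligned = []
    for subj in cohort:
        aff = affine_register(subj.b0, reference_b0, config.registration)
        fa_a = apply_transform(
            subj.fa, aff, None, reference_b0.shape, reference_b0.affine
        )
        b0_a = apply_transform(
            subj.b0, aff, None, reference_b0.shape, reference_b0.affine
        )
        fa_a.space_tag = b0_a.space_tag = "reference"
        aligned.append({"fa": fa_a, "b0": b0_a, "affine": aff})
    return aligned


def _register_and_apply(source, template, mask, fa_to_move, config):
    """Nonlinear-register ``source`` to ``template`` and pull the FA map
    through the estimated warp."""
    res = nonlinear_register(source, template, mask, config.registration)
    moved = apply_transform(fa_to_move, None, res.warp)
    return moved, res


# ---------------------------------------------------------------------------
# single-contrast whole-brain machinery (approaches i and ii)
# ---------------------------------------------------------------------------


def _whole_brain_stage(driving, fa_maps, masks, config):
    """Build the symmetrized template from the driving images and return
    per-subject warps (final template-build iteration) plus normalised FA.

    ``driving`` are the contrast volumes steering the registration (b0
    for approach i, FA for approach ii); ``fa_maps`` are transported
    through the same warps; ``masks`` are per-subject selection masks or
    None.
    """
    by_id = {id(img): i for i, img in enumerate(driving)}
    tmpl_cfg = config.template_registration()

    def regfn(img, tmpl):
        i = by_id[id(img)]
        res = nonlinear_register(img, tmpl, masks[i] if masks else None, tmpl_cfg)
        warped = apply_transform(img, None, res.warp)
        return warped, res

    build = build_template(
        driving,
        regfn,
        tolerance_pct=config.template_tolerance_pct,
        max_iters=config.template_max_iters,
    )
    # final normalisation pass against the converged template, with the
    # full (refined) registration settings
    finals = [
        nonlinear_register(img, build.template, masks[i] if masks else None,
                           config.registration)
        for i, img in enumerate(driving)
    ]
    fa_norm = [
        apply_transform(fa, None, res.warp)
        for fa, res in zip(fa_maps, finals)
    ]
    return build, fa_norm, [r.warp for r in finals]


# ---------------------------------------------------------------------------
# separate-hemisphere machinery (approach iii)
# ---------------------------------------------------------------------------


def _mirror_max(image: VolumetricImage) -> VolumetricImage:
    """Full symmetric volume from a half-volume: max of image and mirror."""
    return image.copy_with(np.maximum(image.data, flip_lr(image).data))


def _hemisphere_stage(fa_maps, brain_masks, config):
    """Separate-hemisphere registration of FA volumes.

    The hemisphere template is built from all left hemispheres plus all
    flipped right hemispheres, registered with the left selection mask,
    then mirrored into a full symmetric volume.  Per subject, the left
    registration (warp_L) and the registration of the flipped volume
    (warp_R, i.e. the mirrored right hemisphere) are combined: output
    left half from warp_L, output right half as the mirror of warp_R's
    left half, averaging on the shared midline column.
    """
    grid = fa_maps[0]
    left_hemi, _right = hemisphere_masks(grid.shape, grid.affine)
    lm = left_hemi.data.astype(np.float64)
    halves = []
    hemi_masks = []
    for fa, bm in zip(fa_maps, brain_masks):
        sel = lm * (bm if bm is not None else 1.0)
        halves.append(fa)  # left hemisphere of the original
        hemi_masks.append(sel)
    for fa, bm in zip(fa_maps, brain_masks):
        halves.append(flip_lr(fa))  # mirrored right hemisphere
        hemi_masks.append(lm * (bm[::-1, :, :] if bm is not None else 1.0))

    by_id = {id(img): i for i, img in enumerate(halves)}
    tmpl_cfg = config.template_registration()

    def regfn(img, tmpl):
        i = by_id[id(img)]
        tmpl_left = tmpl.copy_with(tmpl.data * lm)
        res = nonlinear_register(img, tmpl_left, hemi_masks[i], tmpl_cfg)
        warped = apply_transform(img.copy_with(img.data * lm), None, res.warp)
        return warped, res

    def sym_fn(image):
        return _mirror_max(image)

    build = build_template(
        halves,
        regfn,
        tolerance_pct=config.template_tolerance_pct,
        max_iters=config.template_max_iters,
        symmetrize_fn=sym_fn,
    )
    # final pass with the full registration settings
    tmpl_left_final = build.template.copy_with(build.template.data * lm)
    finals = [
        nonlinear_register(img, tmpl_left_final, hemi_masks[i], config.registration)
        for i, img in enumerate(halves)
    ]
    n = len(fa_maps)
    warps_left = [r.warp for r in finals[:n]]
    warps_rightflipped = [r.warp for r in finals[n:]]

    mid = grid.shape[0] // 2
    outputs = []
    outputs_flipped = []
    for fa, wl, wr in zip(fa_maps, warps_left, warps_rightflipped):
        o1 = apply_transform(fa.copy_with(fa.data * lm), None, wl)
        ff = flip_lr(fa)
        o2 = apply_transform(ff.copy_with(ff.data * lm), None, wr)
        outputs.append(_assemble_hemispheres(o1, o2, mid))
        # running the identical machinery on the flipped input registers
        # exactly the same two half-volumes, so its output assembles the
        # same pair with the roles exchanged
        outputs_flipped.append(_assemble_hemispheres(o2, o1, mid))
    return build, outputs, outputs_flipped, warps_left, warps_rightflipped


def _hemisphere_normalize(fa, brain_mask, template, config):
    """Register one volume's two hemispheres to a fixed hemisphere
    template and assemble the normalized output (used for the flipped arm
    of the multi-contrast approach, whose stage-1 outputs are not exact
    mirrors of the originals)."""
    left_hemi, _right = hemisphere_masks(fa.shape, fa.affine)
    lm = left_hemi.data.astype(np.float64)
    mid = fa.shape[0] // 2
    tmpl_left = template.copy_with(template.data * lm)
    sel = lm * (brain_mask if brain_mask is not None else 1.0)
    sel_f = lm * (brain_mask[::-1, :, :] if brain_mask is not None else 1.0)
    res_l = nonlinear_register(fa, tmpl_left, sel, config.registration)
    ff = flip_lr(fa)
    res_r = nonlinear_register(ff, tmpl_left, sel_f, config.registration)
    o1 = apply_transform(fa.copy_with(fa.data * lm), None, res_l.warp)
    o2 = apply_transform(ff.copy_with(ff.data * lm), None, res_r.warp)
    return _assemble_hemispheres(o1, o2, mid)


def _assemble_hemispheres(
    o_left: VolumetricImage, o_rightflipped: VolumetricImage, mid: int
) -> VolumetricImage:
    """Left half from the left registration, right half as the mirror of
    the flipped-volume registration, mean on the shared midline column."""
    mirrored = flip_lr(o_rightflipped).data
    out = np.empty_like(o_left.data)
    out[:mid] = o_left.data[:mid]
    out[mid + 1 :] = mirrored[mid + 1 :]
    out[mid] = 0.5 * (o_left.data[mid] + mirrored[mid])
    return o_left.copy_with(out)


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------


def run_approach(
    cohort,
    approach: str,
    reference_b0: VolumetricImage,
    config: ApproachConfig | None = None,
    stage1_result: "ApproachResult | None" = None,
) -> ApproachResult:
    """Run one registration approach end to end on a cohort.

    ``cohort`` items need ``.fa`` and ``.b0`` volumes (approaches i/iv
    require the b0 channel).  ``reference_b0`` anchors the affine
    pre-registration and defines the template grid; it must be a
    flip-closed symmetric volume.
    """
    if approach not in APPROACH_IDS:
        raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACH_IDS}")
    config = config or ApproachConfig()
    for subj in cohort:
        if getattr(subj, "b0", None) is None:
            raise ValueError("every subject needs a b0 volume (affine anchor)")

    aligned = _affine_stage(cohort, reference_b0, config)
    fa_list = [a["fa"] for a in aligned]
    b0_list = [a["b0"] for a in aligned]
    affines = [a["affine"] for a in aligned]
    brain_masks = [
        _brain_mask_from_b0(b0, config.brain_b0_threshold) for b0 in b0_list
    ]

    templates: dict = {}
    builds: dict = {}

    if approach == "i":
        build, fa_norm, warps = _whole_brain_stage(b0_list, fa_list, None, config)
        templates["b0"] = build.template
        builds["b0"] = build
        fa_flipped = None
        if config.include_flipped:
            fa_flipped = []
            for b0, fa in zip(b0_list, fa_list):
                moved, _ = _register_and_apply(
                    flip_lr(b0), build.template, None, flip_lr(fa), config
                )
                fa_flipped.append(moved)
        subjects = _pack(fa_norm, fa_flipped, affines, warps, "i")
        return ApproachResult("i", subjects, templates, builds)

    if approach == "ii":
        build, fa_norm, warps = _whole_brain_stage(
            fa_list, fa_list, brain_masks, config
        )
        templates["fa"] = build.template
        builds["fa"] = build
        fa_flipped = None
        if config.include_flipped:
            fa_flipped = []
            for fa, bm in zip(fa_list, brain_masks):
                moved, _ = _register_and_apply(
                    flip_lr(fa), build.template, bm[::-1, :, :], flip_lr(fa), config
                )
                fa_flipped.append(moved)
        subjects = _pack(fa_norm, fa_flipped, affines, warps, "ii")
        return ApproachResult("ii", subjects, templates, builds)

    if approach == "iii":
        build, outputs, outputs_flipped, wl, wr = _hemisphere_stage(
            fa_list, brain_masks, config
        )
        templates["fa_hemi"] = build.template
        builds["fa_hemi"] = build
        subjects = [
            NormalisedSubject(
                fa_norm=o,
                fa_flipped_norm=of if config.include_flipped else None,
                transforms={"affine": aff, "warp_left": l, "warp_right_flipped": r},
                approach="iii",
            )
            for o, of, aff, l, r in zip(outputs, outputs_flipped, affines, wl, wr)
        ]
        return ApproachResult("iii", subjects, templates, builds)

    # approach iv: (i) then (iii) on the output volumes of (i)
    reusable = (
        stage1_result is not None
        and stage1_result.approach == "i"
        and (
            not config.include_flipped
            or stage1_result.subjects[0].fa_flipped_norm is not None
        )
    )
    stage1 = stage1_result if reusable else run_approach(cohort, "i", reference_b0, config)
    fa_stage1 = [s.fa_norm for s in stage1.subjects]
    build, outputs, _mirror_flipped, wl, wr = _hemisphere_stage(
        fa_stage1, brain_masks, config
    )
    # the flipped arm went through its own stage-1 registrations, so its
    # hemisphere normalisation is run on those outputs rather than taken
    # as the mirror of the originals
    outputs_flipped = None
    if config.include_flipped:
        outputs_flipped = [
            _hemisphere_normalize(s.fa_flipped_norm, bm, build.template, config)
            for s, bm in zip(stage1.subjects, brain_masks)
        ]
    templates = dict(stage1.templates)
    templates["fa_hemi"] = build.template
    builds = dict(stage1.template_builds)
    builds["fa_hemi"] = build
    subjects = []
    flipped_iter = outputs_flipped if outputs_flipped is not None else [None] * len(outputs)
    for s1, o, of, l, r in zip(stage1.subjects, outputs, flipped_iter, wl, wr):
        subjects.append(
            NormalisedSubject(
                fa_norm=o,
                fa_flipped_norm=of,
                transforms={
                    **s1.transforms,
                    "warp_left": l,
                    "warp_right_flipped": r,
                },
                approach="iv",
            )
        )
    return ApproachResult("iv", subjects, templates, builds)


def _pack(fa_norm, fa_flipped, affines, warps, approach):
    subjects = []
    for k, fa in enumerate(fa_norm):
        subjects.append(
            NormalisedSubject(
                fa_norm=fa,
                fa_flipped_norm=None if fa_flipped is None else fa_flipped[k],
                transforms={"affine": affines[k], "warp": warps[k]},
                approach=approach,
            )
        )
    return subjects
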