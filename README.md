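# faasym

Spatial-registration strategies and misregistration diagnostics for
voxel-based statistics (VBS) of fractional-anisotropy (FA) hemispheric
asymmetry.

Apparent left-right FA differences in a voxelwise group analysis can be
genuine microstructure — or residual *morphological* mismatch left by
imperfect spatial normalisation, concentrated at white-matter edges.
`faasym` is for diffusion-MRI methods researchers who want to study that
confound quantitatively.  It implements four registration strategies
for FA asymmetry analysis, a full misregistration-quantification suite,
a simplified skeleton-based reference analysis, and a synthetic phantom
generator with known ground truth so every claim can be verified
end-to-end.

## What it computes

**Registration** (module `register`): 12-parameter affine plus
small-deformation nonlinear registration with a separable cosine basis,
7 × 9 × 7 lowest-frequency modes per displacement component:

    u_a(x) = Σ_ijk c_a[ijk] · cos(π i t_x) cos(π j t_y) cos(π k t_z),

minimizing smoothed, masked SSD plus a bending-energy penalty, by
Gauss–Newton with a monotone step-halving line search.

**Four normalisation approaches** (module `approaches`), each with its
own iteratively built, left-right symmetrized customized template:
(i) whole-brain driven by the b0/T2 contrast; (ii) whole-brain driven
by FA; (iii) separate-hemisphere FA (left registered with the right
zeroed, then the flipped volume likewise, outputs recombined at the
midline); (iv) the multi-contrast combination (i) → (iii).

**Asymmetry statistics**: a voxelwise paired t-test of normalised
original vs left-right-flipped FA (`vbs`), and a skeleton-restricted
reference analysis with perpendicular max-FA projection, sign-flip
max-statistic permutation testing, and back-projection "thickening"
(`tbss_lite`).

**Misregistration quantification** (module `misreg`): binary FA masks
(FA > thr) carry morphology but no microstructure, so their
disagreement measures registration error —

* voxelwise mask variance V, its hemispheric sum, and F-ratio maps
  `F_{m/n} = V_sym^m / V_sym^n` thresholded at the critical value `F_c`
  of the F distribution (e.g. `F_c = 2.27` for F(17, 17) at p < 0.05);
* normalized sums of suprathreshold F values per approach pair;
* the hemispheric overlap `κ_thr = ΣĪ / (ΣĪ + ΣΔ̄)` from per-subject
  left/right mask intersections Ī and absolute differences Δ̄
  (1 = no misregistration, 0 = no mirror overlap), over FA thresholds
  0.2–0.5;
* the overlap κ between VBS suprathreshold masks and the thickened
  skeleton mask, and the counts N^F (misregistration-prone voxels vs
  the multi-contrast reference) and N^Diff (VBS findings absent from
  the skeleton reference).

## Worked example

Generate a fully reproducible synthetic cohort with a systematic
left-hemisphere shape difference (and no seeded FA asymmetry), register
it with the whole-brain b0 approach (i) and the multi-contrast
separate-hemisphere approach (iv), and compare their hemispheric
misregistration:

```python
from faasym.phantom import PhantomSpec, generate_cohort, generate_symmetric_template
from faasym.approaches import ApproachConfig, run_approach
from faasym.register import RegistrationConfig
from faasym.vbs import group_fa_mask
from faasym.misreg import subject_fa_mask, hemispheric_kappa

spec = PhantomSpec(grid_shape=(33, 39, 33), voxel_size_mm=4.0, hard_mode=True,
                   warp_amplitude_mm=3.0, hemi_shape_bias_mm=5.0,
                   noise_sigma=0.04, seed=1)
cohort, _ = generate_cohort(spec, 6, seed=1)
_, b0_template = generate_symmetric_template(spec)

cfg = ApproachConfig(registration=RegistrationConfig(max_iterations=6),
                     template_max_iters=2, include_flipped=False)
for approach in ("i", "iv"):
    result = run_approach(cohort, approach, b0_template, cfg)
    mask = group_fa_mask([s.fa_norm for s in result.subjects])
    kappa = {
        thr: hemispheric_kappa(
            [subject_fa_mask(s.fa_norm, thr, mask) for s in result.subjects])
        for thr in (0.2, 0.3, 0.4, 0.5)
    }
    print(approach, {t: round(v, 3) for t, v in kappa.items()})
```

This prints (about a minute on one CPU):

```
i {0.2: 0.889, 0.3: 0.815, 0.4: 0.712, 0.5: 0.58}
iv {0.2: 0.961, 0.3: 0.929, 0.4: 0.851, 0.5: 0.749}
```

κ_thr is the fraction of FA-mask voxels whose mirror position is also
in the mask, averaged over subjects: the b0-driven whole-brain
registration (i) cannot see the interior shape asymmetry (the b0 has no
white-matter contrast there) and leaves substantially more hemispheric
misregistration than the multi-contrast separate-hemisphere approach
(iv) at every FA threshold — the central phenomenon this package
exists to study.

A command-line interface mirrors the library
(`faasym phantom make`, `faasym approaches run`, `faasym vbs stats`,
`faasym tbss-lite run`, `faasym misreg summarize`,
`faasym experiment all`); `faasym experiment all --n 8 --seed 1 --out out/`
writes `report.json` / `report.tsv` plus the templates as NIfTI.

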