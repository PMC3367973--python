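"""End-to-end experiment orchestration.

``run_experiment`` generates (or accepts) a synthetic cohort, runs the
requested registration approaches, computes the FA-VBS and skeleton
statistics, and assembles the full misregistration report:

* hemispheric overlap kappa_thr per approach and FA threshold;
* normalized sums of suprathreshold F values per approach pair;
* kappa overlap between each approach's FA-VBS mask and the thickened
  skeleton mask, at the liberal and conservative t thresholds;
* the voxel-count diagnostics N^F (vs the multi-contrast reference
  approach) and N^Diff (FA-VBS findings absent from the skeleton mask).

Everything is deterministic given the master seed: each stage derives its
own RNG stream by hashing the stage name into the seed, so stages can be
re-run independently.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field

import numpy as np

from .approaches import APPROACH_IDS, ApproachConfig, run_approach
from .misreg import (
    MisregSummary,
    count_diff_voxels,
    count_f_voxels,
    f_critical,
    f_ratio_map,
    hemispheric_kappa,
    kappa_overlap,
    mask_variance,
    normalized_f_sum,
    subject_fa_mask,
    symmetrize_variance,
)
from .phantom import PhantomSpec, generate_cohort, generate_symmetric_template
from .tbss_lite import (
    project_to_skeleton,
    skeleton_paired_test,
    skeletonize,
    thicken_tbss_mask,
)
from .template import symmetrize
from .vbs import group_fa_mask, paired_t_map, threshold_stat_map
from .volio import write_volume

__all__ = ["ExperimentConfig", "run_experiment", "validate_report", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1
PAPER_F_CRITICAL = 2.27  # F(17, 17), p < 0.05


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass(eq=False)
class ExperimentConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_subjects: int = 8
    approaches: tuple = APPROACH_IDS
    vbs_thresholds: tuple = (2.6, 3.7)
    fa_mask_thresholds: tuple = (0.2, 0.3, 0.4, 0.5)
    probability_threshold: float = 0.1
    f_c_mode: str = "computed"  # 'computed' (from cohort dof) or 'paper' (2.27)
    n_permutations: int = 2000
    alpha: float = 0.05
    seed: int = 0
    approach_config: ApproachConfig = field(default_factory=ApproachConfig)
    reference_approach: str = "iv"
    skeleton_approach: str = "ii"  # approach whose outputs feed the skeleton analysis
    with_vbs: bool = True  # flipped-arm registrations + t maps (the expensive half)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.approaches:
            raise ValueError("select at least one approach")
        for a in self.approaches:
            if a not in APPROACH_IDS:
                raise ValueError(f"unknown approach {a!r}")
        if self.f_c_mode not in ("computed", "paper"):
            raise ValueError("f_c_mode must be 'computed' or 'paper'")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full synthetic experiment and return the report dict."""
    t_start = time.time()
    timings: dict = {}
    spec = config.phantom
    seed = stage_seed(config.seed, "cohort")

    t0 = time.time()
    cohort, manifest = generate_cohort(spec, config.n_subjects, seed)
    fa_template, b0_template = generate_symmetric_template(spec)
    timings["cohort"] = time.time() - t0

    acfg = config.approach_config
    acfg.include_flipped = config.with_vbs

    results: dict = {}
    stage1 = None
    for app in config.approaches:
        t0 = time.time()
        res = run_approach(cohort, app, b0_template, acfg, stage1_result=stage1)
        if app == "i":
            stage1 = res
        results[app] = res
        timings[f"approach_{app}"] = time.time() - t0

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": int(config.seed),
        "conditions": {
            "n_subjects": config.n_subjects,
            "grid_shape": list(spec.grid_shape),
            "voxel_size_mm": list(map(float, spec.voxel_size)),
            "warp_amplitude_mm": spec.warp_amplitude_mm,
            "hemi_shape_bias_mm": spec.hemi_shape_bias_mm,
            "noise_sigma": spec.noise_sigma,
            "hard_mode": spec.hard_mode,
            "asymmetry_roi": None
            if spec.asymmetry_roi is None
            else [int(spec.asymmetry_roi[0]), float(spec.asymmetry_roi[1])],
            "approaches": list(config.approaches),
        },
        "kappa_thr": {},
        "vbs_counts": {},
        "kappa_vbs": {},
        "normalized_f": {},
        "n_f": {},
        "n_diff": {},
        "convergence": {},
    }

    dof = config.n_subjects - 1
    f_c = (
        PAPER_F_CRITICAL
        if config.f_c_mode == "paper"
        else f_critical(dof, dof, 0.05)
    )
    report["f_critical"] = f_c
    report["f_dof"] = dof

    # --- hemispheric kappa_thr and per-approach variance masks ------------
    t0 = time.time()
    group_masks = {}
    masks_02 = {}
    for app, res in results.items():
        fa_norm = [s.fa_norm for s in res.subjects]
        gmask = group_fa_mask(fa_norm)
        group_masks[app] = gmask
        report["kappa_thr"][app] = {}
        for thr in config.fa_mask_thresholds:
            masks = [subject_fa_mask(s.fa_norm, thr, gmask) for s in res.subjects]
            if thr == 0.2:
                masks_02[app] = masks
            report["kappa_thr"][app][str(thr)] = hemispheric_kappa(masks)
        if 0.2 not in config.fa_mask_thresholds:
            masks_02[app] = [
                subject_fa_mask(s.fa_norm, 0.2, gmask) for s in res.subjects
            ]
        report["convergence"][app] = {
            stage: [st.relative_change for st in build.states]
            for stage, build in res.template_builds.items()
        }
    timings["kappa_thr"] = time.time() - t0

    # --- pairwise F maps and normalized F sums ---------------------------
    t0 = time.time()
    vsyms = {
        app: symmetrize_variance(mask_variance(masks))
        for app, masks in masks_02.items()
    }
    fmaps = {}
    for m in config.approaches:
        for n in config.approaches:
            if m == n:
                continue
            fm = f_ratio_map(vsyms[m], vsyms[n], m, n)
            fmaps[(m, n)] = fm
            report["normalized_f"][f"{m}/{n}"] = normalized_f_sum(fm, f_c)
    ref = config.reference_approach
    if ref in config.approaches:
        for m in config.approaches:
            if m == ref:
                continue
            report["n_f"][m] = count_f_voxels(fmaps[(m, ref)], f_c)
    timings["f_maps"] = time.time() - t0

    # --- FA-VBS statistics and skeleton reference ------------------------
    if config.with_vbs:
        t0 = time.time()
        vbs_masks = {}
        for app, res in results.items():
            orig = [s.fa_norm for s in res.subjects]
            flip = [s.fa_flipped_norm for s in res.subjects]
            stat = paired_t_map(orig, flip, group_masks[app], approach=app)
            vbs_masks[app] = {}
            report["vbs_counts"][app] = {}
            for thr in config.vbs_thresholds:
                bm = threshold_stat_map(stat, thr)
                vbs_masks[app][thr] = bm
                report["vbs_counts"][app][str(thr)] = bm.count()
        timings["vbs"] = time.time() - t0

        skel_app = (
            config.skeleton_approach
            if config.skeleton_approach in results
            else config.approaches[0]
        )
        t0 = time.time()
        res = results[skel_app]
        orig = [s.fa_norm for s in res.subjects]
        flip = [s.fa_flipped_norm for s in res.subjects]
        mean_fa = symmetrize(
            orig[0].copy_with(np.mean([o.data for o in orig], axis=0))
        )
        skeleton = skeletonize(mean_fa)
        rec_o = [project_to_skeleton(o, skeleton) for o in orig]
        rec_f = [project_to_skeleton(f, skeleton) for f in flip]
        test = skeleton_paired_test(
            rec_o,
            rec_f,
            n_permutations=config.n_permutations,
            alpha=config.alpha,
            seed=stage_seed(config.seed, "permutation"),
        )
        thick = thicken_tbss_mask(
            rec_o, test.significant, skeleton, config.probability_threshold
        )
        report["skeleton"] = {
            "approach": skel_app,
            "n_voxels": int(len(skeleton)),
            "n_significant": int(test.significant.sum()),
            "thickened_voxels": int(thick.mask.count()),
        }
        timings["skeleton"] = time.time() - t0

        # kappa overlap and N^Diff against the thickened skeleton mask.
        # All approaches here normalise to one common reference grid, so
        # the stat-map space mapping is the identity.
        for app in config.approaches:
            report["kappa_vbs"][app] = {}
            for thr in config.vbs_thresholds:
                bm = vbs_masks[app][thr].mask
                report["kappa_vbs"][app][str(thr)] = kappa_overlap(bm, thick.mask)
            report["n_diff"][app] = count_diff_voxels(
                vbs_masks[app][min(config.vbs_thresholds)].mask, thick.mask
            )

    report["timings"] = {k: round(v, 2) for k, v in timings.items()}
    report["total_seconds"] = round(time.time() - t_start, 2)

    if config.out_dir is not None:
        _persist(config, report, results, manifest)
    validate_report(report)
    return report


def summary_from_report(report: dict) -> MisregSummary:
    """Repackage the report's metric blocks as a MisregSummary."""
    return MisregSummary(
        kappa={a: dict(v) for a, v in report.get("kappa_vbs", {}).items()},
        kappa_thr={a: dict(v) for a, v in report.get("kappa_thr", {}).items()},
        normalized_f=dict(report.get("normalized_f", {})),
        n_f=dict(report.get("n_f", {})),
        n_diff=dict(report.get("n_diff", {})),
    )


def _persist(config: ExperimentConfig, report: dict, results, manifest) -> None:
    import pathlib

    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    rows = ["approach\tmetric\tthreshold\tvalue"]
    for app, d in report["kappa_thr"].items():
        for thr, v in d.items():
            rows.append(f"{app}\tkappa_thr\t{thr}\t{v}")
    for pair, v in report["normalized_f"].items():
        rows.append(f"{pair}\tnormalized_f\t{report['f_critical']:.3f}\t{v}")
    for app, d in report.get("kappa_vbs", {}).items():
        for thr, v in d.items():
            rows.append(f"{app}\tkappa_vbs\t{thr}\t{v}")
    for app, v in report.get("n_f", {}).items():
        rows.append(f"{app}\tn_f\t\t{v}")
    for app, v in report.get("n_diff", {}).items():
        rows.append(f"{app}\tn_diff\t\t{v}")
    (out / "report.tsv").write_text("\n".join(rows) + "\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    for app, res in results.items():
        for key, tmpl in res.templates.items():
            write_volume(tmpl, out / f"template_{app}_{key}.nii.gz")


_REQUIRED_KEYS = {
    "schema_version": int,
    "seed": int,
    "conditions": dict,
    "kappa_thr": dict,
    "normalized_f": dict,
    "f_critical": float,
    "timings": dict,
}


def validate_report(report: dict) -> None:
    """Check the report against the versioned schema (raises on failure)."""
    for key, typ in _REQUIRED_KEYS.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has wrong type")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValueError("unsupported report schema version")
    for app, d in report["kappa_thr"].items():
        for thr, v in d.items():
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"kappa_thr[{app}][{thr}] outside [0, 1]")
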