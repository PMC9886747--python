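"""Per-case and per-cohort orchestration of the enhancement-mapping method.

``run_case`` executes the full chain — deformable registration of each
native/arterial pair, subtraction to enhancement maps, rigid pre/post
co-registration, ROI statistics and the response call, and (for residual
calls) feeder tracing — and emits a deterministic JSON-serialisable report.
``run_cohort`` adds the diagnostic cross-tabulation against reference
labels. ``simulate_command`` writes a synthetic cohort to disk in the same
layout ``run_case`` reads.

Reports embed the full effective configuration and the package version;
equal configs and inputs give byte-identical report JSON (stage wall times
go to the log, never into the report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import __version__
from .diagnostics import cross_tabulate, diagnostic_metrics, wilcoxon_rank_sum
from .emap import EnhancementMap, align_em_pair, compute_em
from .feeders import (classify_feeder, detect_residual_regions, trace_feeder,
                      vesselness)
from .phantom import PhantomCase, PhantomSpec, cohort_specs, generate_case
from .register import DeformableParams, register_deformable
from .response import (classify_response, define_normal_roi, define_tumor_roi,
                       relative_enhancement)
from .volgeom import Mask, Volume, read_mask, read_volume, write_mask, write_volume

__all__ = ["RunConfig", "CaseManifest", "CaseData", "run_case", "run_case_data",
           "run_cohort", "simulate_command"]

log = logging.getLogger("cthaem")


@dataclass
class RunConfig:
    """Every threshold the method leaves open, with documented defaults."""

    # deformable registration
    reg_levels: tuple[int, ...] = (4, 2, 1)
    reg_iterations: tuple[int, ...] = (150, 80, 20)
    reg_smooth_sigma_vox: float = 2.0
    reg_clip_hu: tuple[float, float] = (-100.0, 200.0)
    reg_histogram_match: bool = True
    # response statistic
    tau_hu: float = 0.0                 # "higher attenuation" cutoff, ΔHU
    normal_roi_area_mm2: float = 300.0
    # feeder analysis
    residual_threshold_hu: float = 20.0
    vessel_scales_mm: tuple[float, ...] = (0.9, 1.5, 2.4)
    feeder_dilation_mm: float = 1.2
    feeder_overlap_threshold: float = 0.5
    mip_thickness_mm: float = 7.0
    # evaluation
    ci_alpha: float = 0.05
    # reproducibility / output
    seed: int = 0
    output_dir: str | None = None
    write_qc: bool = False

    def deformable_params(self) -> DeformableParams:
        return DeformableParams(
            levels=self.reg_levels,
            iterations=self.reg_iterations,
            smooth_sigma_vox=self.reg_smooth_sigma_vox,
            clip_hu=self.reg_clip_hu,
            histogram_match=self.reg_histogram_match,
        )

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class CaseManifest:
    """File-based description of one case (paths resolved at run time)."""

    case_id: str
    pre_native: str
    pre_arterial: str
    post_native: str
    post_arterial: str
    tumor_mask: str
    liver_mask: str
    vessel_mask_pre: str | None = None
    root_mm: tuple[float, float, float] | None = None
    tumor_lobe: Literal["left", "right"] = "left"
    lobe_split_x_mm: float | None = None
    reference_label: str | None = None

    def load(self) -> "CaseData":
        for p in (self.pre_native, self.pre_arterial, self.post_native,
                  self.post_arterial, self.tumor_mask, self.liver_mask):
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        return CaseData(
            case_id=self.case_id,
            pre_native=read_volume(self.pre_native),
            pre_arterial=read_volume(self.pre_arterial),
            post_native=read_volume(self.post_native),
            post_arterial=read_volume(self.post_arterial),
            tumor_mask=read_mask(self.tumor_mask, "tumor"),
            liver_mask=read_mask(self.liver_mask, "liver"),
            vessel_mask_pre=(read_mask(self.vessel_mask_pre, "vessel")
                             if self.vessel_mask_pre else None),
            root_mm=self.root_mm,
            tumor_lobe=self.tumor_lobe,
            lobe_split_x_mm=self.lobe_split_x_mm,
            reference_label=self.reference_label,
        )


@dataclass
class CaseData:
    """In-memory inputs of one case."""

    case_id: str
    pre_native: Volume
    pre_arterial: Volume
    post_native: Volume
    post_arterial: Volume
    tumor_mask: Mask
    liver_mask: Mask
    vessel_mask_pre: Mask | None = None
    root_mm: Sequence[float] | None = None
    tumor_lobe: Literal["left", "right"] = "left"
    lobe_split_x_mm: float | None = None
    reference_label: str | None = None

    @classmethod
    def from_phantom(cls, case: PhantomCase) -> "CaseData":
        t = case.truth
        return cls(
            case_id=case.case_id,
            pre_native=case.pre_native,
            pre_arterial=case.pre_arterial,
            post_native=case.post_native,
            post_arterial=case.post_arterial,
            tumor_mask=t.tumor_mask,
            liver_mask=t.liver_mask,
            vessel_mask_pre=t.vessel_mask_pre,
            root_mm=(tuple(float(v) for v in t.feeder_root_mm)
                     if t.feeder_root_mm is not None else None),
            tumor_lobe="left",  # phantom tumor sits at +x of the lobe split
            lobe_split_x_mm=t.lobe_split_x_mm,
            reference_label="non_complete" if t.residual_fraction > 0 else "complete",
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_case_data(data: CaseData, config: RunConfig | None = None) -> dict:
    """Run register → emap → response (→ feeders when residual) on one case.

    Returns the per-case report as a plain dict. A stage failure produces a
    structured ``error`` entry naming the stage; results of earlier stages
    are retained.
    """
    config = config or RunConfig()
    report: dict = {
        "case_id": data.case_id,
        "package_version": __version__,
        "config": config.as_dict(),
    }
    stage = "register"
    t0 = time.perf_counter()
    try:
        params = config.deformable_params()
        field_pre, rep_pre = register_deformable(data.pre_arterial, data.pre_native, params)
        field_post, rep_post = register_deformable(data.post_arterial, data.post_native, params)
        report["registration"] = {
            "pre": {"converged": rep_pre.converged, "levels": rep_pre.levels,
                    "iterations": [len(t) for t in rep_pre.metric_trace]},
            "post": {"converged": rep_post.converged, "levels": rep_post.levels,
                     "iterations": [len(t) for t in rep_post.metric_trace]},
        }
        log.info("[register] %s done in %.1fs", data.case_id, time.perf_counter() - t0)

        stage = "emap"
        t0 = time.perf_counter()
        em_pre = compute_em(data.pre_native, data.pre_arterial, field_pre,
                            phase_pair="pre", registration_id=f"{data.case_id}:pre")
        em_post = compute_em(data.post_native, data.post_arterial, field_post,
                             phase_pair="post", registration_id=f"{data.case_id}:post")
        # anchor the rigid pre/post co-registration on the arterial volumes:
        # the maps live on arterial geometry, and the native phases carry the
        # (unrelated) intra-session respiratory deformations
        em_post_on_pre, session_tf = align_em_pair(
            em_pre, em_post, pre_anchor=data.pre_arterial, post_anchor=data.post_arterial
        )
        report["emap"] = {
            "session_translation_mm": [float(v) for v in session_tf.translation],
            "session_rotation_deg": session_tf.rotation_angle_deg(),
        }
        log.info("[emap] %s done in %.1fs", data.case_id, time.perf_counter() - t0)

        stage = "response"
        t0 = time.perf_counter()
        roi_tumor = define_tumor_roi(em_pre, data.tumor_mask)
        roi_normal = define_normal_roi(
            em_pre, data.liver_mask, tumor_lobe=data.tumor_lobe,
            vessel_mask=data.vessel_mask_pre, area_mm2=config.normal_roi_area_mm2,
            lobe_split_x_mm=data.lobe_split_x_mm,
        )
        pre_stats = relative_enhancement(em_pre, roi_tumor, roi_normal,
                                         high_attenuation_mode=False, tau_hu=config.tau_hu)
        # post map is resampled onto the pre grid, so the ROIs transfer as-is
        post_stats = relative_enhancement(em_post_on_pre, roi_tumor, roi_normal,
                                          high_attenuation_mode=True, tau_hu=config.tau_hu)
        call = classify_response(post_stats.T)
        report["response"] = {
            "roi_tumor": _round_floats(roi_tumor.to_dict()),
            "roi_normal": _round_floats(roi_normal.to_dict()),
            "T_pre_RE": round(pre_stats.T, 6),
            "T_post_RE": round(post_stats.T, 6),
            "mean_tumor_pre": round(pre_stats.mean_tumor, 6),
            "mean_tumor_post": round(post_stats.mean_tumor, 6),
            "mean_normal_pre": round(pre_stats.mean_normal, 6),
            "mean_normal_post": round(post_stats.mean_normal, 6),
            "n_voxels_tumor_used": post_stats.n_voxels_tumor_used,
            "high_attenuation_applicable": post_stats.high_attenuation_applicable,
            "tau_hu": config.tau_hu,
            "call": call.call,
        }
        log.info("[response] %s: T_post_RE=%.3f call=%s (%.1fs)",
                 data.case_id, post_stats.T, call.call, time.perf_counter() - t0)

        if call.call == "residual":
            stage = "feeders"
            t0 = time.perf_counter()
            report["feeders"] = _run_feeders(data, config, em_post_on_pre)
            log.info("[feeders] %s done in %.1fs", data.case_id, time.perf_counter() - t0)

        if config.write_qc and config.output_dir:
            stage = "qc"
            _write_qc(data, config, em_pre, em_post_on_pre, roi_tumor)
    except Exception as exc:  # structured failure, partial outputs retained
        report["error"] = {"stage": stage, "message": str(exc)}
        log.error("[%s] %s failed: %s", stage, data.case_id, exc)
    return report


def _run_feeders(data: CaseData, config: RunConfig, em_post: EnhancementMap) -> list[dict]:
    regions = detect_residual_regions(em_post, data.tumor_mask,
                                      threshold_hu=config.residual_threshold_hu)
    out: list[dict] = []
    if not regions or data.root_mm is None:
        return out
    vmap = vesselness(em_post, scales_mm=config.vessel_scales_mm)
    for i, region in enumerate(regions):
        trace = trace_feeder(em_post, region, data.root_mm, vmap)
        entry: dict = {
            "region_id": i,
            "n_voxels": region.n_voxels,
            "mean_delta_hu": round(region.mean_delta_hu, 3),
            "centroid_mm": [round(float(v), 3) for v in region.centroid_mm],
            "threshold_hu": region.threshold_hu,
        }
        if trace is None:
            entry["trace"] = None
        else:
            feeder = None
            if data.vessel_mask_pre is not None:
                feeder = classify_feeder(trace, data.vessel_mask_pre,
                                         dilation_mm=config.feeder_dilation_mm,
                                         overlap_threshold=config.feeder_overlap_threshold)
            entry["trace"] = {
                "path_mm": [[round(float(c), 2) for c in p] for p in trace.path_mm],
                "path_length_mm": round(trace.path_length_mm, 3),
                "mean_intensity": round(trace.mean_intensity, 3),
                "vesselness_min": round(trace.vesselness_min, 4),
                "status": feeder.status if feeder else None,
                "overlap_fraction": round(feeder.overlap_fraction, 4) if feeder else None,
            }
        out.append(entry)
    return out


def _write_qc(data: CaseData, config: RunConfig, em_pre, em_post, roi_tumor) -> None:
    """Inverted-grayscale map slices plus a thin-slab MIP, one PNG per case."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .emap import render_em
    from .volgeom import mip_slab

    os.makedirs(config.output_dir, exist_ok=True)
    k = int(np.argmin(np.abs(em_pre.axis_coords(2) - roi_tumor.slice_world_mm)))
    window = (0.0, 100.0)
    fig, axs = plt.subplots(1, 3, figsize=(10, 3.5))
    axs[0].imshow(render_em(em_pre, window, inverted=True, slice_index=k).T,
                  cmap="gray", origin="lower", vmin=0, vmax=1)
    axs[0].set_title("pre-treatment EM")
    axs[1].imshow(render_em(em_post, window, inverted=True, slice_index=k).T,
                  cmap="gray", origin="lower", vmin=0, vmax=1)
    axs[1].set_title("post-treatment EM")
    slab = mip_slab(em_post.as_volume(), "axial", roi_tumor.slice_world_mm,
                    config.mip_thickness_mm)
    axs[2].imshow(render_em(slab, (0.0, 250.0)).T, cmap="gray", origin="lower",
                  vmin=0, vmax=1)
    axs[2].set_title(f"{config.mip_thickness_mm:g} mm MIP (post)")
    for ax in axs:
        ax.set_axis_off()
    fig.suptitle(data.case_id)
    fig.tight_layout()
    fig.savefig(os.path.join(config.output_dir, f"{data.case_id}_qc.png"), dpi=100)
    plt.close(fig)


def run_case(manifest: CaseManifest, config: RunConfig | None = None) -> dict:
    """Load a case from disk, run it, and (if configured) write the report."""
    config = config or RunConfig()
    report = run_case_data(manifest.load(), config)
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        path = os.path.join(config.output_dir, f"{manifest.case_id}_report.json")
        with open(path, "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=1)
    return report


def run_cohort(
    cases: Sequence[CaseManifest | CaseData],
    config: RunConfig | None = None,
) -> dict:
    """Run every case, then cross-tabulate against reference labels.

    Cases lacking a reference label are still processed but excluded from
    the evaluation. Duplicate case ids abort before any processing.
    """
    config = config or RunConfig()
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case_ids in cohort")
    reports = []
    for c in cases:
        data = c.load() if isinstance(c, CaseManifest) else c
        reports.append(run_case_data(data, config))

    labelled = [
        (r, c.reference_label)
        for r, c in zip(reports, cases)
        if c.reference_label is not None and "response" in r
    ]
    cohort: dict = {
        "package_version": __version__,
        "config": config.as_dict(),
        "cases": reports,
        "evaluation": None,
    }
    if labelled:
        preds = [r["response"]["call"] for r, _ in labelled]
        refs = [lab for _, lab in labelled]
        table = cross_tabulate(preds, refs)
        summary = diagnostic_metrics(table, alpha=config.ci_alpha)
        t_res = [r["response"]["T_post_RE"] for r, _ in labelled
                 if r["response"]["call"] == "residual"]
        t_non = [r["response"]["T_post_RE"] for r, _ in labelled
                 if r["response"]["call"] == "non_residual"]
        ranksum = None
        if t_res and t_non:
            rs = wilcoxon_rank_sum(t_res, t_non)
            ranksum = {"statistic": rs.statistic, "p_value": rs.p_value,
                       "method": rs.method, "n_a": rs.n_a, "n_b": rs.n_b,
                       "significant": rs.significant}
        cohort["evaluation"] = {
            "confusion": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
            "metrics": summary.as_dict(),
            "T_post_RE_ranksum": ranksum,
        }
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        with open(os.path.join(config.output_dir, "cohort_report.json"), "w") as fh:
            json.dump(cohort, fh, sort_keys=True, indent=1)
    return cohort


def simulate_command(
    out_dir: str,
    n_cases: int,
    prevalence: float,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    force: bool = False,
) -> list[CaseManifest]:
    """Write a synthetic cohort (volumes, truth masks, manifests) to disk."""
    if os.path.exists(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    os.makedirs(out_dir, exist_ok=True)
    manifests: list[CaseManifest] = []
    for case_id, spec in cohort_specs(n_cases, prevalence, base_spec=base_spec,
                                      seed=seed):
        case = generate_case(spec, case_id=case_id)
        cdir = os.path.join(out_dir, case.case_id)
        os.makedirs(cdir, exist_ok=True)
        paths = {}
        for name in ("pre_native", "pre_arterial", "post_native", "post_arterial"):
            p = os.path.join(cdir, f"{name}.nii.gz")
            write_volume(getattr(case, name), p)
            paths[name] = p
        t = case.truth
        mask_paths = {}
        for name, mask in (("tumor_mask", t.tumor_mask), ("liver_mask", t.liver_mask),
                           ("vessel_mask_pre", t.vessel_mask_pre)):
            p = os.path.join(cdir, f"{name}.nii.gz")
            write_mask(mask, p)
            mask_paths[name] = p
        label = "non_complete" if t.residual_fraction > 0 else "complete"
        manifest = CaseManifest(
            case_id=case.case_id,
            **paths,
            **mask_paths,
            root_mm=tuple(float(v) for v in t.feeder_root_mm),
            tumor_lobe="left",
            lobe_split_x_mm=t.lobe_split_x_mm,
            reference_label=label,
        )
        manifests.append(manifest)
        truth_manifest = {
            "case_id": case.case_id,
            "seed": case.spec.seed,
            "residual_fraction": t.residual_fraction,
            "expected_T_pre": t.expected_T_pre,
            "expected_T_post": t.expected_T_post,
            "new_collateral_present": t.new_collateral_present,
            "reference_label": label,
            "root_mm": [float(v) for v in t.feeder_root_mm],
            "lobe_split_x_mm": t.lobe_split_x_mm,
        }
        with open(os.path.join(cdir, "truth.json"), "w") as fh:
            json.dump(truth_manifest, fh, sort_keys=True, indent=1)
    index = [dataclasses.asdict(m) for m in manifests]
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(index, fh, sort_keys=True, indent=1)
    return manifests
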