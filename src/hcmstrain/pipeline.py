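"""End-to-end pipeline: simulate -> strain -> morphometry -> stats -> report.

Each stage is a standalone function operating on the previous stage's files
(the CLI exposes them individually); :func:`run_pipeline` chains them and
writes a manifest with the configuration hash, the master seed, package
versions, per-stage wall times and a content hash over all outputs, so a
rerun with the same configuration can be verified byte-identical.

Cohort-level statistics run on the ground-truth metric table of the full
synthetic cohort; the image-based strain and morphometry stages run on a
configurable subset of rendered subjects (rendering and tracking every
subject of a large cohort is wasteful when the generator's truth is exact),
serving as the fidelity check of the imaging chain.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    carrier_group,
    control_group,
    ground_truth,
    sample_cohort,
    truth_table,
)
from .io import (
    config_hash,
    load_contours,
    load_tagged_series,
    read_table,
    save_contours,
    save_tagged_series,
    write_json,
    write_table,
)
from .morphometry import morphometry_from_cine
from .phantom import (
    CineStack,
    ImagingParams,
    reference_contours,
    render_cine_stack,
    render_tagged_series,
)
from .segments import SLICES
from .stats import classify_rule, compare_groups, compare_aucs, roc_analysis
from .strain import analyze_tagged_series
from .timecourse import CardiacTiming

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "stage_simulate", "stage_strain",
           "stage_morph", "stage_stats", "stage_report"]

log = logging.getLogger("hcmstrain.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "cohort": {"preset": "paper_calibrated", "n_carriers": 28, "n_controls": 28},
    "imaging": {
        "pixel_spacing_mm": [1.2, 1.2],
        "matrix": [160, 160],
        "tag_spacing_mm": 7.0,
        "frame_interval_ms": 14.1,
        "cine_phases": 20,
        "slice_thickness_mm": 5.0,
        "slice_gap_mm": 5.0,
        "snr": "inf",
    },
    "analysis": {
        "smooth": True,
        "sl_cutoff": 1.2,
        "dcsr_cutoff_pct_s": 105.0,
        "n_imaging_subjects": 2,
    },
    "output_dir": "hcmstrain_run",
}


class PipelineError(RuntimeError):
    pass


def _cfg_hash(cfg: dict) -> str:
    """Configuration hash over the run-defining keys (the output location
    does not change the content)."""
    return config_hash({k: v for k, v in cfg.items() if k != "output_dir"})


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def _resolve(config: dict | None) -> dict:
    cfg = _merge(DEFAULT_CONFIG, config or {})
    n_car, n_ctl = cfg["cohort"]["n_carriers"], cfg["cohort"]["n_controls"]
    if n_car < 1 or n_ctl < 1:
        raise PipelineError("cohort sizes must be >= 1")
    if cfg["cohort"]["preset"] != "paper_calibrated":
        raise PipelineError(f"unknown preset {cfg['cohort']['preset']!r}")
    return cfg


def _imaging(cfg: dict) -> ImagingParams:
    im = cfg["imaging"]
    snr = im["snr"]
    return ImagingParams(
        pixel_spacing_mm=tuple(im["pixel_spacing_mm"]),
        matrix=tuple(im["matrix"]),
        tag_spacing_mm=im["tag_spacing_mm"],
        frame_interval_ms=im["frame_interval_ms"],
        cine_phases=im["cine_phases"],
        slice_thickness_mm=im["slice_thickness_mm"],
        slice_gap_mm=im["slice_gap_mm"],
        snr=np.inf if snr in ("inf", None) else float(snr),
    )


def _timing_from_row(row) -> CardiacTiming:
    return CardiacTiming(row["cycle_ms"], row["aortic_closure_ms"],
                         row["mitral_opening_ms"])


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    """Sample both cohorts, write ground-truth tables, and render tagged and
    cine data for the first ``n_imaging_subjects`` of each group."""
    seed = cfg["seed"]
    h = _cfg_hash(cfg)
    sim = outdir / "simulate"
    sim.mkdir(parents=True, exist_ok=True)
    imaging = _imaging(cfg)

    carriers = sample_cohort(carrier_group(), cfg["cohort"]["n_carriers"], seed)
    controls = sample_cohort(control_group(), cfg["cohort"]["n_controls"], seed + 1)
    subjects = carriers + controls

    tab = pd.concat([truth_table(carriers), truth_table(controls)],
                    ignore_index=True)
    timing = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "cycle_ms": [s.cycle_ms for s in subjects],
            "aortic_closure_ms": [s.timing.aortic_closure_ms for s in subjects],
            "mitral_opening_ms": [s.timing.mitral_opening_ms for s in subjects],
        }
    )
    tab = tab.merge(timing, on="subject_id")
    write_table(tab, sim / "cohort_truth.csv", seed, h)

    seg_rows = []
    for s in subjects:
        gt = ground_truth(s)
        for i in range(16):
            seg_rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group_label,
                    "segment": i + 1,
                    "edwt_mm": gt.edwt_mm[i],
                    "eswt_mm": gt.eswt_mm[i],
                    "wall_thickening": gt.wall_thickening[i],
                    "peak_scs_pct": gt.peak_scs_pct[i],
                    "peak_dcsr_pct_s": gt.peak_dcsr_pct_s[i],
                    "analyzable": bool(s.analyzable[i]),
                }
            )
    write_table(pd.DataFrame(seg_rows), sim / "ground_truth_segments.csv", seed, h)

    n_img = int(cfg["analysis"]["n_imaging_subjects"])
    img_dir = sim / "images"
    img_dir.mkdir(exist_ok=True)
    written = []
    for j, s in enumerate(carriers[:n_img] + controls[:n_img]):
        for k, sl in enumerate(SLICES):
            series, _ = render_tagged_series(
                s, sl, imaging, seed=(seed + 7919 * j + k) % 2**31
            )
            base = img_dir / f"{s.subject_id}_{sl}_tagged.nii"
            save_tagged_series(series, base, seed, h)
            save_contours(
                {f"{sl}_{n}": c for n, c in reference_contours(series, s).items()},
                Path(str(base) + ".contours.json"), seed, h,
            )
            written.append(base)
        stack = render_cine_stack(s, imaging, seed=seed)
        save_contours(stack.contours,
                      img_dir / f"{s.subject_id}_cine_contours.json", seed, h)
    log.info("simulate: %d subjects, %d imaged", len(subjects), 2 * n_img)
    return [sim / "cohort_truth.csv", sim / "ground_truth_segments.csv", *written]


def stage_strain(cfg: dict, outdir: Path) -> list[Path]:
    """Track all rendered tagged series and write per-segment strain curves
    and peak summaries."""
    seed, h = cfg["seed"], _cfg_hash(cfg)
    sim, out = outdir / "simulate", outdir / "strain"
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_table(sim / "cohort_truth.csv").set_index("subject_id")
    curves_rows, summary_rows = [], []
    for nii in sorted((sim / "images").glob("*_tagged.nii")):
        sid, sl = nii.name.rsplit("_tagged", 1)[0].rsplit("_", 1)
        series = load_tagged_series(nii)
        contours = load_contours(Path(str(nii) + ".contours.json"))
        rc = {"endo": contours[f"{sl}_endo"], "epi": contours[f"{sl}_epi"]}
        timing = _timing_from_row(cohort.loc[sid])
        curves, summaries = analyze_tagged_series(
            series, rc, timing, smooth=cfg["analysis"]["smooth"]
        )
        for c in curves:
            for t, e in zip(c.times_ms, c.strain_pct):
                curves_rows.append(
                    {"subject_id": sid, "slice": sl, "segment": c.segment_id,
                     "time_ms": t, "strain_pct": e, "analyzable": c.analyzable}
                )
        for sm in summaries:
            summary_rows.append(
                {"subject_id": sid, "slice": sl, "segment": sm.segment_id,
                 "peak_scs_pct": sm.peak_scs_pct,
                 "peak_dcsr_pct_s": sm.peak_dcsr_pct_s,
                 "analyzable": sm.analyzable}
            )
    if not summary_rows:
        raise PipelineError("no tagged series found; run the simulate stage first")
    write_table(pd.DataFrame(curves_rows), out / "strain_curves.csv", seed, h)
    write_table(pd.DataFrame(summary_rows), out / "strain_summary.csv", seed, h)
    return [out / "strain_curves.csv", out / "strain_summary.csv"]


def stage_morph(cfg: dict, outdir: Path) -> list[Path]:
    """Morphometry from the rendered cine contour sets."""
    seed, h = cfg["seed"], _cfg_hash(cfg)
    sim, out = outdir / "simulate", outdir / "morph"
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_table(sim / "cohort_truth.csv").set_index("subject_id")
    imaging = _imaging(cfg)
    rows = []
    for cj in sorted((sim / "images").glob("*_cine_contours.json")):
        sid = cj.name.rsplit("_cine_contours", 1)[0]
        contours = load_contours(cj)
        row = cohort.loc[sid]
        n_lv = 9
        stack = CineStack(
            frames=None,
            pixel_spacing_mm=imaging.pixel_spacing_mm,
            phase_times_ms=np.arange(imaging.cine_phases)
            * row["cycle_ms"] / imaging.cine_phases,
            slice_positions_mm=np.arange(n_lv + 5)
            * (imaging.slice_thickness_mm + imaging.slice_gap_mm),
            slice_thickness_mm=imaging.slice_thickness_mm,
            slice_gap_mm=imaging.slice_gap_mm,
            lv_slices=tuple(range(n_lv)),
            la_slices=tuple(
                sorted({k[0] for k in contours if k[2] == "la_endo"})
            ),
            contours=contours,
            anchor_angle=np.pi / 2,
            slice_rings={
                i: ("basal" if (i + 0.5) / n_lv < 1 / 3
                    else "mid" if (i + 0.5) / n_lv < 2 / 3 else "apical")
                for i in range(n_lv)
            },
        )
        rec = morphometry_from_cine(stack, sid, row["bsa_m2"],
                                    _timing_from_row(row))
        rec.validate()
        rows.append(
            {
                "subject_id": sid,
                "group": row["group"],
                "sl_ratio": rec.sl_ratio,
                "lvedv_ml_m2": rec.lvedv_ml_m2,
                "lvesv_ml_m2": rec.lvesv_ml_m2,
                "sv_ml_m2": rec.sv_ml_m2,
                "lvef_pct": rec.lvef_pct,
                "lv_mass_g_m2": rec.lv_mass_g_m2,
                "mass_volume_ratio": rec.mass_volume_ratio,
                "la_min_ml_m2": rec.la_min_ml_m2,
                "la_max_ml_m2": rec.la_max_ml_m2,
                "la_reservoir_ml_m2": rec.la_reservoir_ml_m2,
                "la_passive_ml_m2": rec.la_passive_ml_m2,
                "la_active_ml_m2": rec.la_active_ml_m2,
                "laef_pct": rec.laef_pct,
                "ivrt_ms": rec.ivrt_ms,
                "diastasis_defined": rec.diastasis_defined,
            }
        )
    if not rows:
        raise PipelineError("no cine contours found; run the simulate stage first")
    write_table(pd.DataFrame(rows), out / "morphometry.csv", seed, h)
    return [out / "morphometry.csv"]


_COMPARED_METRICS = [
    "sl_ratio", "basal_dcsr_mean_pct_s", "basal_il_dcsr_pct_s",
    "basal_il_scs_pct", "basal_is_edwt_mm", "basal_is_thickening",
    "la_min_ml_m2", "la_max_ml_m2", "laef_pct", "lvedv_ml_m2", "lvesv_ml_m2",
    "lvef_pct", "lv_mass_g_m2", "ivrt_ms",
]


def stage_stats(cfg: dict, outdir: Path) -> list[Path]:
    """Cohort statistics on the ground-truth metric table: group
    comparisons, ROC for both screening metrics, AUC comparison, and the
    two-threshold classification rule."""
    seed, h = cfg["seed"], _cfg_hash(cfg)
    out = outdir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    tab = read_table(outdir / "simulate" / "cohort_truth.csv")
    car = tab[tab.group == "carrier"]
    ctl = tab[tab.group == "control"]

    rows = []
    for m in _COMPARED_METRICS:
        cmp_ = compare_groups(car[m], ctl[m])
        rows.append(
            {"metric": m, "carrier_mean": cmp_.mean1, "control_mean": cmp_.mean2,
             "test": cmp_.test, "statistic": cmp_.statistic, "p": cmp_.p_value}
        )
    write_table(pd.DataFrame(rows), out / "group_comparison.csv", seed, h)

    labels = (tab.group == "carrier").to_numpy()
    roc_sl = roc_analysis(tab.sl_ratio.to_numpy(), labels, direction="greater")
    roc_dcsr = roc_analysis(tab.basal_il_dcsr_pct_s.to_numpy(), labels,
                            direction="less")
    auc_cmp = compare_aucs(roc_sl, roc_dcsr)
    write_json(
        {
            "sl_ratio": {"auc": roc_sl.auc, "se": roc_sl.se_auc,
                         "cutoff": roc_sl.optimal_cutoff,
                         "sensitivity_pct": roc_sl.sensitivity_pct,
                         "specificity_pct": roc_sl.specificity_pct},
            "basal_il_dcsr": {"auc": roc_dcsr.auc, "se": roc_dcsr.se_auc,
                              "cutoff": roc_dcsr.optimal_cutoff,
                              "sensitivity_pct": roc_dcsr.sensitivity_pct,
                              "specificity_pct": roc_dcsr.specificity_pct},
            "comparison": {"delta_auc": auc_cmp.delta_auc, "z": auc_cmp.z,
                           "p": auc_cmp.p_value, "r": auc_cmp.r},
        },
        out / "roc.json", seed, h,
    )

    res = classify_rule(
        tab.sl_ratio, tab.basal_il_dcsr_pct_s, labels,
        cutoffs=(cfg["analysis"]["sl_cutoff"], cfg["analysis"]["dcsr_cutoff_pct_s"]),
    )
    write_json(
        {
            "cutoffs": res.cutoffs,
            "quadrants": {"positive": res.positive, "negative": res.negative,
                          "sl_only": res.sl_only, "dcsr_only": res.dcsr_only,
                          "excluded": res.excluded},
            "sensitivity_pct": res.sensitivity_pct,
            "specificity_pct": res.specificity_pct,
            "ppv_pct": res.ppv_pct,
            "npv_pct": res.npv_pct,
        },
        out / "classification.json", seed, h,
    )
    return [out / "group_comparison.csv", out / "roc.json",
            out / "classification.json"]


def stage_report(cfg: dict, outdir: Path) -> list[Path]:
    """Plain-text report assembling the statistics outputs."""
    from .io import read_json

    out = outdir / "stats"
    comp = read_table(out / "group_comparison.csv")
    roc = read_json(out / "roc.json")
    cls = read_json(out / "classification.json")
    lines = [
        f"hcmstrain {__version__} report  (seed {cfg['seed']}, "
        f"config {_cfg_hash(cfg)})",
        "",
        "Group comparison (carrier vs control, ground-truth metrics)",
        comp.round(4).to_string(index=False),
        "",
        "ROC",
        f"  SL ratio        AUC {roc['sl_ratio']['auc']:.2f} "
        f"+/- {roc['sl_ratio']['se']:.2f} (cutoff {roc['sl_ratio']['cutoff']:.2f})",
        f"  basal IL DCSR   AUC {roc['basal_il_dcsr']['auc']:.2f} "
        f"+/- {roc['basal_il_dcsr']['se']:.2f} "
        f"(cutoff {roc['basal_il_dcsr']['cutoff']:.0f} %/s)",
        f"  AUC difference  z = {roc['comparison']['z']:.2f}, "
        f"p = {roc['comparison']['p']:.3f} (r = {roc['comparison']['r']:.2f})",
        "",
        f"Two-threshold rule (SL > {cls['cutoffs'][0]}, "
        f"DCSR < {cls['cutoffs'][1]} %/s)",
        f"  positive quadrant: {cls['quadrants']['positive']}",
        f"  negative quadrant: {cls['quadrants']['negative']}",
        f"  SL-only quadrant:  {cls['quadrants']['sl_only']}",
        f"  DCSR-only quadrant:{cls['quadrants']['dcsr_only']}",
        f"  PPV {cls['ppv_pct']:.0f} %   NPV {cls['npv_pct']:.0f} %   "
        f"sensitivity {cls['sensitivity_pct']:.0f} %   "
        f"specificity {cls['specificity_pct']:.0f} %",
        "",
    ]
    path = out / "report.txt"
    path.write_text("\n".join(lines))
    return [path]


# ---------------------------------------------------------------------------


def _content_hash(paths: list[Path]) -> str:
    digest = hashlib.sha256()
    for p in sorted(set(map(Path, paths))):
        digest.update(p.name.encode())
        digest.update(hashlib.sha256(p.read_bytes()).digest())
    return digest.hexdigest()[:16]


def run_pipeline(config: dict | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run all stages and write the run manifest; returns the manifest."""
    cfg = _resolve(config)
    outdir = Path(outdir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    from .io import save_config

    save_config(cfg, outdir / "config.yaml")
    stages = [
        ("simulate", stage_simulate),
        ("strain", stage_strain),
        ("morph", stage_morph),
        ("stats", stage_stats),
        ("report", stage_report),
    ]
    outputs, timings = [], {}
    for name, fn in stages:
        t0 = time.time()
        try:
            outputs.extend(fn(cfg, outdir))
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.time() - t0, 3)
        log.info("stage %s done in %.1f s", name, timings[name])

    import scipy
    import statsmodels

    manifest = {
        "package": f"hcmstrain {__version__}",
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__,
                     "statsmodels": statsmodels.__version__},
        "seed": cfg["seed"],
        "config_hash": _cfg_hash(cfg),
        "content_hash": _content_hash([p for p in outputs if p.is_file()]),
        "stage_seconds": timings,
        "outputs": sorted(str(p.relative_to(outdir)) for p in outputs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
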