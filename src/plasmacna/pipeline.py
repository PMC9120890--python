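"""End-to-end orchestration: simulate -> TF -> recurrence -> longitudinal
-> clinical endpoints, with a machine-readable run report.

A single run seed fans out to per-stage child generators through
``SeedSequence`` spawn keys (a counter-based scheme), so adding a stage
never perturbs the random streams of earlier stages.  Identical config
and seed give an identical report (timestamps aside).
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clinical_stats as cs
from .cn_profile import (
    BinnedProfile, SegmentProfile, TFEstimate, ctdna_status, estimate_noise_sd,
    estimate_tf, segment, write_seg,
)
from .longitudinal import (
    PairedSample, conservation_by_direction, discrepancy_bootstrap,
    ppv_at_progression, region_concordance, tf_dynamics,
)
from .recurrence import find_recurrent_regions, regions_to_frame
from .synthetic_cohort import (
    Cohort, GroundTruth, SimConfig, simulate_cohort, write_cohort,
)

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

# fixed per-stage spawn keys
_STAGE_RECURRENCE = 2
_STAGE_LONGITUDINAL = 3


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Child generator for one pipeline stage, independent of the others."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def estimate_sample(
    profile: BinnedProfile, grid_step: float = 0.01, cn_max: int = 6
) -> tuple[SegmentProfile, TFEstimate]:
    """Segment a binned profile and fit tumor fraction; returns the
    segment profile with the fitted copy numbers assigned."""
    seg = segment(profile)
    est = estimate_tf(
        seg, grid_step=grid_step, cn_max=cn_max,
        noise_sd=estimate_noise_sd(profile),
    )
    return seg.with_cn(est.model), est


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_all(
    config: SimConfig,
    outdir,
    n_perm: int = 500,
    n_boot: int = 1999,
    write_outputs: bool = True,
) -> dict:
    """Run the full analysis on a simulated cohort and return the report.

    Stages: cohort simulation; per-sample TF estimation and ctDNA status;
    recurrent-region discovery on baseline profiles; baseline-vs-
    progression concordance, loss-vs-gain conservation and the
    emergent-alteration bootstrap; TF-dynamics PPV; ctDNA-stratified
    endpoints (Fisher, KM, log-rank, Cox).  Each stage's tabular output
    is persisted under ``outdir``.
    """
    outdir = Path(outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config.to_dict(),
        "warnings": warnings,
        "stages": {},
    }

    # ---- stage 1: simulate -------------------------------------------------
    cohort, truth = simulate_cohort(config)
    clinical = cohort.to_clinical_frame()
    report["stages"]["simulate"] = {
        "n_patients": len(cohort.patients),
        "n_samples": int(sum(len(p.samples) for p in cohort.patients)),
        "baseline_positive": int(clinical["ctdna_baseline"].sum()),
    }

    # ---- stage 2: tumor fraction ------------------------------------------
    tf_rows = []
    fitted: dict[tuple[str, str], SegmentProfile] = {}
    for p in cohort.patients:
        for tp, s in p.samples.items():
            if s.profile is None:
                continue
            seg_cn, est = estimate_sample(s.profile)
            fitted[(p.patient_id, tp)] = seg_cn
            tf_rows.append(
                {
                    "patient_id": p.patient_id,
                    "timepoint": tp,
                    "tf_true": s.tf,
                    "tf_est": est.tf,
                    "fit_score": est.fit_score,
                    "status": ctdna_status(est),
                }
            )
    tf_table = pd.DataFrame(tf_rows)
    report["stages"]["tumor_fraction"] = {
        "n_profiles": len(tf_rows),
        "table": tf_table.to_dict(orient="records"),
    }

    # ---- stage 3: recurrence ----------------------------------------------
    rng_rec = stage_rng(config.seed, _STAGE_RECURRENCE)
    baseline_profiles = [
        p.samples["baseline"].profile
        for p in cohort.patients
        if p.samples["baseline"].profile is not None
    ]
    regions = []
    if len(baseline_profiles) >= 2:
        regions = find_recurrent_regions(baseline_profiles, n_perm=n_perm, rng=rng_rec)
    else:
        warnings.append("recurrence skipped: fewer than two rendered baseline profiles")
    region_frame = regions_to_frame(regions)
    report["stages"]["recurrence"] = {
        "n_regions": len(regions),
        "regions": region_frame.to_dict(orient="records"),
    }

    # ---- stage 4: longitudinal --------------------------------------------
    rng_lon = stage_rng(config.seed, _STAGE_LONGITUDINAL)
    pairs = []
    for p in cohort.patients:
        if not p.pfs_event:
            continue
        b = fitted.get((p.patient_id, "baseline"))
        e = fitted.get((p.patient_id, "eot"))
        if b is None or e is None:
            continue
        pairs.append(PairedSample(p.patient_id, b, e))
    concordance_rows, discrepancy_rows = [], []
    conservation = None
    if pairs and regions:
        conc_results = [region_concordance(pairs, r) for r in regions]
        for c in conc_results:
            concordance_rows.append(
                {
                    "chrom": c.region.chrom, "start": c.region.start,
                    "end": c.region.end, "direction": c.direction,
                    "n_baseline_altered": c.n_baseline_altered,
                    "n_conserved": c.n_conserved,
                    "concordance_pct": c.concordance_pct,
                }
            )
            if not c.defined:
                warnings.append(
                    f"concordance undefined for {c.region.chrom}:{c.region.start}-"
                    f"{c.region.end} ({c.direction}): no pair altered at baseline"
                )
        try:
            med_loss, med_gain, p_wx = conservation_by_direction(conc_results)
            conservation = {
                "median_loss_pct": med_loss,
                "median_gain_pct": med_gain,
                "p_wilcoxon": p_wx,
            }
        except ValueError as exc:
            warnings.append(f"conservation comparison unavailable: {exc}")
        for r in regions:
            d = discrepancy_bootstrap(pairs, r, n_boot=max(n_boot, 999), rng=rng_lon)
            discrepancy_rows.append(
                {
                    "chrom": r.chrom, "start": r.start, "end": r.end,
                    "direction": r.direction, "n_emergent": d.n_emergent,
                    "n_reverted": d.n_reverted, "statistic": d.statistic,
                    "p_boot": d.p_boot, "n_boot": d.n_boot,
                }
            )
    elif not pairs:
        warnings.append("longitudinal skipped: no baseline/progression pairs")

    # TF dynamics and PPV (estimated TF when profiles were rendered)
    dyn_rows = []
    ppv_records = []
    for p in cohort.patients:
        if tf_table.empty:
            tfs = [p.samples[tp].tf for tp in ("baseline", "week7", "eot") if tp in p.samples]
        else:
            sub = tf_table[tf_table["patient_id"] == p.patient_id]
            by_tp = dict(zip(sub["timepoint"], sub["tf_est"]))
            tfs = [by_tp.get(tp) for tp in ("baseline", "week7", "eot")]
            tfs = [t for t in tfs if t is not None]
        if len(tfs) >= 2:
            dyn_rows.append(
                {"patient_id": p.patient_id, "dynamics": tf_dynamics(tfs)}
            )
        else:
            warnings.append(f"{p.patient_id}: <2 TF timepoints, excluded from dynamics")
        ppv_records.append((p.patient_id, tfs, bool(p.pfs_event)))
    ppv = ppv_at_progression(ppv_records)
    report["stages"]["longitudinal"] = {
        "n_pairs": len(pairs),
        "concordance": concordance_rows,
        "conservation": conservation,
        "discrepancy": discrepancy_rows,
        "tf_dynamics": dyn_rows,
        "ppv_rising": {
            "ppv": ppv.ppv, "n_rising": ppv.n_rising,
            "n_rising_progressed": ppv.n_rising_progressed,
            "n_evaluable": ppv.n_evaluable, "n_excluded": ppv.n_excluded,
        },
    }

    # ---- stage 5: clinical endpoints --------------------------------------
    clin: dict = {}
    status = clinical["ctdna_baseline"].to_numpy()
    # ORR by baseline ctDNA status (Fisher)
    evaluable = clinical["response_6m"].notna()
    if evaluable.any() and len(np.unique(status[evaluable])) == 2:
        resp = clinical.loc[evaluable, "response_6m"].astype(bool).to_numpy()
        st = status[evaluable.to_numpy()]
        table = [
            [int((resp & (st == 1)).sum()), int((~resp & (st == 1)).sum())],
            [int((resp & (st == 0)).sum()), int((~resp & (st == 0)).sum())],
        ]
        clin["orr_by_status"] = {"table": table, "p_fisher": cs.fisher_exact(table)}
    # KM / log-rank / Cox by baseline status
    times = clinical["pfs_months"].to_numpy(dtype=float)
    events = clinical["pfs_event"].to_numpy(dtype=int)
    if len(np.unique(status)) == 2 and events.sum() > 0:
        clin["km_by_status"] = {
            str(g): cs.km(times[status == g], events[status == g]).to_dict(orient="list")
            for g in (0, 1)
        }
        clin["logrank_p"] = cs.logrank(times, events, status)
        try:
            fits = cs.cox(
                clinical,
                covariates=["ctdna_baseline", "hr_status", "n_met_sites", "visceral"],
            )
            clin["cox"] = {
                k: {"hr": f.hr, "ci95": list(f.ci95), "p_wald": f.p_wald,
                    "n": f.n, "n_events": f.n_events}
                for k, f in fits.items()
            }
        except Exception as exc:  # small cohorts may separate
            warnings.append(f"Cox fit failed: {exc}")
    else:
        warnings.append("survival comparison skipped: need both strata and >=1 event")
    # week-7 kinetics among baseline-positive patients
    wk = clinical[(clinical["ctdna_baseline"] == 1) & clinical["tf_week7"].notna()]
    cleared = sum(
        cs.week7_status(b, w) == "cleared_or_stable_zero"
        for b, w in zip(wk["tf_baseline"], wk["tf_week7"])
    )
    clin["week7_clearance"] = {"n_cleared": int(cleared), "n_denominator": int(len(wk))}
    report["stages"]["clinical"] = clin

    # ---- persist -----------------------------------------------------------
    if write_outputs:
        write_cohort(cohort, truth, outdir / "cohort")
        tf_table.to_csv(outdir / "tf_table.tsv", sep="\t", index=False)
        region_frame.to_csv(outdir / "regions.bed", sep="\t", index=False)
        pd.DataFrame(concordance_rows).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
        pd.DataFrame(discrepancy_rows).to_csv(outdir / "discrepancy.tsv", sep="\t", index=False)
        pd.DataFrame(dyn_rows).to_csv(outdir / "tf_dynamics.tsv", sep="\t", index=False)
        for (pid, tp), segp in fitted.items():
            d = outdir / "seg_fitted"
            d.mkdir(exist_ok=True)
            write_seg(segp, d / f"{pid}_{tp}.seg")
        (outdir / "report.json").write_text(json.dumps(_jsonable(report), indent=1))
    return report
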