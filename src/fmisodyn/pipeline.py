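"""End-to-end orchestration of one longitudinal hypoxia-monitoring study.

For every patient: estimate the background, segment the hypoxic sub-volume at
each available time-point, classify the W0→W2 and W0→W5 dynamics (ΔV, overlap
metrics, CP), extract the radiomic features inside the transferred baseline
contour, and form the relative deviations.  At cohort level: CP is
dichotomized for Kaplan–Meier/log-rank survival comparison, and the
delta-features enter the per-endpoint prediction analysis with
Benjamini–Hochberg correction, W2→W5 confirmation and Spearman redundancy
filtering.

A patient failing a stage is excluded with a logged reason, never silently
dropped.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import outcome_stats as ost
from .config import RunConfig
from .radiomics import delta_features, feature_vector
from .segmentation import estimate_background, segment_hsv, transfer_contour
from .volumes import BinaryMask, PatientStudy, load_cohort

logger = logging.getLogger("fmisodyn")

FOLLOWUP_PAIRS = (("W0", "W2"), ("W0", "W5"))


def process_patient(study: PatientStudy, config: RunConfig = RunConfig()) -> dict:
    """All per-patient stages; returns a dict of per-stage results."""
    bg = estimate_background(study.volumes["W0"], study.background_mask)
    hsv: dict[str, BinaryMask] = {}
    for tp, vol in study.volumes.items():
        hsv[tp] = segment_hsv(
            vol, study.boost_mask, bg,
            tbr=config.tbr,
            inclusive_threshold=config.inclusive_threshold,
            min_component_voxels=config.min_component_voxels,
        )

    statuses: dict[str, dyn.HypoxiaStatus] = {}
    metrics: dict[str, dyn.OverlapMetrics | None] = {}
    for ref_tp, new_tp in FOLLOWUP_PAIRS:
        if new_tp not in hsv:
            continue
        pair = (ref_tp, new_tp)
        statuses[new_tp] = dyn.classify_pair(hsv[ref_tp], hsv[new_tp], pair)
        if hsv[ref_tp].voxel_count and hsv[new_tp].voxel_count:
            metrics[new_tp] = dyn.overlap_metrics(hsv[ref_tp], hsv[new_tp])
        else:
            metrics[new_tp] = None

    features: dict[str, object] = {}
    deltas: dict[str, object] = {}
    if hsv["W0"].voxel_count:
        rcfg = config.radiomics()
        for tp, vol in study.volumes.items():
            mask = transfer_contour(hsv["W0"], vol)
            features[tp] = feature_vector(vol, mask, rcfg)
        for _, new_tp in FOLLOWUP_PAIRS:
            if new_tp in features:
                deltas[new_tp] = delta_features(features["W0"], features[new_tp])

    return {
        "patient_id": study.patient_id,
        "background": bg,
        "hsv": hsv,
        "statuses": statuses,
        "metrics": metrics,
        "features": features,
        "deltas": deltas,
        "outcome": study.outcome,
    }


def _dynamics_table(records: Sequence[dict]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for tp, status in rec["statuses"].items():
            m = rec["metrics"].get(tp)
            rows.append({
                "patient_id": rec["patient_id"], "pair": f"W0-{tp}",
                "size_class": status.size_class,
                "cp": status.cp if status.cp is not None else math.nan,
                "delta_v": m.delta_v if m else math.nan,
                "dice": m.dice if m else math.nan,
                "sens": m.sens if m else math.nan,
                "ppv": m.ppv if m else math.nan,
                "v_ref_ml": m.v_ref_ml if m else math.nan,
                "v_new_ml": m.v_new_ml if m else math.nan,
            })
    return pd.DataFrame(rows)


def _feature_table(records: Sequence[dict]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for tp, fv in rec["features"].items():
            rows.append({"patient_id": rec["patient_id"], "time_point": tp,
                         **fv.values})
    return pd.DataFrame(rows)


def _delta_table(records: Sequence[dict], tp: str) -> pd.DataFrame:
    rows, index = [], []
    for rec in records:
        if tp in rec["deltas"]:
            rows.append(rec["deltas"][tp].values)
            index.append(rec["patient_id"])
    return pd.DataFrame(rows, index=index)


def _outcome_table(records: Sequence[dict]) -> pd.DataFrame:
    rows = []
    for rec in records:
        o = rec["outcome"]
        rows.append({
            "patient_id": rec["patient_id"],
            "pfs_months": o.pfs_months, "pfs_event": o.pfs_event,
            "os_months": o.os_months, "os_event": o.os_event,
            "local_recurrence": o.local_recurrence,
            "distant_metastasis": o.distant_metastasis,
        })
    return pd.DataFrame(rows).set_index("patient_id")


def cp_survival_analysis(
    records: Sequence[dict], tp: str, config: RunConfig = RunConfig()
) -> dict:
    """Kaplan–Meier + log-rank of PFS between CP_high and CP_low groups."""
    recs = [r for r in records if tp in r["statuses"]]
    statuses = [r["statuses"][tp] for r in recs]
    labels = dyn.dichotomize_cp(
        statuses, rule=config.cp_rule, threshold=config.cp_threshold,
        resolved_to_high=config.resolved_to_high)
    out = _outcome_table(recs)
    t = out["pfs_months"].values
    e = out["pfs_event"].values
    hi = np.array([lab == "CP_high" for lab in labels])
    lo = np.array([lab == "CP_low" for lab in labels])
    result = {
        "pair": f"W0-{tp}",
        "n_high": int(hi.sum()), "n_low": int(lo.sum()),
        "n_excluded": int(len(labels) - hi.sum() - lo.sum()),
        "labels": {r["patient_id"]: lab for r, lab in zip(recs, labels)},
    }
    if hi.sum() and lo.sum() and (e[hi].sum() + e[lo].sum()):
        stat, p = ost.logrank(t[hi], e[hi], t[lo], e[lo])
        result["logrank_stat"], result["logrank_p"] = stat, p
        result["km_high"] = ost.kaplan_meier(t[hi], e[hi])
        result["km_low"] = ost.kaplan_meier(t[lo], e[lo])
        result["median_pfs_high"] = float(np.median(t[hi]))
        result["median_pfs_low"] = float(np.median(t[lo]))
    else:
        result["logrank_stat"] = result["logrank_p"] = math.nan
    return result


def analyze_cohort(studies: Sequence[PatientStudy], config: RunConfig = RunConfig()) -> dict:
    """Run every stage on an in-memory cohort; returns tables and summaries.

    Patients failing any stage are recorded under ``excluded`` with the error
    message and left out of the cohort-level statistics.
    """
    records, excluded = [], {}
    for study in studies:
        try:
            records.append(process_patient(study, config))
        except Exception as err:  # noqa: BLE001 — exclusion policy, not control flow
            logger.warning("patient %s excluded: %s", study.patient_id, err)
            excluded[study.patient_id] = str(err)
    if len(records) < 2:
        raise ValueError("need at least 2 successfully processed patients")

    dynamics_table = _dynamics_table(records)
    outcomes = _outcome_table(records)

    results = {}
    prediction = {}
    for tp in ("W2", "W5"):
        delta = _delta_table(records, tp)
        if len(delta) >= 4:
            prediction[tp] = ost.analyze_delta_features(
                delta, outcomes.loc[delta.index],
                endpoints=config.endpoints, alpha=config.alpha,
                n_boot=config.n_boot, seed=config.seed, auc_for=config.auc_for)
        results[f"delta_{tp.lower()}"] = delta

    if "W2" in prediction and "W5" in prediction:
        confirmation = ost.two_timepoint_confirmation(
            prediction["W2"], prediction["W5"], alpha=config.alpha)
        results["confirmation"] = confirmation
        # redundancy filter among confirmed predictors, per endpoint, on W2 deltas
        kept = {}
        for endpoint in config.endpoints:
            conf = confirmation[(confirmation["endpoint"] == endpoint)
                                & confirmation["confirmed"]]
            if len(conf):
                pvals = prediction["W2"].set_index("feature_name")
                pvals = pvals[pvals["endpoint"] == endpoint]["p_raw"]
                kept[endpoint] = ost.spearman_redundancy_filter(
                    results["delta_w2"], pvals.loc[conf["feature_name"]],
                    r_threshold=config.spearman_r)
        results["selected_features"] = kept

    results.update({
        "records": records,
        "excluded": excluded,
        "features": _feature_table(records),
        "dynamics": dynamics_table,
        "outcomes": outcomes,
        "prediction_w2": prediction.get("W2"),
        "prediction_w5": prediction.get("W5"),
        "cp_survival_w2": cp_survival_analysis(records, "W2", config),
        "cp_survival_w5": cp_survival_analysis(records, "W5", config),
    })
    return results


def run_study(
    manifest_path: str | Path,
    config: RunConfig = RunConfig(),
    out_dir: str | Path = "results",
    force: bool = False,
) -> Path:
    """Disk-to-disk study run: read a manifest, write result tables.

    A completed run directory with the same config hash is left untouched
    unless ``force`` is given (stages are pure, so a re-run reproduces it).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_path = out_dir / "run_meta.json"
    meta = {"config": asdict(config), "config_hash": config.config_hash(),
            "seed": config.seed, "manifest": str(manifest_path)}
    if meta_path.exists() and not force:
        previous = json.loads(meta_path.read_text())
        if previous.get("config_hash") == meta["config_hash"] and \
                (out_dir / "dynamics.csv").exists():
            logger.info("run up to date (config %s); skipping", meta["config_hash"])
            return out_dir

    studies = load_cohort(manifest_path)
    results = analyze_cohort(studies, config)

    results["dynamics"].to_csv(out_dir / "dynamics.csv", index=False)
    results["features"].to_csv(out_dir / "features.csv", index=False)
    results["outcomes"].to_csv(out_dir / "outcomes.csv")
    for tp in ("w2", "w5"):
        delta = results.get(f"delta_{tp}")
        if delta is not None and len(delta):
            delta.to_csv(out_dir / f"delta_features_{tp}.csv")
        pred = results.get(f"prediction_{tp}")
        if pred is not None:
            pred.to_csv(out_dir / f"prediction_{tp}.csv", index=False)
    if results.get("confirmation") is not None:
        results["confirmation"].to_csv(out_dir / "confirmation.csv", index=False)
    for tp in ("w2", "w5"):
        surv = results[f"cp_survival_{tp}"]
        for side in ("high", "low"):
            km = surv.get(f"km_{side}")
            if km is not None:
                km.to_csv(out_dir / f"km_cp_{side}_{tp}.csv", index=False)
    summary = {
        "excluded": results["excluded"],
        "selected_features": results.get("selected_features", {}),
        "cp_survival": {
            tp: {k: v for k, v in results[f"cp_survival_{tp}"].items()
                 if k not in ("km_high", "km_low", "labels")}
            for tp in ("w2", "w5")
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    return out_dir
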