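"""End-to-end report: preprocess -> peri-prandial -> diagnostics -> biomarkers
-> gated statistics, with every headline quantity collected into a single
machine-readable metrics dictionary (and optionally written out as CSV/JSON).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import biomarkers as bm
from . import diagnostics, periprandial, preprocess, stats
from .cohort import NEC_GROUPS, Cohort, read_cohort

METRICS_SCHEMA_VERSION = 1


@dataclass
class ReportConfig:
    sample_period_s: float = 2.0
    sto2_window_h: tuple[float, float] = (0.0, 48.0)
    sto2_threshold: float | None = None
    ifabp_threshold: float | None = None
    roc_unit_sto2: str = "EPOCH"
    roc_unit_ifabp: str = "SAMPLE"
    signed_variability: bool = False
    seed: int | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"report stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_report(cohort: Cohort | str, config: ReportConfig | None = None,
               out_dir: str | None = None) -> dict:
    """Run the full analysis over a cohort (bundle or directory of CSVs).

    Returns a dict with the tables and a ``metrics`` sub-dict carrying every
    headline quantity.  When ``out_dir`` is given, writes table1.csv,
    trajectories.csv, variability.csv, roc_sto2.csv, roc_ifabp.csv,
    biomarker_summary.csv and metrics.json there.
    """
    cfg = config or ReportConfig()
    if isinstance(cohort, str):
        cohort = _stage("cohort_io")(read_cohort)(cohort)

    epochs = _stage("preprocess")(preprocess.epochs_for_cohort)(
        cohort, sample_period_s=cfg.sample_period_s)
    baselines = _stage("preprocess")(preprocess.compute_baseline)(epochs)
    trajectories = _stage("preprocess")(lambda: pd.concat(
        [preprocess.group_trajectory(epochs, cohort.piglets, ch)
         for ch in ("HR", "SPO2", "STO2")], ignore_index=True))()

    per_animal_var, var_summary = _stage("periprandial")(
        periprandial.cohort_variability)(
        epochs, cohort.piglets, cohort.feeds, signed=cfg.signed_variability)

    roc_sto2 = _stage("diagnostics")(diagnostics.screen_sto2)(
        epochs, cohort.piglets, window_h=cfg.sto2_window_h,
        threshold=cfg.sto2_threshold, unit=cfg.roc_unit_sto2)
    roc_ifabp = _stage("diagnostics")(diagnostics.screen_ifabp)(
        cohort.biomarkers, cohort.piglets,
        threshold=cfg.ifabp_threshold, unit=cfg.roc_unit_ifabp)

    traj_ifabp = _stage("biomarkers")(bm.trajectory_summary)(
        cohort.biomarkers, cohort.piglets, "IFABP")
    traj_saa = _stage("biomarkers")(bm.trajectory_summary)(
        cohort.biomarkers, cohort.piglets, "SAA")
    pooled = _stage("biomarkers")(bm.pooled_group_mean)(
        cohort.biomarkers, cohort.piglets, "IFABP")
    dens = _stage("biomarkers")(bm.densitometry_correlation)(cohort.necropsy)

    table1 = _stage("stats")(stats.baseline_table)(cohort.piglets, baselines)
    var_groups = {g: sub["variability"].to_numpy(float)
                  for g, sub in per_animal_var.groupby("group")}
    try:
        var_test = stats.gated_group_test(
            {"NEC": np.concatenate([var_groups[g] for g in NEC_GROUPS
                                    if g in var_groups]),
             "NO_NEC": var_groups.get("NO_NEC", np.array([]))},
            variable="peri-prandial variability")
        var_p = var_test.global_p
    except (stats.InsufficientDataError, KeyError):
        var_p = float("nan")

    sto2 = epochs[(epochs["channel"].astype(str) == "STO2")
                  & epochs["mean_value"].notna()]
    group_of = dict(zip(cohort.piglets["piglet_id"].astype(str),
                        cohort.piglets["group"]))
    pooled_sto2 = {
        g: float(sub["mean_value"].mean())
        for g, sub in sto2.groupby(
            sto2["piglet_id"].astype(str).map(group_of).to_numpy())}
    base_sto2 = baselines[baselines["channel"] == "STO2"]
    baseline_sto2 = {
        g: float(sub["baseline"].mean())
        for g, sub in base_sto2.groupby(
            base_sto2["piglet_id"].astype(str).map(group_of).to_numpy())}

    metrics = {
        "schema_version": METRICS_SCHEMA_VERSION,
        "seed": cfg.seed,
        "n_piglets": int(len(cohort.piglets)),
        "group_counts": cohort.group_counts(),
        "nec_incidence_pct": cohort.nec_incidence_pct(),
        "pooled_sto2_mean": pooled_sto2,
        "baseline_sto2_mean": baseline_sto2,
        "variability_pct": var_summary,
        "variability_p": var_p,
        "sto2_cutoff": roc_sto2.chosen_cutoff,
        "sto2_sens": roc_sto2.sens_at_cutoff,
        "sto2_spec": roc_sto2.spec_at_cutoff,
        "sto2_auc": roc_sto2.auc,
        "sto2_roc_unit": roc_sto2.unit,
        "ifabp_cutoff": roc_ifabp.chosen_cutoff,
        "ifabp_sens": roc_ifabp.sens_at_cutoff,
        "ifabp_spec": roc_ifabp.spec_at_cutoff,
        "ifabp_auc": roc_ifabp.auc,
        "ifabp_roc_unit": roc_ifabp.unit,
        "ifabp_pooled_nec": pooled["nec_mean"],
        "ifabp_pooled_no_nec": pooled["no_nec_mean"],
        "ifabp_pre_feed_mean": traj_ifabp.pre_feed_mean,
        "ifabp_post_feed_peak_mean": traj_ifabp.post_feed_peak_mean,
        "densitometry_rho": dens["rho"],
        "densitometry_p": dens["p_value"],
    }

    result = {
        "metrics": metrics,
        "table1": table1,
        "trajectories": trajectories,
        "variability": per_animal_var,
        "roc_sto2": roc_sto2,
        "roc_ifabp": roc_ifabp,
        "biomarker_grid_ifabp": traj_ifabp.grid,
        "biomarker_grid_saa": traj_saa.grid,
        "baselines": baselines,
    }
    if out_dir is not None:
        _write_report(result, out_dir)
    return result


def _roc_frame(roc) -> pd.DataFrame:
    return pd.DataFrame({"threshold": roc.thresholds,
                         "sens": roc.sens, "spec": roc.spec})


def _write_report(result: dict, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result["table1"].to_csv(os.path.join(out_dir, "table1.csv"), index=False)
    result["trajectories"].to_csv(
        os.path.join(out_dir, "trajectories.csv"), index=False)
    result["variability"].to_csv(
        os.path.join(out_dir, "variability.csv"), index=False)
    _roc_frame(result["roc_sto2"]).to_csv(
        os.path.join(out_dir, "roc_sto2.csv"), index=False)
    _roc_frame(result["roc_ifabp"]).to_csv(
        os.path.join(out_dir, "roc_ifabp.csv"), index=False)
    pd.concat([result["biomarker_grid_ifabp"].assign(analyte="IFABP"),
               result["biomarker_grid_saa"].assign(analyte="SAA")],
              ignore_index=True).to_csv(
        os.path.join(out_dir, "biomarker_summary.csv"), index=False)
    with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
        json.dump(result["metrics"], fh, indent=2, sort_keys=True)
        fh.write("\n")
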