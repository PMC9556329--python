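"""End-to-end pipeline: simulate (or load) -> features -> selection -> model
-> prediction -> endpoint report, with a reproducible run manifest.

Every stage logs its feature counts into the manifest, so a run records
the narrowing of the feature space (universe -> observed -> possible ->
detected -> retained -> candidates -> selected) alongside seeds, configs
and evaluation metrics.  Re-running with the same config and seed
regenerates every output file byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import endpoints, io as iomod
from .features import (AbundanceMatrix, apply_exclusion_rules,
                       filter_by_detection, observed_phenotypes,
                       split_by_prevalence)
from .model import (compare_probability_groups, filter_candidates,
                    fit_gam_lasso, predict_probability, roc_auc)
from .panel import default_panel
from .selection import (normalize_immunome, select_extreme_cohorts,
                        subsample_rank)
from .simulate import (CohortProfile, EffectSpec, generate_cohort,
                       generate_immunome, generate_mutation_data, module_rng,
                       mpr_evaluable, mpr_flag)
from .io import RunConfig, SplitSpec

__all__ = ["run_pipeline", "make_split"]

logger = logging.getLogger(__name__)


def _json_default(obj):
    if hasattr(obj, "item"):   # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def make_split(cohort: pd.DataFrame, sample_ids, training_fraction: float,
               seed: int) -> SplitSpec:
    """Assign immunome samples to training / test 1 / test 2.

    Samples with an MPR assessment (surgery, no EGFR/ALK alteration) are
    split into training and test 1, stratified by MPR status; samples
    without one (no surgery — the radiographic-progression branch) form
    test 2.
    """
    rng = module_rng(seed, "split")
    ids = [s for s in sample_ids if s in cohort.index]
    evaluable = mpr_evaluable(cohort.loc[ids])
    assessed = [s for s in ids if evaluable[s]]
    test2 = [s for s in ids if not evaluable[s]]
    y = mpr_flag(cohort.loc[assessed])
    train, test1 = [], []
    for cls in (0, 1):
        members = [s for s in assessed if y[s] == cls]
        members = list(np.array(members, dtype=object)[rng.permutation(len(members))])
        k = int(round(training_fraction * len(members)))
        train += members[:k]
        test1 += members[k:]
    return SplitSpec(training=sorted(train), test1=sorted(test1),
                     test2=sorted(test2))


def _endpoint_report(cohort: pd.DataFrame, variants: pd.DataFrame,
                     ci_method: str) -> dict:
    """Trial endpoint statistics on the cohort table."""
    evaluable = cohort[mpr_evaluable(cohort)]
    calls = [
        endpoints.classify_response(
            row.viable_percent, row.resection, bool(row.surgery)
        )
        for row in evaluable.itertuples()
    ]
    n = len(calls)
    n_mpr = sum(c.mpr for c in calls)
    n_pcr = sum(c.category == "pCR" for c in calls)
    mpr_ci = endpoints.response_rate_ci(n_mpr, n, method=ci_method)
    pcr_ci = endpoints.response_rate_ci(n_pcr, n, method=ci_method)

    y = np.array([c.mpr for c in calls])

    # MPR by PD-L1 TPS group (known groups only), Freeman-Halton
    tps = evaluable["tps_group"].to_numpy()
    tps_rows, tps_labels = [], []
    for grp in ("<1%", "1-49%", ">=50%"):
        sel = tps == grp
        if sel.sum():
            tps_rows.append([int(y[sel].sum()), int((~y[sel]).sum())])
            tps_labels.append(grp)
    tps_p = endpoints.fisher_exact(tps_rows) if len(tps_rows) >= 2 else None

    # MPR by TMB stratum, pairwise 2x2 Fisher
    tmb_section = None
    if variants is not None:
        shared = [p for p in evaluable.index if p in variants.index]
        tmb_groups = {}
        for p in shared:
            rec = endpoints.compute_tmb(
                int(variants.loc[p, "protein_affecting_mutations"]),
                int(variants.loc[p, "covered_coding_bases"]),
            )
            tmb_groups[p] = rec.tmb_group
        ymap = dict(zip(evaluable.index, y))
        counts = {}
        for g in endpoints.TMB_GROUPS:
            members = [p for p in shared if tmb_groups[p] == g]
            counts[g] = [sum(ymap[p] for p in members),
                         sum(1 - ymap[p] for p in members)]
        pairwise = {}
        for a, b in (("<10", "10-15"), ("<10", ">=16"), ("10-15", ">=16")):
            tbl = [counts[a], counts[b]]
            if min(sum(r) for r in tbl) > 0 and all(sum(c) > 0 for c in zip(*tbl)):
                pairwise[f"{a} vs {b}"] = endpoints.fisher_exact(tbl)
            else:
                pairwise[f"{a} vs {b}"] = None
        tmb_section = {"counts": counts, "pairwise_fisher_p": pairwise}

    # survival in the R0-resected evaluable subset, by MPR status
    r0 = evaluable[evaluable["resection"] == "R0"]
    y_r0 = mpr_flag(r0).to_numpy()
    survival = {}
    for ep in ("dfs", "os"):
        curve = endpoints.km_estimate(r0[f"{ep}_time"], r0[f"{ep}_event"])
        chi2, p = (np.nan, np.nan)
        if 0 < y_r0.sum() < y_r0.size:
            chi2, p = endpoints.log_rank(r0[f"{ep}_time"], r0[f"{ep}_event"], y_r0)
        survival[ep] = {
            "landmark_36m": curve.landmark(36.0),
            "log_rank_chi2": None if np.isnan(chi2) else chi2,
            "log_rank_p": None if np.isnan(p) else p,
        }

    power, critical = endpoints.design_power(0.05, 0.15, 0.05, 180)
    return {
        "n_evaluable": n,
        "mpr": {"count": n_mpr, "rate_percent": mpr_ci.rate_percent,
                "ci_percent": list(mpr_ci.ci_percent), "ci_method": ci_method},
        "pcr": {"count": n_pcr, "rate_percent": pcr_ci.rate_percent,
                "ci_percent": list(pcr_ci.ci_percent), "ci_method": ci_method},
        "tps_fisher": {"groups": tps_labels, "table": tps_rows, "p": tps_p},
        "tmb": tmb_section,
        "survival": survival,
        "design": {"p0": 0.05, "p1": 0.15, "alpha_one_sided": 0.05, "n": 180,
                   "power": power, "critical_value": critical},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write results under ``config.out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.to_dict(),
                      "stages": {}}

    try:
        # ---------------------------------------------------- inputs
        stage = "inputs"
        if config.panel_path:
            panel = iomod.read_panel(config.panel_path)
        else:
            panel = default_panel(config.panel_markers)
        if config.cohort_path:
            cohort = iomod.read_cohort(config.cohort_path)
            pre = iomod.read_abundance(config.abundance_pre_path, panel)
            post = (iomod.read_abundance(config.abundance_post_path, panel)
                    if config.abundance_post_path else None)
            variants = (iomod.read_variants(config.variants_path)
                        if config.variants_path else None)
        else:
            profile = CohortProfile(n_patients=config.n_patients)
            cohort = generate_cohort(profile, config.seed)
            effects = EffectSpec(effects=dict(config.effects),
                                 post_effects=dict(config.post_effects))
            pre, post = generate_immunome(
                cohort, panel, effects, config.seed,
                n_populations=config.n_populations,
            )
            variants = generate_mutation_data(cohort, config.seed)
            iomod.write_cohort(cohort, out / "cohort.csv")
            iomod.write_abundance(pre, out / "abundance_pre.csv")
            iomod.write_abundance(post, out / "abundance_post.csv")
            iomod.write_variants(variants, out / "variants.csv")
            iomod.write_panel(panel, out / "panel.yaml")
        manifest["stages"]["inputs"] = {
            "n_patients": int(len(cohort)),
            "n_universe": panel.n_universe,
            "n_features_emitted": len(pre.feature_ids),
        }

        # ----------------------------------------------------- split
        stage = "split"
        split = make_split(cohort, pre.sample_ids, config.training_fraction,
                           config.seed)
        manifest["stages"]["split"] = {
            "n_training": len(split.training), "n_test1": len(split.test1),
            "n_test2": len(split.test2),
        }

        # -------------------------------------------------- features
        stage = "features"
        train_pre = pre.subset_samples(split.training)
        observed = observed_phenotypes(train_pre)
        possible = apply_exclusion_rules(observed, panel)
        detected = filter_by_detection(
            train_pre.restrict(possible), config.detection_min_fraction
        )
        manifest["stages"]["features"] = {
            "observed": len(observed), "after_exclusion": len(possible),
            "after_detection_filter": len(detected.feature_ids),
        }

        # ------------------------------------------------- selection
        stage = "selection"
        sel_cfg = dataclasses.replace(config.selection, seed=config.seed)
        regression, progression = select_extreme_cohorts(
            cohort, detected.subset_samples(split.training), sel_cfg
        )
        extreme_ids = regression + progression
        norm = normalize_immunome(detected.subset_samples(extreme_ids),
                                  sel_cfg.normalization)
        arm = pd.Series(
            ["regression"] * len(regression) + ["progression"] * len(progression),
            index=extreme_ids,
        )
        sel_result = subsample_rank(norm, arm, sel_cfg)
        retained = sel_result.retained
        iomod.write_selection_result(sel_result, out / "selection.csv")
        manifest["stages"]["selection"] = {
            "n_extreme_per_arm": sel_cfg.per_arm_k,
            "n_scored": sel_result.stage_counts["features_scored"],
            "n_retained": len(retained),
        }

        # ----------------------------------------------------- model
        stage = "model"
        train_kept = detected.restrict(retained)
        y_train = mpr_flag(cohort).loc[split.training]
        split_prev = split_by_prevalence(train_kept, config.prevalence_threshold)
        mdl_cfg = dataclasses.replace(config.model, seed=config.seed)
        candidates = filter_candidates(split_prev, train_kept, y_train, mdl_cfg)
        model = fit_gam_lasso(candidates, train_kept, y_train, mdl_cfg)
        (out / "model.json").write_text(model.to_json(), encoding="utf-8")
        manifest["stages"]["model"] = {
            "n_prevalent": len(split_prev.prevalent),
            "n_non_prevalent": len(split_prev.non_prevalent),
            "n_candidates": len(candidates.all),
            "n_selected": len(model.selected_features),
            "n_prevalent_selected": model.n_prevalent_selected,
            "penalty": model.penalty,
            "apparent_auc": model.apparent_auc,
            "cv_auc": model.cv_auc,
        }

        # ------------------------------------------------ prediction
        stage = "prediction"
        preds, rocs = {}, {}
        for name, ids in (("training", split.training), ("test1", split.test1),
                          ("test2", split.test2)):
            if not ids:
                continue
            preds[name] = predict_probability(model, pre.subset_samples(ids))
            if name != "test2":   # test 2 has no MPR assessment: no ROC
                labels = mpr_flag(cohort).loc[ids]
                if labels.nunique() == 2:
                    roc = roc_auc(preds[name].to_numpy(), labels.to_numpy())
                    rocs[name] = roc
                    pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
                        out / f"roc_{name}.csv", index=False,
                        lineterminator="\n",
                    )
        pred_frame = pd.concat(
            [preds[k].rename("p_mpr").to_frame().assign(set=k) for k in preds]
        )
        pred_frame.to_csv(out / "predictions.csv", index_label="sample_id",
                          lineterminator="\n")
        manifest["stages"]["prediction"] = {
            name: {"n": len(preds[name]),
                   "auc": rocs[name].auc if name in rocs else None}
            for name in preds
        }

        # probability comparison across MPR / non-MPR / PD cohorts
        groups, values = [], []
        ymap = mpr_flag(cohort)
        for name in preds:
            for sid, p in preds[name].items():
                if name == "test2":
                    groups.append("PD")
                else:
                    groups.append("MPR" if ymap[sid] else "non-MPR")
                values.append(p)
        comparison = None
        if len(set(groups)) >= 2:
            cmp = compare_probability_groups(values, groups)
            comparison = {
                "anova": cmp["anova"],
                "pairwise": {
                    " vs ".join(pc["groups"]): {
                        "t": pc["result"].t, "df": pc["result"].df,
                        "p": pc["result"].p,
                    }
                    for pc in cmp["pairwise"]
                },
                "multiplicity_adjusted": cmp["multiplicity_adjusted"],
            }
        manifest["stages"]["probability_comparison"] = comparison

        # --------------------------------------------------- endpoints
        stage = "endpoints"
        report = _endpoint_report(cohort, variants, config.ci_method)
        (out / "endpoints.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=_json_default),
            encoding="utf-8"
        )
        manifest["stages"]["endpoints"] = {
            "mpr_rate_percent": report["mpr"]["rate_percent"],
            "pcr_rate_percent": report["pcr"]["rate_percent"],
        }
    except Exception:
        # persist what we have so a failed run is inspectable
        manifest["failed_stage"] = stage
        (Path(config.out_dir) / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str),
            encoding="utf-8",
        )
        logger.exception("pipeline failed at stage %s", stage)
        raise

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_json_default),
        encoding="utf-8"
    )
    return manifest
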