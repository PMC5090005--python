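"""End-to-end orchestration: simulate → condition → connectome → metrics →
associate → discriminate → validate, from a single config.

Every stochastic stage draws from a child seed spawned from the master
seed, so the whole run is bit-reproducible and stages can be re-run
independently.  All outputs are plain TSV/JSON under the output directory,
with a provenance block (config hash, seed, package versions) in
``report.json``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import dosenbach160_like, make_atlas
from .behavior import (
    RegressionModel,
    f_to_r2,
    fit_regression,
    inverse_efficiency,
    select_features,
    subnetwork_models,
)
from .cohort import CohortSpec, plant_behavior, simulate_cohort, simulate_trials
from .conditioning import ConditioningConfig, condition_series
from .connectome import SparsityGrid, correlation_matrix, roi_timeseries, threshold_series
from .discrimination import group_ttest, median_split, roc_analysis
from .efficiency import (
    integrate_and_normalize,
    nodal_curves,
    null_model_metrics,
)
from . import io
from .validation import random_region_control, shuffle_validation


@dataclass
class PipelineConfig:
    """Single source of truth for a pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    conditioning: ConditioningConfig = field(default_factory=ConditioningConfig)
    grid: SparsityGrid = field(default_factory=SparsityGrid)
    weights: str = "z"
    integration: str = "trapezoid"
    alpha: float = 0.05
    fdr_q: float = 0.05
    n_null: int = 100
    #: subjects used for the small-world (γ, λ) summary
    smallworld_subjects: int = 4
    n_perm: int = 1000
    n_control_draws: int = 1000
    conditions: tuple[str, ...] = ("BMP-Direction",)
    trial_accuracy: float = 0.95
    seed: int = 0
    out_dir: str = "effconn_out"

    def config_hash(self) -> str:
        blob = json.dumps(_to_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML (or JSON) file.

    Recognized top-level keys: cohort, conditioning, grid, and any flat
    PipelineConfig field.  Keyword overrides win over the file.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    kwargs = {}
    if "cohort" in raw:
        c = dict(raw.pop("cohort"))
        for tup_key in ("planted_nodes", "planted_betas"):
            if tup_key in c and c[tup_key] is not None:
                c[tup_key] = tuple(c[tup_key])
        kwargs["cohort"] = CohortSpec(**c)
    if "conditioning" in raw:
        c = dict(raw.pop("conditioning"))
        if "band" in c:
            c["band"] = tuple(c["band"])
        kwargs["conditioning"] = ConditioningConfig(**c)
    if "grid" in raw:
        kwargs["grid"] = SparsityGrid(**raw.pop("grid"))
    if "conditions" in raw:
        raw["conditions"] = tuple(raw["conditions"])
    kwargs.update(raw)
    return PipelineConfig(**kwargs)


def _model_dict(m: RegressionModel) -> dict:
    d = {
        "predictors": m.predictors,
        "coef_standardized": m.coef_standardized,
        "coef_raw": m.coef_raw,
        "intercept": m.intercept,
        "F": m.F,
        "df1": m.df1,
        "df2": m.df2,
        "r2": m.r2,
        "p_model": m.p_model,
        "coef_p": m.coef_p,
        "coef_fdr_flag": m.coef_fdr_flag,
        "coef_p_adjusted": m.coef_p_adjusted,
        "near_saturated": m.near_saturated,
        "dropped_collinear": m.dropped_collinear,
        "circular_selection_caveat": (
            "feature selection and regression reuse the same subjects; "
            "R^2 is optimistic by construction"
        ),
    }
    assert abs(f_to_r2(m.F, m.df1, m.df2) - m.r2) < 1e-8
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write a machine-readable report.

    Returns the report dict (also written to ``<out_dir>/report.json``).
    """
    cfg = config
    if cfg.cohort.n_subjects < 4:
        raise ValueError("pipeline requires at least 4 subjects")
    out = Path(cfg.out_dir)
    for sub in ("series", "connectome", "metrics", "behavior", "association",
                "discrimination", "validation"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed)
    seeds = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(
            ("cohort", "behavior", "trials", "null", "perm", "control"),
            ss.spawn(6),
        )
    }

    # --- stage 1: synthetic cohort -------------------------------------
    spec = replace(cfg.cohort, seed=seeds["cohort"])
    cohort = simulate_cohort(spec)
    if spec.n_nodes == 160 and spec.n_modules == 6:
        atlas = dosenbach160_like()
    else:
        sizes: dict[str, int] = {}
        for m in cohort.modules:
            sizes[f"module{m}"] = sizes.get(f"module{m}", 0) + 1
        atlas = make_atlas(spec.n_nodes, sizes, seed=seeds["cohort"])
    io.write_atlas(atlas, out / "atlas.tsv")

    # --- stages 2–3: conditioning and connectomes ----------------------
    n_sub = spec.n_subjects
    graphs_per_subject = []
    for ts, nuis in zip(cohort.series, cohort.nuisance):
        cond = condition_series(ts, nuis, cfg.conditioning)
        roi = roi_timeseries(cond)
        io.write_series(roi, out / "series" / f"{ts.subject_id}.tsv")
        cm = correlation_matrix(roi)
        io.write_matrix(cm.r, out / "connectome" / f"{ts.subject_id}_r.tsv")
        io.write_matrix(cm.z, out / "connectome" / f"{ts.subject_id}_z.tsv")
        graphs_per_subject.append(threshold_series(cm, cfg.grid, weights=cfg.weights))

    # --- stage 4: nodal metrics over the grid --------------------------
    n_nodes = spec.n_nodes
    local_norm = np.empty((n_sub, n_nodes))
    global_norm = np.empty((n_sub, n_nodes))
    for s, graphs in enumerate(graphs_per_subject):
        curves = nodal_curves(graphs)
        summ = integrate_and_normalize(curves, method=cfg.integration)
        local_norm[s] = summ["e_loc_normalized"]
        global_norm[s] = summ["e_glob_normalized"]
        pd.DataFrame(
            {
                "node_id": np.arange(n_nodes),
                "e_glob_integrated": summ["e_glob_integrated"],
                "e_glob_normalized": summ["e_glob_normalized"],
                "e_loc_integrated": summ["e_loc_integrated"],
                "e_loc_normalized": summ["e_loc_normalized"],
            }
        ).to_csv(
            out / "metrics" / f"{cohort.series[s].subject_id}.tsv",
            sep="\t", index=False, float_format="%.17g",
        )

    # --- small-world summary on a subject subset -----------------------
    smallworld = {}
    sw_n = min(cfg.smallworld_subjects, n_sub)
    if sw_n > 0 and cfg.n_null > 0:
        gammas, lams = [], []
        for s in range(sw_n):
            g_row, l_row = [], []
            for g in graphs_per_subject[s]:
                sw = null_model_metrics(g, n_rand=cfg.n_null, seed=seeds["null"] + s)
                g_row.append(sw.gamma)
                l_row.append(sw.lam)
            gammas.append(g_row)
            lams.append(l_row)
        gam = np.array(gammas)
        lam = np.array(lams)
        smallworld = {
            "levels": cfg.grid.levels,
            "gamma_mean": gam.mean(axis=0),
            "lambda_mean": lam.mean(axis=0),
            "gamma_min": float(gam.mean(axis=0).min()),
            "lambda_max_abs_dev": float(np.abs(lam.mean(axis=0) - 1).max()),
            "n_subjects": sw_n,
            "n_null": cfg.n_null,
        }
        io.write_json(smallworld, out / "metrics" / "smallworld.json")

    # --- stage 5: behavior ---------------------------------------------
    metric_kinds = {"local": local_norm, "global": global_norm}
    report: dict = {
        "provenance": {
            "package": "effconn",
            "version": __version__,
            "seed": cfg.seed,
            "stage_seeds": seeds,
            "config_hash": cfg.config_hash(),
        },
        "conditions": {},
        "smallworld": _to_plain(smallworld),
        "planted": {},
    }
    trial_rows = []
    for ci, condition in enumerate(cfg.conditions):
        planted = plant_behavior(local_norm, spec, seed=seeds["behavior"] + ci)
        ie = np.empty(n_sub)
        for s in range(n_sub):
            trials = simulate_trials(
                planted.ie[s], spec.n_trials, cfg.trial_accuracy,
                seed=seeds["trials"] + 1000 * ci + s,
            )
            rec = inverse_efficiency(
                trials, subject_id=cohort.series[s].subject_id, condition=condition
            )
            ie[s] = rec.ie
            t = trials.copy()
            t.insert(0, "condition", condition)
            t.insert(0, "subject_id", rec.subject_id)
            trial_rows.append(t)
        report["planted"][condition] = {
            "nodes": planted.planted_nodes,
            "betas": planted.betas,
            "noise_sd": planted.noise_sd,
            "population_r2": planted.population_r2,
        }

        cond_report: dict = {"ie": ie}
        split = median_split(ie)
        t_stat, t_df, t_p = group_ttest(ie, split)
        cond_report["median_split"] = {
            "median_ie": split.median_ie,
            "t": t_stat, "df": t_df, "p": t_p,
            "labels": split.labels,
        }

        for kind, matrix in metric_kinds.items():
            sel = select_features(matrix, ie, alpha=cfg.alpha)
            sel_path = out / "association" / f"selection_{condition}_{kind}.tsv"
            sel.to_csv(sel_path, sep="\t", index=False, float_format="%.17g")
            chosen = sel.loc[sel["selected"], "node_id"].astype(int).tolist()
            kind_report: dict = {"n_selected": len(chosen), "selected": chosen}
            if chosen:
                model = fit_regression(
                    matrix[:, chosen], ie, predictors=chosen, fdr_q=cfg.fdr_q
                )
                kind_report["model"] = _model_dict(model)
                subs = subnetwork_models(sel, atlas, matrix, ie, fdr_q=cfg.fdr_q)
                kind_report["subnetworks"] = {
                    net: _model_dict(m) for net, m in subs.items()
                }
                io.write_json(
                    _to_plain(kind_report),
                    out / "association" / f"model_{condition}_{kind}.json",
                )
                # discrimination per selected node
                roc_rows = []
                for node in chosen:
                    try:
                        roc = roc_analysis(matrix[:, node], split)
                    except ValueError:
                        continue
                    roc_rows.append(
                        {
                            "node_id": node, "auc": roc.auc, "se": roc.se,
                            "p": roc.p, "ci_lo": roc.ci95[0], "ci_hi": roc.ci95[1],
                            "sensitivity": roc.sensitivity,
                            "specificity": roc.specificity,
                            "threshold": roc.threshold,
                            "direction": roc.direction,
                        }
                    )
                roc_df = pd.DataFrame(roc_rows)
                roc_df.to_csv(
                    out / "discrimination" / f"roc_{condition}_{kind}.tsv",
                    sep="\t", index=False, float_format="%.17g",
                )
                kind_report["roc"] = roc_rows
                # validation controls
                shuffle = shuffle_validation(
                    matrix[:, chosen], ie, n_perm=cfg.n_perm,
                    seed=seeds["perm"] + ci, alpha=cfg.alpha,
                )
                kind_report["shuffle"] = {
                    "observed_F": shuffle.observed_F,
                    "frac_significant": shuffle.frac_significant,
                    "observed_percentile": shuffle.observed_percentile,
                    "n_perm": cfg.n_perm,
                }
                if len(chosen) < n_nodes:
                    try:
                        control = random_region_control(
                            matrix, set(chosen), len(chosen), ie,
                            n_draws=cfg.n_control_draws,
                            seed=seeds["control"] + ci, alpha=cfg.alpha,
                        )
                        kind_report["random_region_control"] = {
                            "mean_r2": float(control.r2.mean()),
                            "frac_significant": control.frac_significant,
                            "k": control.k,
                            "n_draws": cfg.n_control_draws,
                        }
                    except ValueError as err:
                        kind_report["random_region_control"] = {"skipped": str(err)}
                io.write_json(
                    _to_plain(
                        {"shuffle": kind_report.get("shuffle"),
                         "control": kind_report.get("random_region_control")}
                    ),
                    out / "validation" / f"{condition}_{kind}.json",
                )
            cond_report[kind] = kind_report
        report["conditions"][condition] = cond_report

    io.write_trials(pd.concat(trial_rows, ignore_index=True), out / "behavior" / "trials.tsv")
    report_plain = _to_plain(report)
    io.write_json(report_plain, out / "report.json")
    return report_plain
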