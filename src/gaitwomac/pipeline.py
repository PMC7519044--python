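"""End-to-end pipeline: (simulate) -> extract -> select -> estimate -> report.

Every stage writes its artifact into the output directory and appends its
counts to ``summary.log`` (subjects in, features extracted, features passing
the ANOVA screen, key features, balanced n, train/test n).  Runs are
deterministic given the config, and artifacts carry no timestamps so two
runs with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import io as gio
from .errors import PipelineError, ValidationError
from .estimation import run_estimation
from .extract import extract_matrix
from .registry import registry_by_name
from .selection import run_selection, subscale_association
from .simulate import CohortConfig, generate_cohort
from .womac import SUBSCALE_ITEMS, classify_subscale, classify_total, severity_cutpoints

logger = logging.getLogger(__name__)


def run_pipeline(config: gio.PipelineConfig) -> Dict[str, object]:
    """Run all stages; returns a dict of in-memory results and writes all
    artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: List[str] = [f"config_hash {config.config_hash()}"]

    def log(stage: str, message: str) -> None:
        line = f"{stage}: {message}"
        logger.info(line)
        summary.append(line)

    # -- stage: input ------------------------------------------------------
    try:
        if config.simulate:
            cohort_cfg = CohortConfig(
                group_sizes=(config.n_mild, config.n_moderate, config.n_severe),
                seed=config.seed_cohort,
                effect_scale=config.effect_scale,
                noise_scale=config.noise_scale,
                toe_off_pct=config.toe_off_pct,
            )
            subjects = generate_cohort(cohort_cfg)
            paths = gio.write_cohort(subjects, out / "cohort")
            config.waveform_csv = str(paths["waveform_csv"])
            config.spatiotemporal_csv = str(paths["spatiotemporal_csv"])
            config.womac_csv = str(paths["womac_csv"])
            log("simulate", f"generated {len(subjects)} subjects (seed {config.seed_cohort})")
        trials, records = gio.read_cohort(
            config.waveform_csv,
            config.spatiotemporal_csv,
            config.womac_csv,
            toe_off_pct=config.toe_off_pct,
        )
    except ValidationError as exc:
        raise PipelineError("input", "bad-input", str(exc)) from exc
    if not trials:
        raise PipelineError("input", "empty-cohort", "no subjects after the join")
    log("input", f"{len(trials)} subjects with gait and WOMAC data")

    # -- stage: classify ---------------------------------------------------
    totals = pd.Series({r.subject_id: r.total for r in records}, name="womac_total")
    classes = pd.Series({r.subject_id: classify_total(r).label for r in records}, name="class")
    subscale_classes = {
        s: pd.Series({r.subject_id: classify_subscale(r, s).label for r in records})
        for s in SUBSCALE_ITEMS
    }
    counts = classes.value_counts().to_dict()
    log("classify", f"severity classes {counts} (cuts {severity_cutpoints(24)})")

    # -- stage: extract ----------------------------------------------------
    try:
        registry = registry_by_name(config.registry)
        fm = extract_matrix(trials, registry, occupied_fraction=config.occupied_fraction)
    except ValidationError as exc:
        raise PipelineError("extract", "extract-failed", str(exc)) from exc
    fm_clean = fm.drop_masked_features()
    X = fm_clean.to_frame()
    X.to_csv(out / "features.csv")
    reg_df = pd.DataFrame(
        [
            {
                "feature_id": d.feature_id,
                "parameter": d.parameter,
                "operator": d.operator,
                "window": "" if d.window is None else str(d.window),
                "units": d.units,
            }
            for d in fm_clean.descriptors
        ]
    )
    reg_df.to_csv(out / "registry.csv", index=False)
    log("extract", f"{X.shape[1]} features extracted for {X.shape[0]} subjects")

    # -- stage: select -----------------------------------------------------
    try:
        sel = run_selection(
            X, classes.loc[X.index], config.alpha_anova, config.alpha_pairwise
        )
    except ValidationError as exc:
        raise PipelineError("select", "selection-failed", str(exc)) from exc
    key = sel.key_features
    sel.subscale_features = subscale_association(
        X,
        {s: c.loc[X.index] for s, c in subscale_classes.items()},
        key,
        config.alpha_anova,
        config.alpha_pairwise,
    )
    table = sel.table.copy()
    for s, feats in sel.subscale_features.items():
        table[f"sig_{s}"] = table.index.isin(feats)
    table.index.name = "feature_id"
    table.to_csv(out / "selection.csv")
    log(
        "select",
        f"{int(sel.table['passed_anova'].sum())} features passed ANOVA "
        f"(alpha {config.alpha_anova}); {len(key)} key features "
        f"(pairwise alpha {config.alpha_pairwise}); subscale counts "
        f"{ {s: len(f) for s, f in sel.subscale_features.items()} }",
    )

    # -- stage: estimate ---------------------------------------------------
    reports = {}
    if not key:
        log("estimate", "skipped: no key features were selected")
    else:
        try:
            reports = run_estimation(
                X[key],
                totals.loc[X.index],
                classes.loc[X.index],
                balance_target=config.balance_target,
                train_fraction=config.train_fraction,
                balance_seed=config.seed_balance,
                split_seed=config.seed_split,
                forest_seed=config.seed_forest,
                linear_max_features=config.linear_max_features,
                feature_order=key,
            )
        except ValidationError as exc:
            raise PipelineError("estimate", "estimation-failed", str(exc)) from exc
        preds = []
        for kind, rep in reports.items():
            payload = {
                "model_kind": rep.model_kind,
                "n_train": rep.n_train,
                "n_test": rep.n_test,
                "holdout_rmse": rep.rmse,
                "holdout_pearson_r": rep.pearson_r,
                "in_sample_rmse": rep.in_sample_rmse,
                "in_sample_pearson_r": rep.in_sample_pearson_r,
                "seed": rep.seed,
                "hyperparameters": rep.hyperparameters,
            }
            if rep.coefficients is not None:
                payload["coefficients"] = {"intercept-excluded": rep.coefficients.to_dict()}
            (out / f"model_{kind}.json").write_text(json.dumps(payload, indent=2, default=str))
            p = rep.predictions.copy()
            p["model"] = kind
            preds.append(p)
            log(
                "estimate",
                f"{kind}: train {rep.n_train} test {rep.n_test} "
                f"holdout RMSE {rep.rmse:.2f} r {rep.pearson_r:.3f}",
            )
        pd.concat(preds, ignore_index=True).to_csv(out / "predictions.csv", index=False)

    if config.plots:
        from .plotting import plot_group_means

        plot_group_means(trials, classes, out / "group_means.png")
        log("report", "wrote group-mean waveform figure")

    (out / "summary.log").write_text("\n".join(summary) + "\n")
    return {
        "features": X,
        "selection": sel,
        "key_features": key,
        "reports": reports,
        "classes": classes,
        "totals": totals,
        "summary": summary,
    }
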