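"""One-command end-to-end driver: simulate -> extract -> select -> fit -> evaluate.

Every stage writes its artifact (CSV/JSON) into the output directory and
registers it in a run manifest; two runs with identical configs produce
identical artifact digests.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import evaluation, io, modeling, selection
from ._utils import rng_from
from .config import PipelineConfig
from .features import extract_all
from .synthetic import (
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    perturb_mask,
    split_cohort,
)

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = (
    "age",
    "nihss",
    "aspects",
    "collateral_grade",
    "sex",
    "side",
) + io.BOOL_COLUMNS


def _clinical_frame(cohort_df: pd.DataFrame) -> pd.DataFrame:
    X = cohort_df.set_index("id")[list(CLINICAL_COLUMNS)].copy()
    X["sex"] = (X["sex"] == "male").astype(int)
    X["side"] = (X["side"] == "right").astype(int)
    return X


def extract_cohort_features(records, config: PipelineConfig, pspec: PhantomSpec) -> pd.DataFrame:
    """Phantom + 396-feature extraction for every subject."""
    rows = {}
    t0 = time.time()
    for k, rec in enumerate(records):
        vol, mask = generate_phantom(rec, pspec)
        rows[rec.id] = extract_all(vol, mask, config.preprocessing, config.features)
        if (k + 1) % 25 == 0:
            logger.info("extracted %d/%d subjects (%.1f s)", k + 1, len(records), time.time() - t0)
    return pd.DataFrame.from_dict(rows, orient="index")


def _evaluate_split(rad_lp, comb_prob, y, config, curve_dir=None, split_name="") -> dict:
    """Discrimination/comparison/calibration/utility report for one split.

    With ``curve_dir`` set, ROC and decision curves are also written as CSV.
    """
    rad_prob = expit(rad_lp)
    roc_rad = evaluation.auc_delong(rad_lp, y)
    roc_comb = evaluation.auc_delong(comb_prob, y)
    op_rad = evaluation.youden_point(roc_rad)
    op_comb = evaluation.youden_point(roc_comb)
    cmp_auc = evaluation.delong_compare(rad_lp, comb_prob, y)
    mcn = evaluation.mcnemar_compare(
        (np.asarray(rad_lp) >= op_rad.threshold).astype(int),
        (np.asarray(comb_prob) >= op_comb.threshold).astype(int),
        y,
    )
    out = {
        "radiomics": {
            "auc": roc_rad.auc,
            "se": roc_rad.se,
            "ci": roc_rad.ci,
            "sensitivity": op_rad.sensitivity,
            "specificity": op_rad.specificity,
            "threshold": op_rad.threshold,
        },
        "combined": {
            "auc": roc_comb.auc,
            "se": roc_comb.se,
            "ci": roc_comb.ci,
            "sensitivity": op_comb.sensitivity,
            "specificity": op_comb.specificity,
            "threshold": op_comb.threshold,
        },
        "delong_p": cmp_auc.p,
        "mcnemar_p": mcn.p,
    }
    n = len(y)
    g = 10 if n >= 20 else max(4, n // 4)
    rocs = {"radiomics": roc_rad, "combined": roc_comb}
    for name, probs in (("radiomics", rad_prob), ("combined", comb_prob)):
        hl = modeling.hosmer_lemeshow(probs, y, g=g)
        out[name]["hosmer_lemeshow"] = {"statistic": hl.statistic, "df": hl.df, "p": hl.p}
        dca = evaluation.decision_curve(probs, y, config.evaluation.dca_grid_step)
        out[name]["dca_beneficial_range"] = dca.beneficial_range
        if curve_dir is not None:
            roc = rocs[name]
            pd.DataFrame(
                {"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
                 "specificity": roc.specificity}
            ).to_csv(curve_dir / f"roc_{split_name}_{name}.csv", index=False,
                     float_format=io.FLOAT_FMT)
            pd.DataFrame(
                {"threshold": dca.thresholds, "nb_model": dca.nb_model,
                 "nb_all": dca.nb_all, "nb_none": dca.nb_none}
            ).to_csv(curve_dir / f"dca_{split_name}_{name}.csv", index=False,
                     float_format=io.FLOAT_FMT)
    return out


def run_pipeline(
    config: PipelineConfig,
    outdir,
    write_phantoms: bool = False,
    cohort_spec: CohortSpec | None = None,
) -> dict:
    """Full synthetic-cohort pipeline; returns results including the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = io.RunManifest(config.digest_text(), config.seed)
    t_start = time.time()

    # --- simulate ---------------------------------------------------------
    cspec = cohort_spec if cohort_spec is not None else CohortSpec(seed=config.seed)
    records = generate_cohort(cspec)
    split_cohort(records, config.n_dev, config.n_val, stratify=True, seed=config.seed)
    cohort_path = outdir / "cohort.csv"
    io.write_cohort_csv(records, cohort_path)
    manifest.add("simulate", cohort_path)
    logger.info("simulate: %d subjects (%.1f s)", len(records), time.time() - t_start)

    pspec = PhantomSpec(shape=tuple(config.phantom_shape), seed=config.seed)
    if write_phantoms:
        pdir = outdir / "phantoms"
        pdir.mkdir(exist_ok=True)
        for rec in records:
            vol, mask = generate_phantom(rec, pspec)
            io.write_image_pair(vol, mask, pdir / f"{rec.id}.nii.gz", pdir / f"{rec.id}_mask.nii.gz")

    # --- extract ----------------------------------------------------------
    features = extract_cohort_features(records, config, pspec)
    feats_path = outdir / "features.csv"
    io.write_features_csv(features, feats_path)
    manifest.add("extract", feats_path)

    cohort_df = io.cohort_to_dataframe(records)
    labels = (cohort_df.set_index("id")["tfs_class"] == "early").astype(int)
    dev_ids = cohort_df.loc[cohort_df["split"] == "development", "id"]
    val_ids = cohort_df.loc[cohort_df["split"] == "validation", "id"]

    # --- select (development only) ----------------------------------------
    sel_cfg = config.selection
    params, report, survivors, lasso = selection.run_cascade(
        features.loc[dev_ids],
        labels.loc[dev_ids],
        alpha=sel_cfg.alpha,
        rho_max=sel_cfg.rho_max,
        n_folds=sel_cfg.n_folds,
        seed=sel_cfg.seed,
        n_lambdas=sel_cfg.n_lambdas,
        lambda_decades=sel_cfg.lambda_decades,
    )
    sel_path = outdir / "selection.json"
    io.write_json(
        {
            "univariate": report.reset_index(),
            "univariate_survivors": list(report.index[report["passed"]]),
            "redundancy_survivors": survivors,
            "lasso": {
                "chosen_lambda": lasso.chosen_lambda,
                "intercept": lasso.intercept,
                "coefficients": lasso.coefficients,
                "fold_seed": lasso.fold_seed,
                "lambda_grid": lasso.lambdas,
                "cv_deviance": lasso.cv_deviance,
            },
            "standardization": {
                "means": params.means,
                "sds": params.sds,
                "excluded": params.excluded,
            },
        },
        sel_path,
    )
    manifest.add("select", sel_path)
    logger.info(
        "select: %d univariate -> %d redundancy -> %d lasso",
        int(report["passed"].sum()), len(survivors), len(lasso.coefficients),
    )

    # --- fit ---------------------------------------------------------------
    rad_model = modeling.RadScoreModel.from_lasso(lasso, params)
    radscores = modeling.compute_radscore(rad_model, features)
    clinical = _clinical_frame(cohort_df)
    screen = modeling.screen_clinical(clinical.loc[dev_ids], labels.loc[dev_ids], config.selection.alpha)
    screened = list(screen.index[screen["selected"]])
    combined = modeling.fit_combined(
        radscores.loc[dev_ids], clinical.loc[dev_ids, screened], labels.loc[dev_ids]
    )
    model_path = outdir / "model.json"
    io.write_json(
        {
            "radscore_model": {
                "intercept": rad_model.intercept,
                "coefficients": rad_model.coefficients,
                "source": rad_model.source,
            },
            "clinical_screening": screen.reset_index(),
            "combined_model": {
                "intercept": combined.intercept,
                "coefficients": combined.coefficients,
                "separation_fallback": combined.separation_fallback,
            },
        },
        model_path,
    )
    manifest.add("fit", model_path)
    logger.info("fit: screened clinical variables = %s", screened)

    # --- evaluate ----------------------------------------------------------
    def _combined_inputs(ids):
        X = pd.DataFrame({"radscore": radscores.loc[ids]})
        for c in screened:
            X[c] = clinical.loc[ids, c].to_numpy(dtype=float)
        return X

    results = {"selected_features": list(lasso.coefficients), "screened_clinical": screened}
    for split_name, ids in (("development", dev_ids), ("validation", val_ids)):
        y = labels.loc[ids].to_numpy()
        rad_lp = radscores.loc[ids].to_numpy()
        comb_p = combined.predict_proba(_combined_inputs(ids))
        results[split_name] = _evaluate_split(
            rad_lp, comb_p, y, config, curve_dir=outdir, split_name=split_name
        )
        logger.info(
            "evaluate[%s]: AUC radiomics %.3f, combined %.3f",
            split_name,
            results[split_name]["radiomics"]["auc"],
            results[split_name]["combined"]["auc"],
        )

    # --- reliability (ICC on perturbed masks) ------------------------------
    if config.compute_icc:
        ev = config.evaluation
        icc_records = [r for r in records if r.split == "development"][: ev.n_icc_subjects]
        rows_b, rows_a2 = {}, {}
        for rec in icc_records:
            vol, mask = generate_phantom(rec, pspec)
            seed_b = int(rng_from(config.seed, "raterB", rec.id).integers(2**31))
            seed_a2 = int(rng_from(config.seed, "raterA2", rec.id).integers(2**31))
            mb = perturb_mask(mask, ev.inter_rater_magnitude, seed_b)
            ma2 = perturb_mask(mask, ev.intra_rater_magnitude, seed_a2)
            rows_b[rec.id] = extract_all(vol, mb, config.preprocessing, config.features)
            rows_a2[rec.id] = extract_all(vol, ma2, config.preprocessing, config.features)
        fa = features.loc[[r.id for r in icc_records]]
        fb = pd.DataFrame.from_dict(rows_b, orient="index").loc[fa.index]
        fa2 = pd.DataFrame.from_dict(rows_a2, orient="index").loc[fa.index]
        inter = evaluation.icc(
            {c: np.column_stack([fa[c], fb[c]]) for c in fa.columns}, mode="inter"
        )
        intra = evaluation.icc(
            {c: np.column_stack([fa[c], fa2[c]]) for c in fa.columns}, mode="intra"
        )
        results["icc"] = {
            "inter": {"min": inter.minimum, "max": inter.maximum,
                      "median": float(inter.values.median())},
            "intra": {"min": intra.minimum, "max": intra.maximum,
                      "median": float(intra.values.median())},
        }
        logger.info("icc: inter median %.3f, intra median %.3f",
                    results["icc"]["inter"]["median"], results["icc"]["intra"]["median"])

    # --- correlations -------------------------------------------------------
    corr_cov = clinical[["age", "aspects"]]
    corr = evaluation.spearman_feature_clinical(
        features[list(lasso.coefficients)], corr_cov.loc[features.index]
    )
    results["correlations"] = corr

    report_path = outdir / "report.json"
    io.write_json(results, report_path)
    manifest.add("evaluate", report_path)
    manifest.save(outdir / "manifest.json")
    results["manifest"] = manifest
    logger.info("pipeline complete in %.1f s", time.time() - t_start)
    return results
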