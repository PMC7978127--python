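"""End-to-end orchestration: cohort -> preparation -> age models -> gaps ->
associations -> lifestyle -> trajectory classes -> report.

``run_pipeline`` executes the full analysis under a single config and
master seed and returns a machine-readable results bundle; reruns with
the same config and seed are bit-identical. The planted-truth table of a
synthetic cohort is never read by any analysis stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import age as age_mod
from . import gaps as gaps_mod
from . import lcga as lcga_mod
from . import lifestyle as ls_mod
from .cohort import CohortConfig, SyntheticCohort, generate_cohort, load_cohort
from .prep import (
    ConfoundTable,
    DEFAULT_CONFOUND_SETS,
    FeatureMatrix,
    residualize_features,
    standardize_features,
)

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single entry point configuration for the full analysis."""

    cohort: CohortConfig | None = None
    input_dir: str | None = None
    brain_spec: age_mod.LearnerSpec = field(default_factory=lambda: age_mod.BRAIN_SPEC)
    cognitive_spec: age_mod.LearnerSpec = field(
        default_factory=lambda: age_mod.COGNITIVE_SPEC
    )
    folds: int = 10
    repeats: int = 5
    n_perm: int = 0  # 0 skips the permutation null (1,000 is the reference setting)
    pca_components: int = 20
    predictors: tuple[str, ...] = (
        "education",
        "premorbid_iq",
        "cumulative_lifestyle",
        "lifestyle_class",
    )
    lifestyle_cumulative: str = "mean"  # or "sum"
    lcga_k_max: int = 3
    lcga_order: int = 2
    lcga_starts: int = 50
    lcga_final: int = 5
    blrt_reps: int = 24  # smallest attainable p = 1/25, clears the .05 rule
    run_blrt: bool = True
    outlier_sensitivity: bool = True
    run_pca_variant: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise ValueError("exactly one of cohort config or input_dir must be set")

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = self.cohort.to_dict()
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _prepare_features(cohort: SyntheticCohort) -> tuple[FeatureMatrix, FeatureMatrix]:
    confounds = ConfoundTable(
        cohort.covariates[["scanner", "motion", "sex", "ethnicity", "icv"]]
    )
    brain = cohort.brain_features
    blocks = []
    for modality, confset in (
        ("gray-matter", DEFAULT_CONFOUND_SETS["gray-matter"]),
        ("white-matter", DEFAULT_CONFOUND_SETS["white-matter"]),
    ):
        names = brain.feature_names[brain.modality == modality]
        if len(names) == 0:
            continue
        blocks.append(residualize_features(brain.subset(names), confounds, confset))
    merged = FeatureMatrix(
        pd.concat([b.values for b in blocks], axis=1),
        pd.concat([b.modality for b in blocks]),
    )
    brain_prep = standardize_features(merged)
    cog_prep = standardize_features(cohort.cognitive_features)
    return brain_prep, cog_prep


def _fit_age_model(features, age, spec, tag, cfg: PipelineConfig, seed: int):
    model = age_mod.AgePrediction(features, age, spec, tag=tag)
    res = model.fit(k=cfg.folds, repeats=cfg.repeats, seed=seed)
    out: dict[str, Any] = {"metrics": res.metrics.to_dict()}
    if cfg.n_perm > 0:
        null = res.permutation_null(n_perm=cfg.n_perm)
        out["permutation"] = {
            "p_values": null.p_values,
            "exceedances": null.exceedances,
            "n_perm": null.n_perm,
        }
    return res, out


def _association_block(
    bag, cag, covariates: pd.DataFrame, predictors: dict[str, pd.Series],
) -> tuple[list[gaps_mod.AssociationResult], list[dict]]:
    """Tier-1 associations for every predictor x outcome; tier 2 where the
    tier-1 coefficient is nominally significant (the study's follow-up rule)."""
    results: list[gaps_mod.AssociationResult] = []
    for tag, gap, other in (("BAG", bag, cag), ("CAG", cag, bag)):
        data = covariates.copy()
        data["other_gap"] = other.raw
        for name, series in predictors.items():
            r1 = gaps_mod.associate(gap, series, data, tier=1, predictor_name=name)
            r1.outcome = tag
            results.append(r1)
            if r1.p < 0.05:
                r2 = gaps_mod.associate(gap, series, data, tier=2, predictor_name=name)
                r2.outcome = tag
                results.append(r2)
    rows = [
        {
            "outcome": r.outcome,
            "predictor": r.predictor,
            "tier": r.tier,
            "beta": r.beta,
            "se": r.se,
            "ci_low": r.ci[0],
            "ci_high": r.ci[1],
            "p": r.p,
            "n": r.n,
        }
        for r in results
    ]
    return results, rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a JSON-serializable results bundle."""
    seed = config.seed
    if config.cohort is not None:
        cohort = generate_cohort(dataclasses.replace(config.cohort, seed=seed))
        logger.info("synthesized cohort: n=%d, seed=%d", cohort.config.n_subjects, seed)
    else:
        cohort = load_cohort(config.input_dir)
        logger.info("loaded cohort from %s: n=%d", config.input_dir, len(cohort.covariates))

    bundle: dict[str, Any] = {
        "config_digest": config.digest(),
        "seed": seed,
        "n_subjects": int(len(cohort.covariates)),
    }
    age = cohort.covariates["age"].to_numpy()

    # --- preparation and age models -----------------------------------
    brain_prep, cog_prep = _prepare_features(cohort)
    brain_res, brain_out = _fit_age_model(
        brain_prep, age, config.brain_spec, "brain", config, seed
    )
    cog_res, cog_out = _fit_age_model(
        cog_prep, age, config.cognitive_spec, "cognitive", config, seed + 1
    )
    bundle["age_models"] = {"brain": brain_out, "cognitive": cog_out}

    if config.run_pca_variant:
        pca_block = {}
        for tag, feats, spec, s in (
            ("brain", brain_prep, config.brain_spec, seed + 2),
            ("cognitive", cog_prep, config.cognitive_spec, seed + 3),
        ):
            ncomp = min(config.pca_components, *feats.shape)
            reduced, expl = age_mod.pca_reduce(feats, ncomp)
            m = age_mod.evaluate_cv(reduced, age, spec, k=config.folds,
                                    repeats=config.repeats, seed=s)
            pca_block[tag] = {"metrics": m.to_dict(), "explained_variance": expl,
                              "n_components": ncomp}
        bundle["pca_variant"] = pca_block

    # --- gaps -----------------------------------------------------------
    ids = cohort.covariates.index
    bag = gaps_mod.bias_correct_gap(
        gaps_mod.compute_gap(brain_res.predicted_age.to_numpy(), age, ids, tag="BAG")
    )
    cag = gaps_mod.bias_correct_gap(
        gaps_mod.compute_gap(cog_res.predicted_age.to_numpy(), age, ids, tag="CAG")
    )
    gc = gaps_mod.correlate_gaps(bag, cag)
    bundle["gap_correlation"] = {"r": gc.r, "ci": list(gc.ci), "p": gc.p, "n": gc.n}

    # --- lifestyle scores and trajectory classes ------------------------
    panel = cohort.lifestyle_panel
    wide = ls_mod.index_matrix(panel, phases=range(cohort.config.n_phases))
    cum = ls_mod.cumulative_score(wide, how=config.lifestyle_cumulative).reindex(ids)
    cont = ls_mod.continuous_cumulative_score(panel).reindex(ids)
    zwide = ls_mod.standardize_indices(wide).reindex(ids)
    tm = lcga_mod.transform_time(cohort.config.phase_mean_ages[: cohort.config.n_phases])
    selection, candidates = lcga_mod.enumerate_classes(
        zwide, tm, k_max=config.lcga_k_max, order=config.lcga_order,
        n_starts=config.lcga_starts, n_final=config.lcga_final,
        n_bootstrap=config.blrt_reps, seed=seed + 10, run_blrt=config.run_blrt,
        blrt_spec_overrides={"n_starts": 8, "n_final": 2},
    )
    bundle["lcga"] = {
        "selected_k": selection.selected_k,
        "met_criteria": selection.met_criteria,
        "candidates": selection.audit,
        "class_shares": selection.selected.class_shares.tolist(),
        "coefficients": selection.selected.coefficients.tolist(),
        "residual_sd": float(np.sqrt(selection.selected.sigma2)),
    }
    modal = selection.selected.modal_assignment.reindex(ids)

    # --- associations ----------------------------------------------------
    predictors: dict[str, pd.Series] = {}
    cov = cohort.covariates
    for p in config.predictors:
        if p == "cumulative_lifestyle":
            predictors[p] = cum.fillna(cum.mean())
        elif p == "lifestyle_class":
            # dummy code vs the least favorable class (last label)
            ref = selection.selected.n_classes - 1
            for k in range(selection.selected.n_classes - 1):
                predictors[f"class_{k + 1}_vs_ref"] = (modal == k).astype(float)
        else:
            predictors[p] = cov[p]
    results, rows = _association_block(bag, cag, cov, predictors)

    # FDR families follow the report tables: one family per tier
    assoc = pd.DataFrame(rows)
    assoc["p_corr"] = np.nan
    for tier in sorted(assoc["tier"].unique()):
        m = assoc["tier"] == tier
        assoc.loc[m, "p_corr"] = gaps_mod.fdr_correct(assoc.loc[m, "p"].to_numpy())
    assoc["trend"] = (assoc["p"] < 0.05) & (assoc["p_corr"] >= 0.05)
    bundle["associations"] = assoc.to_dict(orient="records")

    # --- correlated-coefficient comparisons ------------------------------
    z_rows = []
    for name, series in predictors.items():
        data_b = cov.copy(); data_b["other_gap"] = cag.raw
        data_c = cov.copy(); data_c["other_gap"] = bag.raw
        tier1 = assoc[(assoc["predictor"] == name) & (assoc["tier"] == 1)]
        if not (tier1["p"] < 0.05).any():
            continue
        r_c = gaps_mod.associate(cag, series, data_c, tier=2, predictor_name=name)
        r_b = gaps_mod.associate(bag, series, data_b, tier=2, predictor_name=name)
        zc = gaps_mod.z_correlated(r_c.beta, r_c.se, r_b.beta, r_b.se, gc.r)
        z_rows.append(
            {"predictor": name, "beta_cag": r_c.beta, "beta_bag": r_b.beta,
             "z": zc.z, "p": zc.p, "rho": gc.r}
        )
    if z_rows:
        zdf = pd.DataFrame(z_rows)
        zdf["p_corr"] = gaps_mod.fdr_correct(zdf["p"].to_numpy())
        bundle["z_comparisons"] = zdf.to_dict(orient="records")
    else:
        bundle["z_comparisons"] = []

    # --- post hoc continuous lifestyle -----------------------------------
    posthoc_rows = []
    cont_full = cont.dropna()
    for pname, series in (
        ("continuous_cumulative", cont_full["continuous_cumulative"]),
        ("persistent_smoker", cont_full["persistent_smoker"]),
        ("mean_alcohol_units", cont_full["mean_alcohol_units"]),
    ):
        for tag, gap, other in (("BAG", bag, cag), ("CAG", cag, bag)):
            sub = series.index
            g = gaps_mod.compute_gap(
                pd.Series(gap.predicted, index=ids).loc[sub].to_numpy(),
                cov.loc[sub, "age"].to_numpy(), sub, tag=tag,
            )
            data = cov.loc[sub].copy()
            data["other_gap"] = pd.Series(other.raw, index=ids).loc[sub]
            for tier in (1, 2):
                r = gaps_mod.associate(g, series, data, tier=tier, predictor_name=pname)
                posthoc_rows.append(
                    {"outcome": tag, "predictor": pname, "tier": tier, "beta": r.beta,
                     "se": r.se, "p": r.p, "n": r.n}
                )
    ph = pd.DataFrame(posthoc_rows)
    ph["p_corr"] = gaps_mod.fdr_correct(ph["p"].to_numpy())
    bundle["posthoc_continuous"] = ph.to_dict(orient="records")

    # --- outlier sensitivity ----------------------------------------------
    if config.outlier_sensitivity:
        keep = (
            gaps_mod.exclude_outliers(bag.raw)
            & gaps_mod.exclude_outliers(cag.raw)
            & gaps_mod.exclude_outliers(cov["education"].to_numpy())
            & gaps_mod.exclude_outliers(cov["premorbid_iq"].to_numpy())
        )
        kept_ids = ids[keep]
        bag_s = gaps_mod.compute_gap(bag.predicted[keep], age[keep], kept_ids, "BAG")
        cag_s = gaps_mod.compute_gap(cag.predicted[keep], age[keep], kept_ids, "CAG")
        sens_predictors = {
            k: v.loc[kept_ids] for k, v in predictors.items() if not v.loc[kept_ids].isna().any()
        }
        _, sens_rows = _association_block(bag_s, cag_s, cov.loc[kept_ids], sens_predictors)
        bundle["outlier_sensitivity"] = {
            "n_excluded": int((~keep).sum()),
            "associations": sens_rows,
        }

    # per-subject outputs kept as a frame for report writing
    bundle["_per_subject"] = pd.DataFrame(
        {
            "age": age,
            "predicted_brain_age": bag.predicted,
            "predicted_cognitive_age": cag.predicted,
            "bag_raw": bag.raw,
            "bag_corrected": bag.corrected,
            "cag_raw": cag.raw,
            "cag_corrected": cag.corrected,
            "cumulative_lifestyle": cum.to_numpy(),
            "lifestyle_class": modal.to_numpy(),
        },
        index=ids,
    )
    bundle["_lcga_results"] = selection.selected
    return bundle


def _json_ready(bundle: dict) -> dict:
    return {k: v for k, v in bundle.items() if not k.startswith("_")}


def write_report(bundle: dict, out_dir: str | Path, plots: bool = False) -> Path:
    """Write the JSON bundle, per-subject TSV, a text summary, and plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = bundle.get("config_digest", "")
    (out / "results.json").write_text(json.dumps(_json_ready(bundle), indent=2, default=float))

    per_subject: pd.DataFrame | None = bundle.get("_per_subject")
    if per_subject is not None:
        with open(out / "per_subject.tsv", "w") as fh:
            fh.write(f"# config_digest={digest}\n")
            df = per_subject.copy()
            df.insert(0, "subject_id", df.index)
            df.to_csv(fh, sep="\t", index=False)

    lines = [f"# Analysis summary (config {digest})", ""]
    for tag in ("brain", "cognitive"):
        m = bundle["age_models"][tag]["metrics"]
        lines.append(
            f"{tag} age model: R2 = {m['r2_mean']:.2f} +/- {m['r2_sd']:.2f}, "
            f"RMSE = {m['rmse_mean']:.2f}, MAE = {m['mae_mean']:.2f}, r = {m['r']:.2f}"
        )
    g = bundle["gap_correlation"]
    lines.append(
        f"age-adjusted BAG-CAG correlation: r = {g['r']:.3f} "
        f"[{g['ci'][0]:.3f}, {g['ci'][1]:.3f}], p = {g['p']:.3g}"
    )
    lines.append("")
    lines.append("associations (beta [tier] p / p_corr):")
    for row in bundle["associations"]:
        flag = " (trend)" if row.get("trend") else ""
        lines.append(
            f"  {row['outcome']} ~ {row['predictor']}: beta = {row['beta']:+.3f} "
            f"[M{row['tier']}] p = {row['p']:.3g} / {row['p_corr']:.3g}{flag}"
        )
    if bundle["z_comparisons"]:
        lines.append("")
        lines.append("correlated-coefficient comparisons (CAG vs BAG):")
        for row in bundle["z_comparisons"]:
            lines.append(
                f"  {row['predictor']}: Z = {row['z']:.2f}, p = {row['p']:.3g} "
                f"/ {row['p_corr']:.3g}"
            )
    l = bundle["lcga"]
    lines.append("")
    lines.append(
        f"trajectory classes: K = {l['selected_k']} "
        f"(met criteria: {l['met_criteria']}), shares = "
        + ", ".join(f"{s:.1%}" for s in l["class_shares"])
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    if plots and "_lcga_results" in bundle:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        res = bundle["_lcga_results"]
        t = res.model.t
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for k, curve in enumerate(res.class_curves()):
            ax.plot(t, curve, marker="o",
                    label=f"class {k + 1} ({res.class_shares[k]:.0%})")
        ax.set_xlabel("time score ((mean age - 53)/10)")
        ax.set_ylabel("standardized lifestyle index")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "trajectories.png", dpi=120)
        plt.close(fig)
    return out
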