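"""End-to-end pipeline: inputs -> model selection, association, score,
outcomes, analysis tables, manifest -> rendered report.

Every stage writes a TSV artifact; a JSON manifest records the seed, the
config echo and hash, per-stage row counts and accumulated warnings, so a
run is reproducible byte-for-byte from its manifest.  Stage failures abort
with the stage name and offending record in the message.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allele_association import allele_counts, compare_groups, compare_to_reference, hwe_chi2
from .cohort_io import read_annotations, read_genotypes, read_phenotypes
from .errors import WlscoreError
from .genetic_models import loss_outcome, select_models_for_panel
from .inference import (
    GroupSummary,
    anova_from_summary,
    incremental_r2,
    kruskal_wallis,
    paired_t,
    summaries,
    welch_t_from_summary,
)
from .outcomes import derive_outcomes
from .scoring import assign_quartiles, compute_score

BONFERRONI_NOTE = "nominal alpha 0.05 over 25 SNVs; Bonferroni threshold 0.002 (not applied)"


class PipelineError(WlscoreError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Paths, seed and analysis switches for one pipeline run."""

    annotations: str
    genotypes: str
    phenotypes: str
    outdir: str
    seed: int = 0
    threshold_primary: float = 0.02
    threshold_secondary: float = 0.05
    aic_formula: str = "standard"  # or "as-printed"
    outcome_definition: str = "any-loss"  # or "loss-2pct"
    additive_rule: str = "dominant"
    missing_policy: str = "exclude"
    score_weights: str | None = None  # optional TSV rsid<TAB>weight
    covariate_set: str = "table"  # "table" or "methods" predictor ordering

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sex_numeric(s: pd.Series) -> np.ndarray:
    return (s == "M").to_numpy(dtype=float)


def _bool_numeric(s: pd.Series | None, n: int) -> np.ndarray:
    if s is None:
        return np.zeros(n)
    return s.fillna(False).astype(bool).to_numpy(dtype=float)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and return the artifact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    manifest: dict = {
        "tool": "wlscore",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "stages": {},
        "warnings": [],
        "multiple_testing": BONFERRONI_NOTE,
    }

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                self._caught = warnings.catch_warnings(record=True)
                self._log = self._caught.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                for w in self._log:
                    manifest["warnings"].append(f"{name}: {w.message}")
                self._caught.__exit__(None, None, None)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    # --- cohort_io -----------------------------------------------------------
    with _stage("cohort_io"):
        annotations = read_annotations(config.annotations)
        gm = read_genotypes(config.genotypes, annotations)
        phen = read_phenotypes(config.phenotypes)
        manifest["stages"]["cohort_io"] = {
            "n_snvs": len(annotations),
            "n_subjects": gm.n_subjects,
            "n_cases": int((phen.data["group"] == "case").sum()),
            "n_controls": int((phen.data["group"] == "control").sum()),
        }
    order = {sid: i for i, sid in enumerate(gm.subject_ids)}
    phen.data = phen.data.sort_values("subject_id", key=lambda s: s.map(order)).reset_index(drop=True)
    if list(phen.data["subject_id"]) != gm.subject_ids:
        raise PipelineError("cohort_io", WlscoreError("genotype and phenotype subject sets differ"))
    is_case = (phen.data["group"] == "case").to_numpy()

    # --- qc: HWE per SNV -----------------------------------------------------
    with _stage("qc"):
        qc = pd.DataFrame(
            [
                {"rsid": a.rsid, "gene": a.gene, "hwe_chi2": s, "hwe_p": p}
                for a in annotations
                for s, p in [hwe_chi2(gm, a.rsid)]
            ]
        )
        artifacts["qc"] = outdir / "qc.tsv"
        qc.to_csv(artifacts["qc"], sep="\t", index=False)
        manifest["stages"]["qc"] = {"n_snvs": len(qc)}

    # --- outcomes ------------------------------------------------------------
    with _stage("outcomes"):
        out = derive_outcomes(phen, thresholds=(config.threshold_primary, config.threshold_secondary))
        artifacts["outcomes"] = outdir / "outcomes.tsv"
        out.to_csv(artifacts["outcomes"], sep="\t", index=False, na_rep="NA")
        manifest["stages"]["outcomes"] = {
            "n_cases": len(out),
            "category_2pct_sizes": out["category_2pct"].value_counts().to_dict(),
            "category_5pct_sizes": out["category_5pct"].value_counts().to_dict(),
        }

    # --- association ---------------------------------------------------------
    with _stage("association"):
        rows = []
        for a in annotations:
            cc, ct = allele_counts(gm, a.rsid, subset=is_case)
            kc, kt = allele_counts(gm, a.rsid, subset=~is_case)
            cmp_cc = compare_groups(gm, a.rsid, np.where(is_case, "case", "control"), mode="allele")
            cmp_ref = compare_to_reference(cc, ct, a)
            rows.append(
                {
                    "rsid": a.rsid,
                    "gene": a.gene,
                    "case_freq": cc / ct,
                    "control_freq": kc / kt,
                    "ref_freq": a.ref_freq,
                    "chi2_case_control": cmp_cc.statistic,
                    "p_case_control": cmp_cc.p,
                    "chi2_case_reference": cmp_ref.statistic,
                    "p_case_reference": cmp_ref.p,
                }
            )
        assoc = pd.DataFrame(rows)
        artifacts["association"] = outdir / "association.tsv"
        assoc.to_csv(artifacts["association"], sep="\t", index=False)
        manifest["stages"]["association"] = {"n_snvs": len(assoc)}

    # --- model selection -----------------------------------------------------
    with _stage("select_models"):
        gm_cases = gm.subset(is_case)
        if list(out["subject_id"]) != gm_cases.subject_ids:
            raise WlscoreError("outcome rows not aligned with case genotypes")
        y = loss_outcome(out["weight_change_final"].to_numpy(), config.outcome_definition)
        selections = select_models_for_panel(gm_cases, y, aic_formula=config.aic_formula)
        sel_df = pd.DataFrame(
            [
                {
                    "rsid": s.rsid,
                    "aic_additive": s.aic.get("additive", np.nan),
                    "aic_dominant": s.aic.get("dominant", np.nan),
                    "aic_recessive": s.aic.get("recessive", np.nan),
                    "chosen": s.chosen,
                    "tie": s.tie,
                    "skipped": ",".join(s.skipped),
                }
                for s in selections.values()
            ]
        )
        artifacts["model_selection"] = outdir / "model_selection.tsv"
        sel_df.to_csv(artifacts["model_selection"], sep="\t", index=False)
        manifest["stages"]["select_models"] = {
            "chosen_counts": sel_df["chosen"].value_counts().to_dict(),
            "aic_formula": config.aic_formula,
        }

    # --- score ---------------------------------------------------------------
    with _stage("score"):
        weights = None
        if config.score_weights:
            wdf = pd.read_csv(config.score_weights, sep="\t")
            weights = wdf.set_index("rsid").loc[gm.rsids, "weight"].to_numpy()
        score = compute_score(
            gm, selections, weights=weights,
            additive_rule=config.additive_rule, missing=config.missing_policy,
        )
        case_mask = score["subject_id"].isin(set(phen.data.loc[is_case, "subject_id"]))
        case_scores = score.loc[case_mask].reset_index(drop=True)
        labels, cuts, sizes = assign_quartiles(case_scores["score"].to_numpy())
        score["quartile"] = pd.NA
        score.loc[case_mask.values, "quartile"] = labels
        case_scores = score.loc[case_mask.values].reset_index(drop=True)
        artifacts["score"] = outdir / "score.tsv"
        score.to_csv(artifacts["score"], sep="\t", index=False, na_rep="NA")
        manifest["stages"]["score"] = {
            "n_scored": len(score),
            "quartile_cuts": list(map(float, cuts)),
            "quartile_sizes": list(map(int, sizes)),
            "case_score_mean": float(case_scores["score"].mean()),
            "case_score_sd": float(case_scores["score"].std(ddof=1)),
        }

    # --- analyses ------------------------------------------------------------
    with _stage("analyze"):
        merged = (
            case_scores.merge(out, on="subject_id")
            .merge(phen.data, on="subject_id")
        )
        merged["sex_num"] = _sex_numeric(merged["sex"])
        merged["smoking_num"] = _bool_numeric(merged.get("smoking"), len(merged))
        analysis_paths = _write_analysis_tables(merged, phen, config, outdir)
        artifacts.update(analysis_paths)
        manifest["stages"]["analyze"] = {"tables": sorted(analysis_paths)}

    artifacts["manifest"] = outdir / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return artifacts


def _write_analysis_tables(
    merged: pd.DataFrame, phen, config: RunConfig, outdir: Path
) -> dict[str, Path]:
    """The five report tables (baseline groups, incremental R², score-by-
    category, quartile ANOVA, trajectory)."""
    paths: dict[str, Path] = {}

    # baseline characteristics by final 2% weight-change category
    rows = []
    for var in ["age", "baseline_weight", "glucose_baseline", "weight_change_y1"]:
        if var not in merged.columns:
            continue
        sub = merged.dropna(subset=[var])
        if sub["category_2pct"].nunique() < 2:
            continue
        groups = summaries(sub[var].to_numpy(), sub["category_2pct"].to_numpy())
        f, d1, d2, p_anova = anova_from_summary(groups)
        _, _, p_kw = kruskal_wallis(
            *[sub.loc[sub["category_2pct"] == g.label, var].to_numpy() for g in groups]
        )
        for g in groups:
            rows.append(
                {"variable": var, "group": g.label, "n": g.n, "mean": g.mean, "sd": g.sd,
                 "p_anova": p_anova, "p_kruskal_wallis": p_kw}
            )
    paths["table_baseline"] = outdir / "table_baseline_by_category.tsv"
    pd.DataFrame(rows).to_csv(paths["table_baseline"], sep="\t", index=False)

    # incremental adjusted R² tables: year-1 and final change
    predictor_sets = {
        "table": ["baseline_weight", "score", "sex_num", "age", "smoking_num"],
        "methods": ["baseline_weight", "score", "sex_num", "age", "followup_years", "smoking_num"],
    }
    for label, outcome_col, extra in (
        ("y1", "weight_change_y1", []),
        ("final", "weight_change_final", ["followup_years"]),
    ):
        cols = predictor_sets[config.covariate_set]
        cols = cols + [c for c in extra if c not in cols]
        sub = merged.dropna(subset=[outcome_col] + cols)
        rep = incremental_r2(sub[outcome_col].to_numpy(), sub[cols])
        p = outdir / f"table_incremental_r2_{label}.tsv"
        rep.table.to_csv(p, sep="\t", index=False)
        paths[f"table_incremental_{label}"] = p

    # score by weight-change category, with extreme-group summary t-test
    rows = []
    for thr_label in ("category_5pct", "category_2pct"):
        groups = {g.label: g for g in summaries(merged["score"].to_numpy(), merged[thr_label].to_numpy())}
        if not {"lost", "gained"} <= set(groups):
            continue
        ordered = [groups[k] for k in ("lost", "stable", "gained") if k in groups]
        _, _, _, p_anova = anova_from_summary(ordered)
        lo, hi = groups["lost"], groups["gained"]
        _, _, p_extreme = welch_t_from_summary(lo.mean, lo.sd, lo.n, hi.mean, hi.sd, hi.n)
        for g in ordered:
            rows.append(
                {"threshold": thr_label, "group": g.label, "n": g.n, "mean_score": g.mean,
                 "sd_score": g.sd, "p_anova": p_anova, "p_extreme_t": p_extreme}
            )
    paths["table_score_by_category"] = outdir / "table_score_by_category.tsv"
    pd.DataFrame(rows).to_csv(paths["table_score_by_category"], sep="\t", index=False)

    # excess body weight by score quartile
    rows = []
    for var in ("excess_bw_baseline", "loss_excess_bw"):
        groups = summaries(merged[var].to_numpy(), merged["quartile"].astype(int).to_numpy())
        ordered = sorted(groups, key=lambda g: int(g.label))
        _, _, _, p_anova = anova_from_summary(ordered)
        for g in ordered:
            rows.append({"variable": var, "quartile": g.label, "n": g.n, "mean": g.mean,
                         "sd": g.sd, "p_anova": p_anova})
    paths["table_quartiles"] = outdir / "table_quartiles.tsv"
    pd.DataFrame(rows).to_csv(paths["table_quartiles"], sep="\t", index=False)

    # BMI trajectory: mean BMI at baseline and integer follow-up years,
    # with a paired t-test baseline vs year 1
    heights = phen.data.set_index("subject_id")["height"]
    base_w = phen.data.set_index("subject_id")["baseline_weight"]
    visits = phen.visits.copy()
    visits["bmi"] = visits["weight_kg"] / visits["subject_id"].map(heights) ** 2
    visits["year_bin"] = visits["years"].round().astype(int)
    traj = (
        visits.groupby("year_bin")["bmi"].agg(["count", "mean", "std"]).reset_index()
        .rename(columns={"count": "n", "mean": "mean_bmi", "std": "sd_bmi"})
    )
    base_row = pd.DataFrame(
        {"year_bin": [0], "n": [len(phen.cases)],
         "mean_bmi": [(base_w / heights**2)[phen.cases["subject_id"]].mean()],
         "sd_bmi": [(base_w / heights**2)[phen.cases["subject_id"]].std(ddof=1)]}
    )
    traj = pd.concat([base_row, traj[traj["year_bin"] > 0]], ignore_index=True)
    y1 = visits[np.isclose(visits["years"], 1.0)].set_index("subject_id")["bmi"]
    common = [s for s in phen.cases["subject_id"] if s in y1.index]
    p_y1 = np.nan
    if len(common) >= 2:
        bmi0 = (base_w / heights**2)[common]
        try:
            _, _, p_y1 = paired_t(bmi0.to_numpy(), y1[common].to_numpy())
        except WlscoreError:
            pass
    traj["p_paired_vs_baseline_y1"] = p_y1
    paths["trajectory"] = outdir / "trajectory.tsv"
    traj.to_csv(paths["trajectory"], sep="\t", index=False)
    return paths


_REPORT_SECTIONS = [
    ("Baseline characteristics by weight-change category", "table_baseline_by_category.tsv"),
    ("Variance explained, year-1 weight change", "table_incremental_r2_y1.tsv"),
    ("Variance explained, end-of-follow-up weight change", "table_incremental_r2_final.tsv"),
    ("Genetic score by weight-change category", "table_score_by_category.tsv"),
    ("Excess body weight by genetic-score quartile", "table_quartiles.tsv"),
    ("BMI trajectory", "trajectory.tsv"),
]


def render_report(outdir: str | Path) -> str:
    """Render the artifact set as a plain markdown report.

    Missing artifacts are listed as absent; the report always renders.
    """
    outdir = Path(outdir)
    lines = ["# Weight-loss genetic-score report", ""]
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += [
            f"Run seed {manifest.get('seed')}; config hash {manifest.get('config_hash')}.",
            f"Multiple testing: {manifest.get('multiple_testing')}.",
            "",
        ]
        sizes = manifest.get("stages", {}).get("outcomes", {})
        if sizes:
            lines += [f"Category sizes (2%): {sizes.get('category_2pct_sizes')}",
                      f"Category sizes (5%): {sizes.get('category_5pct_sizes')}", ""]
    else:
        lines += ["(manifest absent)", ""]
    for title, fname in _REPORT_SECTIONS:
        lines.append(f"## {title}")
        path = outdir / fname
        if not path.exists():
            lines += ["(artifact absent)", ""]
            continue
        df = pd.read_csv(path, sep="\t")
        lines += ["", df.to_string(index=False, float_format=lambda v: f"{v:.4g}"), ""]
        if len(df) == 0:
            lines += ["(empty: cohort too small for this table)", ""]
    return "\n".join(lines)
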