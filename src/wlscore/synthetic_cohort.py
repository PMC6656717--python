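"""Synthetic weight-loss cohort generator.

Emulates the statistical design the downstream analysis assumes: a large
case group of overweight/obese adults (default 788) followed for 1.5-10
years under a dietary intervention, a smaller normal-BMI control group
(default 168), Hardy-Weinberg genotypes at the 25-SNV obesity panel, and a
year-one fractional weight change in which the true genetic score explains a
configurable share of the variance (default 2.4%) on top of baseline weight,
sex and age.

The year-one change of case i is

    c1_i = mu + b_bw * z_bw_i + beta * (S_i - mean(S)) + b_sex * z_sex_i
           + b_age * z_age_i + eps_i,

with standardized covariates, S_i the true genetic score (risk-genotype
count under the true per-SNV inheritance models), beta calibrated by
:func:`calibrate_score_effect` so the score's variance share equals
``target_partial_r2``, and Gaussian noise carrying the remaining variance.
Later visits regain weight linearly (``regain_rate`` of baseline per year),
giving the U-shaped mean trajectory of a partially maintained intervention.
Negative change means loss throughout.

Reproducibility: one master seed; each stage draws from its own child
stream of the seed sequence, so adding a stage never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    GenotypeMatrix,
    PhenotypeTable,
    SnvAnnotation,
    load_panel,
    write_annotations,
    write_genotypes,
    write_phenotypes,
)
from .errors import ValidationError
from .scoring import risk_genotype_indicators

_TRUTH_PATTERN = ("dominant", "dominant", "additive", "dominant", "recessive")


def default_inheritance_truth(n_snvs: int) -> list[str]:
    """Per-SNV true models: mostly dominant, some additive and recessive."""
    return [_TRUTH_PATTERN[i % len(_TRUTH_PATTERN)] for i in range(n_snvs)]


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with study-scale defaults."""

    n_cases: int = 788
    n_controls: int = 168
    risk_freqs: Sequence[float] | None = None  # default: packaged panel ref_freq
    case_enrichment: float | Sequence[float] = 0.0
    inheritance_truth: Sequence[str] | None = None
    target_partial_r2: float = 0.024
    #: variance shares of the year-1 change attributed to covariates
    var_share_baseline_weight: float = 0.077
    var_share_sex: float = 0.003
    var_share_age: float = 0.001
    y1_change_mean: float = -0.0111  # mean first-year fractional change (1.11% loss)
    y1_change_sd: float = 0.05
    regain_rate: float = 0.002  # fraction of baseline regained per year after year 1
    followup_years_mean: float = 5.58
    followup_years_sd: float = 2.68
    followup_min: float = 1.5
    followup_max: float = 10.0
    case_bmi_mean: float = 29.1
    case_bmi_sd: float = 3.0
    height_mean: float = 1.67
    height_sd: float = 0.09
    score_additive_rule: str = "dominant"
    seed: int = 0

    def validate(self, n_snvs: int) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValidationError("n_cases and n_controls must be >= 0")
        if not 0.0 <= self.target_partial_r2 < 1.0:
            raise ValidationError("target_partial_r2 must be in [0, 1)")
        spent = (
            self.target_partial_r2
            + self.var_share_baseline_weight
            + self.var_share_sex
            + self.var_share_age
        )
        if spent > 1.0 + 1e-12:
            raise ValidationError("variance shares sum to > 1")
        if self.risk_freqs is not None and len(self.risk_freqs) != n_snvs:
            raise ValidationError("risk_freqs length does not match the panel")
        if self.inheritance_truth is not None:
            if len(self.inheritance_truth) != n_snvs:
                raise ValidationError("inheritance_truth length does not match the panel")
            bad = set(self.inheritance_truth) - {"additive", "dominant", "recessive"}
            if bad:
                raise ValidationError(f"unknown inheritance model(s) in truth: {sorted(bad)}")


def simulate_genotypes(
    annotations: Sequence[SnvAnnotation],
    n: int,
    freqs: Sequence[float],
    seed: int | np.random.Generator = 0,
    id_prefix: str = "S",
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: each subject draws two independent risk
    alleles per SNV with the given frequency."""
    freqs = np.asarray(freqs, dtype=float)
    if len(freqs) != len(annotations):
        raise ValidationError("freqs length does not match annotations")
    if ((freqs <= 0.0) | (freqs >= 1.0)).any():
        j = int(np.flatnonzero((freqs <= 0.0) | (freqs >= 1.0))[0])
        raise ValidationError(
            f"{annotations[j].rsid}: risk-allele frequency {freqs[j]} is degenerate "
            "(must be strictly between 0 and 1)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = rng.binomial(2, freqs, size=(n, len(annotations))).astype(float)
    ids = [f"{id_prefix}{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(ids, list(annotations), g)


def calibrate_score_effect(
    target_partial_r2: float, score_variance: float, residual_variance: float
) -> float:
    """Effect size (change-fraction per score unit) hitting a variance share.

    Solves beta^2 * V_s / (beta^2 * V_s + V_r) = target for beta, where V_s
    is the score variance and V_r the variance of everything else in the
    outcome.  Returned on the weight-change scale, where a positive beta
    means a higher score predicts less loss / more gain.
    """
    if not 0.0 <= target_partial_r2 < 1.0:
        raise ValidationError("target_partial_r2 must be in [0, 1)")
    if score_variance <= 0 or residual_variance <= 0:
        raise ValidationError("variances must be positive")
    if target_partial_r2 == 0.0:
        return 0.0
    return float(
        np.sqrt(target_partial_r2 / (1.0 - target_partial_r2) * residual_variance / score_variance)
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd


def _visit_times(followup: float) -> np.ndarray:
    """3 visits in year one, annual visits after, ending at the follow-up time."""
    t = [0.25, 0.5, 1.0] + [float(y) for y in range(2, int(np.floor(followup)) + 1)]
    if followup - t[-1] >= 0.25:
        t.append(float(followup))
    return np.asarray(t)


def simulate_cohort(
    config: SimulationConfig,
    annotations: Sequence[SnvAnnotation] | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable, dict]:
    """Generate (genotypes, phenotypes, truth record) for one cohort.

    Cases carry the full longitudinal design; controls get genotypes and
    baseline covariates only.  The truth record holds the generating beta,
    the true per-SNV models, the true scores and the full config echo.
    """
    if annotations is None:
        annotations = load_panel()
    m = len(annotations)
    config.validate(m)
    freqs = (
        np.asarray([a.ref_freq for a in annotations], dtype=float)
        if config.risk_freqs is None
        else np.asarray(config.risk_freqs, dtype=float)
    )
    enrich = np.broadcast_to(np.asarray(config.case_enrichment, dtype=float), (m,))
    case_freqs = np.clip(freqs + enrich, 0.01, 0.99)
    truth_models = (
        default_inheritance_truth(m)
        if config.inheritance_truth is None
        else list(config.inheritance_truth)
    )

    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(6)]
    rng_gcase, rng_gctrl, rng_cov, rng_noise, rng_follow, rng_gluc = streams

    gm_cases = simulate_genotypes(annotations, config.n_cases, case_freqs, rng_gcase, id_prefix="case")
    gm_ctrl = simulate_genotypes(annotations, config.n_controls, freqs, rng_gctrl, id_prefix="ctrl")
    ids = gm_cases.subject_ids + gm_ctrl.subject_ids
    gm = GenotypeMatrix(ids, list(annotations), np.vstack([gm_cases.g, gm_ctrl.g]))

    selections = {a.rsid: mdl for a, mdl in zip(annotations, truth_models)}
    indicators = risk_genotype_indicators(gm, selections, additive_rule=config.score_additive_rule)
    true_scores = indicators.sum(axis=1)

    nc, nk = config.n_cases, config.n_controls
    # --- baseline covariates -------------------------------------------------
    sex = np.concatenate([
        (rng_cov.random(nc) < 0.597).astype(int),  # cases ~60% men
        (rng_cov.random(nk) < 0.487).astype(int),
    ])
    age = np.concatenate([
        np.clip(rng_cov.normal(59.0, 11.6, nc), 18, 90),
        np.clip(rng_cov.normal(48.1, 14.0, nk), 18, 90),
    ])
    height = np.clip(rng_cov.normal(config.height_mean, config.height_sd, nc + nk), 1.40, 2.10)
    bmi = np.concatenate([
        np.clip(rng_cov.normal(config.case_bmi_mean, config.case_bmi_sd, nc), 25.05, 39.95),
        np.clip(rng_cov.normal(22.0, 1.6, nk), 18.6, 24.95),
    ])
    weight0 = bmi * height**2
    smoking = rng_cov.random(nc + nk) < 0.25
    diabetes = np.concatenate([rng_cov.random(nc) < 0.198, rng_cov.random(nk) < 0.053])
    hypertension = np.concatenate([rng_cov.random(nc) < 0.379, rng_cov.random(nk) < 0.158])
    glucose0 = np.clip(rng_cov.normal(98.0, 24.0, nc + nk), 55, None)

    followup = np.round(
        np.clip(
            rng_follow.normal(config.followup_years_mean, config.followup_years_sd, nc),
            config.followup_min,
            config.followup_max,
        ),
        2,
    )

    # --- year-one weight change for cases -----------------------------------
    sigma = config.y1_change_sd
    t = config.target_partial_r2
    case_scores = true_scores[:nc]
    score_var = float(case_scores.var()) if nc > 1 else 0.0
    beta = (
        calibrate_score_effect(t, score_var, sigma**2 * (1.0 - t))
        if (t > 0 and score_var > 0)
        else 0.0
    )
    v_noise = max(
        0.0,
        1.0 - t - config.var_share_baseline_weight - config.var_share_sex - config.var_share_age,
    )
    b_bw = -np.sqrt(config.var_share_baseline_weight) * sigma
    b_sex = -np.sqrt(config.var_share_sex) * sigma
    b_age = np.sqrt(config.var_share_age) * sigma
    if nc:
        noise = rng_noise.normal(0.0, sigma * np.sqrt(v_noise), nc)
        c1 = (
            config.y1_change_mean
            + b_bw * _standardize(weight0[:nc])
            + beta * (case_scores - case_scores.mean())
            + b_sex * _standardize(sex[:nc].astype(float))
            + b_age * _standardize(age[:nc])
            + noise
        )
    else:
        c1 = np.empty(0)

    # --- longitudinal visits -------------------------------------------------
    visit_rows: list[tuple[str, float, float]] = []
    final_change = np.empty(nc)
    for i in range(nc):
        times = _visit_times(followup[i])
        change = np.where(times <= 1.0, c1[i] * times, c1[i] + config.regain_rate * (times - 1.0))
        weights = weight0[i] * (1.0 + change)
        visit_rows.extend((ids[i], float(tt), float(w)) for tt, w in zip(times, weights))
        final_change[i] = change[-1]

    gchange = 0.3 * final_change + rng_gluc.normal(0.0, 0.15, nc)
    glucose_final = np.clip(glucose0[:nc] * (1.0 + gchange), 40, None)

    data = pd.DataFrame(
        {
            "subject_id": ids,
            "group": ["case"] * nc + ["control"] * nk,
            "sex": np.where(sex == 1, "M", "F"),
            "age": np.round(age, 1),
            "height": np.round(height, 3),
            "baseline_weight": np.round(weight0, 2),
            "followup_years": np.concatenate([followup, np.full(nk, np.nan)]),
            "glucose_baseline": np.round(glucose0, 1),
            "glucose_final": np.round(np.concatenate([glucose_final, np.full(nk, np.nan)]), 1),
            "smoking": smoking,
            "diabetes": diabetes,
            "hypertension": hypertension,
        }
    )
    visits = pd.DataFrame(visit_rows, columns=["subject_id", "years", "weight_kg"])
    phenotypes = PhenotypeTable(data, visits)

    truth = {
        "seed": config.seed,
        "beta": float(beta),
        "intercept": config.y1_change_mean,
        "sigma_total": sigma,
        "coefficients": {"baseline_weight_z": b_bw, "sex_z": b_sex, "age_z": b_age},
        "noise_sd": float(sigma * np.sqrt(v_noise)),
        "noise_distribution": "gaussian",
        "true_models": selections,
        "true_scores": dict(zip(ids, true_scores.tolist())),
        "score_variance_cases": score_var,
        "config": dataclasses.asdict(config),
    }
    truth["config"]["risk_freqs"] = freqs.tolist()
    truth["config"]["inheritance_truth"] = truth_models
    return gm, phenotypes, truth


def write_cohort(
    gm: GenotypeMatrix, phenotypes: PhenotypeTable, truth: dict, outdir: str | Path
) -> dict[str, Path]:
    """Write the three cohort TSVs plus the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_annotations(gm.snvs, paths["annotations"])
    write_genotypes(gm, paths["genotypes"])
    write_phenotypes(phenotypes, paths["phenotypes"])

    def _coerce(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    paths["truth"].write_text(json.dumps(truth, indent=1, default=_coerce))
    return paths
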