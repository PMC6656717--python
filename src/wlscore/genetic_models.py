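"""Inheritance-model coding and per-SNV model selection by AIC.

Each biallelic SNV, stored as a risk-allele count g in {0, 1, 2}, can enter a
regression under three codings:

* additive  — the count itself (0, 1, 2),
* dominant  — 1 if at least one risk allele (MM + Mm vs mm),
* recessive — 1 only for risk-allele homozygotes (MM vs Mm + mm).

For every SNV the three codings are fitted as logistic regressions on a
binary weight-loss outcome and the coding with the smallest AIC wins.  The
default AIC is the standard 2k - 2*ln(L); an "as-printed" variant 2k + ln(L)
is available behind a flag for fidelity experiments (with equal k across the
three codings, both formulas are monotone in ln L, so with the standard
formula the ranking is by likelihood — the as-printed variant inverts it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import FitError, SeparationError, ValidationError

MODELS = ("additive", "dominant", "recessive")

#: AIC difference below which two models are considered exactly tied.
TIE_TOL = 1e-9


def code_genotype(g, model: str):
    """Map risk-allele counts to the numeric predictor of one inheritance model.

    Accepts scalars or arrays; NaN (missing genotype) propagates.
    """
    arr = np.asarray(g, dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        bad = arr[~ok].flat[0]
        raise ValidationError(f"genotype value {bad!r} outside {{0, 1, 2, NA}}")
    if model == "additive":
        coded = arr
    elif model == "dominant":
        coded = np.where(np.isnan(arr), np.nan, (arr >= 1).astype(float))
    elif model == "recessive":
        coded = np.where(np.isnan(arr), np.nan, (arr == 2).astype(float))
    else:
        raise ValidationError(f"unknown inheritance model {model!r}")
    if np.isscalar(g) or np.ndim(g) == 0:
        return float(coded)
    return coded


@dataclass
class BinaryFit:
    """Result of a maximum-likelihood logistic fit."""

    coef: np.ndarray  # intercept first
    log_likelihood: float
    k: int  # number of estimated coefficients, intercept included


def fit_binary(outcome, predictors) -> BinaryFit:
    """Fit a logistic regression of a 0/1 outcome on one or more predictors.

    Complete separation raises :class:`SeparationError` rather than silently
    returning a diverged fit; a rank-deficient design or one-class outcome
    raises :class:`FitError`.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isin(y, (0.0, 1.0)).all():
        raise FitError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise FitError("outcome has a single class; logistic fit undefined")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("rank-deficient predictor matrix")
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"complete separation in logistic fit: {exc}") from None
    if not res.mle_retvals.get("converged", True) or np.abs(res.params).max() > 50:
        raise SeparationError("logistic fit diverged (quasi-complete separation)")
    return BinaryFit(coef=np.asarray(res.params), log_likelihood=float(res.llf), k=design.shape[1])


def aic(k: int, log_likelihood: float, formula: str = "standard") -> float:
    """Akaike information criterion for a fitted model.

    ``standard`` is 2k - 2*ln(L); ``as-printed`` computes 2k + ln(L), a
    nonstandard variant kept only for fidelity experiments.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if formula == "standard":
        return 2.0 * k - 2.0 * log_likelihood
    if formula == "as-printed":
        return 2.0 * k + log_likelihood
    raise ValidationError(f"unknown AIC formula {formula!r}")


@dataclass
class ModelSelection:
    """Per-SNV inheritance-model selection record."""

    rsid: str
    log_likelihood: dict[str, float]
    k: dict[str, int]
    aic: dict[str, float]
    chosen: str
    tie: bool
    skipped: list[str] = field(default_factory=list)
    aic_formula: str = "standard"


def select_inheritance_model(
    genotypes,
    outcome,
    covariates=None,
    rsid: str = "",
    aic_formula: str = "standard",
) -> ModelSelection:
    """Choose the inheritance coding with minimal AIC for one SNV.

    Subjects with a missing genotype are dropped pairwise.  A coding whose
    predictor is constant in the retained subjects (e.g. recessive with no
    risk-homozygotes) is skipped.  Exact AIC ties are broken in the order
    additive > dominant > recessive with the tie flag set.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if g.shape[0] != y.shape[0]:
        raise ValidationError("genotype and outcome vectors differ in length")
    keep = ~np.isnan(g)
    g, y = g[keep], y[keep]
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov = cov[keep]

    lls: dict[str, float] = {}
    ks: dict[str, int] = {}
    aics: dict[str, float] = {}
    skipped: list[str] = []
    for model in MODELS:
        coded = code_genotype(g, model)
        if np.ptp(coded) == 0:
            skipped.append(model)
            continue
        X = coded[:, None] if cov is None else np.column_stack([coded, cov])
        try:
            fit = fit_binary(y, X)
        except SeparationError:
            skipped.append(model)
            continue
        lls[model] = fit.log_likelihood
        ks[model] = fit.k
        aics[model] = aic(fit.k, fit.log_likelihood, aic_formula)
    if not aics:
        raise FitError(f"{rsid or 'SNV'}: no inheritance model could be fitted")
    best = min(aics.values())
    contenders = [m for m in MODELS if m in aics and aics[m] - best < TIE_TOL]
    chosen = contenders[0]  # MODELS order encodes the tie-break preference
    return ModelSelection(
        rsid=rsid,
        log_likelihood=lls,
        k=ks,
        aic=aics,
        chosen=chosen,
        tie=len(contenders) > 1,
        skipped=skipped,
        aic_formula=aic_formula,
    )


def select_models_for_panel(
    gm,
    outcome,
    covariates=None,
    aic_formula: str = "standard",
) -> dict[str, ModelSelection]:
    """Run per-SNV selection over a whole genotype matrix.

    ``outcome`` is the binary weight-loss indicator aligned to the matrix's
    subject order.
    """
    return {
        ann.rsid: select_inheritance_model(
            gm.g[:, j], outcome, covariates=covariates, rsid=ann.rsid, aic_formula=aic_formula
        )
        for j, ann in enumerate(gm.snvs)
    }


def loss_outcome(weight_change, definition: str = "any-loss") -> np.ndarray:
    """Binarize a weight-change fraction into the selection outcome.

    ``any-loss`` marks change < 0; ``loss-2pct`` marks change < -0.02 (the
    2% category boundary).
    """
    change = np.asarray(weight_change, dtype=float)
    if definition == "any-loss":
        return (change < 0).astype(float)
    if definition == "loss-2pct":
        return (change < -0.02).astype(float)
    raise ValidationError(f"unknown outcome definition {definition!r}")
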