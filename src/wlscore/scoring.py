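"""Genetic-score construction and quartile assignment.

The score is the per-subject count, over the 25-SNV panel, of loci at which
the risk genotype is present under that SNV's selected inheritance model:
dominant-selected loci contribute 1 when g >= 1, recessive-selected when
g == 2.  Additive-selected loci have no natural "presence" indicator; by
default they use the dominant indicator (at least one risk allele), with a
homozygote-only alternative behind a flag.  An experimental weighted mode
multiplies each indicator by a user-supplied per-SNV weight.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import GenotypeMatrix
from .errors import DegenerateDataError, ValidationError
from .genetic_models import ModelSelection


def _indicator_rule(chosen: str, additive_rule: str) -> str:
    if chosen == "additive":
        if additive_rule not in ("dominant", "recessive"):
            raise ValidationError(f"additive_rule must be dominant or recessive, got {additive_rule!r}")
        return additive_rule
    if chosen not in ("dominant", "recessive"):
        raise ValidationError(f"unknown selected model {chosen!r}")
    return chosen


def risk_genotype_indicators(
    gm: GenotypeMatrix,
    selections: Mapping[str, ModelSelection | str],
    additive_rule: str = "dominant",
) -> np.ndarray:
    """Subjects x SNVs 0/1 indicators of risk-genotype presence (NaN missing)."""
    ind = np.full_like(gm.g, np.nan)
    for j, ann in enumerate(gm.snvs):
        if ann.rsid not in selections:
            raise ValidationError(f"no selected inheritance model for {ann.rsid}")
        sel = selections[ann.rsid]
        chosen = sel if isinstance(sel, str) else sel.chosen
        rule = _indicator_rule(chosen, additive_rule)
        g = gm.g[:, j]
        present = (g >= 1) if rule == "dominant" else (g == 2)
        ind[:, j] = np.where(np.isnan(g), np.nan, present.astype(float))
    return ind


def compute_score(
    gm: GenotypeMatrix,
    selections: Mapping[str, ModelSelection | str],
    weights: Sequence[float] | None = None,
    additive_rule: str = "dominant",
    missing: str = "exclude",
) -> pd.DataFrame:
    """Per-subject genetic score.

    Subjects missing any panel genotype are excluded by default
    (``missing='exclude'``); ``missing='impute'`` substitutes each SNV's
    modal genotype instead.  Returns columns subject_id, score, n_snvs_used.
    """
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape[0] != len(gm.snvs):
            raise ValidationError(
                f"weights length {weights.shape[0]} does not match panel size {len(gm.snvs)}"
            )
    work = gm
    if missing == "impute":
        g = gm.g.copy()
        for j in range(g.shape[1]):
            col = g[:, j]
            if np.isnan(col).all():
                continue
            vals, counts = np.unique(col[~np.isnan(col)], return_counts=True)
            col[np.isnan(col)] = vals[np.argmax(counts)]
        work = GenotypeMatrix(gm.subject_ids, gm.snvs, g)
    elif missing != "exclude":
        raise ValidationError(f"missing policy must be 'exclude' or 'impute', got {missing!r}")

    ind = risk_genotype_indicators(work, selections, additive_rule=additive_rule)
    complete = ~np.isnan(ind).any(axis=1)
    if not complete.all():
        n_drop = int((~complete).sum())
        all_missing = int(np.isnan(ind).all(axis=1).sum())
        msg = f"{n_drop} subject(s) with missing genotypes excluded from the score"
        if all_missing:
            msg += f" ({all_missing} with no genotypes at all)"
        warnings.warn(msg, stacklevel=2)
    w = np.ones(len(work.snvs)) if weights is None else weights
    scores = np.where(complete, (np.nan_to_num(ind) * w).sum(axis=1), np.nan)
    out = pd.DataFrame(
        {
            "subject_id": work.subject_ids,
            "score": scores,
            "n_snvs_used": np.where(complete, len(work.snvs), 0).astype(int),
        }
    )
    return out[complete].reset_index(drop=True)


def assign_quartiles(scores) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quartile labels (1-4) by the empirical 25/50/75 percentiles.

    Ties at a cut point go to the LOWER quartile, so with many tied integer
    scores the four groups can be markedly unequal.  Returns (labels,
    cut_points, group_sizes).  Constant scores raise (quartiles undefined).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 4:
        raise ValidationError("need at least 4 scored subjects for quartiles")
    if np.isnan(s).any():
        raise ValidationError("NaN score passed to assign_quartiles")
    if np.ptp(s) == 0:
        raise DegenerateDataError("constant scores: quartiles undefined")
    cuts = np.percentile(s, [25, 50, 75])
    labels = 1 + (s > cuts[0]).astype(int) + (s > cuts[1]).astype(int) + (s > cuts[2]).astype(int)
    sizes = np.array([(labels == q).sum() for q in (1, 2, 3, 4)])
    return labels, cuts, sizes
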