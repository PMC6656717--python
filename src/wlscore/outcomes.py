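"""Weight-change outcomes, loss/stable/gain categories and excess body weight.

Sign convention: weight change is the signed fraction
``(final - baseline) / baseline``, so losers are NEGATIVE.  A strict-formula
mode with the opposite orientation ((baseline - final)/baseline, losers
positive) exists for cross-checking against sources that state the formula
that way; everything downstream assumes the default.

Categories: a subject is "lost" when the change is below -threshold,
"gained" above +threshold, and "stable" within the band, boundaries
included.  Thresholds of 2% and 5% are both derived for each subject.

Excess body weight is the weight above a BMI of 25 at the subject's height,
weight - 25*height^2 (kg); it may be negative for lean subjects and is not
clamped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_io import PhenotypeTable
from .errors import ValidationError

CATEGORIES = ("lost", "stable", "gained")


def weight_change(baseline_kg: float, final_kg: float, strict_formula: bool = False) -> float:
    """Signed fractional weight change; negative means loss (default)."""
    if baseline_kg <= 0:
        raise ValidationError("baseline weight must be positive")
    change = (final_kg - baseline_kg) / baseline_kg
    return -change if strict_formula else change


def glucose_change(baseline: float, final: float, strict_formula: bool = False) -> float:
    """Signed fractional glucose change (same formula as weight change)."""
    return weight_change(baseline, final, strict_formula=strict_formula)


def categorize(change: float, threshold: float = 0.02) -> str:
    """Classify a signed change fraction as lost / stable / gained."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if change < -threshold:
        return "lost"
    if change > threshold:
        return "gained"
    return "stable"


def excess_body_weight(weight_kg: float, height_m: float) -> float:
    """Kilograms above the weight giving BMI 25; negative if below it."""
    if height_m <= 0:
        raise ValidationError("height must be positive")
    return weight_kg - 25.0 * height_m**2


def _visit_weight_at(visits: pd.DataFrame, target_years: float, window: float) -> float:
    """Weight at the visit closest to ``target_years`` within +/- window, else NaN."""
    if visits.empty:
        return np.nan
    d = (visits["years"] - target_years).abs()
    i = d.idxmin()
    if d.loc[i] > window:
        return np.nan
    return float(visits.loc[i, "weight_kg"])


def derive_outcomes(
    phenotypes: PhenotypeTable,
    thresholds: tuple[float, float] = (0.02, 0.05),
    year1_window: float = 0.5,
) -> pd.DataFrame:
    """Per-case outcome records.

    Year-1 change uses the visit closest to 1.0 years within +/-``year1_window``
    (NaN if none); final change uses the last recorded visit.  Categories at
    both thresholds are computed for the year-1 and final change.  Glucose
    change is reported only for non-diabetic subjects with both measurements
    (diabetics are excluded upstream of the glucose models).
    """
    t_lo, t_hi = thresholds
    rows = []
    by_subject = dict(tuple(phenotypes.visits.groupby("subject_id", sort=False)))
    empty = phenotypes.visits.iloc[0:0]
    for _, subj in phenotypes.cases.iterrows():
        sid = subj["subject_id"]
        visits = by_subject.get(sid, empty)
        post = visits[visits["years"] > 0]
        if post.empty:
            raise ValidationError(f"case {sid!r} has no post-baseline visit")
        b = float(subj["baseline_weight"])
        w_y1 = _visit_weight_at(post, 1.0, year1_window)
        w_final = float(post.sort_values("years").iloc[-1]["weight_kg"])
        c_y1 = weight_change(b, w_y1) if not np.isnan(w_y1) else np.nan
        c_final = weight_change(b, w_final)
        h = float(subj["height"])
        ebw0 = excess_body_weight(b, h)
        ebw1 = excess_body_weight(w_final, h)
        gchange = np.nan
        diabetic = bool(subj.get("diabetes", False)) if not pd.isna(subj.get("diabetes", np.nan)) else False
        gb, gf = subj.get("glucose_baseline", np.nan), subj.get("glucose_final", np.nan)
        if not diabetic and not pd.isna(gb) and not pd.isna(gf):
            gchange = glucose_change(float(gb), float(gf))
        rows.append(
            {
                "subject_id": sid,
                "weight_change_y1": c_y1,
                "weight_change_final": c_final,
                "category_2pct_y1": categorize(c_y1, t_lo) if not np.isnan(c_y1) else "NA",
                "category_5pct_y1": categorize(c_y1, t_hi) if not np.isnan(c_y1) else "NA",
                "category_2pct": categorize(c_final, t_lo),
                "category_5pct": categorize(c_final, t_hi),
                "glucose_change": gchange,
                "excess_bw_baseline": ebw0,
                "excess_bw_final": ebw1,
                "loss_excess_bw": ebw1 - ebw0,
            }
        )
    return pd.DataFrame(rows)
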