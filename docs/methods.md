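# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `wlscore`. Problem sizes and simulator
defaults are the package's own design choices for a realistic dietary
weight-loss cohort.

## Genetic score

The panel holds 25 obesity-associated SNVs, each annotated with a risk
allele, the other allele, and a reference population frequency
(`ref_freq`, with `ref_n = 5008` chromosomes as the reference panel size).
Genotypes are stored as risk-allele counts g ∈ {0, 1, 2}; NaN marks a
missing call and propagates. When importing VCF, the risk allele is matched
against REF/ALT: ALT = risk counts ALT alleles, REF = risk counts 2 − ALT;
allele mismatches become missing with a warning.

Per SNV, the inheritance coding is chosen by fitting a logistic regression
of a binary weight-loss outcome (default: any loss at end of follow-up) on
each of the three codings —

- additive: x = g,
- dominant: x = 1{g ≥ 1} (risk carriers vs non-carriers),
- recessive: x = 1{g = 2} (risk homozygotes vs the rest),

and minimising AIC = 2k − 2·lnL. All three codings have the same k, so the
default formula ranks by log-likelihood; an `as-printed` variant
(2k + lnL) is provided for cross-checking against sources that state the
formula that way, but it reverses the ranking at equal k and is not the
default. Exact AIC ties (which arise when two codings produce identical
design vectors, e.g. with no risk homozygotes in the sample) are broken in
the order additive > dominant > recessive, with a tie flag on the result;
constant codings are skipped rather than fitted.

The score is the unweighted count of risk genotypes over the panel
(dominant rule for additive-selected SNVs by default, switchable), so
S ∈ [0, 25]. Subjects with missing genotypes are excluded from scoring by
default (`missing="impute"` substitutes the modal genotype instead). An
optional per-SNV weight vector exists for sensitivity analyses; the primary
analysis is unweighted because per-SNV effect estimates at this panel size
are too noisy to stabilise weights. Quartiles are cut at the 25/50/75
sample percentiles with ties assigned to the lower quartile, so quartile
sizes are unequal when the integer score ties at a cut.

## Outcomes

Relative weight change is (final − baseline)/baseline, negative = loss; a
`strict_formula` flag provides the opposite orientation for cross-checks.
Year-1 change uses the visit closest to 1.0 years within ±0.5 years (NaN
if none); end-of-follow-up change uses the last recorded visit. Categories
at thresholds t ∈ {2%, 5%}: lost if change < −t, gained if change > +t,
stable otherwise (boundaries are stable). Excess body weight is
weight − 25·height² (kg above BMI 25), unclamped; its change over
follow-up equals the raw weight change in kg, since the height term
cancels. Glucose change is reported only for non-diabetic subjects with
both measurements.

## Inference

The incremental ("cumulative corrected") R² table adds predictors in a
fixed order — baseline weight, score, sex, age, smoking (a `methods`
variant inserts follow-up duration) — recording the adjusted R² of each
nested OLS model while taking coefficients, 95% CIs and p-values from the
full model. The score's increment over baseline weight alone is the
headline quantity. End-of-follow-up models additionally include follow-up
duration.

Group tests exist in raw-data and summary-statistic forms. The summary
forms (Welch t with Satterthwaite df, or pooled Student t; one-way ANOVA
rebuilt from the between/within sum-of-squares decomposition of (mean, sd,
n) triplets) are exact identities of their raw-data counterparts when the
summaries come from the raw sample, which lets published group tables be
tested directly. Allele and genotype frequencies are compared by Pearson
chi-squared without continuity correction; comparisons against the
reference population use pseudo-counts round(ref_freq · ref_n). A zero
margin raises an error; expected counts below 5 warn. Hardy–Weinberg
equilibrium is checked per SNV with a 1-df chi-squared. The pipeline
manifest notes the Bonferroni threshold (0.05/25 = 0.002) but p-values are
reported nominally.

## Synthetic cohorts

The simulator emulates a dietary-treatment cohort: overweight/obese cases
(baseline BMI uniform-clipped to [25, 40], drawn N(29.1, 3.0)) and
normal-weight controls (BMI in [18.5, 25]), heights N(1.67, 0.09) m,
follow-up truncated-normal 5.58 ± 2.68 years clipped to [1.5, 10], visits
at 0.25/0.5/1.0 years then annually plus the final visit. Genotypes are
drawn under Hardy–Weinberg at per-SNV risk-allele frequencies; the true
per-SNV inheritance models default to a fixed mixed pattern.

Year-1 relative weight change for cases is

c₁ = μ + b_bw·z(bw) + β·(S − S̄) + b_sex·z(sex) + b_age·z(age) + ε,

with μ = −0.0111 (mean 1.11% loss at one year) and total SD σ = 0.05.
Variance shares allocate σ²: baseline weight 0.077, genetic score 0.024
(the calibration target), sex 0.003, age 0.001, remainder noise. The score
effect is solved in closed form so that its partial R² over the remaining
variance hits the target: β = sqrt(t/(1 − t) · V_resid/V_score)
(`calibrate_score_effect`), applied with a positive sign on the change
scale — a higher risk score means less loss. After year 1, weight drifts
back at `regain_rate` = 0.002 (0.2% of baseline per year), a slow-regain
abstraction: it reproduces gradual long-term regain without modelling the
lapse/relapse dynamics, seasonal variation or treatment changes of real
cohorts, so very long follow-ups remain mildly net-negative rather than
crossing back above baseline. Glucose change is coupled to final weight
change (slope 0.3 plus noise). All randomness flows from one seed through
`numpy.random.SeedSequence` sub-streams, so cohorts are bit-reproducible.

What the generator does *not* emulate: linkage disequilibrium between
SNVs, genotyping error, informative dropout (follow-up length is
independent of outcome), measurement error in weights, or non-Gaussian
change distributions.

## Numerical choices

- Logistic fits use maximum likelihood via statsmodels; perfect separation
  and single-class outcomes are raised as errors rather than returning
  unstable estimates (|coef| > 50 is also treated as separation).
- OLS rank deficiency is detected and the collinear columns are named by
  rank-drop probing.
- AIC tie tolerance is 1e-9 on the AIC scale — far above floating-point
  noise for identical designs, far below any real likelihood difference.
- Welch df is computed explicitly (Satterthwaite); summary ANOVA rebuilds
  SS_between from means/sizes and SS_within from sample SDs.
- Quartile cuts use linear-interpolation percentiles (numpy default).

## Open design decisions

- **Additive-selected SNVs in the score.** A presence/absence score needs a
  binary rule; the dominant rule (g ≥ 1) is the default on the grounds that
  a single risk allele already shifts an additive effect, with the
  recessive rule available as a switch.
- **Unweighted score.** Equal weights are the primary definition; the
  weighted variant exists only for sensitivity analyses.
- **Outcome for model selection.** Any loss at end of follow-up is the
  default binary outcome; a 2%-loss variant is provided.
- **Regain rate.** 0.002/year is deliberately conservative; pushing it high
  enough to cross baseline within the observed follow-up window would
  contradict the mildly negative long-term mean changes the simulator is
  calibrated to.

## Limitations

Summary-statistic tests inherit the assumptions of their raw-data
counterparts (normality for t/ANOVA) and cannot check them. The chi-squared
reference comparison treats the reference frequency as a finite sample of
`ref_n` chromosomes; for very large `ref_n` it approaches a one-sample
test. Selection accuracy of the AIC procedure depends strongly on effect
size and allele frequency; at small n or extreme frequencies the additive
and dominant codings are nearly collinear and misselection between them is
common (and largely inconsequential for the score, which binarises both the
same way by default).
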