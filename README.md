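# wlscore

Genetic risk scores and weight-loss outcome analysis for longitudinal
obesity cohorts.

`wlscore` implements an end-to-end analysis of how a multi-locus genetic
risk score relates to weight change under dietary treatment:

- **Panel and genotypes.** A 25-SNV obesity risk panel (TSV annotations with
  risk/other alleles and reference frequencies), genotype I/O as risk-allele
  counts with VCF orientation support, and Hardy–Weinberg QC.
- **Inheritance-model selection.** Per SNV, logistic regressions of a binary
  weight-loss outcome under additive, dominant and recessive codings are
  compared by AIC; the winning coding defines the SNV's contribution to the
  score.
- **Genetic score.** The unweighted count of risk genotypes across the panel
  (dominant: at least one risk allele; recessive: two risk alleles), giving a
  score in 0–25, with quartile grouping.
- **Outcomes.** Relative weight change at one year and at end of follow-up,
  lost/stable/gained categories at 2% and 5% thresholds, excess body weight
  (kg above BMI 25) and its change, and glucose change in non-diabetics.
- **Inference.** Incremental ("cumulative corrected") adjusted-R² regression
  tables, allele-frequency chi-squared tests against control and reference
  groups, and t/ANOVA/Kruskal–Wallis tests that work from raw data *or*
  directly from published (mean, sd, n) group summaries.
- **Synthetic cohorts.** A calibrated simulator producing genotypes,
  longitudinal visit weights and covariates with a known generating model,
  for power analysis and for validating the whole pipeline against ground
  truth.

## The model in brief

For subject *i*, the score is
S_i = Σ_j 1{genotype at SNV j is a risk genotype under the selected coding}.
Relative weight change at one year, c_i = (w_i(1yr) − w_0)/w_0 (negative =
loss), is analysed with nested linear models

c ~ baseline weight → + S → + sex → + age → + smoking,

reporting each predictor's full-model coefficient with 95% CI beside the
adjusted R² of the nested model it completes; the score's increment in
adjusted R² over baseline weight alone quantifies the variance in weight
change explained by genetics. Per-SNV inheritance codings are chosen by
minimising AIC = 2k − 2·lnL across the three codings of a logistic model
for the binary loss outcome.

## Worked example

Simulate a cohort of 788 treated cases and 168 normal-weight controls, run
every analysis stage, and render the report:

```bash
wlscore simulate --out cohort --seed 7
wlscore run \
  --annotations cohort/annotations.tsv \
  --genotypes cohort/genotypes.tsv \
  --phenotypes cohort/phenotypes.tsv \
  --out run --seed 7
wlscore report --artifacts run
```

The report opens with the category breakdown and the incremental-R² table
(output abridged):

```
# Weight-loss genetic-score report

Run seed 7; config hash d49547bcc60e7f45.
Multiple testing: nominal alpha 0.05 over 25 SNVs; Bonferroni threshold 0.002 (not applied).

Category sizes (2%): {'gained': 265, 'lost': 285, 'stable': 238}
Category sizes (5%): {'gained': 120, 'lost': 136, 'stable': 532}

## Variance explained, year-1 weight change

      predictor      beta     ci_low    ci_high         p  cum_adj_r2
baseline_weight -0.001054   -0.00133 -0.0007768 2.117e-13     0.06415
          score  0.002577   0.001076   0.004079 0.0007915     0.07645
        sex_num -0.006789   -0.01357 -1.079e-05   0.04964      0.0796
            age 0.0001704 -0.0001234  0.0004641    0.2553     0.08005
    smoking_num   0.00582  -0.001778    0.01342    0.1331     0.08153
```

Adding the genetic score lifts the adjusted R² from 0.064 to 0.076: in this
seed the score explains about 1.2% of the year-1 weight-change variance
beyond baseline weight, with a positive coefficient (higher score, less
loss; p ≈ 8 × 10⁻⁴). The simulator's design target for this increment is
2.4% in expectation; any single cohort scatters around it.

Published group summaries can be tested without raw data:

```bash
wlscore summary-tests \
  --t "18.36,2.68,141:22.28,3.04,148" \
  --anova "-1.47,4.06,173:-0.90,5.73,185:-0.77,4.35,275:2.15,4.66,155"
```

```
t = -11.6416	df = 285.30	p = 6.87e-26
F = 19.3617	df = (3, 784)	p = 4.06e-12
```

The library mirrors the CLI:

```python
import wlscore as w

gm, phen, truth = w.simulate_cohort(w.SimulationConfig(seed=7))
out = w.derive_outcomes(phen)                     # per-case weight changes
score = w.compute_score(gm, truth["true_models"])  # 0-25 risk-genotype count
```

## Layout

```
src/wlscore/
  cohort_io.py          annotations, genotypes (TSV/VCF), phenotypes
  genetic_models.py     codings, logistic fits, AIC model selection
  scoring.py            genetic score and quartiles
  outcomes.py           weight change, categories, excess body weight
  allele_association.py chi-squared frequency comparisons, HWE
  inference.py          OLS/incremental R², summary-statistic tests
  synthetic_cohort.py   calibrated cohort simulator
  pipeline.py, cli.py   staged runner, report, command-line interface
docs/methods.md         modelling assumptions and parameter rationale
```
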