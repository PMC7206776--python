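# twosample-mr

Two-sample Mendelian randomization (MR) from GWAS summary statistics, for
epidemiologists asking whether an observational exposure–disease association
is causal. Genetic variants robustly associated with an exposure (here, the
published instruments for moderate-to-vigorous physical activity, vigorous
physical activity, sedentary behaviour and sleep duration from UK Biobank
and CHARGE GWAS) serve as instrumental variables against disease outcomes
(coronary artery disease, myocardial infarction, stroke, blood lipids) whose
association statistics come from an independent sample. Because alleles are
randomized at conception, the design is protected from classical confounding
and reverse causation, provided the instruments affect the outcome only
through the exposure.

## The estimators

For SNP *j* with exposure effect β<sub>Xj</sub> (SE σ<sub>Xj</sub>) and
outcome effect β<sub>Yj</sub> (SE σ<sub>Yj</sub>) on a common effect allele,
the per-SNP Wald ratio is θ̂<sub>j</sub> = β<sub>Yj</sub>/β<sub>Xj</sub> with
first-order SE σ<sub>Yj</sub>/|β<sub>Xj</sub>|. The package combines J
instruments with:

- **Fixed-effect IVW**: θ̂ = Σw<sub>j</sub>θ̂<sub>j</sub> / Σw<sub>j</sub>,
  w<sub>j</sub> = β<sub>Xj</sub>²/σ<sub>Yj</sub>², SE = (Σw<sub>j</sub>)^−½ —
  identically the zero-intercept weighted regression of β<sub>Y</sub> on
  β<sub>X</sub> with weights 1/σ<sub>Y</sub>².
- **Simple / weighted median**: the (weight-interpolated) median of the
  ratios, consistent when >50% of instruments (of the weight) are valid;
  SEs from a seeded parametric bootstrap.
- **MR-Egger**: the same regression with a free intercept after orienting
  all β<sub>X</sub> ≥ 0; the intercept estimates average directional
  pleiotropy (test of intercept = 0), the slope is robust to it under the
  InSIDE assumption. SEs are inflated by max(1, residual scale), inference
  on t(J−2).
- **Cochran's Q / I²** heterogeneity of the ratios around the IVW estimate.

A pipeline layer runs the exposure × outcome grid, applies the Bonferroni
threshold α/(exposures × outcomes), labels each pair
significant / suggestive / null from the IVW p-value, and writes TSV tables
(odds-ratio scale for binary outcomes, effect sizes for continuous ones).
A synthetic-data module generates two-sample summary statistics with known
causal effect, configurable pleiotropy and allele corruption, and backs a
Monte-Carlo calibration harness.

## Worked example

Simulate a two-sample dataset with a true causal log-OR of 0.25 and 30%
balanced pleiotropy, then analyse it:

```sh
mr simulate --config sim.yaml --out-prefix toy     # n_snps: 20, causal_effect: 0.25, seed: 11
mr run --exposure toy.exposure.tsv --outcome toy.outcome.tsv \
      --column-map map.yaml --seed 3 --n-tests 1 --out -
```

```text
exposure	outcome	method	n_snps	estimate	se	ci_low	ci_high	pvalue	scale	significance
toy.exposure.tsv	outcome	ivw_fe	20	1.25	0.0188	1.20	1.29	1.33e-31	OR	significant
toy.exposure.tsv	outcome	simple_median	20	1.30	0.0317	1.22	1.38	3.18e-16	OR	significant
toy.exposure.tsv	outcome	weighted_median	20	1.29	0.0275	1.23	1.36	8.08e-21	OR	significant
toy.exposure.tsv	outcome	egger_slope	20	1.24	0.0460	1.13	1.36	0.0002	OR	significant
```

Every 95% CI covers the generating odds ratio exp(0.25) ≈ 1.28 on this
single 20-SNP realization; `se` is
reported on the log-OR scale, the estimate and CI on the OR scale, and the
pair is flagged `significant` against the uncorrected 0.05 threshold
(`--n-tests 1`). The same library
calls are available in Python:

```python
from twosample_mr import load_instrument_fixture, apply_selection_filters

vpa = load_instrument_fixture("VPA")            # 5 packaged instruments
sleep = load_instrument_fixture("sleep_duration")
apply_selection_filters(sleep).snp_ids          # one SNP per locus:
# ('rs1191685', 'rs4587207')
```

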