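# Methods

## Model and assumptions

The package implements two-sample summary-data Mendelian randomization. A
genetic variant is a valid instrument when it (i) associates with the
exposure, (ii) shares no confounder with the outcome, and (iii) affects the
outcome only through the exposure. Under these assumptions and approximate
linearity, each SNP's Wald ratio θ̂_j = β_Yj/β_Xj estimates the same causal
effect θ, and the estimators differ in how they average the ratios and in
which violations of (iii) — horizontal pleiotropy — they tolerate:

| method | estimate | robustness |
|---|---|---|
| fixed-effect IVW | inverse-variance mean, w_j = β_Xj²/σ_Yj² | none (all instruments valid) |
| simple median | median of ratios | up to 50% invalid instruments |
| weighted median | weight-interpolated median | up to 50% invalid weight |
| MR-Egger slope | free-intercept weighted regression | directional pleiotropy under InSIDE |

The Egger intercept itself is the diagnostic: its deviation from zero
estimates the average directional pleiotropic effect per instrument.
Cochran's Q around the IVW estimate, with I² = max(0, (Q−df)/Q)·100,
quantifies ratio heterogeneity.

Exposure scales are taken from the source GWAS and never rescaled: the
packaged sleep-duration instruments keep their minutes/night-per-allele
betas, and estimates for the binary vigorous-activity trait read "per 1
unit higher log odds". Binary outcomes are reported as odds ratios,
continuous outcomes as effect sizes in the input table's units.

## Numerical conventions

- Wald-ratio SE: first-order delta method σ_Yj/|β_Xj| by default. The
  exposure-side term is the `second_order` option; it matters only for weak
  instruments (|β_X|/σ_X small) and is not the field's default reporting
  convention.
- IVW is fixed-effect; a multiplicative random-effects variant
  (SE × max(1, √(Q/(J−1)))) sits behind a flag. p-values are two-sided
  normal.
- Median methods: SE = SD of the estimate over a parametric bootstrap
  (default 5000 replicates) that redraws every β_X and β_Y from normals at
  the observed values; the seed is mandatory, so results are bit-reproducible.
  The weighted median uses standardized cumulative weights
  p_j = (S_j − w_j/2)/S_J and linear interpolation at 0.5.
- MR-Egger: instruments re-oriented to β_X ≥ 0 (the intercept is defined
  relative to the exposure-increasing allele); coefficient SEs scaled by
  max(1, residual scale) — under-dispersion never shrinks SEs — and tested
  against t(J−2). Collinear exposure effects (no variance) are rejected.
- Confidence level fixed at 95% (z = 1.959964) to match the reporting
  convention of the source studies.
- Degenerate inputs: β_X = 0 raises a degenerate-instrument error naming
  the SNP; medians and Egger require J ≥ 3 and are skipped (with a logged
  reason) by the pipeline below that, heterogeneity requires J ≥ 2; p-values
  are clamped away from exact 0.

## Harmonization

Effects are expressed per copy of the exposure's effect allele. Decision
order: palindromic SNPs (A/T, G/C) first — dropped when either allele
frequency lies inside the ambiguity window (default [0.42, 0.58]; [0.5, 0.5]
disables dropping), otherwise kept with a frequency-concordance sign rule —
then exact allele match, swap (sign flip), and A↔T/C↔G strand
complementation; irreconcilable allele pairs are dropped with a logged
reason, never raised. When the exposure table records no non-effect allele
(the situation of the packaged instruments), a swap is also recognised from
outcome EAF ≈ 1 − exposure EAF within ±0.08; when neither the other allele
nor EAF is available the SNP is kept as-is with an explicit "unverifiable"
log entry. Dropped SNPs never reach the estimators. Harmonizing an already
common-allele pair is a no-op for non-palindromic SNPs; kept palindromic
SNPs re-classify as `palindromic_kept` with unchanged betas (value-level
idempotence).

Locus pruning (`apply_selection_filters`) is bookkeeping only: genome-wide
threshold on p, then single-linkage position clusters (default window
500 kb) keep the lowest-p variant, ties by smaller SE then rsID. No
reference-panel LD is computed. The packaged sleep-duration set
deliberately retains all seven printed variants (four PAX8, three IER3
SNPs within ~40 kb); pruning is the caller's decision.

## Multiple testing

The family-wise threshold is α/(n_exposures × n_outcomes), derived from the
actual grid; a user override triggers a warning. A pair is `significant`
when the primary (IVW) p-value is below the corrected threshold,
`suggestive` when below 0.05 but above it, `null` otherwise.

## Synthetic data generator

Per SNP: EAF ~ U(eaf_range); true effect γ_j ~ N(0, exposure_effect_sd²);
SE(β) = 1/√(2·EAF·(1−EAF)·n) in each sample; β_Xj ~ N(γ_j, σ_Xj²) and
β_Yj ~ N(θγ_j + pleiotropy, σ_Yj²) drawn independently (non-overlapping
samples). Defaults — 50 SNPs, exposure n = 250 000, outcome n = 180 000,
EAF ∈ (0.1, 0.9), γ SD = 0.05 (mean instrument F ≈ 200) — represent a
well-powered biobank-scale design comparable to the instrument tables the
package ships.

Pleiotropy: `balanced` draws α_j ~ N(0, sd²), `directional`
α_j ~ N(mean, sd²), on a configurable fraction of SNPs (1.0 allowed: every
SNP pleiotropic). Directional pleiotropy enters as sign(γ_j)·α_j, i.e.
relative to the exposure-increasing allele. This is a deliberate modelling
convention: allele orientation in a summary table is arbitrary, and a
"directional" effect attached to an arbitrary allele would average to zero
under the re-orientation MR-Egger performs, making the intercept target
ill-defined. Corruption modes rewrite the outcome table's allele
bookkeeping only (strand complementation; effect/other swap with sign and
frequency flip; palindromic allele pairs), so a corrupted dataset carries
exactly the clean dataset's information and harmonization can be tested for
exact round-trip recovery.

What the generator does **not** emulate: LD between instruments, winner's
curse in instrument selection, sample overlap between the two GWAS,
non-normal effect distributions, and allele-frequency differences between
samples (the two tables share EAFs). Passing calibration tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data complications.

## Calibration study design

The Monte-Carlo scenarios (used by the test suite and
`scripts/acceptance.py`) are:

- **Null**: θ = 0, J = 50, no pleiotropy, defaults otherwise; 1000
  replicates. Checks IVW type-I error and CI coverage at nominal 5%/95%.
- **Recovery**: θ = 0.3, outcome n = 10⁶, 500 replicates. At the default
  instrument strength the two-sample regression-dilution factor
  σγ²/(σγ² + E[σ_X²]) ≈ 0.996, so the mean IVW estimate sits within 1% of
  the truth.
- **Directional pleiotropy**: mean α = 0.05 (SD 0.01) on every SNP,
  θ = 0.3, γ SD = 0.1 with exposure n = 10⁶; 500 replicates. The strong
  instruments make allele orientation essentially unambiguous; with the
  default strength, observed-sign orientation errors flip α on a few
  percent of SNPs and attenuate the mean intercept by ~11% — a property of
  orientation ambiguity, not of the estimator — so the recovery scenario
  removes that nuisance by design.
- **Balanced pleiotropy**: α SD = 0.01 on every SNP, θ = 0.3,
  EAF ∈ (0.3, 0.7); 500 replicates. The narrowed EAF range keeps σ_Y nearly
  constant across SNPs so the 1/σ_Y² weights match the true per-SNP error
  σ_Y² + α_sd² up to a common factor, the regime in which the
  dispersion-scaled t-test on the intercept is calibrated; with strongly
  unequal weights the test is mildly anticonservative by construction.

Problem sizes (replicate counts, J, bootstrap sizes in tests) were chosen
so the whole suite and the acceptance script each run in well under a
minute of simulation time while keeping Monte-Carlo error small relative to
the assertion bands.

## Known limitations

- No MR-PRESSO, mode-based estimators, multivariable MR, Steiger filtering,
  or LD-proxy lookup for instruments absent from the outcome table.
- Reproducing published odds ratios for the lifestyle–cardiovascular
  analyses requires the source consortia's per-SNP outcome statistics,
  which cannot be shipped; the corresponding end-to-end test fails loudly
  (rather than skipping) when those tables are absent.
- Exact agreement with any particular third-party MR implementation is not
  guaranteed beyond the documented conventions (bootstrap SEs for medians,
  t(J−2) for Egger, fixed-effect IVW): reasonable implementations differ in
  these choices.
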