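# Methods

This note records the statistical model behind `mrscreen`, the defaults and
why they were chosen, and the numerical decisions that matter for anyone
auditing or extending the package.

## Model

For SNP j, let β̂x_j ± σx_j be its estimated effect on the exposure
(a serum metabolite) and β̂y_j ± σy_j its effect on the outcome
(iridocyclitis, on the log-odds scale). Under the instrumental-variable
assumptions, each valid instrument satisfies

    β̂y_j ≈ θ · β̂x_j + α_j + ε_j,   ε_j ~ N(0, σy_j²)

where θ is the causal effect of interest and α_j is horizontal pleiotropy
(zero for valid instruments). All estimators treat β̂x_j as fixed
("NOME"-style first-order weighting with weights w_j = 1/σy_j²); this is
standard for two-sample MR with strong instruments and is exactly the
regime the F > 10 filter enforces.

## Instrument selection

1. **Significance**: exposure p < 1e-5 (metabolomics GWAS are small; the
   conventional 5e-8 leaves too few instruments per metabolite).
2. **Clumping**: greedy by ascending p-value; a candidate is discarded if
   it lies within 500 kb of an already-kept SNP and their LD r² ≥ 0.01.
   Without an LD table the distance rule alone applies (conservative:
   distant-but-correlated pairs cannot be detected, nearby independent
   pairs are pruned). Ties in p are broken by SNP id so the result is
   independent of input row order; `clump` is idempotent.
3. **Strength**: F = (β̂x/σx)², keep F > 10; variance explained
   r² = F/(F + n − 2).
4. **Exclusion**: instruments with outcome p < 1e-5 are removed (they
   likely act through the outcome directly).
5. **Minimum instruments**: fewer than 4 surviving IVs → the metabolite is
   reported as `insufficient_ivs`, not analyzed.

## Harmonization

Outcome records are oriented onto the exposure's effect allele: identical
label pairs are kept, swapped pairs have β and EAF flipped, and allele-set
mismatches are dropped. Palindromic SNPs (A/T, C/G) cannot be oriented by
labels across strands, so orientation uses the allele-frequency side; when
either frequency lies in [0.40, 0.60] or is missing, the SNP is dropped as
ambiguous. No strand-complement inference is attempted. Harmonizing a
dataset against itself is the identity map (a tested invariant).

## Estimators

- **Wald ratio**: θ̂_j = β̂y_j / β̂x_j, first-order SE σy_j/|β̂x_j|.
- **IVW (multiplicative random effects)**: weighted zero-intercept
  regression; θ̂ = Σw β̂x β̂y / Σw β̂x². Overdispersion
  φ = max(1, Q/(J−1)) multiplies the variance, so the SE is never smaller
  than the fixed-effect one but grows under heterogeneity.
- **MR-Egger**: weighted regression with free intercept after orienting
  all β̂x ≥ 0. The slope SE carries the φ floor. The **intercept SE does
  not**: it uses the raw WLS dispersion σ̂² = Q_egger/(J−2), which makes
  the intercept test an exact t(J−2) under the null. With the floored
  variant the null rejection rate was 0.0255 instead of 0.05 (measured
  over 2000 replicates) — i.e. the standard floor makes the pleiotropy
  test conservative, so it is deliberately not applied there.
- **Weighted median**: ratios sorted, weights w_j = (β̂x_j/σy_j)²
  normalized, centred cumulative weights s_j = Σ_{k≤j} w_k − w_j/2, linear
  interpolation at s = 0.5. SE by parametric bootstrap (resampling β̂x,
  β̂y from their sampling distributions), seeded.
- **Simple/weighted mode**: kernel density over ratios with the modified
  Silverman bandwidth h = 0.9 · 1.4826 · MAD · J^(−1/5) (× a bandwidth
  factor), 512-point grid; bootstrap SEs.

## Sensitivity battery

- **Cochran's Q** on Wald ratios with weights β̂x²/σy²; p from χ²(J−1).
- **Radial MR**: the IVW fit re-expressed per SNP; Q_j = w_j(θ̂_j − θ̂)²
  sums *exactly* to Cochran's Q (tested at 1e-8 relative). SNPs with
  Q_j above the χ²(1) 0.95 quantile are flagged as outliers.
- **MR-PRESSO**: observed leave-one-out residual sums of squares compared
  with a parametric simulation of the no-pleiotropy model. The global p is
  empirical with floor 1/n_sim; per-SNP outlier p-values are Bonferroni
  adjusted; the distortion test compares the outlier-corrected estimate
  with estimates from random same-size removals. The whole simulation is
  vectorized ((n_sim × J) arrays), so n_sim = 10 000 takes milliseconds.
- **Leave-one-out**: the result is "stable" if every J−1 subset preserves
  the sign and significance status of the full estimate.

## Decision rule

Validated ⇔ IVW p < 0.05 (criterion 1) AND no heterogeneity/pleiotropy
(Q p ≥ 0.05, PRESSO global p ≥ 0.05, Egger intercept p ≥ 0.05; criterion 2)
AND leave-one-out stable (criterion 3) AND the reverse (disease →
metabolite) analysis shows no directional pleiotropy. Screen p-values are
deliberately raw — the screen is hypothesis-generating and criteria 2–3
already discard fragile hits — but a BH-FDR column is emitted for readers
who want it. In `staged` mode the expensive estimators and diagnostics run
only for IVW-significant metabolites; `full` mode runs everything for all.

## LDSC

Single trait: E[χ²_j] = 1 + n h² ℓ_j / M regressed in two steps (OLS pilot,
then weights 1/[max(ℓ,1)(1 + n ĥ² ℓ/M)²]); h² = slope · M / n̄. Cross-trait:
E[z1 z2] = ρ_g √(n1 n2) ℓ / M + intercept; rg = gencov/√(h1² h2²).
Standard errors come from a delete-one block jackknife over 200 contiguous
SNP blocks, computed from per-block sufficient statistics (the jackknife
recomputes the full rg ratio per block, not just the slope). Estimates
outside sanity ranges (h² ∉ [−0.5, 1.5], |rg| > 1.25) or with degenerate
jackknives are flagged unreliable and serialized as `NA` — mirroring how
small-sample metabolite h² estimates are conventionally reported.

## Synthetic data generator

The generator is a first-class module; its defaults are the study
conditions under which every calibration and recovery claim is made, and
they were fixed before any acceptance measurement:

- J = 30 instruments, γ_j ~ N(0, 0.1²), σx = 0.01 (so F ≈ 100),
  σy = 0.03; sample sizes 7824 (exposure) and 365 120 (outcome:
  7306 cases / 357 814 controls).
- Full datasets add 50 null background SNPs per instrument, 10%
  palindromic alleles (half with ambiguous frequency), 2% allele-pair
  mismatches, 20% of outcome rows reported on the opposite allele, and
  MAF ~ U(0.05, 0.5).
- Pleiotropy: α_j ~ N(pleio_mean, pleio_sd²); planted outliers set
  α_j = ±10 σy for round(outlier_frac · J) SNPs.
- Options `oriented_instruments` (γ_j ≥ 0) and `select_significant`
  (rejection-sample until the observed exposure p passes the instrument
  threshold) exist because the Egger intercept is only interpretable for
  instruments that would actually pass the selection filter: with
  symmetric γ, sign orientation flips the pleiotropy of near-zero-β̂x SNPs
  and biases the intercept toward zero. These are opt-in, not defaults.
- LDSC inputs: M = 5000 SNPs, ℓ = 1 + Gamma(3, 10), N = 20 000; bivariate
  z-scores drawn with Cov(z1, z2) = rg · n · h² ℓ/M via the conditional
  normal.

Scope: the generator produces summary-level data only (no individual-level
genotypes), with independent instruments (LD enters only through the
clumping table and LD scores) and normal effect-size sampling. That is
exactly the regime the estimators assume; it cannot probe violations such
as winner's curse from a shared discovery sample or weak-instrument bias
at F ≈ 10.

## Reproducibility and numerics

Everything stochastic takes an explicit seed; per-metabolite and
per-bootstrap seeds are derived deterministically, so a full CLI run is
byte-reproducible (tested). Accumulation formulas are used in the
estimators, but each is tested at 1e-8 relative tolerance against
independent `numpy.linalg.lstsq` / `np.interp` oracles on fixtures.
Monte-Carlo test sizes (2000 replicates for null calibration with PRESSO
n_sim = 1000; 500 for parameter recovery; 200 for outlier and LDSC
recovery) keep the full suite near 30 s on one CPU.

## Limitations

- The first-order Wald-ratio SE ignores σx; fine at F ≈ 100, optimistic
  near the F = 10 boundary.
- Distance-only clumping (no LD table) can under-prune long-range LD.
- Binary-outcome effects are treated as log-ORs throughout; no
  non-collapsibility correction is attempted.
- MR-PRESSO's empirical p is floored at 1/n_sim; extremely small global
  p-values are reported at the floor (`global_p_at_floor`).
- LDSC here is the univariate/bivariate summary form with user-supplied
  LD scores; it does not compute LD scores from a reference panel.
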