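# Methods

## Model

For each genetic instrument *j* the data are two independent summary
associations: the exposure effect γ̂ⱼ with standard error σ_xj and the
outcome effect Γ̂ⱼ with standard error σ_yj, both on the log-odds scale for
binary traits. The structural assumption is log-linearity:

    Γⱼ = α · γⱼ + uⱼ,

where α is the causal effect of the exposure on the outcome and uⱼ is the
horizontal-pleiotropy effect of variant *j* (zero for a valid instrument).
Estimation treats γ̂ⱼ ~ N(γⱼ, σ_xj²) and Γ̂ⱼ ~ N(Γⱼ, σ_yj²) as independent
(two non-overlapping GWAS samples).

## Estimators

**Wald ratios and IVW.** Each ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ carries the first-order
delta-method SE σ_yj/|γ̂ⱼ|, which ignores the exposure-side variance term;
the corresponding weights wⱼ = γ̂ⱼ²/σ_yj² make the IVW estimate identical to
weighted least squares of Γ̂ on γ̂ through the origin (the implementation
uses the division-free normal-equation form, so a zero γ̂ⱼ cannot produce a
0/0). Second-order weights are deliberately not the default — the first-order
convention is what the heterogeneity statistic and the GRS identity below are
defined against. The fixed-effect SE is (Σwⱼ)^(−1/2); the random-effects
model is *multiplicative*, inflating that SE by max(1, √(Q/(J−1))) — never
deflating it — and `model="auto"` selects it exactly when the Cochran's Q
p-value falls below 0.05.

**Medians.** The weighted median is the 0.5 quantile of the weighted
empirical CDF with standardized cumulative weights pⱼ = (Sⱼ − wⱼ/2)/S_total,
linearly interpolated between order statistics; with equal weights it reduces
exactly to the sample median (both parities of J). SEs come from a
parametric bootstrap — each ratio resampled from N(β̂ⱼ, se_ratioⱼ), weights
held fixed, default 1000 replicates, seeded.

**Egger regression.** Weighted regression of Γ̂ on γ̂ with an intercept,
after orienting all γ̂ⱼ ≥ 0 (the slope and intercept are not invariant to
allele recoding; orientation is applied only here). Implemented on top of
statsmodels WLS; the reported SEs use the multiplicative overdispersion
scale max(1, √(RSS_w/(J−2))) relative to unit dispersion, and p-values use
t(J−2). The intercept estimates directional pleiotropy.

**MR-PRESSO.** The observed statistic is the residual sum of squares
RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)² with leave-one-out IVW slopes β̂₍₋ⱼ₎ and
wⱼ = σ_yj⁻². The null distribution is parametric: each replicate draws
γ*ⱼ ~ N(γ̂ⱼ, σ_xj) and Γ*ⱼ ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_yj) (both sides simulated, so
the null reflects the full expected ratio dispersion) and recomputes the
statistic with fresh leave-one-out slopes, vectorized across replicates.
Empirical p-values carry the +1 correction, so the floor is 1/(n_sim+1) at
the default n_sim = 1000. Per-SNP outliers are flagged at p < α/J
(Bonferroni, α = 0.05); the corrected estimate is fixed-effect IVW on the
unflagged set; the distortion test compares (β_raw − β_corr)/β_corr against
the same quantity under random removal of equally many instruments. If every
instrument is flagged the correction is refused with an explicit error.

**RAPS.** The robust adjusted profile score solves
Σⱼ ψ(tⱼ(β)) ∂tⱼ/∂β = 0 with standardized residuals
tⱼ = (Γ̂ⱼ − βγ̂ⱼ)/√(σ_yj² + β²σ_xj² + τ²) and the Huber score ψ with
tuning constant k = 1.345 (95% normal efficiency). τ² = 0 by default; with
`overdispersion=True` it is profiled by alternating root-finding on the
second-moment equation Σⱼ(ψ(tⱼ)² − c₂)/vⱼ = 0, where c₂ = E[ψ(Z)²] for
standard normal Z (closed form from Φ and φ; similarly E[ψ′(Z)] = 2Φ(k)−1).
The root is bracketed by doubling around the IVW start with a wide grid-scan
fallback; absence of any sign change over [−10, 10] raises a non-convergence
error naming the bracket. The SE is the sandwich form
√(c₂/(c₁² Σ(∂tⱼ/∂β)²)), which collapses to the profile-score variance when
k → ∞.

**GRS summary method.** α̂ = Σωⱼβⱼσⱼ⁻²/Σωⱼ²σⱼ⁻² with
se(α̂) = √(1/Σωⱼ²σⱼ⁻²). The standard error is the square root of the
inverse weighted sum — written without the root the expression is
dimensionally inconsistent — and with ω = γ̂, β = Γ̂, σ = σ_y both the point
estimate and the SE coincide exactly with fixed-effect IVW (both are the
same weighted regression through the origin). That identity is an acceptance
check at 10⁻¹⁰ relative tolerance.

**P-values and intervals.** Normal reference for IVW, medians, RAPS and
GRS; t(J−2) for both Egger coefficients (J is small in practice). All CIs
are 95% Wald intervals on the log-odds scale; odds ratios are produced only
at reporting time by exponentiation.

## Selection and harmonization

Stages run in the order significance → palindrome removal → LD clumping →
MAF → exclusion list, the order in which the screening narrative reports its
counts; MAF sits before the exclusion list because no intermediate count
pins its position. Clumping is greedy by p-value (ties: position, then
variant id), removing neighbours within ±500 kb at r² ≥ 0.01; the "500 kb
window" is read as a half-width, the dominant convention of clumping tools,
and both numbers are configurable. Pairs absent from the LD matrix count as
unlinked, which degrades gracefully to distance-only pruning when no panel
is supplied. Palindromic (A/T, C/G) variants are dropped unconditionally —
allele frequencies are never used to rescue them, since strand cannot be
resolved from the alleles and frequency inference is exactly the ambiguity
the rule exists to avoid. Strand-complemented allele representations are
matched before a pair is declared mismatched. Duplicate variant ids within
a table keep the record with the smallest p-value. Missing allele frequency
is tolerated at load time and fails the MAF filter conservatively.

## Synthetic data generator

`simulate_instruments` draws, in a fixed documented order from one seed:
true effects γⱼ ~ N(0.15, 0.05²), standard errors σ_xj ~ U(0.01, 0.03) and
σ_yj ~ U(0.02, 0.05), pleiotropy uⱼ per regime, observed γ̂ⱼ and Γ̂ⱼ, an
outlier subset (Γ̂ += outlier_scale·σ_yj, default 5), and allele
frequencies ~ U(0.01, 0.5). The defaults describe a well-powered GWAS
exposure: per-instrument F statistics cluster around 50–80, comfortably
above the weak-instrument line, which is the regime the first-order weights
assume. Pleiotropy regimes: `balanced` (mean-zero, breaks only efficiency),
`directional` (nonzero mean, breaks IVW and the Egger intercept detects
it), `inside_violation` (uⱼ correlated with γⱼ through a configurable ρ,
the assumption Egger and MR-PRESSO are sensitive to).

`simulate_raw_tables` wraps an instrument draw as full exposure/outcome
summary tables with alleles, positions (loci spaced 2 Mb apart across 22
chromosomes), p-values consistent with β̂/σ via the normal tail, and planted
violations of each selection criterion: sub-threshold decoys, an exact
round(share·J) of palindromic instruments, LD satellites (attenuated copies
of their index at r² = 0.95 within the clump window, always with a larger
p-value), rare variants (EAF 0.005) and exclusion-listed variants. Planted
instruments are guaranteed genome-wide significant by rejection-sampling
the whole SNP — true effect, observed exposure and outcome association
jointly — so the exposure/outcome pairing stays consistent; satellites
attach only to non-palindromic indexes so every stage's expected drop count
is exact by construction. Conditioning on significance leaves a small
winner's-curse-like truncation (end-to-end IVW estimates are attenuated by
roughly 0.01–0.02 at α = 0.3 with the default settings), which is inherent
to selecting significant instruments and visible in the pipeline tests'
tolerances.

What the generator does *not* emulate: real LD panels (LD is planted, not
derived from genotypes), sample overlap between the two GWAS, winner's
curse beyond the significance conditioning above, population stratification,
or allele-frequency differences between studies. Passing tests therefore
demonstrate the statistical machinery under the stated generative model,
not robustness to those artefacts of real data.

## Calibration conditions used in the checks

- Type-I error and coverage of the primary IVW run at J = 25 (null) and
  J = 50 (recovery) with the generator defaults; observed rejection ≈ 0.04
  and coverage ≈ 0.94 sit inside the stated bands.
- Cochran's Q calibration is checked with negligible exposure-side noise
  (σ_x ~ U(0.001, 0.003)): the first-order weights ignore the β²σ_x² term,
  so Q is exactly χ²(J−1) only in that limit; at α = 0.2 with the default
  σ_x the rejection rate inflates by under one percentage point.
- The Egger-intercept power check plants a +0.05 offset with strong
  instruments and small SEs (σ_x ~ U(0.005, 0.01), σ_y ~ U(0.008, 0.015));
  with the default SEs the intercept SE (~0.02) makes 0.05 a ≈2.5σ effect
  and the check would measure sampling noise rather than the detector.
- The planted-outlier recovery check uses J = 15 and plants the 10σ_y
  outlier on the strongest instrument. A 10σ_y outlier displaces the IVW
  estimate by ≈ 10·zⱼ/Σz² (zⱼ = γ̂ⱼ/σ_yj) while the corrected estimate's SE
  is (Σz²)^(−1/2), so the displacement is ≈ 10/√J SEs for a typical
  instrument: "removal moves the estimate strictly closer to truth" is only
  a high-probability event when the planted outlier is influential, which
  the strongest-instrument placement guarantees (≈3.5 SEs at J = 15).

## Numerical choices, degenerate inputs

- Empirical p-values are +1-corrected; analytic p-values are clipped into
  (0, 1] at the smallest positive double.
- Ratio estimates refuse γ̂ⱼ = 0 with an error naming the SNP; IVW itself
  never divides by γ̂.
- Estimator minimums: IVW 2 (1 with an explicit override, returning the
  Wald ratio), medians and RAPS 3, Egger 3 (J−2 df), MR-PRESSO 4.
- Clumping requires chromosome and position whenever more than one record
  is present; ties are broken deterministically.
- All stochastic procedures are bit-reproducible given (inputs, seed,
  n_sim/n_boot); report bundles contain no timestamps and rerun
  byte-identically.

## Limitations

- No MR-Steiger directionality test, multivariable MR, contamination
  mixture, or colocalization; no I² or Rucker framework.
- No proxy-SNP substitution: instruments absent from the outcome table are
  dropped and logged.
- Confounder screening is a static exclusion list supplied by the user; no
  online variant-annotation lookup.
- F statistics are computed per-SNP from summary data; the n·R² variant is
  out of scope.
- Binary formats (GWAS-VCF, PLINK) and genome-build liftover are not
  supported; inputs are delimited text.
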