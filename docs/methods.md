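# Methods

## The cumulative conversion-factor estimator

A dilution experiment releases the prokaryotic community from grazing and
resource limitation: sample water is diluted 1:10 with 0.2-µm filtrate and
incubated in the dark, with daily flow-cytometry (biomass) and
³H-leucine (LIR) subsampling until stationary phase, typically 6–8 days.
If every mole of incorporated leucine produced a fixed amount of biomass
carbon, then biomass at time *t* obeys

    B(t) = eCF · Λ(t) + B(0),   Λ(t) = ∫₀ᵗ LIR dτ,

and the OLS slope of B on Λ estimates the conversion factor. Units are
arranged so the slope needs no rescaling: B in µg C L⁻¹, Λ in nmol Leu L⁻¹
(LIR in pmol L⁻¹ h⁻¹ × 24 h d⁻¹ integrated over days, divided by 1000);
µg/nmol equals kg/mol exactly.

Numerical choices:

- **Quadrature.** Λ is the trapezoidal integral of the measured LIR
  between sampling times. The sampling interval (24 h) is short relative
  to the growth timescale, so the trapezoid error is negligible against
  measurement noise.
- **Biomass-decline exclusion.** Loss processes (grazers passing the
  dilution filter, viral lysis) depress biomass without depressing
  incorporation, which would bias the slope low. A timepoint is excluded
  when its biomass falls below that of the previously *retained*
  timepoint (a running reference rather than a pairwise-adjacent
  comparison), which keeps the retained biomass series monotone — the
  regime in which the cumulative identity above is meaningful. The first
  timepoint is always retained, and Λ keeps integrating across excluded
  points (the leucine was really incorporated; only the biomass
  observation is distrusted). A curve with fewer than 3 retained points is
  flagged unusable.
- **Degenerate fits.** Constant biomass yields slope 0 with p = 1 (no
  relationship); zero variance in Λ is an error. A numerically perfect fit
  (zero residual) reports p = 0.

### Hierarchical aggregation

Per-curve slopes with a two-sided slope-test p < α (default α = 0.1) are
averaged within a sample (arithmetic mean; sem = SD/√n of retained
slopes, 0 with a flag when only one curve survives); depth-level values
are the unweighted mean of sample means. When no curve in a sample is
significant the aggregate is an explicit no-estimate result, never a zero.
Comparisons against printed reference tables round half-away-from-zero to
two decimals. Published sem values are not reproduced by any single
formula we tested and are therefore not asserted anywhere.

## Upstream conversions

- **Cytometry.** Relative side scatter (population SSC / bead SSC) maps to
  cell diameter through a log-log calibration. The calibration
  coefficients are instrument-specific and not published for the reference
  campaign, so `SSCCalibration` defaults to the identity and should be set
  explicitly for real data. Biovolume assumes spheres, BBv = (π/6)d³;
  carbon per cell uses C = 0.12·BBv⁰·⁷² pg (allometric defaults
  configurable); biomass = abundance × C with mL→L and pg→µg folding.
  Per-timepoint biovolumes are the default; a pooled mean biovolume per
  curve is available.
- **Radioassay.** Net DPM = mean(samples) − mean(blanks), blanks matched
  within a timepoint; negative nets are clamped to zero with a logged
  warning (blank noise), not an error. Conversion assumes no isotope
  dilution: mol Leu = DPM / (2.22×10¹² DPM Ci⁻¹ × SA), SA default
  160 Ci mmol⁻¹, giving pmol L⁻¹ h⁻¹ after volume/time normalisation. The
  centrifugation method is selected for depths ≤ 1000 m, filtration below.

## PHP and depth structure

PHP = LIR × CF, converted to µmol C m⁻³ d⁻¹ with a carbon molar mass of
12.011 g mol⁻¹ (the factor 24/12.011 folds h→d, ng→µg and L→m³; the CF is
mass-based while PHP is molar, and no conversion constant is printed in
the reference work, so the standard atomic weight is used). The
theoretical variant fixes CF = 1.55 kg C mol Leu⁻¹. Depth layers:
epipelagic [0, 100), upper mesopelagic [100, 450), lower mesopelagic
[450, 1000], bathypelagic (1000, ∞) m.

Depth dependence is modelled on the log10–log10 scale (base 10 chosen
as convention; the base only rescales coefficients) with degree-1 and
degree-2 OLS, compared by AIC = n·ln(RSS/n) + 2k, k = coefficients + 1.
Because the AIC convention of the source analysis is unknown, absolute AIC
values are never asserted — only the selection order, which is invariant
to the additive constant. The RSS is floored at 10⁻³⁰⁰ per point so that
exact fits of nested models tie on the likelihood term and the parameter
penalty decides (exactly linear data select the linear model). Group
comparisons use one-way ANOVA with Tukey HSD across layers and a
two-sample t-test between sections; an all-identical input is returned as
the well-defined limit F = 0, p = 1.

## DOM optics and the correlation screen

Ratio indices (peak M/peak T, peak M/a254, peak M/DOC) are elementwise
quotients; undefined ratios (zero/missing denominator) are NaN with an
explicit flag. The eCF screen computes Pearson r and two-sided p per
variable with pairwise-complete deletion (cruise tables are ragged),
flags significance at α = 0.1, and reports a Shapiro–Wilk p-value as a
diagnostic only — Pearson is computed regardless, matching the source
analysis.

## Community composition

Singleton ASVs (total count 1) are removed before rarefaction.
Rarefaction is a multivariate-hypergeometric subsample to a common depth
(without replacement), seeded. Shannon H′ uses natural log (community-
ecology convention; the base is not stated in the source); Chao1 uses the
bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), finite when F₂ = 0.
Rare-ASV pooling keeps ASVs ≥ 1% overall relative abundance, aggregates
the rest at phylum level, and pools phyla still below 1% into "Others";
counts are conserved.

ANOSIM is implemented in-package (R = (r̄_between − r̄_within)/(M/2) on
tied-rank dissimilarities, seeded label permutations, p counts the
observed labelling) because a seeded permutation stream was required; the
independent scikit-bio implementation serves as a cross-check in the test
suite, and a brute-force exhaustive-permutation oracle validates both R
and p on a 6-sample fixture. SIMPER decomposes each between-group pair's
Bray–Curtis dissimilarity into per-taxon terms |x_ij − x_ik| / Σ(x_ij +
x_ik), averaged over pairs; per-pair contributions sum to the pair's
dissimilarity by construction.

Zero replacement is Bayesian-multiplicative: a uniform Dirichlet prior of
total mass 1 per sample (the source names the method but no prior) gives
each zero its posterior expected proportion s/(D(n+s)) and scales non-zero
parts multiplicatively, preserving totals and within-sample rankings. CLR
is ln(x/gmean(x)) on the replaced compositions. CLR values are averaged
within depth layers *after* the transform (the source is ambiguous on the
order; post-transform averaging keeps the matrix's zero-sum rows
interpretable as average log-ratios), then regressed on layer eCFs with
the same linear-vs-quadratic AIC selection as the depth models.

## CF regression

OLS of eCF on potential temperature, peak M and peak T in raw units (the
reference equation is unstandardised), with an intercept. Designs with
condition number above 10¹² are rejected as collinear. Negative predicted
conversion factors are flagged out-of-domain rather than clamped: the
model is exploratory and a negative CF is physically meaningless.

## What the synthetic generators emulate — and what they do not

- **Incubations.** Logistic regrowth from 2 to 20 µg C L⁻¹ at 1 d⁻¹
  (stationary by day 7 of an 8-day, 24-h-interval design). LIR samples
  are defined by inverting the trapezoid rule so that the discrete
  cumulative leucine reproduces cumulative carbon production exactly:
  this makes the noise-free estimator round-trip an identity to machine
  precision, which is the property the oracle tests rely on; a pointwise
  dB/dt sample would leave an O(dt²) quadrature bias. Crashes are
  transient one-sampling-day multiplicative dips off the undisturbed
  trajectory (loss followed by rebound to the carrying-capacity path), so
  excluded crash days leave the retained points exactly on the regression
  line. Real losses are neither instantaneous nor fully transient; the
  generator does not model grazer or viral population dynamics, so
  passing tests demonstrate correctness of the estimator's arithmetic and
  exclusion logic, not robustness to structured biological loss.
  Measurement noise is mean-one multiplicative lognormal (positive by
  construction), defaults 5% on both channels.
- **Profiles.** Hydrography/DOM anchors follow observed north-east
  Atlantic values (DOC 72.7→50.0 µmol C L⁻¹, peak T 0.76→0.31 QSU,
  a254 1.48→0.83 m⁻¹ decreasing; peak M 0.36→0.84 QSU increasing),
  interpolated linearly in log-depth so gradients concentrate in the
  upper ocean. No water-mass structure, seasonality or station-to-station
  covariance is modelled.
- **PHP profiles.** Log-log polynomial signal (default the published
  quadratic −0.33x² + 0.35x + 1.19) plus Gaussian noise scaled for a
  target refit R² (default 0.80), over 300 log-spaced depths between 50
  and 2000 m — a problem size at which the quadratic term is identified
  essentially always at that noise level.
- **ASV tables.** Per-sample multinomial draws from a depth-weighted
  mixture of a surface and a deep composition (weight 0 at the shallowest
  sample, 1 at the deepest), default read depth 6513 per sample. No
  sequence-level error model, no overdispersion beyond multinomial.
- **CF regression design.** Eight station/depth samples shaped like the
  two observed sections, with predictors inside observed ranges and
  arranged so the noise-free conversion factors approximate the published
  depth eCFs (≈0.4–4.4 kg C mol Leu⁻¹) while peak T retains enough
  variation orthogonal to the other predictors to identify its
  coefficient. Response noise is scaled for a target R² of 0.96. The
  stochastic recovery test measures coefficients against twice the
  reference standard errors (0.1, 3, 2, 3): a per-fit estimated-SE
  yardstick is not usable here, because with 4 residual degrees of
  freedom the Student-t coverage of ±2·SE is 88.4% per coefficient — a
  ceiling no generator can exceed.

## Known limitations

- The estimator assumes a constant conversion factor within an
  incubation; shifts in community composition over the week are folded
  into the slope.
- Isotope dilution is assumed absent throughout, consistent with the
  theoretical CF's definition.
- The exclusion rule removes crash observations only when the crash
  actually depresses biomass below the running reference; a loss small
  enough to leave biomass non-decreasing is undetectable by construction.
- SIMPER reports raw percent contributions without the contribution/SD
  discrimination statistic some implementations add.
- The CF regression is exploratory (n = 8 in the reference analysis);
  predictions outside the calibration envelope are flagged, not prevented.
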