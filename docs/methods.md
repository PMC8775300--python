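# Methods

## The question and the design

Observational studies report that periodontal disease (dental caries and
periodontitis) is associated with higher cardiovascular risk, but such
associations are vulnerable to confounding and reverse causation.
Two-sample Mendelian randomization (MR) addresses this by using genetic
variants as instrumental variables: SNP-exposure associations come from a
GWAS of the combined dental-caries/periodontitis liability (GLIDE
consortium + UK Biobank, n = 487,823), SNP-outcome associations from
separate cardiovascular consortia (coronary artery disease, heart
failure, atrial fibrillation, and stroke with its ischemic subtypes —
eight outcomes in all). Because alleles assort randomly at meiosis, a
valid instrument's association with the outcome can only run through the
exposure, so the ratio of the two associations estimates the causal
effect.

This package implements that workflow end to end: instrument selection,
outcome-side exclusion, allele harmonization, three complementary
estimators, and Bonferroni-corrected inference over the outcome grid.
The consortium outcome files are not redistributable; the package
therefore ships a synthetic two-sample GWAS generator with known ground
truth, and the `analysis/` scripts run the study-shaped grid on
simulated outcomes. Only the exposure side — the bundled 47-instrument
table — is real data.

## Instrument handling

Instruments are selected at genome-wide significance with a strict
inequality, p < 5 × 10⁻⁸. Before each outcome analysis, an instrument is
excluded when it is absent from the outcome GWAS (it cannot be
harmonized) or when it is itself significantly associated with the
outcome (a pleiotropy suspect); the exclusion threshold defaults to the
same genome-wide level and is configurable, since outcome consortia
differ in their conventions. LD independence is assumed established by
the source GWAS; no clumping, proxy lookup or F-statistic screening is
performed.

## Harmonization

Exposure and outcome effects are expressed on the exposure's effect
allele. A differing outcome allele negates the outcome beta and
complements its effect-allele frequency. Palindromic SNPs (A/T, C/G)
cannot be oriented from labels alone; the default policy aligns them by
frequency concordance when both minor-allele frequencies are below 0.42
and drops them otherwise (a strict drop-all policy is available). The
bundled instruments publish only the effect allele, so an
effect-allele-only mode treats any differing, non-complementary outcome
allele as the other allele; complementary labels (e.g. exposure `a`,
outcome `t`) are strand-ambiguous and handled like palindromic SNPs.
Indel codes (`d`/`i`) are compared literally and never complemented.
Harmonization never alters standard errors or the exposure side, and
every decision is recorded in an audit log so instrument counts always
reconcile.

## Estimators

All methods operate on per-SNP Wald ratios r_j = β_yj / β_xj with
first-order standard errors se(r_j) = se_yj / |β_xj| (NOME: exposure
measurement error ignored, appropriate for strongly selected
instruments).

**IVW.** θ̂ = Σ w_j r_j / Σ w_j with w_j = se(r_j)⁻²; identical to the
weighted regression of β_y on β_x through the origin with weights
se_y⁻². Default inference is multiplicative random-effects: the fixed
standard error (Σ w_j)^(-1/2) is inflated by max(1, √(Q/(J−1))), with Q
the Cochran statistic, so heterogeneity can widen but never narrow the
interval. p-values are standard-normal; the CI uses ±1.96 SE.

**MR-Egger.** Instruments are oriented to β_xj ≥ 0 and β_y is regressed
on β_x with a free intercept, weights se_y⁻². The slope estimates the
causal effect under InSIDE (instrument strength independent of direct
effects); the intercept estimates the average directional pleiotropic
effect. Standard errors carry the same max(1, σ̂) residual floor;
inference uses t with J−2 degrees of freedom, conventional at the small
instrument counts typical of MR.

**Weighted median.** The weighted 50th percentile of the ordered ratios,
interpolated through the standardized cumulative-weight midpoints
p_j = (S_j − w_j/2)/S_total; consistent when valid instruments carry at
least half the total weight. Its standard error comes from a parametric
bootstrap (each beta redrawn from a normal at its stated SE; default
1000 replicates; seed mandatory).

Degenerate inputs are handled explicitly: IVW with one instrument equals
the Wald ratio; Egger requires ≥ 3 instruments and positive spread in
exposure effects; exactly-affine data recover the Egger line with the
unit-scale covariance (the residual floor cannot divide by a zero σ̂);
p-values are clamped into (0, 1] at the smallest positive float.

## Multiple testing

The familywise threshold is α/m with m the number of outcome tables
actually supplied — 0.05/8 = 0.00625 for the study grid (commonly quoted
rounded as 0.006). Significance uses a strict inequality, so p = 0.015
over eight outcomes is not significant.

## The synthetic generator

For SNP j: MAF p_j ~ Uniform(maf_range); true instrument effect γ_j
from a mean-zero normal (default SD 0.1) or a user-fixed list; reported
effects β_x,j ~ N(γ_j, se²) and β_y,j ~ N(θγ_j + α_j, se²) with the
standardized-trait GWAS error se = (2p(1−p)n)^(-1/2); p-values from the
normal ratio; allele labels from non-palindromic pairs. A configurable
fraction of SNPs is invalid, with direct effects α_j ~ N(μ_α, σ_α²)
plus an optional component proportional to γ_j that violates InSIDE.
Per-replicate seeds derive from the master seed as
`SeedSequence([seed, rep])`, so any replicate is reproducible in
isolation and everything is byte-identical given the seed.

Parameter choices, with rationale:

- **γ SD = 0.1 (default).** Instruments in real two-sample MR are
  post-selection genome-wide-significant hits, i.e. strong by
  construction (the bundled instruments have |β|/se between 5.4 and 16
  at n ≈ 488k). At the recovery-study sizes (n = 10⁵ per side) this SD
  gives mean instrument F-statistics in the hundreds, so weak-instrument
  attenuation is negligible relative to Monte-Carlo noise. Selection
  itself (winner's curse) is not modelled.
- **Fixed positive γ lists for pleiotropy regimes.** With mean-zero
  signed γ, orienting instruments to β_x ≥ 0 flips pleiotropic effects
  too, and directional pleiotropy averages out — the Egger intercept
  target would be ill-defined. Directional-pleiotropy scenarios
  therefore use a fixed positive effect ladder (linspace 0.05–0.25
  across 50 SNPs). Under frequency-independent weights the implied IVW
  bias has the closed form μ_α Σγ / Σγ², which the recovery study
  verifies.
- **Sample sizes.** Defaults mirror the real study (exposure 487,823;
  outcomes at consortium sizes in the analysis scripts). Recovery
  studies use 10⁵ per side with J = 50 instruments and 200 replicates —
  large enough that Monte-Carlo SEs resolve the effects of interest,
  small enough that the whole battery runs in seconds.

What passing the simulation suite shows — and what it does not: the
estimators are correctly implemented and calibrated under the generating
model (independent instruments, normal summary errors, standardized
traits, no sample overlap). Real consortium data add LD between
instruments, binary-trait scales, population structure and partial
sample overlap, none of which the generator emulates; conclusions about
those failure modes are out of scope.

## Known limitations and open choices

- The exposure is the combined caries/periodontitis liability as
  published; the two conditions are not modelled separately.
- Whether the original analysis dropped or frequency-aligned palindromic
  SNPs is not documented; both policies are implemented and the default
  (frequency alignment with a 0.42 ambiguity ceiling) is standard
  conservative practice.
- Per-outcome instrument counts from the original consortium data
  (44/36/41/…) depend on files that are not public and are not
  reproduced here.
- No mode-based estimators, MR-PRESSO, multivariable MR or Steiger
  filtering; no binary-trait liability scaling of simulated outcomes.
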