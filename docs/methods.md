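# Methods

`protmed` implements a proteome-wide two-sample Mendelian-randomization
(MR) mediation screen: does an adiposity trait (e.g. BMI) act on colorectal
cancer risk through circulating proteins?  The pipeline is a four-step
decision procedure over GWAS summary statistics, exercised end to end on
synthetic studies with known causal structure.  This note records the
models, the defaults and why, the numerical choices, and what the synthetic
studies can and cannot show.

## The causal model and the four steps

Let G denote genetic variants, X an adiposity exposure (per inverse-rank-
normal SD), M_j circulating protein j (per SD), and Y a binary cancer
outcome (log-odds scale).  Each step is a two-sample MR contrast built
from per-variant effect pairs harmonized to a shared effect allele:

- **Step i** (X → Y): genome-wide instruments for X (P < 5×10⁻⁸, LD
  clumped at r² = 0.001 in a 10 Mb window).  Identified when every
  computed MR model agrees in sign and the reverse MR (Y → X) shows no
  sign-consistent association at a nominal 0.05.  The forward rule is
  sign-consistency only; no p-threshold is imposed.
- **Step ii** (X → M_j): the same rule plus a multiplicity-corrected
  threshold α = 0.05/Meff (below).  Reverse MR uses each protein's cis and
  trans instruments at the proteome-wide threshold P < 1.8×10⁻⁹; proteins
  associated in both directions are *conflicted* and removed.
- **Step iii** (M_j → Y): cis-only instruments (within 1 Mb of the gene's
  transcription start site, P < 1.8×10⁻⁹, clumped within the region),
  corrected threshold, no reverse conflict, and corroboration by
  colocalization (robust h4 ≥ 0.8; h4 < 0.5 is explicitly tagged
  not-corroborated).
- **Step iv** (mediation): for each surviving, sign-consistent triple,
  multivariable MR of Y on (X, M_j).  A *mediation flag* requires the
  direct X estimate to attenuate toward the null **and** its 95% CI to
  newly overlap the null while the univariable CI excluded it.

Every decision records an ordered rule trace from which `identified` can
be re-derived, and each per-variant harmonization action (kept, flipped,
dropped-palindromic, proxied) is tagged.

## Estimators

**Wald ratio** (1 SNP): β_Y/β_X with first-order SE se_Y/|β_X|.

**IVW-MRE** (main model, ≥2 SNPs): weighted regression of β_Y on β_X
through the origin, weights 1/se_Y²; θ̂ = Σwβ_Xβ_Y / Σwβ_X²; Cochran's
Q = Σw(β_Y − θ̂β_X)²; multiplicative scale φ = Q/(k−1); SE = √(φ/Σwβ_X²).
The library default leaves φ unfloored (the pure random-effects regression
form); the screen floors it at 1.  Rationale: with k = 2 the scale has one
residual degree of freedom and collapses the SE whenever the two ratios
happen to agree, which manufactures spurious reverse-direction
"associations" precisely where reverse instrument sets are smallest (two
cis SNPs).  Flooring at the fixed-effects variance is the standard guard
and only ever widens intervals.

**MR-Egger** (≥3): weighted regression with intercept after orienting all
pairs to β_X ≥ 0 (Egger is not orientation-invariant; a fixed convention
is required).  Both SEs scaled by max(1, σ̂); t reference with k−2 df.
The intercept estimates average directional pleiotropy.

**Weighted median / weighted mode** (≥3): per-variant ratios θ_j with
inverse first-order-variance weights se_Y²/β_X² (a second-order term is
available by flag).  Median: weighted 50th percentile with linear
interpolation over cumulative midpoint weights.  Mode: normal-kernel
density argmax with bandwidth 0.9·φ·min(sd, mad)·k^(−1/5) (mad scaled
normal-consistent, matching the convention of the R tooling this follows);
all ratios identical ⇒ the common ratio.  SEs by parametric bootstrap of
(β_X, β_Y) from their sampling distributions (default 1000 replicates,
seeded; the screen uses 100 since the decisions use only point-estimate
signs and the main-model p-value).  The mode's evaluation grid is 512
points standalone and 256 inside the screen.

**Steiger directionality**: per-variant r² ≈ z²/(z²+n); for the binary
outcome n is the effective size 4/(1/n_case + 1/n_control).  A
liability-scale r² using registry prevalence can be supplied via `r2_fn`.
The test statistic is the difference of Fisher-transformed multiple
correlations, variance 1/(n_X−3) + 1/(n_Y−3).

**MVMR**: inverse-variance-weighted regression of β_Y on (β_X, β_M)
without intercept, multiplicative residual scale as in the main model.
An all-zero mediator column drops out of the design (direct effect 0,
reproducing the univariable IVW estimate exactly); any other rank
deficiency raises a collinearity error.  Q_A uses weights
1/(se_Y² + Σ_l θ̂_l² se_{X,l}²) (pairwise covariances assumed zero)
against χ²(k−L).  Conditional instrument strength profiles
Q(δ) = Σ(β_a − δβ_b)²/(se_a² + δ²se_b²) and reports Q_min/(k−1)
(k−2 by flag).  When the other exposure carries no signal this profile is
degenerate — Q decreases monotonically in |δ| with infimum 0 — so a
bounded minimizer that hits its bound falls back to the inverse-variance
regression estimate of δ, which reproduces the closed-form reduction
Q(0) = Σ(β_a/se_a)² for β_b ≡ 0.

**Colocalization**: single-causal-variant approximate Bayes factors,
lABF = ½[log(1−r) + r·z²], r = W/(V+W), prior effect SD √W = 0.15 (per-SD
traits) or 0.2 (log-odds).  Hypothesis sums are accumulated in log space;
the distinct-variants term is the stable log-difference
log(ΣBF₁·ΣBF₂ − ΣBF₁BF₂), which correctly gives h3 = 0 for a single
shared variant.  Main priors p1 = p2 = 10⁻⁶, p12 = 10⁻⁷ (chosen for
~5000-variant regions); the sensitivity grid probes windows of 250 kb,
500 kb, 1 Mb (main) and 2 Mb around the lead cis variant (window = total
span) and the prior set (10⁻⁵, 10⁻⁵, 10⁻⁶).  The published sensitivity
list contains a duplicated prior set; duplicates are collapsed.  The
robustness verdict is quantified as: h4 ≥ 0.8 in the main cell AND in ≥2
non-main windows under the main priors AND in ≥1 non-main prior set at
the main window.

**Effective number of tests**: phenotypic correlation is estimated as the
Pearson correlation of summary z-scores over variants with |z| < 1.96 in
both traits (signal variants would masquerade as phenotypic correlation);
the spectrum λ of that matrix gives Nyholt
Meff = 1 + (m−1)(1 − var(λ)/m) and Li–Ji
Meff = Σ[1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)].  The larger ("more conservative")
estimate sets α = 0.05/Meff.

## The synthetic-data generator

The generator emulates the statistical shape of the study's data sources
directly at the summary level: joint per-variant effects on the
standardized-genotype scale are propagated through regional LD
(marginal = R·b), converted to the per-allele scale, and observed with
LD-correlated sampling noise (Cholesky of the regional AR-1 matrix),
se = 1/√(2f(1−f)n); each trait's cohort draws its own noise (strict
two-sample setting).  Binary outcomes use the log-odds scale with the
effective sample size 4/(1/n_case + 1/n_control) instead of a logistic
simulation.  Individual-level genotypes exist only as Gaussian dosages
for verifying the panel's LD empirically.

Defaults are the emulated study scale: exposure GWAS n = 450,000
(sex-combined adiposity), protein GWAS n = 35,000 (Icelandic plasma
proteome), outcome 58,000 cases / 67,000 controls.  The panel is
block-AR-1 (ρ = 0.9, spacing 10 kb): one 11-variant region per exposure
or outcome QTL and one 61-variant gene region per protein (TSS at the
region center, cis QTLs at the third quartile positions).  The exposure
has 30 QTLs explaining 6% of variance (BMI-like); each protein has 2 cis
QTLs explaining 10% (strong cis-pQTLs); the outcome has 10 own QTLs of
0.04 log-odds per SD genotype.  Allele frequencies are uniform on
(0.05, 0.95); alleles are drawn uniformly over ordered base pairs, so
about a third of variants are strand-ambiguous and the harmonizer's
palindrome rules are exercised organically.

The default causal structure plants one fully mediated chain as a
positive control — exposure → protein 0 (0.15 SD) → outcome (0.6
log-odds per SD protein), no direct path — and makes 40% of the other
proteins adiposity-responsive (±0.1 SD) and 10% outcome-associated
(±0.3 log-odds) without completing a chain.  The full-mediation positive
control is a deliberate design choice: the step-iv flag is a conjunction
of a significant total effect and a null-overlapping direct effect, so a
detectable planted flag requires the mediated path to carry essentially
the whole effect.  A chain with a 0.1 SD × 0.3 log-odds mediated path on
top of a direct effect (the configuration used in the chain-identification
test, with n = 100,000 protein / 25,000+25,000 outcome cohorts) moves the
direct estimate by only ~1.6 SE, which supports an attenuation call but
not a reliable CI-overlap flag — that configuration is therefore tested
for steps i–iii plus attenuation.

What the generator does **not** emulate: realistic human LD maps, allele
frequency spectra, ancestry structure, sample overlap, liability-scale
case-control effects, winner's-curse-corrected instrument selection, or
assay artifacts (aptamer cross-reactivity).  Passing calibration here
shows the decision machinery is correct and calibrated under its own
assumptions, not that those assumptions hold in any real cohort.

## Problem sizes used by the test and acceptance runs

End-to-end calibration runs 100 replicates of the default 1-exposure ×
50-protein × 1-outcome study per arm (mediated and global-null), ~3500
variants each; calibration suites use 500 replicates (IVW coverage),
100 (Egger, weighted median) and 2×200 regions of 500 variants (coloc).
The materialized 3 × 50 × 5 fixture study is the CLI demonstration
object; per-stratum screens are independent re-runs, so the single
stratum is the unit of repeated calibration.

## Numerical choices and degenerate inputs

- p-values are floored at 1e-320 to stay within (0, 1].
- Palindromic variants with allele frequency within 0.08 of 0.5 in either
  study (or missing eaf) are dropped; others are aligned by frequency.
- Variants absent from the LD reference cannot be assessed for
  independence and are dropped from clumping with a logged warning.
- Proxy search requires r² ≥ 0.8 ("LD ≥ 0.8" read as r², the convention
  of the tooling this follows; configurable) and orients the proxy's
  effect by the sign of r.
- Collinearity in MVMR is declared above condition number 1e8.
- Eigenvalues of estimated correlation matrices are clipped at 0 before
  the Meff formulas.
- Instrument sets with mean F ≤ 10 are flagged weak, not excluded.
- Sign of a point estimate exactly 0 counts as inconsistent with any
  nonzero sign in the direction-consistency rule.
- Odds ratios live on the log-odds scale internally; exponentiation only
  at serialization.

## Known limitations

- Reverse-MR "conflict" with one or two instruments rests on a single
  sign and the main-model p-value only; the sensitivity models need ≥3.
- The Steiger r² for the binary outcome uses the z²/(z²+n_eff)
  approximation, not a prevalence-based liability transform (hook
  provided).
- Colocalization assumes a single causal variant per trait per region;
  allelic heterogeneity inflates h3.
- The weighted-mode bandwidth rule of thumb can oversmooth with very few
  instruments; its bootstrap SE inherits grid resolution.
- Meff from null-z correlations needs ≥100 shared null variants per pair
  and degrades when traits share dense genome-wide signal.
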