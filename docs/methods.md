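# Methods

## Setting and notation

Two-sample MR estimates the causal effect θ of an exposure X (continuous,
analysed in SD units) on an outcome Y (binary, analysed on the log-odds
scale) from per-variant GWAS summary statistics estimated in two
non-overlapping cohorts: the SNP-exposure effects γ̂ⱼ with standard errors
σₓⱼ and the SNP-outcome effects Γ̂ⱼ with σᵧⱼ, j = 1…J. The identifying
assumptions are the usual instrumental-variable triple — relevance,
independence from confounders, and exclusion (no effect on Y except
through X) — and the estimator suite exists precisely because exclusion
is fragile: each sensitivity method trades efficiency for robustness to a
different pattern of horizontal pleiotropy.

## Instrument selection and harmonization

Instruments are variants with exposure p < 5×10⁻⁸ pruned to pairwise
r² < 0.001 by greedy clumping: sort by ascending p, keep a variant iff
its squared correlation with every already-kept variant is below the
threshold. Clumping against a full signed LD matrix replaces
reference-panel clumping; it is deterministic and exact at the scale of
instrument lists (tens to hundreds of variants).

Harmonization re-expresses every outcome record on the exposure's effect
allele. Non-palindromic variants are matched directly, after an
effect/other swap (Γ̂ sign flip, frequency complement), or after a strand
complement. For palindromic variants (A/T, C/G) a swap and a strand flip
are indistinguishable from allele labels, so labels are aligned nominally
and the strand is then verified by frequency concordance: the outcome
effect is flipped iff (eafₓ − ½)(eaf_y − ½) < 0. This resolves all four
coding combinations (swap, strand, both, neither) correctly whenever the
minor-allele frequency is informative. Frequency is deemed informative
only when MAF < 0.3 on **both** sides, with a strict inequality (a MAF of
exactly 0.3 drops); a missing frequency on either side also drops, as the
strand cannot be verified. Every input variant gets exactly one audit
entry (kept / flipped / dropped + reason); kept+flipped+dropped equals
the intersection size by construction, and harmonization is idempotent.

## Univariate estimators

* **Wald ratio** β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order delta-method SE σᵧⱼ/|γ̂ⱼ|.
  The second-order term (the γ̂ uncertainty) is deliberately omitted —
  the convention for genome-wide-significant instruments, and a
  documented limitation for weak ones.
* **IVW**, the primary estimator: inverse-variance-weighted mean of the
  ratios. Random-effects flavour is **multiplicative with the scale
  floored at 1**: se = (Σw)^(−1/2)·max(1, √(Q/(J−1))). The floor means
  the SE never falls below the fixed-effect SE; under-dispersed data are
  not rewarded. J = 1 reduces exactly to the Wald ratio.
* **Cochran's Q** around any candidate β, with a χ²(J−1) p-value.
* **MR-Egger**: WLS of Γ̂ on γ̂ with intercept, weights 1/σᵧⱼ². Sign
  pairs are flipped so all γ̂ⱼ ≥ 0 first — without a fixed orientation
  the intercept is not interpretable under InSIDE. SEs use the same
  multiplicative floor with J−2 df; inference uses the t distribution
  (J is small in this regression). The intercept estimates the mean
  directional pleiotropic effect; its p-value is the pleiotropy test.
* **Weighted median**: order the ratios, form cumulative weight
  midpoints pⱼ = S_{j−1} + w′ⱼ/2 with normalized weights, and linearly
  interpolate the ratio at p = ½. SE by parametric bootstrap (resampling
  γ̂ⱼ, Γ̂ⱼ from their sampling normals; default 1000 draws, seeded).
* **Weighted mode**: weighted normal-kernel density over the ratios,
  bandwidth φ·0.9·min(sd, IQR/1.349)·J^(−1/5) (φ = 1 by default),
  evaluated on a 512-point grid spanning the ratios ± 3 bandwidths; the
  estimate is the density argmax, SE again by parametric bootstrap. All
  ratios identical is a degenerate bandwidth; the common value is
  returned directly.
* **Steiger directionality**: per-SNP R² from the t-approximation
  R²ⱼ = tⱼ²/(tⱼ² + n − 2), summed per trait; the declared direction is
  exposure→outcome iff ΣR²ₓ > ΣR²ᵧ. The p-value is a two-sample z test
  on the Fisher-transformed correlations √ΣR² — the two cohorts are
  independent, so no dependent-correlation covariance term arises. The
  same t-based R² is used for the binary outcome (a liability-scale
  approximation; noted, not corrected).

All p-values are two-sided normal except where a statistic is χ² or the
Egger t. Confidence intervals are β̂ ± z₀.₉₇₅·se; odds ratios exponentiate
the bounds.

## MR-PRESSO

The observed statistic is RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)² with
wⱼ = 1/σᵧⱼ² and β̂₍₋ⱼ₎ the leave-one-out IVW estimate (computed in O(J)
via sum updates). The null distribution redraws γ*ⱼ ~ N(γ̂ⱼ, σₓⱼ²) and
Γ*ⱼ ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σᵧⱼ²) and recomputes RSS, vectorized across all
n_sim draws (default 10,000, significance threshold 0.05). Empirical
p-values carry the +1 correction, p = (1 + #{RSS* ≥ RSS})/(1 + n_sim),
so they are never zero and are bounded below by 1/(n_sim+1). The
per-SNP test compares each observed contribution with its simulated
column; a SNP is an outlier iff its Bonferroni-adjusted p < α. A
warning fires when J/(n_sim+1) ≥ α, since no SNP can then be flagged at
any evidence level — n_sim must comfortably exceed J/α. The corrected
estimate is exactly the IVW on the non-outlier subset. The distortion
statistic is 100·(β_corrected − β_raw)/|β_corrected|; its two-sided
p-value comes from removing random pseudo-outlier subsets of the same
size (drawn uniformly without replacement). The reference construction
of the distortion resampling is not fully pinned down in the
literature's settings-level descriptions; the uniform-subset scheme is
this package's documented choice, and distortion p-values should be
treated as reproducible only in distribution.

## Multivariable IVW

With K exposures, Γ̂ⱼ = Σₖ βₖ γ̂ⱼₖ is fitted by no-intercept WLS with
weights 1/σᵧⱼ², SEs scaled by max(1, √(RSS_w/(J−K))). The instrument
set is the **union** of the per-exposure instrument lists (each variant
once), harmonized to a common effect-allele frame against the outcome;
a variant missing from any exposure table is dropped with an audit
entry. The per-exposure "number of SNPs" reported is the count of that
exposure's own instruments surviving assembly — multi-exposure results
tables conventionally annotate per-exposure counts even though all J
variants enter every coefficient. Rank-deficient exposure matrices
raise a collinearity error naming the offending exposures. Conditional
weak-instrument F statistics are not computed in this version (known
limitation).

## Gene-region (drug-target) MR

Within a target gene region the instruments are few and correlated, so
the estimator is GLS without intercept under Ωⱼₖ = σᵧⱼσᵧₖρⱼₖ, ρ the
signed LD correlation aligned to the harmonized effect alleles:
β̂ = (γᵀΩ⁻¹γ)⁻¹γᵀΩ⁻¹Γ, se = √((γᵀΩ⁻¹γ)⁻¹)·max(1, √(Q_gls/(J−1))),
where Q_gls is the GLS residual quadratic form (the reported
heterogeneity statistic, χ² with J−1 df). Pairs with r² ≥ 0.3 are
warned about but **retained** — the correlation is modeled, not pruned.
Ω is factored untouched when positive definite; otherwise a diagonal
ridge of 10⁻⁶ (escalating tenfold to at most 10⁻³, recorded in the
output) is added, since empirical reference-panel LD matrices are
noisy. Trying the unridged factorization first keeps the identity-LD
case algebraically identical to the ordinary IVW. No intercept term is
offered regionally: with 5–7 instruments an Egger-style intercept is
not estimable with useful precision.

## Synthetic-data generator

The generator emulates the summary-statistic regime of a
lipid→osteoarthritis study and is the ground-truth source for all
tests. Defaults are the study conditions: J = 79 instruments,
θ = ln(0.91) per SD, exposure GWAS n = 188,578, outcome GWAS 77,052
cases / 378,169 controls. Per-SNP exposure effects have magnitude
~N(0.08, 0.02) SD per allele floored at 0.03 (so every instrument is
genome-wide significant at these sample sizes) with random sign;
SEs derive from sample size and allele frequency via
se ≈ 1/√(2·n·eaf(1−eaf)) for the standardized exposure and
1/√(2·n·φ(1−φ)·eaf(1−eaf)) for the case-control outcome (φ the case
fraction). Pleiotropy α_j is planted **relative to the
exposure-increasing allele** — the orientation in which "directional"
pleiotropy is directional — on a configurable fraction of instruments,
optionally correlated with instrument strength to violate InSIDE.
Outliers displace Γ by a configured number of outcome SEs. Outcome
tables are emitted with randomized allele order and strand, and
palindromic variants are planted at a configurable fraction (a
sub-fraction with intermediate frequency, which harmonization must
drop), so the harmonizer is exercised on every run. AR(1) LD blocks
propagate joint effects to marginal ones (γ_marg = Rγ_joint) and
correlate the summary noise accordingly, matching the GLS model.

What the generator does **not** emulate: real LD structure beyond AR(1)
blocks, allele-frequency/effect-size coupling, sample overlap between
cohorts, population stratification, or winner's-curse selection bias.
Passing tests therefore demonstrate the estimators' correctness under
their own model assumptions, not robustness to these real-data
features.

The named fixture regimes (`null`, `effect`, `invalid40`, `outlier`,
`palindrome`, `mvmr`, `region`) freeze the test conditions. The
`invalid40` regime uses strong instruments (per-ratio SE ≈ 0.02,
pleiotropic shift ≈ 0.25): the weighted median's half-weight guarantee
is asymptotic in instrument strength, and its residual finite-noise
bias is ≈ 0.97·se(ratio) at 40% invalid weight — the regime is chosen
so that this bias is an order of magnitude below the IVW's pleiotropy
bias, which is the property the regime demonstrates. The `region`
regime uses J = 6, AR(1) ρ = 0.4 and θ = ln(0.76), the scale of a
statin-target analysis; `mvmr` uses four correlated exposures with
effects (ln 0.91, 0, 0, ln 2.14) and 80 instruments.

## Numerical and design choices

* Weighted regressions (Egger, multivariable) use explicit normal
  equations rather than a generic WLS fit, because the multiplicative
  random-effects convention floors the scale at 1; the algebra is
  cross-checked against statsmodels WLS in the tests where the two
  conventions coincide.
* Empirical p-values always use the +1 correction; simulation seeds are
  mandatory arguments and are recorded in outputs.
* Bootstrap defaults: 1000 draws for median/mode SEs. These SEs are
  Monte-Carlo estimates; do not expect last-digit agreement across
  platforms or against other implementations.
* Greedy p-ordered clumping, the frequency-concordance palindrome rule,
  the strand-complement fallback for non-palindromic mismatches, and
  the union instrument set for multivariable MR are all conventions the
  package documents rather than universal standards; each is isolated
  behind one function so an alternative rule is a local change.
* The problem sizes used by the test suite and the acceptance script
  (replicate counts of 100–1000, n_sim = 1000–10,000) were chosen to
  keep Monte-Carlo error well inside the asserted tolerances while
  remaining desk-scale.

## Known limitations

First-order Wald SEs ignore exposure-side noise (anti-conservative for
weak instruments). No NOME/I²_GX diagnostics for Egger, no conditional
F statistics for multivariable MR, no proxy-variant lookup for
instruments missing from the outcome GWAS, no MVMR-Egger or regional
intercept models, and no individual-level simulation. The Steiger R²
for a binary outcome is a scale approximation. MR-PRESSO distortion
p-values are resampling-scheme dependent.
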