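# Methods

## Model and assumptions

Two-sample MR treats genetic variants as instruments for an exposure X on
an outcome Y measured in a different sample. Validity rests on the usual
three conditions: the instrument associates with X; it is independent of
confounders of X–Y; and it affects Y only through X (no horizontal
pleiotropy). All estimators here consume summary statistics only — per-SNP
effect/SE pairs — never individual-level data. For binary traits effects
are log-odds, and odds-ratio views are exponentials of the effect and its
Wald 95% CI (β ± 1.96·SE throughout; the normal quantile is fixed at 1.96
to match how such intervals are printed and back-derived in published
tables).

## Harmonization

Exposure and outcome records are matched by SNP identifier (positions are
carried but never used for joins, since the upstream sources are
rsID-keyed). Outcome effects are rewritten in the exposure's effect-allele
convention: direct match, allele swap (sign flip, eaf → 1−eaf), strand
complement, or complement-plus-swap. Palindromic variants (A/T, C/G) are
oriented by allele frequency and kept only when both frequencies are
known, both are outside 0.5 ± 0.08, and both fall on the same side of 0.5
after nominal alignment; anything ambiguous is dropped with a logged
reason. The 0.08 window is common practice; the upstream pipelines this
package emulates do not state theirs, so it is an explicit, configurable
stand-in rather than an inference. Multi-base or non-ACGT alleles are
rejected in this version to keep the allele algebra exact. Every SNP in
the overlap appears exactly once in the provenance log
(kept / sign-flipped / strand-flipped / dropped + reason), so
|kept| + |dropped| always equals the overlap size.

## Instrument selection and strength

Instruments pass a strict p < threshold filter (default 5 × 10⁻⁶, per
exposure; genome-wide 5 × 10⁻⁸ is a config choice) and are pruned by
greedy clumping: visit SNPs by ascending p (ties by identifier), accept
the best, discard every remaining SNP that is jointly within the window
(default 10,000 kb, same chromosome) and correlated at r² ≥ 0.001 against
an accepted SNP. The window value follows the convention that the paired
"r² < 0.001, 10,000 kb" thresholds describe a clumping window. LD comes
from a user-supplied r² matrix; without one, pruning is purely positional,
and with a matrix but no positions the r² condition alone decides.
Because the filtered set is a prefix of the clumping order, filtering and
clumping commute exactly.

Strength is R² = 2·MAF(1−MAF)β² per SNP and F = R²(n−k−1)/(k(1−R²)),
with per-SNP (k = 1) and aggregate (R² summed, k = #SNPs) modes both
exposed since published reports rarely say which was used; F < 10 flags a
weak instrument. R² is a variance fraction only for standardized traits —
the caller owns that scaling.

## Estimators

*IVW.* β̂ = Σw·β̂_X·β̂_Y / Σw·β̂_X² with w = σ_Y⁻². The fixed-effect SE is
(Σw·β̂_X²)^(−1/2); the multiplicative random-effects (MRE) SE multiplies
it by max(1, √(Q/(k−1))). Both variants are always emitted (same point
estimate); the headline pick is MRE exactly when Q/(k−1) > 1, making the
choice auditable. One SNP degenerates to the Wald ratio β̂_Y/β̂_X with
first-order SE σ_Y/|β̂_X| (the exposure SE is retained in the data model
but does not enter this SE).

*MR-Egger.* WLS of β̂_Y on β̂_X with intercept, weights σ_Y⁻², after
flipping each pair so β̂_X ≥ 0. SEs carry the residual-scale inflation
max(1, √(RSS_w/(k−2))) and p-values use t(k−2). The intercept estimates
the mean directional pleiotropic effect.

*Weighted median.* The 0.5-crossing of the weighted empirical CDF of the
sorted Wald ratios (weights β̂_X²/σ_Y², linear interpolation between
cumulative midpoints). *Weighted mode.* The argmax of the weighted
normal-kernel density of the ratios, bandwidth = factor × 0.9·min(SD,
normalized MAD)·k^(−1/5) on a 2048-point grid spanning the ratio range (a
degenerate spread returns the heaviest point mass). Both get SEs from a
parametric bootstrap — β̂_X*, β̂_Y* redrawn from normals at their SEs,
default 5000 draws — under a single integer seed; identical seeds give
bit-identical results.

## Sensitivity suite

Cochran's Q uses the Wald-ratio form Σw_j(θ̂_j − θ̂_IVW)² with
w_j = β̂_Xj²/σ_Yj² (df k−1) or the Egger weighted RSS (df k−2);
heterogeneity is flagged at p < 0.05. Leave-one-out refits the IVW-MRE
estimate k times and marks exclusions whose CI no longer covers the
full-set estimate. MR-PRESSO computes the leave-one-out weighted RSS,
simulates its null by redrawing both β̂_X and β̂_Y at their SEs around the
leave-one-out fitted values (each draw re-deriving its own leave-one-out
slopes), and reports the empirical global p with floor 1/(n_sim+1);
per-SNP outlier p-values are empirical tails Bonferroni-adjusted by k
(the original method's convention), and flagged SNPs are removed for the
corrected IVW estimate. The distortion test is deliberately out of scope.
Funnel coordinates are (θ̂_j, |β̂_Xj|/σ_Yj); rendering is left to the
caller.

## Multivariable MR and mediation

MVMR regresses β̂_Y on the exposure-effect matrix (no intercept, weights
σ_Y⁻²). The joint instrument set is the union of each exposure's clumped
instruments, intersected with every source, then re-clumped using the
best p-value any exposure assigns a SNP — a defensible default where the
upstream pipelines are silent. SEs carry max(1, √(Q/df)) inflation,
df = k − p; whether published MVMR SEs used such scaling is unstated, so
the floor-at-1 convention is adopted and documented. With one informative
exposure the fit reduces to IVW exactly (MRE SE); an all-zero exposure
column is reported as inert (β = 0, infinite SE) rather than an error,
while genuine collinearity among informative columns raises, naming the
offending exposures.

The mediation decomposition estimates βa, βb, βc by (headline) IVW and
βb′, βc′ by MVMR. The route rule — Propagation of Error on βa·βb′ when
βb′'s 95% CI excludes zero, else a Sobel test on βa·βb (p < 0.05), else
no proportion — is reconstructed from the published worked examples'
footnotes and row pattern; it is a documented interpretation and the
alpha is configurable. The Sobel denominator and the PoE SE are one
implementation: √(a²·se_b² + b²·se_a²). Proportions divide by the total
effect βc, with first-order ratio propagation for their SE. When the
mediator has no instruments at the threshold the result is a
not-available verdict (with βa and βc still reported), since that is what
the two-step design means by "cannot be conducted". SEs consumed from
printed tables are back-derived from 95% CIs as width/(2×1.96).

## Multiplicity

Benjamini–Hochberg step-up adjustment (delegated to statsmodels'
`fdr_bh`, with a brute-force step-up oracle in the tests) across a
user-declared family — by default the exposure panel against one outcome;
mediation analyses form their own families. Bonferroni is available as a
utility only. Display rounding (OR to 2 dp, p to 3 significant digits)
applies to report columns; underlying tables keep full precision.

## Synthetic data

The generator emulates consortium-scale GWAS summary statistics directly —
no individual-level genotypes, which is sufficient for every consumer
module. Per SNP: MAF ~ U(0.05, 0.5); true instrument effect
γ ~ N(0, 0.05²); SEs follow (2·MAF(1−MAF)·n)^(−1/2) with biobank-scale
defaults n_exp = 460,000, n_out = 486,601, n_med = 500,000; observed
effects are normal around the truth. The default true effect θ = 0.162
(log-odds) and the default of ~80 instruments mirror the
alcohol-frequency→IBS analysis scale this package was validated against.
The γ scale puts mean per-SNP F in the hundreds — the strong-instrument
regime in which IVW's regression-dilution bias (order 1/F̄) is negligible
relative to Monte-Carlo error; this is the regime the recovery properties
describe.

Pleiotropic effects (a configurable fraction of SNPs, N(μ, σ²)) act on
the exposure-increasing allele: under arbitrary allele coding that is the
only orientation in which "directional" pleiotropy is well defined, and
it is what the Egger intercept estimates. Relatedly, the pleiotropy
recovery analyses apply the p-value instrument filter first: a
noise-dominated β̂_X has a random sign, and including such SNPs
mis-orients their pleiotropy and attenuates the intercept — an artifact
absent from real Egger usage, where instruments are genome-wide
significant by construction.

Mediation chains add mediator effects a·γ and outcome effects
(c′ + a·b)·γ on the exposure SNPs, plus a block of mediator-specific
instruments (effects γ_m on the mediator, b·γ_m on the outcome, null on
the exposure). Without that block the MVMR design is collinear in
expectation (both columns proportional to γ) and a mediator-instrument
regression would estimate c′/a + b rather than b; the block is what makes
the mediator independently instrumentable, as real mediation MR assumes.
The closed-form mediated proportion is a·b/(c′ + a·b).

Coordinates spread SNPs over 22 chromosomes at >20 Mb spacing so default
clumping treats them as independent; `inject_ld_structure` overlays
block-diagonal r² with block-local coordinates for clumping tests.
Alleles are non-palindromic by default; a palindrome fraction exists
solely to exercise harmonization drops. What the generator does **not**
model: realistic LD beyond block-diagonal injections, liability-scale
conversions for binary traits, winner's curse from same-sample discovery
(recovery analyses therefore use the generated instrument set directly),
sample overlap between the two GWAS, and population stratification.
Passing recovery tests demonstrate correctness of the estimators under
the stated generative model, not robustness to these real-data features.

## Numerical conventions

P-values are two-sided and floored at the smallest subnormal to stay in
(0, 1]; empirical (PRESSO) p-values use the (1 + #exceedances)/(n_sim+1)
form, so they can never be zero. Clumping ties break lexicographically on
SNP identifier. Weighted-median interpolation clamps to the extreme ratio
when the CDF crosses 0.5 at an endpoint. All simulation replicates derive
their seed as base + replicate index. Problem sizes in the validation
studies (200 replicates for effect recovery, 500 for type-I error, 1000
PRESSO simulations, 40–80 instruments) were chosen to put Monte-Carlo
error well below the effect sizes being checked while keeping a full
validation run in the seconds-to-minutes range on one CPU.

## Known limitations

Wald-ratio SEs are first order (no β̂_X uncertainty term); MVMR has no
conditional F-statistics or weak-instrument-robust variant; MR-PRESSO
omits the distortion test; Steiger directionality filtering is not
implemented; no reference-panel LD computation (r² matrices are inputs);
no VCF/liftover support. Reverse-direction analyses are a configuration
(exposure and outcome swapped), not a separate code path.
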