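# Methods

## Model and estimand

Two independent samples X_ik ~ F_i (i = 1, 2; k = 1, …, n_i; N = n1 + n2),
with F_i arbitrary apart from the trivial one-point case. Distribution
functions are used in their normalized form F = (F⁺ + F⁻)/2, which treats
continuous and discrete data uniformly; the induced ranks are midranks. The
estimand is the Mann–Whitney effect

θ = ∫ F1 dF2 = P(X1 < X2) + ½ P(X1 = X2) ∈ [0, 1],

interpreted as the tendency of the second sample toward larger values.
The package convention is fixed: the *second* sample is the one whose
larger values push θ above ½. Readers and the CLI expose a `direction`
flag that swaps the groups, because in applications either orientation may
be the scientifically meaningful one (e.g. for pain scores, "treatment
below control" is the benefit direction).

The estimator is the rank form θ̂ = (R̄₂· − (n2+1)/2)/n1, where R̄₂· is the
mean overall midrank of the second sample. It equals the pairwise count
(wins + half-ties)/(n1·n2) exactly; this identity is enforced in the test
suite by brute-force oracles. θ̂ lives on the grid of multiples of
1/(2·n1·n2).

## Variance estimators

With placements R*_ik (overall minus internal midrank):

* **Plug-in ("DeLong") estimator.** σ̂_i² is the sample variance of the
  placements of sample i divided by (N − n_i)²;
  v̂_DL² = N(σ̂₁²/n1 + σ̂₂²/n2) estimates Var(√N θ̂). It is positively
  biased for continuous data (verified empirically in the suite).
* **Unbiased rank-based estimator.**
  σ̂_N² = [Σ_ik (R*_ik − R̄*_i·)² − n1 n2 (θ̂(1−θ̂) − τ̂/4)] / [n1(n1−1)n2(n2−1)],
  where τ̂ estimates the cross-sample tie probability τ = P(X1 = X2) from
  the spread between max- and min-rank means. σ̂_N² is unbiased for
  Var(θ̂), non-negative for n_i ≥ 2, and obeys the sharp empirical
  Birnbaum–Klose bound σ̂_N² ≤ θ̂(1−θ̂)/(m−1), m = min(n1, n2).
  Negative values of magnitude below 1e−14 (relative to the placement sum
  of squares) are clamped to zero: the estimator is provably non-negative,
  so such values can only be floating-point round-off; anything larger
  raises an assertion.

Ties are detected by exact equality of stored floating-point values, the
natural rule for ordinal codes and discrete measurements; the readers
accept an optional `decimals` rounding for metric data whose tie precision
is coarser than the stored representation (default: none).

## Tests

**Brunner–Munzel.** T = √N(θ̂ − ½)/v̂_DL referred to a central t
distribution with Satterthwaite degrees of freedom. The d.f. use the
placement variances S_i² = Σ(R*_ik − R̄*_i·)²/(n_i − 1) as the Welch
weights w_i = S_i²/(N − n_i):

f̂ = (w1 + w2)² / [w1²/(n1−1) + w2²/(n2−1)],

which reduces to 2(n−1) for balanced equal-variance samples and to n_i − 1
when the other sample's variance vanishes, and agrees with
`scipy.stats.brunnermunzel` (used in the suite as an independent oracle,
never as the implementation). When v̂_DL = 0 (separated or fully tied
samples) the statistic is reported as signed infinity with p = 0 (p = 1
when θ̂ = ½) and a degeneracy flag, preserving monotonicity of evidence
and letting simulation code account for these replicates separately.

**Studentized permutation.** The pooled vector is permuted; the full
statistic — ranks included — is recomputed for each permutation. The
two-sided p-value doubles the smaller tail proportion, capped at 1
("plain" rule); the "add-one" alternative counts the identity permutation
once, p = (2·min(L, U) + 1)/(n_perm + 1), so the smallest reportable value
is 1/(n_perm + 1). Degenerate permuted replicates contribute signed
infinities under the same rule as above. Random permutations are simple
seeded shuffles (draws with replacement from the permutation space); an
`exact=True` option enumerates all C(N, n1) assignments for small samples.
The compatible interval uses the empirical α/2 and 1−α/2 permutation
quantiles c₂, c₁: [θ̂ − c₁ v̂_DL/√N, θ̂ − c₂ v̂_DL/√N].

**C²-test.** The idea is to estimate the ratio of Var(θ̂) to its
Birnbaum–Klose maximum θ(1−θ)/m rather than to plug a variance estimate
into a normal approximation. Setting q̂ = σ̂_N²/[θ̂(1−θ̂)] gives the
working approximation Var(θ̂) ≈ q̂·θ(1−θ), hence for H₀: θ = θ₀

C² = (θ̂ − θ₀)² / [q̂ θ₀(1−θ₀)]  ~  χ²₁ under H₀,

which for θ₀ = ½ is 4(θ̂ − ½)²/q̂, equivalently (θ̂ − ½)²/σ̃² with the
inflated variance σ̃² = σ̂_N²/[4θ̂(1−θ̂)] (the two forms are asserted
equal in the suite). The optional (m−1)/m small-sample factor on the ratio
is implemented but off by default. When σ̂_N² = 0 — including complete
separation, θ̂ ∈ {0, 1} — the variance is replaced by its sharp maximum,
giving C² = 4m(θ̂ − ½)²; at θ̂ ∈ {0, 1} this is just m, so a separated
sample rejects at α = 0.05 iff m ≥ 4 and at α = 0.01 iff m ≥ 7.

**Intervals.** Inverting C² à la Wilson yields

θ_{L,U} = [2θ̂ + q̂c ∓ √(q̂²c² + 4q̂θ̂(1−θ̂)c)] / [2(1 + q̂c)],  c = χ²₁;₁₋α,

range-preserving and compatible with the test by construction (½ outside
the interval ⇔ rejection). The degenerate branch inverts the bound
variance instead: θ_{L,U} = [2mθ̂ + c ∓ √(4mθ̂(1−θ̂)c + c²)]/[2(m+c)],
collapsing to the one-sided forms [m/(m+c), 1] and [0, c/(m+c)] at
θ̂ = 1 and 0. The t-inversion interval θ̂ ∓ t·v̂_DL/√N is reported
*unclipped* by default — its excursions beyond [0, 1] are informative —
with an opt-in clip for display.

Two-sided inference only; all quantiles come from scipy's special-function
routines.

## Simulation design

`simulate` reproduces the benchmark study design. Null scenarios (14
settings): normal (equal variances, and variance ratio 9), beta
(B(1,1), B(2,5) homoscedastic; B(5,5) vs B(1,1)/B(2,2) heteroscedastic),
the corresponding 5-point ordinal versions, Poisson(1), Exp(1), and
Laplace with scale 1 vs 1 and 1 vs 3 (variance 2b², hence variance
ratio 9). Sample-size grids cover n1/n2 ∈ {½, 1, 2} from 15 to 100 per
arm, so both positive pairing (larger variance with the larger group) and
negative pairing are exercised. Power/coverage settings parameterize one
arm (normal shift with variance 1 or 9, B(a,1)-based ordinal scales,
exponential rates) and solve the free parameter from a target effect by
Brent root-finding on the exact effect functional (closed forms for
normal/normal and exponential/exponential; exact finite sums for discrete
pairs; adaptive quadrature otherwise, tolerance 1e−10).

Ordered-categorical data are generated by drawing from the latent beta
distribution and cutting (0,1) at {0.2, 0.4, 0.6, 0.8} into five
equal-width categories coded 1–5 — an explicit design choice for what a
"5-point Likert scale from a beta" means here.

Exponential(λ) is parameterized by rate (mean 1/λ). RNG streams are
spawned per scenario from one master `SeedSequence`, so results are
reproducible and independent of evaluation order. Degenerate replicates
are analyzed with each method's degenerate branch, never dropped, and
counted in the output; the coverage denominator is always the replication
count, with undefined t-inversion intervals counted as non-covering.

The default harness sizes (10,000 replications; the test suite uses
10,000 for calibration/coverage checks and 20,000/200,000 for the
unbiasedness check) give Monte-Carlo standard errors of about 0.0007 at
α = 0.05 and 0.0007·√θ-scale for coverage — small enough to detect
miscalibration of a few tenths of a percent while keeping the whole suite
in the tens of seconds. Larger replication counts are a parameter, not a
code change.

## What the synthetic scenarios do and do not show

The generators emulate the distributional shapes the methods are stressed
by — skewness, heavy tails, heteroscedasticity, discreteness and heavy
ties — under independent sampling with known true effects. They do not
emulate dependence between observations, covariates, missingness, or
measurement drift; calibration results here say nothing about clustered or
longitudinal designs. Near-boundary effects (θ > 0.9) are a documented
weak spot of *all* three interval methods; the C² interval degrades last
but also becomes liberal eventually. For n_i < 15 the χ²₁ approximation
of the C²-test has limited support from the study design; the permutation
test is the safer choice there.

## Numerical choices

* θ̂ is clipped to [0, 1] against float drift off its rational grid;
  degeneracy checks use exact comparisons (θ̂ ∈ {0, 1}, σ̂_N² == 0 after
  the round-off clamp).
* The permutation p-value is capped at 1; ties between permuted and
  observed statistics count in both tails (≤ and ≥), the conservative
  convention.
* Exact enumeration refuses above 200,000 assignments; callers fall back
  to random permutations.
* The batch kernel (`_kernel`) vectorizes ranking across replicates; its
  agreement with the scalar reference path is itself a test.
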