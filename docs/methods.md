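# Methods

## Model and null hypothesis

The working model for pair distances is

    d_ij = α + β_M·G_ij + β_E·|E_i − E_j| + β_I·Δ_ij + ε_ij

with `G_ij = |g_i − g_j|`, `Δ_ij = |g_i E_i − g_j E_j|`, dosages g ∈ {0,1,2}
and an environment variable E. The score statistics for β_M and β_I evaluated
at the null are `S_M = Σ_{i<j} d′_ij G_ij` and `S_I = Σ_{i<j} d′_ij Δ_ij`,
where d′ are the distances after removing the null-model nuisance terms
(overall mean; for the interaction analysis also the environment main effect,
by ordinary least squares of d_ij on |E_i − E_j| over all pairs; covariates by
the dbRDA projection described below).

Inference conditions on the distance matrix and the observed environment and
randomizes genotypes only: each subject's dosage is an independent
Hardy–Weinberg draw ((1−f)², 2f(1−f), f²) at the SNP's minor-allele frequency
f. This conditioning is what makes a MAF-grid precomputation possible, and it
matches the biology of the question (the community structure is the fixed
phenotype; the SNP is scanned).

One consequence of holding E fixed deserves note. After the pair-level OLS,
residuals are orthogonal to the intercept and to |E_i − E_j|, but for a
binary E the E-concordant strata (both exposed vs. both unexposed) share
|ΔE| = 0 while having different expectations of Δ. The interaction score
therefore has a nonzero exact null mean, `E₀[S_I] = Σ d′_ij E[Δ_ij|E_i,E_j]`,
which this package computes analytically and subtracts before standardizing:
`Z_I = (S_I − E₀[S_I]) / sd₀(S_I)`. Treating E as exchangeable instead would
set this mean to zero by fiat; the fixed-E choice is the one whose
calibration the test suite certifies.

## Exact null moments via pattern enumeration

All null moments — Var₀(S_M), Var₀(S_I), Cov₀(S_M, S_I), and every third- and
fourth-order (cross-)moment — decompose over the ways the pair indices of a
product of score terms can coincide. The decomposition is generated
programmatically rather than derived by hand:

1. For a product of m score factors, every set partition of the 2m pair
   endpoints that does not collapse a pair onto one subject defines a
   *pattern*: a small multigraph whose vertices are distinct subjects and
   whose edges are pair terms (tagged main-effect or interaction).
2. Patterns containing a connected component with a single edge vanish,
   because the pair kernels are centered and disjoint pairs are independent.
3. Each surviving pattern contributes (distance sum) × (genotype moment):
   * the distance sum runs over tuples of distinct subjects arranged as the
     pattern, evaluated by einsum contractions with inclusion–exclusion over
     vertex coincidences (quotient patterns with self-loops vanish since the
     matrix has a zero diagonal) — never by explicit high-order loops;
   * the genotype moment is an exact expectation over {0,1,2}^k (k ≤ 6
     pattern vertices) weighted by HWE probabilities — never sampled.
4. With an environment, pattern vertices additionally carry an environment
   stratum; distance sums are stratified through indicator vectors folded
   into the contraction, and genotype moments are evaluated per stratum
   assignment. Environments with more than 8 distinct values are discretized
   into 8 quantile strata *for the moment computation only* (the scores
   themselves always use the exact E values); a binary exposure — the main
   use case — is exact.

Because multiplicity constants come from enumeration, not derivation, the
test battery certifies every assembled moment against an independent oracle:
exact summation over all 3^N genotype vectors on N ≤ 8 instances (relative
tolerance 1e-9), plus Monte-Carlo agreement at N = 100. The same engine run
at second order reproduces the closed-form variance
N(N−1)/2·Var(G)·μ₂ + N(N−1)(N−2)·Cov(G_ij,G_ik)·μ₃ to machine precision,
which is kept in the code as an independent cross-check route.

Per-SNP cost in a scan is O(N²): distance-structure sums are computed once
per study, genotype moments are tabulated on a MAF grid (default step 0.005,
interpolation error on skewness ≈ 1e-4 relative, verified in the tests) and
linearly interpolated at each SNP's MAF. SNPs with missing genotypes take an
exact slow path: affected subjects are dropped, the pair values are
re-residualized on the remaining subjects and moments recomputed at the
SNP's own MAF (cached per missingness pattern). This is exact but expensive
when many distinct missingness patterns exist; heavily missing datasets
should be pre-imputed or pre-filtered upstream.

## Tail correction

The standardized scores carry positive skewness γ ∝ N^(−1/2) and excess
kurtosis κ ∝ N^(−1); the normal tail is therefore too small by orders of
magnitude exactly where GWAS cares. The corrected upper tail is an
exponentially tilted normal approximation built from the truncated cumulant
function K(ξ) = ξ²/2 + γξ³/6 + κξ⁴/24:

    P₀(Z > b) ≈ exp(K(ξ) − bξ + σ²ξ²/2) · Φ(−σξ),
    K′(ξ) = b,   σ² = K″(ξ) = 1 + γξ + κξ²/2.

The saddlepoint equation is solved by vectorized Newton iteration from
ξ = b, which selects the root continuous in (γ, κ) → 0 (the κ = 0 branch has
the closed form ξ = (√(1+2γb) − 1)/γ and the two routes agree to 1e-10 in
the tests). The correction targets the upper tail: for b < 1, or when no
admissible root exists or the tilted variance is nonpositive, the code falls
back to Φ(−b) and flags the value. Output p-values are clipped to
[1e-300, 1].

## Joint one-sided test

(Z_M, Z_I) is asymptotically bivariate normal with null correlation ρ
(computed exactly from the mixed second moments). The joint statistic Q is
the likelihood-ratio statistic under the positivity constraints, a
chi-bar-square on four cones:

* A1 (both effects pulled positive): Q = Z'Ω⁻¹Z;
* A2/A3 (one active): Q = ((Z_I − ρZ_M)/√(1−ρ²))² resp. the mirror —
  algebraically equal to (w₁Z_M + w₂Z_I)² with w₁ = (θ−1/θ)/2,
  w₂ = (θ+1/θ)/2, θ = √((1−ρ)/(1+ρ));
* A4: Q = 0.

Cone boundaries follow the KKT conditions of the constrained projection. The
null survival has the closed form

    P(Q > q) = q₁·P(χ²₂ > q) + P(N(0,1) > √q),     q > 0,

with q₁ = 1/4 + arcsin(ρ)/2π: each one-active cone contributes
P(half-plane)·P(N > √q) = ½·P(N > √q) because the projected coordinate is
independent of the half-plane indicator. (A naive reading that weights the
one-active terms by the cone probabilities q₂ = q₃ = 1/4 instead of ½ does
not integrate to the correct survival; the closed form above is certified by
exact-null uniformity simulations in the test suite.) The statistic has an
atom at Q = 0 with mass q₄ = 1/4 − arcsin(ρ)/2π, where the p-value is 1 by
construction; below its continuous ceiling q₁ + ½ the p-value is exactly
uniform under the null.

Moment corrections per cone: in A2/A3 the tilted tail is applied to the
projected combination with its own exact null skewness/kurtosis (assembled
from the mixed score moments); in A1 each marginal tail is corrected, mapped
back through the normal quantile, and the chi-bar statistic of the corrected
pair is re-evaluated at the unchanged ρ (tilting barely moves the bulk
correlation). With all corrections zero the asymptotic evaluation is
recovered identically.

## Covariate adjustment

Covariates are removed once, before the scan, by a distance-based redundancy
construction: Gower-center the squared distances, G = −½·C(d∘d)C; apply the
orthogonal projector complement of span(1, X) on both sides,
G_res = (I−H)G(I−H); reconstruct residual distances from the residual Gower
form, clipping the rare negative squared values at 0. With no covariates (or
constant columns, which are absorbed into the intercept) the construction is
the identity on Euclidean-embeddable matrices; it is idempotent; and a
covariate that truly generated a community shift is annihilated (H·G_res = 0),
which the tests verify along with restoration of nominal type-I error under
planted stratification-style confounding. Genuinely collinear covariate
columns raise an error naming the offending columns.

## Synthetic data

Two community generators provide all fixtures and calibration studies; both
reduce to exchangeable null matrices at zero effects.

* **dirichlet** (default): per-subject taxa proportions from a Dirichlet
  whose log-concentration shifts with genotype (and genotype×environment on
  an affected-taxa contrast), multinomial counts at fixed depth, Bray–Curtis
  distances. Defaults emulate a rarefied 16S profile: 200 taxa, log-normal
  base abundances (sd 2 on the log scale, so a few taxa dominate), total
  concentration 30 (strong overdispersion), depth 10,000 reads. This regime
  produces the right-skewed pair-distance structure (score skewness ≈ 0.2 at
  N = 100, MAF 0.2) typical of real cohort matrices.
* **latent**: multivariate-normal subject profiles with genotype/interaction
  shifts on a latent axis, Euclidean distances. Lighter-tailed; used for
  fast power simulations.

What the generators do *not* emulate: phylogenetic structure (no UniFrac),
read-depth variation and rarefaction artifacts, taxa correlation networks,
and longitudinal repeat structure. Passing calibration on these matrices
demonstrates that the moment corrections adapt to whatever pair-distance
structure they are given (the machinery is matrix-agnostic by construction);
it does not by itself validate upstream distance estimation on real
sequencing data.

The environment factor defaults to binary at 50% frequency, drawn
independently of genotype. A single root seed drives all streams;
independent sub-streams are split off with `numpy` generators.

For the sample-size scaling study the matrix family grows by *subject
replication at the pair mean*: each subject appears k times, inherited
distances are kept, and pairs of copies of the same subject sit at the
overall mean distance so that, after centering, duplicated pairs carry zero
weight. This preserves all per-tuple-normalized distance sums up to O(1/N);
naive tiling (copy pairs at distance zero) instead injects N artificial
extreme pairs that dominate the third moment and break the family. On this
family γ halves per quadrupling and κ per doubling of N as expected; note
that for a *single* heavy-tailed matrix at moderate N the skewness can sit
visibly off its asymptote — the decay laws are asymptotic statements.

## Numerical choices and edge cases

* Distance files: square labeled TSV/CSV or lower-triangle PHYLIP; relative
  asymmetry up to 1e-8 is symmetrized by averaging, anything worse is a
  format error naming the worst cell; negative, non-finite or nonzero
  diagonal entries are format errors; at least 3 subjects (μ₃ is undefined
  below that).
* PLINK input: .bed SNP-major v1.00 only; dosages oriented so the minor
  allele is counted (MAF ≤ 0.5); monomorphic and below-threshold-MAF SNPs
  are skipped with a reason, never silently zero-filled; the MAF filter
  defaults to 0.05 and is a flag because the sensible threshold depends on
  the study size.
* Degenerate cases: nonpositive null variance (possible at tiny N with very
  negative μ₃), constant environment, and |ρ| ≈ 1 joint geometry all skip
  the affected statistic with an explicit reason.
* The genomic-control λ uses the median of the implied χ²₁ statistics, so
  tail miscalibration does not register in λ — which is precisely why the
  scan reports both λ and before/after-correction genome-wide counts.
* Determinism: identical inputs and configuration produce byte-identical
  output tables.

## Known limitations

* Additive dosage coding only; no dominance coding, no multi-allelic
  variants, no dosage (imputed) genotypes, no VCF/BGEN/PLINK-2 input.
* One distance matrix per scan (no multi-metric or generalized-UniFrac
  sweep) and no permutation-mode inference.
* The fixed-E higher-order Δ moments are exact for categorical environments
  (≤ 8 levels); continuous exposures are quantile-discretized for the
  moments, an approximation documented above.
* The per-SNP missing-genotype path is exact but can dominate runtime when
  most SNPs have distinct missingness patterns.
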