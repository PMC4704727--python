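# Methods

## Setting

Data are an experimental cross of *n* lines — selfed recombinant inbred
lines (RIL, genotypes AA/BB) or an F2 intercross (AA/AB/BB) — with a
genetic map of markers (chromosome, cM) and a function-valued phenotype:
one value per line at each of *T* ordered time points t₁ < … < t_T.  The
goal is to locate quantitative trait loci (QTL) affecting the curve, and
to estimate when in time each QTL acts.

## Genetic model and genotype probabilities

Genotypes along a chromosome follow a Markov chain without crossover
interference.  Map distance d (cM) converts to a recombination fraction by
the Haldane function r(d) = (1 − e^(−2d/100))/2; for selfed RIL the
two-state chain uses the map-expanded fraction R = 2r/(1+2r), and the F2
three-state chain is the product of two independent meioses.  The
simulator draws from exactly this chain, inserting latent QTL as extra
loci and hiding them from the observed genotype matrix.

Posterior genotype probabilities at every marker and at pseudomarkers
every `step` cM (default 1) are computed by a scaled forward–backward pass
with a symmetric genotyping-error emission (default error probability
1e-4; 0 gives exact posteriors for testing).  Missing genotypes and
pseudomarkers contribute flat emissions.  For selfed RIL the pairwise
fraction R does not compose exactly along a refined grid (the selfing
process is only pairwise-Markov at marker resolution); the grid chain is
the standard working approximation and is the contract the tests pin down
by brute-force path enumeration.

Ties in any argmax over the grid resolve to the lowest chromosome index,
then the leftmost position, so results are deterministic.

## Smoothing

Each line's curve is approximated in one shared cubic B-spline basis
(order 4) with K − 4 interior knots equally spaced on (t₁, t_T) — the
designs this package targets sample time uniformly, so quantile placement
would add nothing.  The T×K design matrix Φ, Φ_{jk} = φₖ(tⱼ), is factored
once and every line's coefficients are the least-squares solution
ĉ = (Φ′Φ)⁻¹Φ′y.

K is chosen by ten-fold cross-validation over **time points**: folds
partition the time axis (seeded, shared across lines), each fold is
predicted from a basis fit to the remaining points, and squared error is
summed over all lines and folds; ties go to the smaller K.  Folding over
time rather than lines matches what is being selected — a per-curve
smoother shared by all lines; folding over lines is available as an
option.  Held-out points falling outside a training fold's span are
predicted at the nearest domain endpoint.  K grids default to
4 … min(40, T−1); infeasible K (training fold smaller than K) are
reported as infinite CV error.  Missing phenotype cells are imputed per
line by linear interpolation in time (with a warning) before fitting.

## Functional PCA

With curves in basis coordinates, all inner products go through the Gram
matrix W = [∫φⱼφₖ], computed exactly by per-knot-interval Gauss–Legendre
quadrature.  Writing ψ = Σ bₖφₖ and u = L′b with W = LL′ (Cholesky), the
sequential maximization of Σᵢ⟨ŷᵢ, ψ⟩² under orthonormality becomes the
symmetric eigenproblem of (1/n)·L′C′CL (C the n×K coefficient matrix), so
the eigenfunctions are exactly W-orthonormal and scores are
Zᵢⱼ = cᵢ′Wbⱼ.  Signs are fixed by making each eigenfunction's
largest-magnitude coordinate positive.

**Centering.** By default the mean curve is subtracted before the
eigenproblem, as in conventional functional PCA.  The alternative —
applying the maximization criterion literally to uncentered curves — is
kept as `center=False`, but it is not a useful default: the leading
uncentered component is essentially the mean direction and absorbs
\>99.8% of uncentered "variation" on growth-curve data, so the 99% rule
would keep a single component and collapse the multi-trait statistics to
a single-trait scan.  The retained dimension p is the smallest count
whose cumulative eigenvalue fraction reaches the threshold (default
0.99), optionally capped by `max_pc`, and by n−1 when centering.

## Single-QTL scans

At grid position λ the traits are regressed on an intercept plus expected
genotype dosages: for RIL one additive column P(BB) − P(AA) (±1 at typed
markers); for F2 additive P(BB) − P(AA) plus a dominance column P(AB)
(three-parameter model, the default for intercrosses).  Per-trait
LODⱼ(λ) = (n/2)·log₁₀(RSS₀ⱼ/RSSⱼ(λ)) against the intercept-only null.
SL and ML average and maximize these across the p score traits; SLOD and
MLOD do the same across the raw time points of the smoothed curves.  The
multivariate HKLOD replaces per-trait RSS ratios with determinants of the
p×p residual cross-product matrices; it requires p ≤ n − q.

Numerics: all scans are computed from centered cross-products with
stacked per-position solves (pseudo-inverse with a 1e-10 relative cutoff,
so uninformative positions degrade gracefully to LOD 0); RSS is floored
at 1e-12·RSS₀ so perfect fits yield a large finite LOD rather than
infinity; log-determinants use `slogdet` with a 1e-10·trace ridge as a
fallback on numerically singular matrices; constant traits get a zero
LOD curve and a warning.  An independent dense least-squares oracle
reproduces every LOD to 1e-8 in the tests.

## Permutation thresholds

Genome-wide significance uses permutation: rows of the trait matrix are
permuted jointly (preserving the trait covariance) against the genotypes,
the genome scan is repeated, and the maximum recorded.  The threshold at
level α is the order statistic of rank ⌈(1−α)R⌉ of the R maxima — a
bit-reproducible definition.  Permutations are seeded from the root seed
by counter (SeedSequence spawn keys), so results are independent of
batching and execution order.  Statistics that share a scan (SL/ML;
SLOD/MLOD) are extracted from one batched pass in which permuted trait
matrices ride along as extra trait columns; permuting score rows is valid
because smoothing and PCA never see the genotypes, so they commute with
permutation.

## Multiple-QTL models

A model γ is a set of QTL positions fitted jointly: Z = Qβ + ε with one
dosage block per QTL (strictly additive across QTL).  Its criterion is
pLOD(γ) = LOD(γ) − T·|γ|, where LOD(γ) is the joint SL/ML/HKLOD (or
SLOD/MLOD) against the null and T is the 5% permutation threshold of the
matching single-QTL statistic.

The search runs forward selection to `max_qtl` (default 10), each
addition taking the grid position that maximizes the joint statistic,
followed by coordinate-ascent refinement of all positions; then backward
elimination to the null; the returned model maximizes pLOD over every
model visited (ties: smaller model, then lower chromosome, leftmost cM).
Two QTL may not sit within `min_sep` (default 10 cM) on one chromosome —
closer pairs give near-collinear designs the data cannot separate.

Refinement moves each QTL, on its own chromosome, to the argmax of its
*profile objective*: the joint statistic with the QTL at λ minus the
statistic with it dropped.  For SL and HKLOD the dropped-model term is a
constant, so this is ordinary coordinate ascent on the joint statistic;
for ML the per-trait differences are maximized, which makes the fitted
positions coincide with the peaks of the reported ML profiles (the same
convention used for profile curves: per-trait profiles first, then
average or maximize).  Profile curves are computed per QTL over its
chromosome grid with all other QTL fixed.

Effects translate to the time domain as β̂Ψ, with Ψ the eigenfunctions
evaluated at the data time points; QTL rows are reported as the
high-minus-low allele contrast (twice the additive coefficient under ±1
dosage coding), and the baseline adds back the subtracted mean curve.

## Simulation designs (and what they do not emulate)

**Single-QTL logistic intercross.** One 100 cM chromosome, six equally
spaced markers, a QTL at 32 cM.  Mean curves follow
g(t) = a/(1 + b·e^(−rt)) at t = 1…10 with genotype-specific parameters
AA (29, 7, 0.70), AB (28.5, 6.5, 0.73), BB (27.5, 5, 0.75); residual
curves are multivariate normal with covariance c·Σ, Σ autoregressive
(σ² = 3, ρ = 0.6), equicorrelated (σ² = 3, ρ = 0.5), or user-supplied;
c ∈ {1, 2, 3, 6} spans mean heritabilities (analytic, reported by
`mean_heritability`) from 0.088 down to 0.017.  Optional i.i.d. Gaussian
measurement noise (sd 1 or 2) is added cell-wise.  Ten equally spaced
time points at t = 1…10 are a package choice; the count is the design's,
the placement configurable.

**Cubic multi-QTL RIL.** Five 100 cM chromosomes (markers every 10 cM by
default).  Each line's curve is a cubic a + bt + ct² + dt³ on t ∈ [0, 1]
sampled at 241 equally spaced points; the four coefficients are a
baseline plus ±1-dosage multiples of per-QTL cubic effect coefficients
plus a multivariate-normal individual deviation, with N(0, 1) measurement
noise.  No canonical effect coefficients exist for this design, so they
are required inputs; `example_threeqtl_spec` provides the package's
documented example (QTL at chr1@61, chr3@76, chr4@40; late-rising,
mid-bump, and early-broad effect shapes; diagonal coefficient covariance
diag(4, 16, 16, 4)) used by the tests and benchmark.

These generators emulate dense, regularly sampled curves with Gaussian
residuals, a shared time grid, and genotype effects that are additive
across loci.  They do not emulate irregular or line-specific sampling,
heteroscedastic or skewed measurement error, genotype-by-environment
structure, segregation distortion, or epistasis — so passing benchmarks
demonstrate correctness and power under the stated models, not
performance on data violating them.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` run the designs at desk scale,
chosen as the package's standard benchmark sizes: 200 null genomes × 200
permutations for threshold calibration (99% binomial acceptance band
around 0.05); 100 replicates at n = 400, c = 1 for stepwise recovery
(success = exactly one QTL within 10 cM of truth; the recovered effect
curve is compared to the true genotype contrast through its pointwise
3-SE band); 100 paired replicates at the equicorrelated c = 3 setting
for the noise-robustness comparison (per-replicate thresholds, since a
single shared threshold's sampling error can mask the effect); and a
six-condition sweep (c ∈ {1, 3, 6} × n ∈ {100, 400}, 50 replicates) for
the power/precision trade-off.  Power comparisons between noise levels
use the low-heritability end of the design grid because power saturates
at 1 for every method above h̄² ≈ 0.05 at n = 200, where no ordering is
observable.

## Known limitations

- Sparse/irregular per-line time grids are out of scope (scores are plain
  inner products, not conditional expectations).
- Covariates, X-chromosome handling, sib-mated RIL, epistatic penalties,
  and interval mapping by EM are not implemented.
- The RIL grid chain is the pairwise-Markov approximation discussed above.
- Permutation thresholds assume exchangeable lines (no family or
  population structure).
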