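# Methods

## The Poisson-Tweedie family

`ptseq` models an RNA-seq expression profile — the counts of one gene across
replicate samples — with the Poisson-Tweedie (PT) family of count
distributions. The family has canonical parameters (a, b, c) on the domain
a ≤ 1, b > 0, 0 ≤ c < 1 and is defined through its probability generating
function

    G(y) = exp{ (b/a) [ (1−c)^a − (1−cy)^a ] },        a ≠ 0,
    G(y) = [ (1−c) / (1−cy) ]^b,                        a = 0,

so that a single shape parameter moves continuously between the classical
count models: Poisson (a = 1), negative binomial (a = 0),
Poisson-inverse-Gaussian (a = 1/2), Pólya-Aeppli (a = −1) and, in the limit
a → −∞, Neyman type A. For interpretation the package works in (μ, φ, a)
with μ the mean and φ = σ²/μ the dispersion index; the two parameterizations
are linked by

    c = (φ − 1)/(φ − a),      b = μ (1 − c)^{1−a} / c.

The expression for b is the unique choice with G′(1) = μ; it is validated in
the test suite by finite differences of the pgf and by the negative-binomial
closed form. φ = 1 is the Poisson boundary: any request with
φ ≤ 1 + 1e−8 or a ≥ 1 − 1e−8 is dispatched to Poisson(μ) closed forms,
because c degenerates there (0/0 at a = 1).

### pmf evaluation

The pmf has no closed form for general a and is computed by the forward
recursion

    p₀ = exp{ b[(1−c)^a − 1]/a }   (a ≠ 0),   p₀ = (1−c)^b   (a = 0),
    p₁ = b c p₀,
    p_{k+1} = [ b c p_k + Σ_{j=1}^{k} j r_{k+1−j} p_j ] / (k+1),
    r₁ = (1−a) c,    r_{j+1} = c r_j (j−1+a)/(j+1).

Numerical policy:

* The recursion runs in a scaled linear space: values are stored relative to
  a running log-offset, with renormalization whenever the working maximum
  overflows, so profiles with log p₀ < −700 (μ ≳ 10⁴) remain computable.
  `expm1` keeps the a → 0 limit smooth to machine precision — without it the
  likelihood surface acquires gradient noise exactly at the NB cut-point
  where most optimizations converge.
* Entries in [−1e−12, 0) are clipped to 0; anything more negative raises a
  numeric-failure error rather than being masked.
* For very negative shapes (a ≲ −40) the alternating recursion coefficients
  can cancel catastrophically and produce garbage *positive* entries; any
  pmf whose partial sum exceeds 1 + 1e−8 (1e−6 inside the optimizer) is
  rejected. The optimizer treats such regions as infeasible (objective 1e30)
  and converges in stable territory.
* cdf, quantile and sampling tabulate the pmf, extending the support by
  doubling until the cumulative mass reaches 1 − 1e−12, with a hard cap of
  10⁶ support points and a saturation rule: if mass ≥ 1 − 1e−9 and a
  doubling step gains < 1e−13, the remaining deficit is below
  double-precision resolution and extension stops. Sampling uses one
  uniform draw per variate inverted against the tabulated cdf; Poisson and
  NB members use their closed-form samplers.

## Maximum-likelihood fitting

A profile is summarized as the frequency table y₀…y_m of observed counts and
fitted by maximizing Σ y_i log p_i(θ), with per-cell floors at log(1e−300).
The optimizer is L-BFGS-B on the coordinates (log μ, log(φ−1), a) with the
single box constraint a ∈ [−100, 1]: the transform removes the positivity
constraints, behaves well as φ → 1, and a = −100 is numerically
indistinguishable from the Neyman-type-A limit. Starting values are the
moment estimates (sample mean; dispersion index from the unbiased variance,
clamped at 1 + 1e−6; a = 0, the NB cut-point of the shape domain). On a
line-search stall the optimum is polished by a Nelder-Mead pass; up to three
restarts perturb the start (1.5× the dispersion excess, a = ±0.5). Fits
whose dispersion collapses to the φ = 1 boundary are returned as Poisson
fits with Var(μ̂) = μ̂/n; all-equal profiles are flagged degenerate instead
of failing so genome-wide loops survive.

The parameter covariance is the negative inverse of a central-difference
Hessian (relative steps 1e−4, absolute floor 1e−6) computed in the optimizer
coordinates and mapped back by the delta method; singular Hessians fall back
to the pseudo-inverse with a flag.

## Goodness of fit to the negative binomial

Since NB is the a = 0 member, H₀: a = 0 is tested inside the family by the
likelihood ratio 2 log T = 2(ℓ_PT − ℓ_NB) referred to χ²₁ (a = 0 is interior
to the shape domain, so no boundary mixture applies; small negative values
from optimizer noise are clipped at 0).

Finite-sample behaviour worth knowing: at n ≈ 70 the χ²₁ reference is
accurate when overdispersion is strong (φ ≳ 5, where the shape is well
identified — verified by KS against χ²₁ on 500 simulated NB profiles with
μ = 100, φ = 15), but at mild overdispersion (φ ≤ 3) the statistic is
*conservative* (mean ≈ 0.6 rather than 1): the shape is weakly identified
and its MLE drifts into the flat a → −∞ region, truncating the likelihood
gain. Conservative means the test under-rejects the NB null; it never
over-reports non-NB genes.

## The two-sample test for differential expression

For each gene both groups are fitted independently and the group means
compared by the Wald statistic. By default the test is performed on the
logarithmic scale, H₀: log μ_A = log μ_B,

    T = (log μ̂_A − log μ̂_B) / sqrt( Var(μ̂_A)/μ̂_A² + Var(μ̂_B)/μ̂_B² ),

with delta-method variances; the raw-scale statistic
(μ̂_A − μ̂_B)/√(Var(μ̂_A)+Var(μ̂_B)) is available as an option. T is treated
as standard normal under the null and p-values are two-sided (the
alternative μ_A ≠ μ_B is symmetric). Genes whose fit fails in either group
are reported with flags and missing p-values — excluded from the BH
denominator, never silently dropped and never assigned p = 1.

At 15 samples per group the test is mildly liberal (empirical type-I error
≈ 0.057 at α = 0.05 over 4,000 simulated null genes spanning NB and non-NB
shapes), within the binomial-3·SE band; this is ordinary small-sample Wald
behaviour and is the package's recommended minimum sample size.

## Normalization

* `cpm_filter` keeps genes whose mean counts-per-million strictly exceeds
  the threshold (default 0.1).
* `tmm_factors` implements trimmed-mean-of-M-values factors with the
  standard defaults: 30% two-sided trim on M, 5% on A, precision weights
  from the delta-method variance of M, reference sample chosen by
  75th-percentile proximity to the mean, factors rescaled to geometric mean
  1. Agreement with the reference implementation is frozen into the test
  suite at 1e−9.
* `normalize_counts` rescales counts to the geometric mean of the effective
  library sizes and maps the resulting real-valued pseudocounts back to
  integers via ceiling(x − 0.5) (round-half-up, floored at 0), which keeps
  the zero fraction of the data as close as possible to the raw counts.
* `apply_offsets` consumes externally computed per-gene-per-sample log2
  offsets (e.g. conditional-quantile normalization output adjusting for
  gene length and GC content): counts go to log2 reads-per-million, offsets
  are added, and the result is rolled back through the library size and the
  same integer rule. Zeros bypass the log round trip and stay zero,
  preserving the zero-inflation structure the PT model is designed to
  capture. Computing such offsets is out of scope.

## Simulated studies

`simulate_pt_profiles` draws each gene's two group blocks i.i.d. from
explicit PT laws — identical laws make a null gene. The type-I-error studies
cycle over four laws spanning the family: NB(μ=50, φ=3), PIG(μ=50, φ=3),
Pólya-Aeppli(μ=20, φ=5) and a heavy-tailed member (μ=100, φ=2, a=0.8).

`simulate_gamma_poisson_study` generates a full study: per-gene dispersion
φ_g = 1 + Gamma(k=2, θ=0.7) (the shift keeps every draw a valid dispersion
index; truncation-with-redraw is available), baseline means log-uniform on
[5, 500] (a realistic expressed-gene range after abundance filtering;
config-exposed), a chosen number of DE genes at a fixed fold-change — half
up-, half down-regulated, the odd gene going up — and optional per-sample
library factors exp(N(0, σ)) applied multiplicatively. Counts are Poisson
with gamma rates of shape f μ/(φ−1) and scale φ−1, making the marginal
exactly NB with mean fμ and dispersion φ (enforced by a χ² frequency test
in the suite). What this generator does not emulate: correlated genes,
gene-length/GC biases, outlier samples, or empirical mean-dispersion trends;
passing calibration here demonstrates correctness of the statistics, not
robustness to those real-data artefacts.

`null_resample_groups` recreates the null with real or simulated data by
repeatedly splitting same-condition samples into two pseudo-groups (a
random partition without replacement when ≥ 2n samples carry the label,
with replacement otherwise).

## π0, q-values and calibration metrics

q-values are BH step-up values scaled by Storey's π̂0. π̂0(λ) =
#{p > λ}/((1−λ)m) is evaluated on λ = 0.05, 0.10, …, 0.95 and pooled by
averaging the central grid points (0.20 ≤ λ ≤ 0.80). The design was
genuinely open here: tail extrapolation (the spline-smoother recipe) is
unbiased when m is very large but at m ≈ 2,000 its variance is dominated by
the handful of p-values above 0.9 — measured across replicate studies it
mis-estimated the number of DE genes by ±80 with a systematic excess of
≈ 50, while the central-grid average was nearly unbiased (SD ≈ 50). The
average is slightly conservative when true positives leak above λ = 0.2,
which is negligible at the fold-changes and sample sizes these studies use;
`method="smoother"` restores the polynomial fit evaluated at λ = 0.95.

Empirical-FDR curves call genes at q ≤ q* over a grid of 101 nominal levels
on [0, 0.25] and record the observed false-positive fraction among calls
(0 when nothing is called); the curve's MSE against the diagonal summarizes
calibration, comparable only within a fixed grid. Precision/recall/F use the
standard definitions with precision undefined (NaN) on empty call sets and
F = 0 when precision + recall = 0. Per-gene uniformity of replicated null
p-values is assessed by a one-sample Kolmogorov-Smirnov test against
U(0, 1), requiring at least 10 replicates.

## Problem sizes used by the shipped checks

The acceptance-style tests run: 4,000 null genes at 15 + 15 samples for the
type-I error; 200 profiles × 3 scenarios at n = 200 for parameter recovery;
500 NB profiles at n = 69 for GOF calibration; a 500-gene × 40-sample
condition resampled 100 times (20 vs 20) for p-value uniformity; and five
replicates of 2,000 genes × 70 samples (100 DE at 2-fold) for FDR
calibration — sizes chosen so the statistical bands are tight while a full
run stays in the tens of minutes on one core.

## Known limitations

* The general power-variance representation of the PT mean-variance
  relationship (exponent p) is not implemented; only σ² = μφ is exposed.
* The Wald DE test needs roughly 15 samples per group; below that it is
  liberal, and fits are increasingly often boundary cases.
* The GOF LRT is conservative at mild overdispersion (see above).
* The recursion is O(m²) in the maximum count; profiles with counts in the
  millions are better served by the NB/Poisson closed-form members.
* π̂0 estimation assumes well-separated alternatives; weak signals bias the
  central-grid average upward (fewer estimated DE genes).
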