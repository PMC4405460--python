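# Methods

`steppescan` implements an inference chain for detecting and dating
directional gene flow from a candidate source region into a set of focal
populations, together with the synthetic-data generators needed to exercise
every step with known ground truth. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## IBD sharing statistic

The input is a table of identity-by-descent (IBD) segments between pairs of
individuals, with lengths in cM (the shape of fastIBD-style post-processed
output; segment *detection* is upstream of this package). Segments are sorted
into half-open length bins — by default 1–2, 2–3, 3–4, 4–5, 5–6 cM — and for
each population pair and bin the total segment length is divided by the
number of individual pairs:

    S[i, j, b] = (total cM of bin-b segments between pops i and j) / (n_i n_j)

with `n_i (n_i − 1) / 2` unordered pairs for within-population entries. The
per-pair normalization makes S comparable across unequal sample sizes; the
normalizing "sample size" is the number of *pairs*, which is the reading that
makes the statistic an average per pair of individuals. Segment intervals are
half-open `[start, end)` so abutting segments never double-count.

## Distance decay

IBD sharing between populations decays approximately exponentially with
geographic distance. The decay analysis converts S into an IBD sharing
distance `−ln S`, computes great-circle distances (haversine, Earth radius
6371.0 km), divides each matrix by its own maximum ("max-standardization"),
and reports the Pearson correlation over off-diagonal upper-triangle entries
with a Fisher-z 95% CI. Zero-sharing pairs are masked rather than floored:
`−ln 0` is undefined and a pseudo-count would manufacture signal. The
p-value ignores the non-independence of matrix entries and is nominal. On a
noiseless `β exp(−d/λ)` network the transform is exactly linear in distance,
so r = 1 to machine precision — a structural self-check, not evidence about
real data.

## Subtraction–accumulation scan

For each focal population f, an ordered vector of its sharing with every
reference population is compared with the matching vector of f's pooled
geographic neighbors; the element-wise differences are summed across focal
populations. A reference with a *correlated* excess toward all focal
populations accumulates a large sum `A_ref`; references above the 0.90
sample quantile (linear-interpolation / type-7; the convention had to be
fixed somewhere) of `{A_ref}` are flagged, with strict inequality so ties
never flag.

The neighbor vector pools the neighbor populations' individuals into one
super-population and applies the standard per-pair normalization. This is
computed exactly from the sharing matrix and the per-population sample sizes
(a sample-size-weighted recombination of the pairwise totals, including
self-comparison terms when the reference sits inside the pool); a
per-population-average variant is available behind `pooled=False`. Pooling
matches the permutation test's pooling and makes the scan translation
invariant: adding a constant to every sharing value leaves every `A_ref`
unchanged. A focal population found inside another focal's neighbor set is
removed from that set with a warning — otherwise the signal would subtract
itself.

The randomization null replaces each focal population with one neighbor
drawn from its own set (the remaining members become the pseudo-focal's
neighbors) and re-runs the scan; replicate draws derive deterministically
from the master seed. Because focal and reference sets must stay disjoint,
pseudo-focal populations drop out of their replicate's reference list; flag
frequencies are therefore normalized per reference by the number of
replicates in which it was eligible.

## Permutation test

The observed statistic is the binned sharing between a focal population and
a candidate source. Each of `n_perm` permutations (default 10,000) draws,
without replacement, a pseudo-population of the focal's size from the pooled
neighbor individuals and recomputes the statistic against the source over
the *fixed* segment table. The p-value is `n_geq / n_perm` where `n_geq`
counts permuted values greater than or equal to the observed one — ties
count, there is no +1 correction, and the minimum resolvable p (`1/n_perm`)
is reported alongside. Within one focal population the same pseudo-population
draws are reused across sources and bins so the per-focal count of
significant sources is internally coherent.

Because the pseudo-populations are drawn from the neighbors only (never from
the focal sample itself), the test is mildly anti-conservative when the pool
is not much larger than the focal sample: sampling without replacement
shrinks the permutation spread by the finite-population factor
`√(1 − n/N)`, and the pool mean itself is noisy, giving a type-I rate of
roughly `0.05 + 0.17 · n/N` at the 0.05 level. At the calibration scale used
here (focal n = 10, five neighbor populations of 100 pooled) the empirical
rate is ≈ 0.04–0.06; with a pool only four times the focal sample it rises
to ≈ 0.11. Users with small neighbor pools should read borderline p-values
accordingly.

## f3 admixture test

For a trio (target T; sources A, B) with per-SNP sample frequencies
`â, b̂, ĉ` and observed target chromosome count `n_c`:

    summand = (ĉ − â)(ĉ − b̂) − ĉ(1 − ĉ)/(n_c − 1)

f3 is the SNP average; the correction removes the sampling bias of ĉ and no
heterozygosity normalization is applied (the qp3Pop default convention). A
significantly negative f3 indicates the target is admixed between groups
related to the two sources; testing is one-tailed on the negative side, at
Z < −1.64 nominally and at the Bonferroni-corrected quantile
`Φ⁻¹(α / n_tests)` for a test census (−4.89 at α = 0.05 over 97,548 trios).
Standard errors come from a weighted delete-one-block jackknife (Busing
weighting, weights proportional to SNP counts) over contiguous 5 cM windows;
the block size is configurable and was fixed here, not taken from a source.
Missing genotypes are handled per SNP (pairwise-complete frequencies); SNPs
with fewer than 2 observed chromosomes in any population, or monomorphic
across all three, are dropped. Trio enumeration takes all ordered targets
times unordered source pairs, `N(N−1)(N−2)/2` trios.

## Admixture dating

Three routes to the number of generations g since a one-pulse admixture:

**Analytic conversions.** A single-path IBD tract surviving 2g meioses has
expected length `100/(2g)` cM (2.5 cM at g = 20, 0.94 cM at g = 53). Years
convert to generations at 30 years per generation (600 y → 20, 1600 y → 53),
and calendar dates anchor at `year = 2000 − 30 g`, negative values read as
BCE. The anchor year and generation time are config keys.

**Weighted-LD decay.** Admixture LD between loci separated by d Morgans
decays as `exp(−g d)`. Per SNP the weight is the allele-frequency contrast
between the two reference panels, `w_s = p̂₁ₛ − p̂₂ₛ`; for every
within-chromosome SNP pair at distance 0.5–30 cM the admixed-panel dosage
covariance accumulates `D̂ₛₜ wₛ wₜ` into 0.25 cM distance bins, and the bin
averages are fit with `y(d) = A exp(−g d) + c` (least squares, A > 0, g > 0,
initialized from a log-linear regression with multiple g restarts). This is
deliberately a single-reference-pair simplification of weighted-LD dating:
no pre-test filtering, no cross-population LD subtraction, no amplitude
ranking across reference pairs. The affine term c absorbs background
covariance and is reported, never interpreted. `d_min = 0.5` cM excludes
background LD; both window edges and the bin width are configurable. The
95% CI is a delete-one-chromosome jackknife — the resampling unit was an
open choice and chromosomes are the natural exchangeable block for LD
statistics. A curve whose fitted exponential contributes nothing across the
window (amplitude at the zero boundary, or a degenerate zero-rate fit)
raises "no admixture LD detected" rather than returning a number.

**Ancestry-tract lengths.** In a one-pulse model the tracts of ancestry 1
are approximately exponential with mean `1/((1 − α) g)` Morgans, so
`ĝ = 1/(L̄ (1 − α))` with L̄ the mean tract length; for single-path IBD
segment lengths the analogue is `ĝ = 1/(2 L̄)`. Tracts touching a chromosome
end are censored and excluded rather than corrected; on 3-Morgan chromosomes
this biases ĝ upward by roughly `E[L]/C` (≈ 7% at g = 10, negligible by
g = 40) because long tracts are less likely to fit in the interior. The CI
is a percentile bootstrap over tracts (default 200 resamples). At least 30
tracts are required.

**Benchmark harness.** For a grid of true g values (default
5, 10, 20, 30, 40, 50, 60) and a replicate count, the harness simulates,
estimates, and reports `RMSE = √mean((ĝ − g)²)` and
`bias = (Σĝ − Σg)/n`; failed replicates are recorded as missing and excluded
with a logged count. RMSE ≥ |bias| always holds and is asserted.

## Synthetic data generators

**Sharing network.** Expected per-individual-pair sharing between
populations i and j in bin b is `β_b exp(−d_ij/λ) + δ_b` on designated
source→recipient edges (δ applies to the pair regardless of orientation;
the generator's truth table records every expectation). Segments are
realized per population pair and bin as Poisson counts with mean
`n_pairs · μ_b / E[length | bin]`, lengths drawn from the single-path
exponential (mean `100/(2 g_seg)` cM, g_seg default 20) truncated to the
bin, so the realized expectation matches μ_b exactly. Segment placement
(22 nominal chromosomes, uniform starts) is cosmetic: downstream statistics
consume only binned totals. The generator reproduces the statistical
*structure* of distance-decaying IBD sharing, not its demographic causes —
no shared ancestry between overlapping pairs, no population-specific
variance, independence across pairs. Calibration results on it therefore
validate the statistics' arithmetic and null behavior, not robustness to
real-data correlation structure.

**Admixed haplotypes.** Source allele frequencies are Balding–Nichols draws
around a shared ancestral frequency ~ Uniform(0.05, 0.95) with drift
parameter F (default 0.2, a strongly differentiated pair). Founder
haplotypes carry ancestry 1 with probability α; N diploids (default 500)
mate randomly for g generations, recombining as a Poisson process of rate 1
per Morgan — implemented on the marker grid via the exact Haldane
inter-marker switch probabilities `(1 − e^{−2d})/2`, which is the marginal
of the Poisson crossover process at marker positions; ancestry between
markers is unobserved anyway because alleles live on the grid. Tract
boundaries are emitted at inter-marker midpoints so tracts tile each
chromosome exactly. Alleles are copied from the local ancestry's source
frequencies, so source haplotype structure (background LD) is absent by
construction — admixture LD is the only LD in the data, which is the regime
the weighted-LD estimator assumes. The default scale is 30 Morgans as
10 × 3 M chromosomes with 1500 evenly spaced SNPs each (0.2 cM spacing),
100 sampled haplotypes and reference panels of 25 diploids: dense enough to
resolve decay scales down to g ≈ 60, small enough that a replicate simulates
in a few seconds. Constant population size is used throughout; growth over
the admixture period is not modeled.

**Frequency trios.** For f3 testing, a target with per-SNP frequency
`α p₁ + (1 − α) p₂` (optionally with post-admixture drift, default none)
plus Binomial(2, p) genotypes; `target_mode="independent"` draws the target
as an unadmixed third population for the null. Under the admixed
construction `E[f3] = −α(1−α) E[(p₁−p₂)²] < 0` by design, so these runs
check calibration and power of the estimator and its jackknife, not whether
admixture exists.

All generators are pure functions of config plus seed: identical inputs give
byte-identical outputs.

## Degenerate inputs and tie-breaks

Zero-sharing pairs are masked in the decay transform; an all-zero matrix is
an error. Quantile flagging needs ≥ 5 references and never flags ties.
Permutation p-values compare with a relative tolerance of 1e−9 so that
floating-point summation order cannot break the "equal or higher" tie rule.
f3 needs ≥ 2 jackknife blocks; a zero jackknife SE (identical blocks)
reports an infinite Z rather than dividing by zero. Tract dating refuses
all-censored tract sets; the LD fit refuses curves with fewer than 8 bins.

## Known limitations

The sharing-network generator's independence assumptions understate the
variance of real IBD statistics, so the permutation and scan calibrations
are best-case. The weighted-LD estimator assumes a single pulse and
drift-free references; continuous migration or reference admixture biases g.
Tract-based dating requires true tracts (here, the simulator's ground truth)
and the true α — it is a simulator-side benchmark companion, not an
inference tool for unlabeled data. The f3 census of a specific published
dataset (97,548 trios) is not reconstructible from a population count alone;
the enumeration formula is documented instead.
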