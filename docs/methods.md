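# Methods

## Homeolog proportion model

For one locus in the polyploid, replicate *i* contributes homeolog-assigned
read counts (x_A,i, x_B,i). The generative model is

    x_A,i ~ Poisson(λ_i · p),    x_B,i ~ Poisson(λ_i · (1 − p)),
    p = θ(1 − q_A) + (1 − θ) q_B,

with λ_i the replicate's total expression intensity (Gamma prior), θ the
locus-level homeolog proportion, and q_A, q_B the probabilities that a read
from one homeolog is assigned to the other's reference. Conditioning each
replicate on its total n_i = x_A,i + x_B,i integrates λ_i out exactly,
leaving x_A,i | n_i ~ Binomial(n_i, p). Because p is shared across
replicates, the likelihood depends on the data only through Σx_A and Σx_B.

With a Beta(a₀, b₀) prior on θ (flat by default) the posterior is evaluated
by normalised quadrature on a uniform grid over [0, 1] (default 2001 nodes;
Simpson weights for the normaliser and posterior mean, trapezoid cumulative
sums for the equal-tailed interval). Two exact checks anchor the numerics:

* q_A = q_B = 0 collapses the posterior to Beta(a₀+Σx_A, b₀+Σx_B); the grid
  density matches this closed form at every node to ~1e-13 relative error.
* For q > 0 the posterior mean agrees with 10× finer quadrature to <1e-11.

Endpoint conventions use 0·log 0 = 0 (`scipy.special.xlogy`); priors with
a₀ < 1 or b₀ < 1 have an integrable endpoint singularity that the grid
truncates to zero mass, so such priors are supported only approximately.

A locus is `biased_A`/`biased_B` when the 95% (configurable) equal-tailed
credible interval excludes 0.5, `unbiased` otherwise. Loci with fewer than
`min_total = 10` homeolog reads across replicates are excluded and logged
rather than reported as unbiased: with a flat prior their call would be
prior-dominated, not data-driven.

A single locus-level (q_A, q_B) pair is used for all replicates; the screen
that produces it operates on pooled diploid cross-mapping counts, and
replicate-level variation in misassignment is not modelled.

## Category semantics

The parental DE call (A higher / B higher / no DE) crossed with the bias
class gives nine categories: 1–3 parental legacy (no difference anywhere,
or bias mirroring the parental difference), 4–5 absence of bias (parents
differ, homeologs do not), 6–9 novel bias (bias without parental
difference, or against its direction). The category numbers within the
novel group follow the fixed order (no_de, biased_A) → 6, (no_de,
biased_B) → 7, (A_higher, biased_B) → 8, (B_higher, biased_A) → 9; the
group memberships, not the numbers 7–9, are the semantically meaningful
(and tested) surface.

## Mapping-bias screen

"Predominant" cross-mapping is operationalised as a cross-assignment
fraction above 0.5 (configurable) in either direction, with denominators
below `min_reads = 10` yielding `indeterminate` — ratio estimates from a
handful of reads are too unstable to act on. Misassignment estimates add a
+0.5 pseudocount per cell by default so that loci with zero observed
cross-mapping get a small positive rate rather than an impossible 0.

## Negative-binomial DE engine

Counts are normalised with median-of-ratios size factors (rescaled to
geometric mean 1; total-count fallback when no locus is positive in every
sample). Per-locus dispersions use method-of-moments within groups under
Var = μ + φμ², then are shrunk toward a fitted trend φ(μ) = a₀ + a₁/μ with
weight 0.8 on the trend. The heavy shrinkage is deliberate: with three
replicates per group the per-locus moment estimate is extremely noisy, and
the trend-dominated combination gives near-nominal null behaviour
(empirical type-I error ≈ 0.05 and KS distance from uniform ≈ 0.01–0.02 at
5,000 null loci, 3 vs 3) while preserving power at 4-fold effects.

Two-group contrasts use a Wald statistic on log(μ̂₁) − log(μ̂₂) with
delta-method variance (1/μ + φ)/n per group; the mid-parent contrast tests
H₀: μ_M = (μ_A+μ_B)/2 on the natural scale as a linear combination, so
replicate-level variance of all three groups enters directly and no
averaged pseudo-samples are constructed. Group means of zero are floored at
half a read per group for the statistic; displayed log2 fold changes use a
+0.5 pseudocount but the test never does. BH adjustment is applied per
contrast; a direction call is made at FDR < 0.05.

Exact numerical agreement with any specific GLM package is a non-goal, but
fold changes correlate >0.95 with an independent NB GLM implementation on
simulated data (cross-checked in the test suite).

Locus QC removes zero-total loci, loci with mean normalised count below 1,
and loci where one observation exceeds 10× the locus' largest-excluded
trimmed mean — a cheap leverage guard standing in for a full Cook's
distance. Sample QC runs PCA on log2(normalised+1) counts and
average-linkage clustering; a sample is flagged when the first cluster it
joins contains any member of another group, i.e. it fails to join its own
replicates first.

## Pattern classification

The three direction calls (M vs A, M vs B, A vs B) map onto patterns by a
fixed decision table: no change (M≈A and M≈B), transgressive up/down
(M beyond both parents), ELD toward A or B (M equals one parent, differs
from the other, parents differ), additivity (parents differ, M strictly and
significantly between them). ELD does not require sign consistency of the
third call — M≈A with M>B and A<B is still dominance toward A, since
near-threshold direction calls can disagree in sign. Triples the scheme
does not define (e.g. A≈B but M differing from exactly one parent) are
labelled `conflict` and reported, never coerced into a neighbouring
pattern, because silent coercion would bias the subgenome balance tests.
The 27 possible triples are exhaustively enumerated in the tests.

Subgenome balance of bias or dominance counts uses the 1-df chi-square
goodness-of-fit statistic Σ(obs−exp)²/exp against 1:1; the proportion of
non-additive loci between two polyploid forms is compared with a two-sided
Fisher exact test.

## Enrichment

Hypergeometric one-sided over-representation per term by default. With gene
lengths, the null is built by weighted sampling without replacement, the
weight being an isotonic (monotone) fit of target membership against
length; empirical tail p-values use +1 smoothing so p = 0 is impossible. In
the equal-weights limit this converges to the hypergeometric answer (tested
within Monte-Carlo error). No term-graph propagation is performed.

## Synthetic data generator

Baseline locus means are log-normal (location log 100, scale 1.0) — the
heavy right tail typical of RNA-seq, retaining low-count loci so QC filters
have work to do. Counts are Gamma-Poisson with dispersion φ = 0.05, three
replicates per group. Each locus draws a total-expression pattern
(no-change majority of 76.3%, additivity 1.1%, ELD 6.2/7.2%, transgressive
3.3/5.9% by default, proportions of the order seen in young natural
allopolyploids); patterns that presuppose parental DE force a ±2 log2-unit
parental fold change, no-change loci force zero, and transgressive loci
draw parental DE at rate 0.3. The polyploid mean is then the mid-parent
value (additivity), one parent's mean (ELD), or 2 log2-units beyond the
extreme parent (transgressive). Homeolog proportions are 0.5 except for a
20% biased fraction drawn uniformly from (0.65, 0.9) on a random side, and
homeolog counts split each polyploid replicate's total binomially with
p = θ(1−q_A)+(1−θ)q_B at q = 0.02 — misassignment applied at the read
level, exactly as the inference model assumes. All randomness flows from
one integer seed.

What the generator does *not* emulate: read-level effects (positional
bias, GC bias, mapping ambiguity correlated along the transcript),
locus-locus correlation, outlier samples, or library-composition shifts
between sequencing platforms. Recovery results on this generator therefore
demonstrate correctness of the inferential chain under its own model
assumptions, not robustness to real-data artefacts; depth factors are
configurable for sensitivity checks.

## Problem sizes and defaults

Parameter-recovery runs use 2,000 loci and DE calibration 5,000 loci —
sizes at which binomial/Monte-Carlo error on the reported rates is well
below the margins of interest while the whole suite runs in seconds.
Key defaults: credible level 0.95, grid 2001 nodes, `min_total` 10,
FDR α 0.05, dispersion-shrinkage weight 0.8, cross-mapping threshold 0.5,
`min_reads` 10, RBH filter (1e-10, 80%, 200 bp) applied to the B-as-query
direction (configurable to require both directions).

## Known limitations

* The conditional-binomial formulation discards no information for θ but
  does not model replicate-specific misassignment or extra-binomial
  overdispersion between replicates of the homeolog split.
* The Wald test's normal reference is asymptotic; at very low counts
  (mean < ~5 per group) p-values become conservative-to-erratic, which is
  why the QC filter removes such loci by default.
* The dispersion trend is a two-parameter curve, not a spline; datasets
  with non-monotone mean-dispersion relationships would be better served by
  a dedicated GLM package.
* Enrichment treats terms independently (no graph propagation, no
  between-term correlation in the FDR).
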