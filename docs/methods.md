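# Methods

## Model and likelihood

`blocklik` treats the genome as a collection of exchangeable sequence blocks
of fixed length `L`. For a sample of `b = (b_1, ..., b_X)` genomes from `X`
populations, the branches of any genealogy partition into *mutation classes*
indexed by the vector of sampled lineages they are ancestral to per
population; unfolded there are `prod(b_x + 1) - 2` classes, and without an
outgroup each class is merged with its complement (canonical representative =
lexicographic minimum). A block's data reduce to the count vector `k` of
mutations per class; the genome reduces to the histogram `n_k` of these
configurations (the bSFS). Monomorphic blocks count under the all-zero
configuration.

Conditional on a blockwise ancestral recombination graph (ARG) `A` with
marginal trees of spans `w_p` and per-class branch lengths `t_{i,p}`, the
class lengths aggregate as `t_{i,A} = (1/L) sum_p w_p t_{i,p}`, mutations are
independent Poissons with rates `theta_block * t_{i,A}`, and the likelihood
of a parameter point is approximated by averaging the configuration
probabilities over `M` simulated ARGs. The composite log-likelihood weights
each configuration by its block count. Blocks are treated as independent and
statistically exchangeable: heterogeneity in mutation or recombination rate
across the genome, selection, and between-block linkage are all outside the
model (the parametric bootstrap exists precisely because the independence
assumption makes the composite likelihood overconfident).

Two conventions close the probability space:

* zero-length classes contribute probability 1 at count 0 and probability 0
  at any positive count (they fall out of the Poisson recurrence naturally);
* with a per-class cap `k_max`, counts above the cap pool into a tail entry
  whose mass is the complementary Poisson CDF, computed via the complemented
  regularized incomplete gamma function (`scipy`'s Poisson survival
  function) rather than `1 - partial sum`, which loses precision for large
  caps. With the tail, the probabilities over the full enumeration sum to
  one exactly (a unit test holds this to 1e-12).

Tabulation from data defaults to *observed-only* mode — probabilities are
computed for exactly the configurations present — since capping is only
needed when a closed table is required.

## Units and scaling

Internally all times are in units of `4 * N_ref` generations and migration
rates are `4 * N_ref * m` (the ms convention); sizes are stored in
individuals, per-generation rates (`mu`, `r`, growth) unscaled. Block rates
derive as `theta_block = 4 N_ref mu * effective_length` and
`rho_block = 4 N_ref r * (L - 1)` — mutation scales with the callable bases
actually used, crossovers with the `L - 1` inter-site gaps. The small fixed
histories used for analytic cross-checks (stepwise size change; two-population
isolation-with-migration, IM; three-population isolation with a unidirectional
admixture pulse, IUA) accept times in the `2 * Ne` units their literature
uses and convert on construction, to keep factor-of-two errors structurally
impossible. Migration direction is named forward in time (donor ->
recipient); backwards in time lineages move recipient -> donor, and an
admixture pulse moves each recipient lineage to the donor with probability
`f`. A population split is an ms-style join: at the event time all lineages
of the derived population move to the ancestral one and migration involving
the absorbed deme ceases.

## ARG sampling and reduction

Genealogies and ARGs are drawn with msprime (discrete genome of length `L`,
haploid sample sets, diploid time scaling); the package's own contribution is
the reduction of each tree sequence to the class-length vector via a
postorder leaf-count sweep per marginal tree, weighted `span/L`. The weight
is written so that a single-tree ARG reproduces the dedicated single-tree
reduction bit-for-bit; with `rho_block = 0` the two code paths agree
draw-for-draw at matched seeds, which is asserted in the tests. The
simulator backend is pluggable in principle: the contract is only "marginal
trees with spans summing to `L`".

A genealogy's *topology signature* is the set of classes with positive
length. For a folded (2,2) sample this distinguishes congruent genealogies
(no mixed-pair branch, no shared polymorphisms possible) from incongruent
ones; the configuration space on a single genealogy is obtained by exact
enumeration of coalescent merge sequences (memoized on the lineage-class
multiset) and excludes, e.g., configurations containing both a shared
polymorphism and a fixed difference — hence 396 configurations at
`k_max = 4` instead of the unconstrained `6^4 = 1296`.

## Optimization

Likelihood evaluations are Monte-Carlo noisy, so the search is derivative
free and two-stage: replicate differential-evolution global searches inside
broad bounds, then replicate Nelder-Mead refinements inside a box spanning
the global bests expanded by 25% of the spanned range per side (log space
for positive parameters). Positive-bounded parameters are searched in log
space; signed growth rates linearly. Infeasible points — bound violations or
ordering constraints such as "admixture precedes the split" (`T_2 < T`) —
return a sentinel objective value, so the optimizer routes around them; an
all-infeasible stage raises with the binding constraint named. Within a
local replicate the same random draws can be reused across evaluations
(common random numbers), which turns the surface deterministic and lets the
simplex converge cleanly; fresh draws per evaluation are the default
elsewhere. The reference schedule is 10 global replicates at 5e4 ARGs per
evaluation, 20 local replicates at 5e5, and a final re-evaluation of the
incumbent at 1e6; a single scale factor shrinks the whole schedule for
desk-scale work. Stopping tolerances default to relative parameter movement
below 1e-3 and log-likelihood movement below 0.5 per simplex cycle, both
configurable. An upper bound for size parameters can be seeded from
Watterson's theta of the table via a helper; it is never applied silently.

## Synthetic data

The generator simulates blockwise data under the full ARG with mutations
placed by a Poisson process under infinite sites (binary alleles, continuous
positions — exact infinite sites; integer discretization would only matter
for VCF export, which the generator does not do). Two linkage regimes:
independent blocks (the regime the composite likelihood assumes), and long
contiguous stretches cut into consecutive blocks, reproducing the
between-block correlation the likelihood ignores — the conservative regime
for bootstrap confidence intervals (reference protocol: 0.5-Mb stretches of
2-kb blocks, 100 replicates; desk versions scale `num_blocks` down). For
unlinked blocks a fast exact-equivalent path draws the per-class Poisson
counts directly conditional on each block's ARG instead of materializing
genotypes; a test checks the two routes agree in distribution. What the
generator does *not* emulate: rate heterogeneity along the genome, gene
conversion (conversion tracts crossing block boundaries masquerade as
crossovers and bias `r` upward for short blocks), selection, sequencing
error, and real missingness patterns — so passing recovery tests demonstrate
statistical correctness of the machinery under the model, not robustness to
those features.

The parametric bootstrap re-simulates datasets at the fitted point and
re-estimates each with a local-only search inside the boundaries used for
the original analysis, reporting per-parameter SDs and MCLE +/- 2 SD
intervals (sample SD, `n-1` denominator). The misspecification driver
cross-fits lists of true and fitted models and also evaluates point
log-likelihoods of fixed alternatives (e.g. the truth, or variants with the
split time replaced by the admixture time).

## Numerical choices

* Per-ARG configuration probabilities are computed by a vectorized Poisson
  pmf recurrence over (draws x classes), chunked at 512 draws to bound
  memory; the Monte-Carlo average uses numpy pairwise summation. Linear
  space is adequate because observed configurations have small counts; the
  zero-rate conventions make degenerate inputs exact.
* Configurations observed in data but assigned zero mass by all `M` ARGs are
  floored at `1/(10 M)` (configurable) and counted in the result, so the
  optimizer sees a strong finite penalty instead of `-inf`; results flag
  whenever the floor was touched.
* Event times bound out of order by a parameter proposal are classified as
  infeasible (sentinel), not as errors; structural defects of a template
  raise.
* All randomness flows from integer seeds through numpy `SeedSequence`
  spawning; simulator seeds are folded into `[1, 2^32)`. Every search and
  bootstrap records its seeds, budgets and bounds in its trace.

## Desk-scale test sizes

The test suite exercises the full protocol at reduced Monte-Carlo sizes
chosen as the package's own desk-scale defaults: the recovery study uses
2e4 unlinked 2-kb blocks of a (2,2) sample under the three-size split model
(ancestral size 1,400; daughter sizes 22,000 and 8,600; split at 2.5 in
4*N_A generations; mu = r = 2e-8), a schedule of 2 global replicates at
`M = 100` plus 3 local replicates at `M = 400`, and a 20-replicate bootstrap
at `M = 200`. Convergence checks run at `M = 1e4` against closed forms (the
geometric blockwise spectrum for a pair of genomes) and at 1e5 genealogy
draws for topology-class probabilities under the IM history.

## Known limitations

* One genome-wide `mu` and `r`; no per-block rates, no gene conversion, no
  selection.
* The model requires a single ancestry root (island models without a final
  join parse from ms strings but cannot be simulated).
* Composite likelihoods are overconfident by construction; always report
  bootstrap rather than curvature-based intervals.
* Replicate searches run serially; traces are seed-deterministic, so
  parallelizing replicates externally does not change results.
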