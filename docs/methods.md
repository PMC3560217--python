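# Methods

## Data model

A dataset is T pools; pool t holds N_t diploid individuals (2N_t
chromosomes) typed at L diallelic loci, alleles coded 0/1. The observation
per pool is the *pool genotype* α_t: at each locus, the count of allele 1
among the 2N_t chromosomes, an integer in [0, 2N_t] or missing. Missing is
a dedicated sentinel, never 0. Haplotypes are bit-packed integers with the
first locus in the most significant bit, so integer order equals
lexicographic order of the usual 0/1-string rendering; multisets of
haplotypes are kept as sorted tuples, giving every pool solution a
canonical, hashable form.

The model assumes random mating (haplotype counts multinomial in the
population frequencies θ), exact allele counts up to the explicit noise
model, and pools small enough (N ≤ 4 structurally, 2–3 in practice) that
the consistent-multiset space per short block is enumerable. Per-individual
phase is a latent variable only; the estimand is θ.

## Enumeration

A pool solution is any multiset of 2N haplotypes whose per-locus sums equal
the observed counts at non-missing loci. Missing loci are simply
unconstrained, which equals the union over all possible calls of that locus
of the constrained solution sets. Enumeration recurses over haplotypes in
ascending order, choosing multiplicities and pruning on remaining
column-sum feasibility (each remaining sum must lie in [0, chromosomes
left]); output is deduplicated by construction and sorted. A cap (default
100 000 solutions per pool) guards against wide blocks with missing data,
where the solution count explodes; exceeding it is an error rather than a
silent truncation. The universe Z is the union of all pools' solution
haplotypes and is *not* pruned of haplotypes supported only by noisy pools
— Z is defined by consistency alone.

## Sequential estimator

With a Dirichlet prior over θ, conditioning on a concrete phasing of pools
1…t keeps the posterior Dirichlet; its parameter vector ρ(t) (prior
pseudo-counts plus assigned-haplotype counts) is the stream's sufficient
statistic. The engine therefore carries, per stream, only the assignment
history, log-weight, and ρ.

Extension weights multiply the parent weight by
∏_j ρ_{h_j}(t−1) / (Σ ρ(t−1))^{2N_t}: every chromosome of the incoming pool
is scored against the statistics *before* that pool; no within-pool
updating occurs during scoring. This is a product of prior means, not the
exact multiset predictive; the exact Dirichlet-multinomial variant
(rising factorials ρ(ρ+1)… in numerator and denominator) is available via
`EngineConfig(exact_predictive=True)` and is validated against its own
exhaustive oracle, but the product-of-means rule is the default scoring.

Selection keeps the min(K, #distinct) highest-weighted distinct histories,
ties broken by the canonical lexicographic order of the history, and
renormalizes weights to sum to one — fully deterministic, so repeated runs
are bit-identical. Since surviving parents are distinct and each extension
appends a distinct solution, candidate histories are automatically
distinct; the public `select_streams` nevertheless merges duplicates, for
use on externally constructed stream sets. Weights live in log space;
renormalization makes this invisible at the API. When K is at least the
number of joint histories no truncation occurs and the stream weights equal
the exhaustive sequential posterior (tested to 1e-10 on random tiny
instances).

Defaults: K = 50 streams; prior ρ_m(0) = 1/M uniformly over the current
universe (total mass 1), so a handful of pools dominates the prior. The
per-haplotype scalar can be overridden (`prior_rho`), and known haplotypes
from an external panel can be injected as extra pseudo-counts
(`prior_counts`). Pools are processed in input order; no reordering
heuristic is applied.

The point estimate aggregates **all** retained streams by weighted
posterior mean, θ̂_m = Σ_k w^(k) ρ_m^(k)/Σ_j ρ_j^(k), i.e. the full
particle approximation of the posterior rather than the single best stream;
on tiny instances this equals the exact posterior mean.

Conservation: each stream's statistics carry an integer count of absorbed
chromosomes on which Σ_t 2N_t conservation is exact; the float total
mirrors it and is asserted to 1e-9 on every run (float addition cannot
promise bit-exactness when the prior total is not a dyadic rational).

## Partition–ligation

Loci are partitioned into ⌊L/b⌋ blocks of b = 4 consecutive SNPs plus a
remainder block (4 keeps per-block solution counts manageable; 5-SNP blocks
can admit thousands of solutions, especially with missing data). Each block
is phased with the engine; per pool, the solutions occurring in any of the
final top-K streams are retained. Two adjacent blocks are ligated by
forming, per pool, every concatenation of a retained left solution with a
permutation of a retained right solution (the chromosome pairing across the
boundary is latent, so all pairings are examined, then deduplicated), and
re-running the engine on the merged span with a freshly rebuilt universe.
The universe is rebuilt per ligation unit rather than fixed globally: the
merged-span universe is exactly the haplotypes occurring in merged
candidates.

Merge order is greedy minimum entropy: each adjacent pair's trial ligation
is scored by the Shannon entropy −Σ θ̂ ln θ̂ of its merged frequency
estimate, the lowest-entropy pair is committed (leftmost on ties), and
trials are cached so the committed pair's run is reused. Entropy over the
estimated frequency distribution (rather than over per-pool solution
multiplicities) was chosen as the functional: it directly expresses "most
homogeneous merged region first", is cheap given the cached engine run, and
reduces to 0 for monomorphic merges. Trial ligations use the full K. The
loop performs exactly (#blocks − 1) merges. When no truncation occurs
anywhere (K exhaustive), splitting then ligating reproduces the
single-block posterior exactly, which is tested.

## Simulator

Each pool draws 2N haplotypes i.i.d. from a specified truth distribution;
counts are column sums. Both the *specified* (gold) and the *realized*
(empirical over all 2NT drawn chromosomes) distributions are returned:
evaluation defaults to the realized frequencies — the pool content an
estimator could at best recover — with the specified truth reported
alongside, as is the realized-vs-specified χ² (the sampling-noise floor).

Noise is applied on the frequency scale: per non-missing cell,
f' = clip(f + x, 0, 1) with x ~ N(0, σ²), re-discretized to
round(f'·2N) (halves away from zero) clipped to [0, 2N]. For pools of two
individuals the allowable frequencies are spaced 0.25 apart, so an interior
cell flips only when |x| exceeds 0.125, giving the closed-form flip rate
2Φ(−0.125/σ) that the tests check empirically. Whether noise is
conceptually added before or after count conversion is immaterial under
this frequency-space definition. Masking sets each pool×locus cell to
missing independently with the given rate.

Sampling, noise and masking consume independent substreams spawned from the
single seed, so toggling noise or masking never changes the underlying
pools — this makes noise/missing comparisons paired by construction. All
outputs are bit-identical under a fixed seed.

The bundled truth tables are `jain3` (3 SNPs, 4 haplotypes; the printed
frequencies sum to 0.996 and are renormalized with a logged warning) and
`agt10` (10 SNPs of the AGT gene, 11 haplotypes, the major one at 0.507).
The simulator emulates i.i.d. draws from a fixed haplotype distribution; it
does not model linkage to unobserved loci, genotyping batch effects,
population structure, or correlated (non-Gaussian) measurement error, so
passing tests demonstrate correct recovery under the stated sampling model,
not robustness to every failure mode of real pooled assays.

## Evaluation harness

χ²(f, g) = Σ (fᵢ − gᵢ)²/gᵢ over the gold haplotypes (which must have
strictly positive frequency); gold haplotypes absent from the estimate
enter with f = 0, and estimated haplotypes outside the gold support add no
term — they are penalized through the mass they drain from gold haplotypes.
`run_experiment` repeats simulate → estimate → score with per-replicate
seeds derived from a master seed and records both χ² variants plus the
sampling floor, making summaries reproducible bit-exactly.

Experiment defaults use 20 replicates per configuration and pool counts
T ∈ {50, 150}; these are the package's desk-scale choices for routine
verification, and the replicate count is configurable.

## Known limitations

- The engine is order-dependent (a greedy deterministic sampler): pool
  order can change the estimate slightly. Tests check that accuracy, not
  the exact estimate, is stable across orderings.
- Enumeration-based phasing does not extend to large pools (tens of
  individuals); normal-approximation methods serve that regime.
- With K = 1 the method degenerates to a greedy phaser; very small K with
  highly ambiguous pools can prune the true phasing irrecoverably.
- The minimum-entropy ligation order costs O(B²) trial engine runs over the
  whole schedule; at the supported scales this is negligible, but very
  large L with many candidate solutions would warrant reduced-K trials.
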