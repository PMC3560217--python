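"""Enumeration of haplotype multisets consistent with a pool genotype.

For a pool of N individuals typed at L loci, a *solution* is any multiset of
2N binary haplotypes whose per-locus allele-1 sums equal the observed counts
at every non-missing locus. Missing loci are unconstrained: any column sum in
[0, 2N] is admissible there, which is exactly the union over all possible
calls of that locus. The solution set psi_t per pool, and their union Z (the
haplotype universe), feed the sequential estimator.

Enumeration recurses over haplotypes in ascending bit-packed order choosing a
multiplicity for each, pruning on remaining-column-sum feasibility; it is
exact and deterministic, and capped because blocks wider than 4 loci (or
missing data) can blow the solution count up combinatorially.
"""

from __future__ import annotations

import logging

from .model import (
    MISSING,
    DataError,
    EnumerationCapError,
    HaplotypeUniverse,
    PoolDataset,
    PoolGenotype,
    PoolSolution,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MAX_ENUM_LOCI",
    "MAX_ENUM_POOL_SIZE",
    "DEFAULT_SOLUTION_CAP",
    "enumerate_pool_solutions",
    "enumerate_dataset",
    "build_universe",
    "universe_from_solutions",
]

#: Hard structural bounds: enumeration is only ever invoked on short blocks
#: (partition keeps blocks to <= 4 loci) and small pools (the method targets
#: pools of 2-3 individuals).
MAX_ENUM_LOCI = 8
MAX_ENUM_POOL_SIZE = 4

#: Default cap on solutions per pool; wide blocks with missing data can
#: produce thousands of solutions, and beyond this the instance is hopeless.
DEFAULT_SOLUTION_CAP = 100_000


def enumerate_pool_solutions(
    pool: PoolGenotype, max_solutions: int = DEFAULT_SOLUTION_CAP
) -> list[PoolSolution]:
    """All haplotype multisets consistent with one pool genotype.

    Returns every distinct multiset of 2N bit-packed haplotypes whose column
    sums equal ``pool.counts`` at non-missing loci, as canonical sorted
    tuples, in lexicographic order. Raises :class:`EnumerationCapError` when
    more than ``max_solutions`` exist.
    """
    L = pool.n_loci
    if L > MAX_ENUM_LOCI:
        raise DataError(
            f"enumeration supports at most {MAX_ENUM_LOCI} loci per block, got {L}"
        )
    if pool.pool_size > MAX_ENUM_POOL_SIZE:
        raise DataError(
            f"enumeration supports pools of at most {MAX_ENUM_POOL_SIZE} "
            f"individuals, got {pool.pool_size}"
        )
    n_chrom = pool.n_chromosomes
    for j, c in enumerate(pool.counts):
        if c != MISSING and not (0 <= c <= n_chrom):
            raise DataError(
                f"count {c} out of range [0, 2N={n_chrom}] at pool "
                f"{pool.pool_id or '?'}, locus index {j}"
            )

    # Remaining required column sums; missing loci carry no constraint.
    observed = [j for j, c in enumerate(pool.counts) if c != MISSING]
    remaining = {j: pool.counts[j] for j in observed}
    n_haps = 1 << L
    # bit of haplotype z at locus j (locus 0 = most significant bit)
    bit = [[(z >> (L - 1 - j)) & 1 for j in range(L)] for z in range(n_haps)]

    out: list[PoolSolution] = []
    prefix: list[int] = []

    def recurse(z: int, n_rem: int) -> None:
        if n_rem == 0:
            if all(remaining[j] == 0 for j in observed):
                if len(out) >= max_solutions:
                    raise EnumerationCapError(
                        f"pool {pool.pool_id or '?'} admits more than "
                        f"{max_solutions} candidate solutions"
                    )
                out.append(tuple(prefix))
            return
        if z >= n_haps:
            return
        zbits = bit[z]
        # max copies of z: bounded by chromosomes left and, at each observed
        # locus where z carries allele 1, by the count still needed there
        c_max = n_rem
        for j in observed:
            if zbits[j] and remaining[j] < c_max:
                c_max = remaining[j]
        for c in range(c_max, -1, -1):
            feasible = True
            for j in observed:
                r = remaining[j] - c * zbits[j]
                if r < 0 or r > n_rem - c:
                    feasible = False
                    break
            if not feasible:
                continue
            for j in observed:
                remaining[j] -= c * zbits[j]
            prefix.extend([z] * c)
            recurse(z + 1, n_rem - c)
            del prefix[len(prefix) - c :]
            for j in observed:
                remaining[j] += c * zbits[j]

    recurse(0, n_chrom)
    out.sort()
    return out


def enumerate_dataset(
    dataset: PoolDataset, max_solutions: int = DEFAULT_SOLUTION_CAP
) -> list[list[PoolSolution]]:
    """Per-pool solution sets psi_t for every pool of the dataset."""
    solutions = []
    for t, pool in enumerate(dataset.pools):
        sols = enumerate_pool_solutions(pool, max_solutions)
        if not sols:  # cannot happen for valid counts, kept as a guard
            raise DataError(
                f"pool {pool.pool_id or t} has no consistent phasing"
            )
        solutions.append(sols)
    return solutions


def universe_from_solutions(
    solutions_per_pool: list[list[PoolSolution]], n_loci: int
) -> HaplotypeUniverse:
    """Union of all haplotypes occurring in any solution of any pool."""
    haps: set[int] = set()
    for sols in solutions_per_pool:
        for sol in sols:
            haps.update(sol)
    return HaplotypeUniverse(tuple(haps), n_loci)


def build_universe(
    dataset: PoolDataset, max_solutions: int = DEFAULT_SOLUTION_CAP
) -> HaplotypeUniverse:
    """The compatible-haplotype universe Z = union of psi_t over all pools."""
    solutions = enumerate_dataset(dataset, max_solutions)
    universe = universe_from_solutions(solutions, dataset.n_loci)
    logger.debug(
        "universe over %d loci: %d haplotypes from %d pools",
        dataset.n_loci,
        len(universe),
        dataset.n_pools,
    )
    return universe
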