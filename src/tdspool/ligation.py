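"""Partition-ligation: scaling the sequential engine to many loci.

Candidate enumeration is exponential in block width, so long haplotype
vectors are handled divide-and-conquer: loci are partitioned into blocks of
at most four consecutive SNPs, each block is phased with the engine, and
blocks are then merged pairwise. Ligating two adjacent blocks builds, per
pool, every concatenation of a retained left solution with a permutation of
a retained right solution (the chromosome pairing across the block boundary
is unknown, so all pairings are examined), and reruns the engine on the
merged candidates over a freshly built merged-span universe.

Merges are greedy in minimum-entropy order: at each step the adjacent pair
whose trial ligation yields the lowest Shannon entropy of estimated
haplotype frequencies is committed (leftmost on ties), so the most
homogeneous — most certain — regions are resolved first. Trial ligations are
cached and the chosen one is reused, not recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

from .model import (
    DataError,
    EnumerationCapError,
    FrequencyEstimate,
    HaplotypeUniverse,
    PoolDataset,
    PoolSolution,
    SolutionStream,
)
from .engine import EngineConfig, estimate_frequencies, run_tds
from .enumeration import (
    DEFAULT_SOLUTION_CAP,
    enumerate_dataset,
    universe_from_solutions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "partition_blocks",
    "phase_block",
    "merge_pool_solutions",
    "ligate_pair",
    "ligation_entropy",
    "run_full",
]

DEFAULT_BLOCK_SIZE = 4


@dataclass
class Block:
    """A phased locus span: retained per-pool solutions plus the engine state.

    ``per_pool_solutions[t]`` is the set of solutions for pool t that occur
    in at least one of the final top-K streams of this span's engine run.
    ``streams``, ``universe`` and ``estimate`` cache that run so entropy
    scoring and the final read-out need no recomputation.
    """

    span: tuple[int, int]
    per_pool_solutions: list[tuple[PoolSolution, ...]]
    streams: list[SolutionStream]
    universe: HaplotypeUniverse
    estimate: FrequencyEstimate

    @property
    def width(self) -> int:
        return self.span[1] - self.span[0]


def partition_blocks(
    n_loci: int, block_size: int = DEFAULT_BLOCK_SIZE
) -> list[tuple[int, int]]:
    """Split loci into floor(L/b) blocks of b consecutive loci plus a
    remainder block; spans are half-open, disjoint, ordered and covering."""
    if n_loci < 1:
        raise DataError(f"need at least one locus, got {n_loci}")
    if block_size < 2:
        raise DataError(f"block size must be >= 2, got {block_size}")
    spans = [
        (start, min(start + block_size, n_loci))
        for start in range(0, n_loci, block_size)
    ]
    return spans


def _run_span(
    dataset: PoolDataset,
    span: tuple[int, int],
    solutions: list[list[PoolSolution]],
    universe: HaplotypeUniverse,
    config: EngineConfig,
) -> Block:
    streams = run_tds(dataset.pools, solutions, universe, config)
    retained: list[tuple[PoolSolution, ...]] = []
    for t in range(dataset.n_pools):
        used = {s.assignments[t] for s in streams}
        retained.append(tuple(sorted(used)))
    estimate = estimate_frequencies(streams, universe)
    return Block(span, retained, streams, universe, estimate)


def phase_block(
    dataset: PoolDataset,
    span: tuple[int, int],
    config: EngineConfig,
    max_solutions: int = DEFAULT_SOLUTION_CAP,
) -> Block:
    """Phase one locus span with the engine; retain the solutions that
    appear in the final top-K streams."""
    start, stop = span
    sub = dataset.restrict(start, stop)
    solutions = enumerate_dataset(sub, max_solutions)
    universe = universe_from_solutions(solutions, sub.n_loci)
    logger.info(
        "phasing block [%d, %d): universe %d haplotypes, "
        "candidate solutions per pool max %d",
        start,
        stop,
        len(universe),
        max(len(s) for s in solutions),
    )
    return _run_span(sub, span, solutions, universe, config)


def merge_pool_solutions(
    left: PoolSolution, right: PoolSolution, right_width: int
) -> list[PoolSolution]:
    """All distinct full-span multisets pairing left and right haplotypes.

    The chromosome correspondence across the block boundary is latent, so
    every pairing of the 2N left haplotypes with a permutation of the 2N
    right haplotypes is formed; duplicates collapse (repeated haplotypes on
    either side make many pairings coincide). Deterministic sorted output.
    """
    if len(left) != len(right):
        raise DataError(
            f"cannot merge solutions of cardinality {len(left)} and {len(right)}"
        )
    merged = {
        tuple(sorted((l << right_width) | r for l, r in zip(left, perm)))
        for perm in set(permutations(right))
    }
    return sorted(merged)


def ligate_pair(
    block_a: Block,
    block_b: Block,
    dataset: PoolDataset,
    config: EngineConfig,
    max_solutions: int = DEFAULT_SOLUTION_CAP,
) -> Block:
    """Merge two genome-adjacent phased blocks into one.

    Per pool, the merged candidate set is the union of all pairings of every
    retained left solution with every retained right solution; the engine is
    then rerun on the merged span with a rebuilt universe.
    """
    if block_a.span[1] != block_b.span[0]:
        raise DataError(
            f"blocks {block_a.span} and {block_b.span} are not adjacent"
        )
    span = (block_a.span[0], block_b.span[1])
    right_width = block_b.width
    merged_solutions: list[list[PoolSolution]] = []
    for t in range(dataset.n_pools):
        cands: set[PoolSolution] = set()
        for sol_a in block_a.per_pool_solutions[t]:
            for sol_b in block_b.per_pool_solutions[t]:
                cands.update(merge_pool_solutions(sol_a, sol_b, right_width))
        if len(cands) > max_solutions:
            raise EnumerationCapError(
                f"pool {dataset.pools[t].pool_id or t}: {len(cands)} merged "
                f"candidates exceed the cap {max_solutions}; raise the cap or "
                f"lower the number of streams"
            )
        merged_solutions.append(sorted(cands))
    universe = universe_from_solutions(merged_solutions, span[1] - span[0])
    sub = dataset.restrict(*span)
    logger.info(
        "ligating [%d, %d) + [%d, %d): universe %d, max candidates %d",
        *block_a.span,
        *block_b.span,
        len(universe),
        max(len(s) for s in merged_solutions),
    )
    return _run_span(sub, span, merged_solutions, universe, config)


def ligation_entropy(
    block_a: Block,
    block_b: Block,
    dataset: PoolDataset,
    config: EngineConfig,
    max_solutions: int = DEFAULT_SOLUTION_CAP,
) -> float:
    """Shannon entropy (nats) of the frequency estimate a trial ligation of
    the pair would produce; lower means a more homogeneous merged region."""
    return ligate_pair(block_a, block_b, dataset, config, max_solutions).estimate.entropy()


def run_full(
    dataset: PoolDataset,
    config: EngineConfig | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    max_solutions: int = DEFAULT_SOLUTION_CAP,
) -> FrequencyEstimate:
    """End-to-end estimate: partition, phase blocks, ligate to one block.

    Greedy minimum-entropy ligation order with leftmost tie-break; performs
    exactly (initial blocks - 1) merges. For L <= block_size this reduces to
    a single engine run.
    """
    if config is None:
        config = EngineConfig()
    spans = partition_blocks(dataset.n_loci, block_size)
    logger.info("partition of %d loci: %s", dataset.n_loci, spans)
    blocks = [phase_block(dataset, span, config, max_solutions) for span in spans]

    trials: dict[tuple[int, int], Block] = {}
    while len(blocks) > 1:
        entropies = []
        for i in range(len(blocks) - 1):
            key = (id(blocks[i]), id(blocks[i + 1]))
            if key not in trials:
                trials[key] = ligate_pair(
                    blocks[i], blocks[i + 1], dataset, config, max_solutions
                )
            entropies.append(trials[key].estimate.entropy())
        best = min(range(len(entropies)), key=lambda i: (entropies[i], i))
        logger.info(
            "ligation entropies %s -> merging pair %d (spans %s + %s)",
            [f"{e:.4f}" for e in entropies],
            best,
            blocks[best].span,
            blocks[best + 1].span,
        )
        merged = trials[(id(blocks[best]), id(blocks[best + 1]))]
        blocks[best : best + 2] = [merged]

    return blocks[0].estimate
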