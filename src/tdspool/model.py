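"""Core data model for pooled-DNA haplotype frequency estimation.

Haplotypes over L diallelic loci are bit-packed integers: the allele at the
first locus occupies the most significant of the L bits, so integer order
coincides with lexicographic order of the "0101..." string rendering. A pool
of N diploid individuals contributes 2N chromosomes; its observed *pool
genotype* is, per locus, the count of allele "1" among those 2N chromosomes
(an integer in [0, 2N], or missing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: Sentinel for a missing (un-called) allele count. Distinct from every valid
#: count; never use 0 to mean "missing".
MISSING: int = -1

__all__ = [
    "MISSING",
    "DataError",
    "InconsistentDataError",
    "EnumerationCapError",
    "Haplotype",
    "PoolSolution",
    "hap_to_str",
    "hap_from_str",
    "canonicalize_solution",
    "solution_column_sums",
    "PoolGenotype",
    "PoolDataset",
    "HaplotypeUniverse",
    "SufficientStatistics",
    "SolutionStream",
    "FrequencyEstimate",
]


class DataError(ValueError):
    """Malformed or out-of-range input data."""


class InconsistentDataError(RuntimeError):
    """No haplotype configuration can explain the observed pool genotypes."""


class EnumerationCapError(RuntimeError):
    """A pool genotype admits more candidate solutions than the configured cap."""


# A haplotype is a bit-packed int; a pool solution is the canonical (sorted)
# tuple of the 2N haplotypes assigned to one pool.
Haplotype = int
PoolSolution = tuple[int, ...]


def hap_to_str(hap: Haplotype, n_loci: int) -> str:
    """Render a bit-packed haplotype as a '0101...' string (first locus leftmost)."""
    if hap < 0 or hap >= (1 << n_loci):
        raise DataError(f"haplotype {hap} does not fit in {n_loci} loci")
    return format(hap, f"0{n_loci}b")


def hap_from_str(s: str) -> Haplotype:
    """Parse a '0101...' allele string into a bit-packed haplotype."""
    if not s or any(c not in "01" for c in s):
        raise DataError(f"invalid haplotype string {s!r}: must be non-empty 0/1")
    return int(s, 2)


def canonicalize_solution(
    haplotypes: Iterable[Haplotype | str], n_loci: int | None = None
) -> PoolSolution:
    """Return a haplotype multiset in canonical (sorted ascending) order.

    Accepts bit-packed ints or '01' strings (not mixed meaningfully —
    strings are parsed first). String inputs must share a single length,
    matching ``n_loci`` when given; a length mismatch is a structural error.
    Canonicalization is idempotent and insensitive to input order, so two
    equal multisets always compare equal as tuples.
    """
    packed: list[int] = []
    for h in haplotypes:
        if isinstance(h, str):
            if n_loci is None:
                n_loci = len(h)
            elif len(h) != n_loci:
                raise DataError(
                    f"mixed haplotype lengths: {h!r} has {len(h)} loci, expected {n_loci}"
                )
            packed.append(hap_from_str(h))
        else:
            if h < 0:
                raise DataError(f"negative haplotype code {h}")
            if n_loci is not None and h >= (1 << n_loci):
                raise DataError(f"haplotype {h} does not fit in {n_loci} loci")
            packed.append(int(h))
    return tuple(sorted(packed))


def solution_column_sums(solution: PoolSolution, n_loci: int) -> np.ndarray:
    """Per-locus allele-1 counts of a haplotype multiset (locus 0 first)."""
    sums = np.zeros(n_loci, dtype=np.int64)
    for h in solution:
        for j in range(n_loci):
            sums[j] += (h >> (n_loci - 1 - j)) & 1
    return sums


@dataclass(frozen=True)
class PoolGenotype:
    """One pool's size and per-locus allele-1 counts (``MISSING`` allowed).

    Parameters
    ----------
    pool_size
        Number of diploid individuals N in the pool (2N chromosomes).
    counts
        Length-L sequence of allele-1 counts, each in [0, 2N] or ``MISSING``.
    pool_id
        Optional label used in diagnostics.
    """

    pool_size: int
    counts: tuple[int, ...]
    pool_id: str = ""

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise DataError(f"pool size must be >= 1, got {self.pool_size}")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.counts) == 0:
            raise DataError("pool genotype must cover at least one locus")
        for j, c in enumerate(self.counts):
            if c != MISSING and not (0 <= c <= 2 * self.pool_size):
                label = self.pool_id or "?"
                raise DataError(
                    f"count {c} out of range [0, 2N={2 * self.pool_size}] "
                    f"at pool {label}, locus index {j}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.counts)

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.pool_size

    def restrict(self, start: int, stop: int) -> "PoolGenotype":
        """Pool genotype over the half-open locus span [start, stop)."""
        return PoolGenotype(self.pool_size, self.counts[start:stop], self.pool_id)

    def is_consistent(self, solution: PoolSolution) -> bool:
        """Exact-consistency indicator: per-locus sums match all non-missing counts."""
        if len(solution) != self.n_chromosomes:
            return False
        sums = solution_column_sums(solution, self.n_loci)
        return all(
            c == MISSING or c == s for c, s in zip(self.counts, sums)
        )


@dataclass
class PoolDataset:
    """An ordered collection of pools typed on a shared set of loci."""

    pools: list[PoolGenotype]
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pools:
            raise DataError("dataset contains no pools")
        L = self.pools[0].n_loci
        for p in self.pools:
            if p.n_loci != L:
                raise DataError(
                    f"pool {p.pool_id or '?'} has {p.n_loci} loci, expected {L}"
                )
        if not self.locus_ids:
            self.locus_ids = [f"L{j + 1}" for j in range(L)]
        elif len(self.locus_ids) != L:
            raise DataError(
                f"{len(self.locus_ids)} locus ids for {L} loci"
            )

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_loci(self) -> int:
        return self.pools[0].n_loci

    def restrict(self, start: int, stop: int) -> "PoolDataset":
        return PoolDataset(
            [p.restrict(start, stop) for p in self.pools],
            self.locus_ids[start:stop],
        )


@dataclass(frozen=True)
class HaplotypeUniverse:
    """The set Z of haplotypes consistent with at least one pool genotype.

    Haplotypes are stored sorted (lexicographic) with a bidirectional
    haplotype <-> dense-index mapping used by the sufficient statistics.
    """

    haplotypes: tuple[Haplotype, ...]
    n_loci: int
    _index: dict[int, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        haps = tuple(sorted(set(self.haplotypes)))
        object.__setattr__(self, "haplotypes", haps)
        object.__setattr__(self, "_index", {h: m for m, h in enumerate(haps)})

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __contains__(self, hap: Haplotype) -> bool:
        return hap in self._index

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self.haplotypes)

    def index_of(self, hap: Haplotype) -> int:
        try:
            return self._index[hap]
        except KeyError:
            raise KeyError(
                f"haplotype {hap_to_str(hap, self.n_loci)} not in universe"
            ) from None

    def indices(self, solution: PoolSolution) -> np.ndarray:
        return np.array([self.index_of(h) for h in solution], dtype=np.int64)

    def labels(self) -> list[str]:
        return [hap_to_str(h, self.n_loci) for h in self.haplotypes]


@dataclass
class SufficientStatistics:
    """Dirichlet parameters rho over the universe, with an exactly-tracked total.

    The posterior over population haplotype frequencies after any number of
    pools is Dirichlet; ``rho`` holds its parameters (prior pseudo-counts plus
    observed haplotype counts). ``data_count`` counts the absorbed
    chromosomes as an exact integer, so the conservation identity
    ``data_count(t) == sum of 2N over processed pools`` holds with no float
    summation error; ``total`` mirrors it in float for the Dirichlet mean.
    """

    rho: np.ndarray
    total: float = None  # type: ignore[assignment]
    data_count: int = 0

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)
        if self.rho.ndim != 1 or len(self.rho) == 0:
            raise DataError("rho must be a non-empty 1-D vector")
        if np.any(self.rho <= 0):
            raise DataError("all Dirichlet parameters must be positive")
        if self.total is None:
            self.total = float(self.rho.sum())

    def updated(self, indices: np.ndarray) -> "SufficientStatistics":
        """Posterior update: add one count per assigned chromosome."""
        rho = self.rho.copy()
        np.add.at(rho, indices, 1.0)
        return SufficientStatistics(
            rho, self.total + float(len(indices)), self.data_count + len(indices)
        )

    def mean(self) -> np.ndarray:
        """Posterior mean of the haplotype frequencies, E[theta_m] = rho_m / total."""
        return self.rho / self.total


@dataclass
class SolutionStream:
    """One candidate joint phasing of all processed pools (a "particle").

    Carries the per-pool haplotype assignments, an importance weight stored in
    log space (underflow-safe for long pool sequences), and the Dirichlet
    sufficient statistics implied by prior + assignments.
    """

    assignments: tuple[PoolSolution, ...]
    log_weight: float
    stats: SufficientStatistics

    @property
    def weight(self) -> float:
        return math.exp(self.log_weight)


class FrequencyEstimate:
    """A haplotype -> probability table over L loci, summing to one.

    Iteration and ``items()`` are in descending-probability order with
    lexicographic tie-break, matching the on-disk table format.
    """

    def __init__(
        self,
        probs: Mapping[Haplotype, float],
        n_loci: int,
        *,
        renormalize: bool = False,
        _tol: float = 1e-9,
    ) -> None:
        if not probs:
            raise DataError("frequency estimate has no entries")
        clean: dict[int, float] = {}
        for h, p in probs.items():
            h = hap_from_str(h) if isinstance(h, str) else int(h)
            if h < 0 or h >= (1 << n_loci):
                raise DataError(f"haplotype {h} does not fit in {n_loci} loci")
            p = float(p)
            if p < 0:
                raise DataError(f"negative probability {p} for haplotype {h}")
            clean[h] = clean.get(h, 0.0) + p
        total = math.fsum(clean.values())
        if total <= 0:
            raise DataError("frequencies sum to zero")
        if renormalize:
            clean = {h: p / total for h, p in clean.items()}
        elif abs(total - 1.0) > _tol:
            raise DataError(f"frequencies sum to {total!r}, not 1")
        self._probs = clean
        self.n_loci = int(n_loci)

    @classmethod
    def from_table(
        cls, table: Mapping[str, float], n_loci: int | None = None
    ) -> "FrequencyEstimate":
        """Build from string-keyed frequencies, renormalizing if needed."""
        keys = list(table)
        if n_loci is None:
            n_loci = len(keys[0])
        return cls(table, n_loci, renormalize=True)

    def __len__(self) -> int:
        return len(self._probs)

    def __contains__(self, hap: Haplotype) -> bool:
        return int(hap) in self._probs

    def __getitem__(self, hap: Haplotype | str) -> float:
        h = hap_from_str(hap) if isinstance(hap, str) else int(hap)
        return self._probs[h]

    def get(self, hap: Haplotype | str, default: float = 0.0) -> float:
        h = hap_from_str(hap) if isinstance(hap, str) else int(hap)
        return self._probs.get(h, default)

    def items(self) -> list[tuple[Haplotype, float]]:
        return sorted(self._probs.items(), key=lambda kv: (-kv[1], kv[0]))

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(h for h, _ in self.items())

    @property
    def haplotypes(self) -> tuple[Haplotype, ...]:
        return tuple(sorted(self._probs))

    def as_dict(self) -> dict[Haplotype, float]:
        return dict(self._probs)

    def labels(self) -> dict[str, float]:
        return {hap_to_str(h, self.n_loci): p for h, p in self.items()}

    def entropy(self) -> float:
        """Shannon entropy -sum p ln p in nats, with 0 ln 0 := 0."""
        return -math.fsum(p * math.log(p) for p in self._probs.values() if p > 0)

    def allele_frequency(self, locus: int) -> float:
        """Marginal frequency of allele 1 at one locus (0-based)."""
        bit = self.n_loci - 1 - locus
        return math.fsum(p for h, p in self._probs.items() if (h >> bit) & 1)

    def __repr__(self) -> str:
        top = ", ".join(
            f"{hap_to_str(h, self.n_loci)}:{p:.4g}" for h, p in self.items()[:4]
        )
        more = "" if len(self) <= 4 else f", ... ({len(self)} total)"
        return f"FrequencyEstimate({top}{more})"
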