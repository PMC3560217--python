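"""Tree-based deterministic sampling engine for pooled haplotype data.

Pools are absorbed one at a time. The estimator maintains up to K *solution
streams* — candidate joint phasings of all pools processed so far, each with
an importance weight and Dirichlet sufficient statistics rho. Processing pool
t extends every stream by every haplotype multiset consistent with that
pool's genotype, scores each extension by the posterior-predictive weight

    w_t ∝ w_{t-1} * prod_j rho_{h_j}(t-1) / (sum_m rho_m(t-1))^{2N_t},

deterministically keeps the K highest-weighted distinct streams, and updates
the survivors' statistics. Because the posterior over frequencies given a
phasing is Dirichlet, each stream is summarized exactly by rho; the final
frequency estimate is the weight-averaged posterior mean across streams.

The weight above multiplies prior means for the 2N_t draws, which ignores the
within-pool updating of a full Dirichlet-multinomial predictive; the exact
rising-factorial predictive is available via ``EngineConfig.exact_predictive``
but is off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (
    DataError,
    FrequencyEstimate,
    HaplotypeUniverse,
    InconsistentDataError,
    PoolGenotype,
    PoolSolution,
    SolutionStream,
    SufficientStatistics,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EngineConfig",
    "prior_statistics",
    "extension_weight",
    "update_statistics",
    "select_streams",
    "run_tds",
    "estimate_frequencies",
]


@dataclass(frozen=True)
class EngineConfig:
    """Tuning knobs of the sequential estimator.

    Parameters
    ----------
    n_streams
        Maximum number K of solution streams retained after each pool
        (default 50).
    prior_mass
        Total Dirichlet prior mass spread uniformly over the current
        haplotype universe when ``prior_rho`` is not given, i.e. each
        haplotype gets ``prior_mass / M`` pseudo-counts. The default of 1
        keeps the prior weak so data dominate quickly.
    prior_rho
        Per-haplotype scalar pseudo-count applied uniformly; overrides
        ``prior_mass`` when set.
    prior_counts
        Optional haplotype -> pseudo-count map added on top of the uniform
        base; this is how externally known haplotypes (e.g. a reference
        panel for the same population) enter as prior information.
    exact_predictive
        Score extensions with the exact Dirichlet-multinomial predictive
        (rising factorials) instead of the product of prior means.
    """

    n_streams: int = 50
    prior_mass: float = 1.0
    prior_rho: float | None = None
    prior_counts: Mapping[int, float] | None = None
    exact_predictive: bool = False

    def __post_init__(self) -> None:
        if self.n_streams < 1:
            raise DataError(f"n_streams must be >= 1, got {self.n_streams}")
        if self.prior_rho is not None and self.prior_rho <= 0:
            raise DataError("prior_rho must be positive")
        if self.prior_rho is None and self.prior_mass <= 0:
            raise DataError("prior_mass must be positive")
        if self.prior_counts is not None and any(
            v < 0 for v in self.prior_counts.values()
        ):
            raise DataError("prior pseudo-counts must be non-negative")


def prior_statistics(
    config: EngineConfig, universe: HaplotypeUniverse
) -> SufficientStatistics:
    """Dirichlet prior rho(0) over the universe implied by the config."""
    M = len(universe)
    base = config.prior_rho if config.prior_rho is not None else config.prior_mass / M
    rho = np.full(M, base, dtype=np.float64)
    if config.prior_counts:
        for hap, extra in config.prior_counts.items():
            if hap in universe:
                rho[universe.index_of(hap)] += float(extra)
    return SufficientStatistics(rho)


def _log_extension_weight(
    rho: np.ndarray, total: float, indices: np.ndarray, exact: bool
) -> float:
    """log of the (un-normalized) predictive score for one pool solution."""
    if not exact:
        return float(np.log(rho[indices]).sum()) - len(indices) * math.log(total)
    # exact Dirichlet-multinomial predictive for the multiset of 2N draws:
    # prod_z rho_z^(c_z rising) / total^(2N rising)
    num = 0.0
    mult: dict[int, int] = {}
    for m in indices.tolist():
        num += math.log(rho[m] + mult.get(m, 0))
        mult[m] = mult.get(m, 0) + 1
    den = math.fsum(math.log(total + i) for i in range(len(indices)))
    return num - den


def extension_weight(
    stream: SolutionStream,
    solution: PoolSolution,
    universe: HaplotypeUniverse,
    exact_predictive: bool = False,
) -> float:
    """Un-normalized weight of extending a stream by one pool solution.

    Implements the sequential weight update: the parent weight times the
    product over the 2N assigned chromosomes of their prior-mean
    probabilities rho_h(t-1) / total(t-1).
    """
    indices = universe.indices(solution)
    return math.exp(
        stream.log_weight
        + _log_extension_weight(
            stream.stats.rho, stream.stats.total, indices, exact_predictive
        )
    )


def update_statistics(
    stats: SufficientStatistics,
    solution: PoolSolution,
    universe: HaplotypeUniverse,
) -> SufficientStatistics:
    """Dirichlet posterior update: one pseudo-count per assigned chromosome."""
    return stats.updated(universe.indices(solution))


def select_streams(
    candidates: Sequence[SolutionStream], n_streams: int
) -> list[SolutionStream]:
    """Keep the highest-weighted distinct streams and renormalize.

    Streams with identical assignment histories are merged (they carry equal
    weights by construction, so one survives). Ties in weight are broken by
    the canonical lexicographic order of the assignment history, making the
    whole procedure deterministic. Surviving weights are renormalized to sum
    to one.
    """
    if not candidates:
        raise DataError("no candidate streams to select from")
    if all(not math.isfinite(c.log_weight) for c in candidates):
        raise InconsistentDataError(
            "all stream weights vanished: no phasing explains the data"
        )
    distinct: dict[tuple, SolutionStream] = {}
    for cand in candidates:
        prev = distinct.get(cand.assignments)
        if prev is None or cand.log_weight > prev.log_weight:
            distinct[cand.assignments] = cand
    ranked = sorted(
        distinct.values(), key=lambda s: (-s.log_weight, s.assignments)
    )[:n_streams]
    log_norm = _logsumexp([s.log_weight for s in ranked])
    return [
        SolutionStream(s.assignments, s.log_weight - log_norm, s.stats)
        for s in ranked
    ]


def _logsumexp(logs: Sequence[float]) -> float:
    m = max(logs)
    if not math.isfinite(m):
        return m
    return m + math.log(math.fsum(math.exp(x - m) for x in logs))


def run_tds(
    pools: Sequence[PoolGenotype],
    solutions_per_pool: Sequence[Sequence[PoolSolution]],
    universe: HaplotypeUniverse,
    config: EngineConfig,
) -> list[SolutionStream]:
    """Run the deterministic-sampling pass over all pools.

    Starts from a single empty stream carrying the prior, absorbs pools in
    input order, and returns the final streams with weights normalized to
    sum to one. Raises when a pool has no consistent solution.
    """
    prior = prior_statistics(config, universe)
    prior_total = prior.total
    K = config.n_streams
    exact = config.exact_predictive

    # Internal stream state: history as per-pool solution indices (solution
    # lists are lexicographically sorted, so index order == canonical order),
    # log weight, rho vector and exact running total.
    histories: list[tuple[int, ...]] = [()]
    log_w = np.zeros(1, dtype=np.float64)
    rhos: list[np.ndarray] = [prior.rho]
    totals: list[float] = [prior.total]

    added = 0
    for t, (pool, sols) in enumerate(zip(pools, solutions_per_pool)):
        if not sols:
            raise InconsistentDataError(
                f"pool {pool.pool_id or t} has no consistent phasing"
            )
        sol_idx = np.array(
            [universe.indices(s) for s in sols], dtype=np.int64
        )  # (S, 2N)
        n_chrom = sol_idx.shape[1]
        # score every (stream, solution) extension against rho(t-1)
        cand: list[tuple[float, tuple[int, ...], int]] = []
        for k, (hist, rho, total) in enumerate(zip(histories, rhos, totals)):
            if exact:
                scores = np.array(
                    [
                        _log_extension_weight(rho, total, sol_idx[i], True)
                        for i in range(len(sols))
                    ]
                )
            else:
                scores = np.log(rho)[sol_idx].sum(axis=1) - n_chrom * math.log(total)
            base = log_w[k]
            for i in range(len(sols)):
                cand.append((base + float(scores[i]), hist + (i,), k))
        # distinct parents extended by distinct solutions are automatically
        # distinct histories; select top K with deterministic tie-break
        cand.sort(key=lambda c: (-c[0], c[1]))
        kept = cand[:K]
        logs = [c[0] for c in kept]
        log_norm = _logsumexp(logs)
        if not math.isfinite(log_norm):
            raise InconsistentDataError(
                f"all stream weights vanished at pool {pool.pool_id or t}"
            )
        new_histories, new_rhos, new_totals = [], [], []
        log_w = np.empty(len(kept))
        for i, (lw, hist, parent) in enumerate(kept):
            rho = rhos[parent].copy()
            np.add.at(rho, sol_idx[hist[-1]], 1.0)
            new_histories.append(hist)
            new_rhos.append(rho)
            new_totals.append(totals[parent] + n_chrom)
            log_w[i] = lw - log_norm
        histories, rhos, totals = new_histories, new_rhos, new_totals
        added += n_chrom
        # conservation of absorbed chromosomes (float mirror of the exact
        # integer data_count attached to the final statistics)
        assert all(abs(tot - prior_total - added) < 1e-6 for tot in totals)
        logger.debug(
            "pool %s: %d solutions, %d candidate extensions, %d streams kept",
            pool.pool_id or t,
            len(sols),
            len(cand),
            len(histories),
        )

    return [
        SolutionStream(
            assignments=tuple(
                solutions_per_pool[t][i] for t, i in enumerate(hist)
            ),
            log_weight=float(log_w[k]),
            stats=SufficientStatistics(rhos[k], totals[k], added),
        )
        for k, hist in enumerate(histories)
    ]


def estimate_frequencies(
    streams: Sequence[SolutionStream], universe: HaplotypeUniverse
) -> FrequencyEstimate:
    """Weight-averaged Dirichlet posterior mean over the retained streams.

    theta_hat_m = sum_k w_k * rho_m^(k) / total^(k); with weights summing to
    one this sums to one (renormalized against float round-off).
    """
    if not streams:
        raise DataError("no streams to estimate from")
    theta = np.zeros(len(universe), dtype=np.float64)
    for s in streams:
        theta += s.weight * s.stats.mean()
    probs = {h: float(theta[m]) for m, h in enumerate(universe.haplotypes)}
    return FrequencyEstimate(probs, universe.n_loci, renormalize=True)
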