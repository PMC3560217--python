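"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package internals: solutions are
enumerated by filtering all multisets of binary-string haplotypes, and the
sequential posterior is computed by exhaustively walking every joint
assignment history.
"""

from __future__ import annotations

import itertools
import math


def all_haplotypes(n_loci: int) -> list[str]:
    return ["".join(bits) for bits in itertools.product("01", repeat=n_loci)]


def brute_force_solutions(
    counts: list[int | None], pool_size: int
) -> list[tuple[str, ...]]:
    """All multisets of 2N binary-string haplotypes whose column sums match
    the non-None counts. Filtering over every combination-with-replacement
    of the full haplotype space."""
    n_loci = len(counts)
    out = []
    for combo in itertools.combinations_with_replacement(
        all_haplotypes(n_loci), 2 * pool_size
    ):
        ok = True
        for j, c in enumerate(counts):
            if c is None:
                continue
            if sum(int(h[j]) for h in combo) != c:
                ok = False
                break
        if ok:
            out.append(tuple(sorted(combo)))
    return sorted(set(out))


def solutions_grouped_by_counts(
    n_loci: int, pool_size: int
) -> dict[tuple[int, ...], list[tuple[str, ...]]]:
    """Map from every achievable count vector to its solution set, built by
    a single pass over all multisets (for exhaustive sweeps)."""
    groups: dict[tuple[int, ...], list[tuple[str, ...]]] = {}
    for combo in itertools.combinations_with_replacement(
        all_haplotypes(n_loci), 2 * pool_size
    ):
        key = tuple(
            sum(int(h[j]) for h in combo) for j in range(n_loci)
        )
        groups.setdefault(key, []).append(tuple(sorted(combo)))
    for key in groups:
        groups[key] = sorted(set(groups[key]))
    return groups


def exhaustive_posterior(
    solutions_per_pool: list[list[tuple[str, ...]]],
    universe: list[str],
    prior: dict[str, float],
    exact_predictive: bool = False,
) -> dict[tuple[int, ...], float]:
    """Exact posterior over joint assignment histories.

    Walks every element of the product of the per-pool solution sets,
    accumulating the sequential predictive weight: at each pool the factor is
    prod_j rho_{h_j} / total^{2N} evaluated at the statistics *before* that
    pool (or the rising-factorial Dirichlet-multinomial predictive when
    ``exact_predictive``). Returns normalized weights keyed by the history
    expressed as per-pool solution indices.
    """
    weights: dict[tuple[int, ...], float] = {}
    for history in itertools.product(
        *[range(len(s)) for s in solutions_per_pool]
    ):
        rho = dict(prior)
        logw = 0.0
        for t, i in enumerate(history):
            sol = solutions_per_pool[t][i]
            total = math.fsum(rho.values())
            if exact_predictive:
                seen: dict[str, int] = {}
                for h in sol:
                    logw += math.log(rho[h] + seen.get(h, 0))
                    seen[h] = seen.get(h, 0) + 1
                for i2 in range(len(sol)):
                    logw -= math.log(total + i2)
            else:
                for h in sol:
                    logw += math.log(rho[h]) - math.log(total)
            for h in sol:
                rho[h] += 1.0
        weights[history] = math.exp(logw)
    norm = math.fsum(weights.values())
    return {k: v / norm for k, v in weights.items()}


def posterior_mean_estimate(
    solutions_per_pool: list[list[tuple[str, ...]]],
    universe: list[str],
    prior: dict[str, float],
) -> dict[str, float]:
    """Weight-averaged Dirichlet posterior mean over all histories."""
    post = exhaustive_posterior(solutions_per_pool, universe, prior)
    theta = {h: 0.0 for h in universe}
    for history, w in post.items():
        rho = dict(prior)
        for t, i in enumerate(history):
            for h in solutions_per_pool[t][i]:
                rho[h] += 1.0
        total = math.fsum(rho.values())
        for h in universe:
            theta[h] += w * rho[h] / total
    norm = math.fsum(theta.values())
    return {h: v / norm for h, v in theta.items()}
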