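"""Synthetic pooled-DNA data generator.

Emulates the standard evaluation protocol for pooled haplotype frequency
estimation: each of T pools contains N diploid individuals, each individual
draws two haplotypes i.i.d. from a known population distribution, and the
pool genotype records per-locus allele-1 counts over the 2N chromosomes.
Measurement error is modelled on the allele-frequency scale — Gaussian noise
with standard deviation sigma added to each called frequency, then
re-discretized to the nearest allele count consistent with the pool size —
and missing data by masking each pool x locus cell independently.

Sampling, noise and masking use independent RNG substreams spawned from one
seed, so turning noise or masking on never changes the underlying pools.

Two literature-derived truth distributions ship with the package: ``jain3``
(3 SNPs, 4 haplotypes, estimated from 135 individuals at an established
3-SNP panel) and ``agt10`` (10 SNPs of the AGT gene, 11 haplotypes). They
are the standard small and medium benchmarks for this problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    MISSING,
    DataError,
    FrequencyEstimate,
    PoolDataset,
    PoolGenotype,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "sample_pools",
    "perturb_counts",
    "mask_missing",
    "simulate",
    "builtin_distributions",
]


# 3-SNP benchmark: EM estimates from 135 genotyped individuals. The printed
# table sums to 0.996 and is renormalized on load (with a logged warning).
_JAIN3 = {
    "100": 0.082,
    "001": 0.525,
    "101": 0.283,
    "111": 0.106,
}

# 10-SNP AGT-gene benchmark, 11 haplotypes (sums to 1.000 as printed).
_AGT10 = {
    "1111011000": 0.033,
    "1101011110": 0.016,
    "1101001001": 0.017,
    "1001011001": 0.017,
    "1101011001": 0.017,
    "1111011101": 0.507,
    "0101100111": 0.017,
    "1100001111": 0.033,
    "0101001111": 0.1,
    "1101011111": 0.193,
    "1111111111": 0.05,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated pooled-genotyping study.

    ``haplotype_distribution`` is the truth; ``n_pools`` (T) and
    ``pool_size`` (N individuals per pool) set the study size; ``noise_sd``
    is the allele-frequency measurement-error SD; ``missing_rate`` the
    per-cell masking probability; ``seed`` drives all randomness.
    """

    haplotype_distribution: FrequencyEstimate
    n_pools: int
    pool_size: int = 2
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pools < 1:
            raise DataError("need at least one pool")
        if self.pool_size < 1:
            raise DataError("pool size must be >= 1")
        if self.noise_sd < 0:
            raise DataError("noise SD must be >= 0")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise DataError("missing rate must lie in [0, 1]")


def _substreams(seed: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(3)


def sample_pools(
    spec: SimulationSpec,
) -> tuple[PoolDataset, FrequencyEstimate, FrequencyEstimate]:
    """Draw noiseless pools from the truth distribution.

    Each pool's 2N chromosomes are i.i.d. draws from the haplotype
    distribution; counts are per-locus sums. Returns the dataset together
    with the *gold* (specified) distribution and the *realized* empirical
    distribution over the 2NT drawn chromosomes — the realized frequencies
    are what a frequency estimator can at best recover from these pools.
    """
    dist = spec.haplotype_distribution
    L = dist.n_loci
    haps = np.array(dist.haplotypes, dtype=np.int64)
    probs = np.array([dist[h] for h in haps], dtype=np.float64)
    probs = probs / probs.sum()
    n_chrom = 2 * spec.pool_size

    rng = np.random.default_rng(_substreams(spec.seed)[0])
    draws = rng.choice(len(haps), size=(spec.n_pools, n_chrom), p=probs)

    bits = ((haps[:, None] >> np.arange(L - 1, -1, -1)[None, :]) & 1).astype(
        np.int64
    )  # (n_haps, L)
    counts = bits[draws].sum(axis=1)  # (T, L)

    pools = [
        PoolGenotype(spec.pool_size, tuple(counts[t]), pool_id=f"P{t + 1}")
        for t in range(spec.n_pools)
    ]
    dataset = PoolDataset(pools, [f"L{j + 1}" for j in range(L)])

    drawn, mult = np.unique(draws, return_counts=True)
    realized = FrequencyEstimate(
        {int(haps[i]): m / draws.size for i, m in zip(drawn, mult)},
        L,
        renormalize=True,
    )
    return dataset, dist, realized


def perturb_counts(dataset: PoolDataset, sigma: float, seed: int) -> PoolDataset:
    """Gaussian measurement error on the allele-frequency scale.

    Per non-missing cell with count c: f = c / 2N, f' = clip(f + x, 0, 1)
    with x ~ N(0, sigma^2), and the perturbed count is f' * 2N rounded to
    the nearest integer (halves away from zero), clipped to [0, 2N].
    Missing cells are untouched; sigma = 0 returns the dataset unchanged.
    """
    if sigma < 0:
        raise DataError("noise SD must be >= 0")
    if sigma == 0:
        return dataset
    rng = np.random.default_rng(seed)
    pools = []
    for pool in dataset.pools:
        n_chrom = pool.n_chromosomes
        counts = np.array(pool.counts, dtype=np.float64)
        miss = counts == MISSING
        f = counts / n_chrom
        f_pert = np.clip(f + rng.normal(0.0, sigma, size=len(counts)), 0.0, 1.0)
        new = np.floor(f_pert * n_chrom + 0.5).astype(np.int64)
        new = np.clip(new, 0, n_chrom)
        new[miss] = MISSING
        pools.append(PoolGenotype(pool.pool_size, tuple(new), pool.pool_id))
    return PoolDataset(pools, list(dataset.locus_ids))


def mask_missing(dataset: PoolDataset, rate: float, seed: int) -> PoolDataset:
    """Set each pool x locus cell to MISSING independently with probability
    ``rate``."""
    if not (0.0 <= rate <= 1.0):
        raise DataError("missing rate must lie in [0, 1]")
    if rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    pools = []
    for pool in dataset.pools:
        mask = rng.random(pool.n_loci) < rate
        counts = tuple(
            MISSING if m else c for c, m in zip(pool.counts, mask)
        )
        pools.append(PoolGenotype(pool.pool_size, counts, pool.pool_id))
    return PoolDataset(pools, list(dataset.locus_ids))


def simulate(
    spec: SimulationSpec,
) -> tuple[PoolDataset, FrequencyEstimate, FrequencyEstimate]:
    """Full generator: sample pools, then apply noise and masking.

    The three stages draw from independent substreams of ``spec.seed``, so
    e.g. raising ``noise_sd`` perturbs exactly the same underlying pools.
    """
    dataset, gold, realized = sample_pools(spec)
    _, s_noise, s_mask = _substreams(spec.seed)
    if spec.noise_sd > 0:
        dataset = perturb_counts(
            dataset, spec.noise_sd, s_noise.generate_state(1)[0] & 0x7FFFFFFF
        )
    if spec.missing_rate > 0:
        dataset = mask_missing(
            dataset, spec.missing_rate, s_mask.generate_state(1)[0] & 0x7FFFFFFF
        )
    return dataset, gold, realized


def builtin_distributions() -> dict[str, FrequencyEstimate]:
    """The bundled benchmark truth distributions, renormalized to sum to 1."""
    out = {}
    for name, table in (("jain3", _JAIN3), ("agt10", _AGT10)):
        total = sum(table.values())
        if abs(total - 1.0) > 1e-9:
            logger.warning(
                "distribution %r sums to %.6g; renormalizing", name, total
            )
        out[name] = FrequencyEstimate.from_table(table)
    return out
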