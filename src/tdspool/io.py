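"""On-disk formats: pool-genotype tables and haplotype-frequency tables.

Pool-genotype TSV: header ``pool_id<TAB>pool_size<TAB><locus_1>...``, one row
per pool, cells are integer allele-1 counts or ``NA`` for missing. Locus
order is column order; indices are 0-based internally.

Haplotype-frequency TSV: header ``haplotype<TAB>frequency``; haplotypes are
0/1 strings (first locus leftmost), rows sorted by descending frequency with
lexicographic tie-break, frequencies written with 17 significant digits so a
write -> read round trip is bit-exact.
"""

from __future__ import annotations

import math
from os import PathLike
from pathlib import Path

from .model import (
    MISSING,
    DataError,
    FrequencyEstimate,
    PoolDataset,
    PoolGenotype,
    hap_from_str,
)

__all__ = [
    "read_pool_table",
    "write_pool_table",
    "read_frequency_table",
    "write_frequency_table",
]

NA = "NA"


def read_pool_table(path: str | PathLike) -> PoolDataset:
    """Parse and validate a pool-genotype TSV (diagnostics carry file:line)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise DataError(f"{path}:1: empty pool table")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 3 or header[0] != "pool_id" or header[1] != "pool_size":
        raise DataError(
            f"{path}:1: malformed header; expected "
            f"'pool_id<TAB>pool_size<TAB><locus ids...>'"
        )
    locus_ids = header[2:]
    pools: list[PoolGenotype] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise DataError(
                f"{path}:{lineno}: {len(cells)} columns, expected {len(header)}"
            )
        pool_id = cells[0]
        try:
            pool_size = int(cells[1])
        except ValueError:
            raise DataError(
                f"{path}:{lineno}: pool_size {cells[1]!r} is not an integer"
            ) from None
        if pool_size < 1:
            raise DataError(f"{path}:{lineno}: pool_size must be >= 1")
        counts = []
        for j, cell in enumerate(cells[2:]):
            if cell == NA:
                counts.append(MISSING)
                continue
            try:
                c = int(cell)
            except ValueError:
                raise DataError(
                    f"{path}:{lineno}: cell {cell!r} at locus {locus_ids[j]} "
                    f"is neither an integer nor {NA}"
                ) from None
            if not (0 <= c <= 2 * pool_size):
                raise DataError(
                    f"{path}:{lineno}: count {c} > 2N={2 * pool_size} at pool "
                    f"{pool_id}, locus {locus_ids[j]}"
                    if c > 2 * pool_size
                    else f"{path}:{lineno}: negative count {c} at pool "
                    f"{pool_id}, locus {locus_ids[j]}"
                )
            counts.append(c)
        pools.append(PoolGenotype(pool_size, tuple(counts), pool_id))
    if not pools:
        raise DataError(f"{path}: no pool rows")
    return PoolDataset(pools, locus_ids)


def write_pool_table(path: str | PathLike, dataset: PoolDataset) -> None:
    lines = ["\t".join(["pool_id", "pool_size", *dataset.locus_ids])]
    for pool in dataset.pools:
        cells = [NA if c == MISSING else str(c) for c in pool.counts]
        lines.append("\t".join([pool.pool_id, str(pool.pool_size), *cells]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_frequency_table(path: str | PathLike) -> FrequencyEstimate:
    """Parse a haplotype-frequency TSV; frequencies must sum to ~1."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[:2] != ["haplotype", "frequency"]:
        raise DataError(
            f"{path}:1: malformed header; expected 'haplotype<TAB>frequency'"
        )
    table: dict[int, float] = {}
    n_loci = None
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != 2:
            raise DataError(f"{path}:{lineno}: expected 2 columns")
        hap_str, freq_str = cells
        if n_loci is None:
            n_loci = len(hap_str)
        elif len(hap_str) != n_loci:
            raise DataError(
                f"{path}:{lineno}: haplotype {hap_str!r} has {len(hap_str)} "
                f"loci, expected {n_loci}"
            )
        try:
            hap = hap_from_str(hap_str)
        except DataError as exc:
            raise DataError(f"{path}:{lineno}: {exc}") from None
        try:
            freq = float(freq_str)
        except ValueError:
            raise DataError(
                f"{path}:{lineno}: frequency {freq_str!r} is not a number"
            ) from None
        if not math.isfinite(freq) or freq < 0:
            raise DataError(f"{path}:{lineno}: invalid frequency {freq}")
        if hap in table:
            raise DataError(f"{path}:{lineno}: duplicate haplotype {hap_str}")
        table[hap] = freq
    if not table:
        raise DataError(f"{path}: no frequency rows")
    total = math.fsum(table.values())
    if abs(total - 1.0) <= 1e-6:
        # accept as written so a write -> read round trip is bit-exact
        return FrequencyEstimate(table, n_loci, _tol=1e-6)
    return FrequencyEstimate(table, n_loci, renormalize=True)


def write_frequency_table(path: str | PathLike, estimate: FrequencyEstimate) -> None:
    """Write descending by frequency (lexicographic tie-break), 17 sig digits."""
    if len(estimate) == 0:
        raise DataError("refusing to write an empty frequency estimate")
    lines = ["haplotype\tfrequency"]
    for hap, freq in estimate.items():
        lines.append(f"{format(hap, f'0{estimate.n_loci}b')}\t{freq:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")
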