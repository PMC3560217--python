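import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tdspool import (
    FrequencyEstimate,
    HaplotypeUniverse,
    PoolDataset,
    PoolGenotype,
    builtin_distributions,
    hap_from_str,
)


@pytest.fixture(scope="session")
def jain3() -> FrequencyEstimate:
    return builtin_distributions()["jain3"]


@pytest.fixture(scope="session")
def agt10() -> FrequencyEstimate:
    return builtin_distributions()["agt10"]


def make_dataset(rows: list[tuple[int, list[int]]]) -> PoolDataset:
    """Dataset from (pool_size, counts) rows; counts use -1 for missing."""
    return PoolDataset(
        [
            PoolGenotype(n, tuple(counts), pool_id=f"P{i + 1}")
            for i, (n, counts) in enumerate(rows)
        ]
    )


def universe_of(hap_strings: list[str]) -> HaplotypeUniverse:
    n_loci = len(hap_strings[0])
    return HaplotypeUniverse(
        tuple(hap_from_str(s) for s in hap_strings), n_loci
    )
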