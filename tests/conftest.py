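"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; no binary test data.
"""

from __future__ import annotations

import numpy as np
import pytest

from matesv.caller import Breakpoint
from matesv.model import FORWARD, REVERSE, MatePair, ReadMapping
from matesv.simulate import SimulationConfig, random_variants
from matesv.svset import SvSet


def make_pair(
    pair_id: str,
    chrom1: str,
    start1: int,
    chrom2: str,
    start2: int,
    strand1: str = "+",
    strand2: str = "-",
    read_len: int = 50,
) -> MatePair:
    """Forward-role read at (chrom1, start1), reverse-role at (chrom2, start2)."""
    return MatePair(
        pair_id,
        ReadMapping(chrom1, start1, start1 + read_len, strand1, f"{pair_id}/1", FORWARD),
        ReadMapping(chrom2, start2, start2 + read_len, strand2, f"{pair_id}/2", REVERSE),
    )


def normal_pairs(
    n: int,
    rng: np.random.Generator,
    chrom: str = "chr1",
    mean: int = 5000,
    sd: int = 300,
    region: int = 1_000_000,
    read_len: int = 50,
    prefix: str = "p",
) -> list[MatePair]:
    """Plain consistent-looking pairs with normal outer distances."""
    pairs = []
    for i in range(n):
        insert = int(round(rng.normal(mean, sd)))
        insert = max(insert, 2 * read_len + 1)
        start = int(rng.integers(0, region))
        pairs.append(
            make_pair(f"{prefix}{i:06d}", chrom, start, chrom, start + insert - read_len)
        )
    return pairs


def make_breakpoint(
    chromA: str, b1: int, e1: int, chromB: str, b2: int, e2: int,
    support: int = 5, variant_class: str = "deletion", sample: str = "s",
    name: str = ".",
) -> Breakpoint:
    return Breakpoint(
        chromA=chromA, b1=b1, e1=e1, chromB=chromB, b2=b2, e2=e2,
        support=support, effective_support=support,
        variant_class=variant_class, sample=sample, name=name,
    )


def random_svset(
    name: str,
    n: int,
    rng: np.random.Generator,
    chroms: tuple = ("chr1", "chr2", "chr3"),
    span: int = 5_000_000,
    i_max: int = 2000,
) -> SvSet:
    bps = []
    for i in range(n):
        ca, cb = sorted(rng.choice(chroms, size=2))
        b1 = int(rng.integers(0, span))
        b2 = int(rng.integers(0, span))
        if ca == cb and b2 < b1:
            b1, b2 = b2, b1
        bps.append(
            make_breakpoint(
                ca, b1, b1 + int(rng.integers(100, 2000)),
                cb, b2, b2 + int(rng.integers(100, 2000)),
                support=int(rng.integers(1, 20)),
                variant_class=str(rng.choice(["deletion", "inversion", "translocation"])),
                name=f"{name}_{i}",
            )
        )
    return SvSet(name, bps, i_max=i_max)


@pytest.fixture(scope="session")
def small_genome() -> dict:
    return {f"chr{i}": 1_500_000 for i in (1, 2, 3, 4)}


@pytest.fixture(scope="session")
def small_sim_config(small_genome) -> SimulationConfig:
    """A compact study: a handful of variants of every class at ~8x coverage."""
    rng = np.random.default_rng(2024)
    variants = random_variants(
        small_genome, rng,
        n_deletions=2, n_insertions=2, n_inversions=2, n_translocations=2,
        size_range=(20_000, 30_000), spacing=60_000, margin=80_000,
        fusion_arm=100_000,
    )
    return SimulationConfig(
        genome=small_genome, variants=variants, n_pairs=12_000, seed=7,
        clonal_rate=0.05,
    )
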