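"""Reusable validation studies run by the test suite and benchmark script.

The studies exercise the toolkit end to end on simulated data at desk
scale: a 20 Mb / 50-variant genome at 10x clone coverage for breakpoint
recovery, a subclonal variant of the same study for low-coverage
sensitivity, and a null-calibration study for the enrichment permutation
test.  Everything is deterministic given the seeds passed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .caller import CallerConfig, call_breakpoints, thin_members
from .enrichment import EnrichmentConfig, permutation_enrichment
from .model import build_insert_model, dedup_clonal
from .caller import Breakpoint, partition_by_chrom_pair
from .simulate import (
    INSERTION,
    PlantedVariant,
    SimulatedDataset,
    SimulationConfig,
    donor_genome_size,
    random_variants,
    simulate,
)
from .svset import SvSet, breakpoints_overlap, match_calls
from .tracks import FeatureTrack


def benchmark_genome(n_chroms: int = 8, chrom_len: int = 2_500_000) -> Dict[str, int]:
    return {f"chr{i}": chrom_len for i in range(1, n_chroms + 1)}


def benchmark_variants(seed: int, genome: Optional[Dict[str, int]] = None) -> List[PlantedVariant]:
    """Fifty variants covering all four classes, well separated."""
    rng = np.random.default_rng([abs(int(seed)), 1])
    return random_variants(
        genome if genome is not None else benchmark_genome(),
        rng,
        n_deletions=14, n_insertions=14, n_inversions=14, n_translocations=8,
    )


def benchmark_config(
    seed: int,
    coverage: float = 10.0,
    tumor_fraction: float = 1.0,
    clonal_rate: float = 0.05,
    variant_seed: Optional[int] = None,
) -> SimulationConfig:
    """The standard recovery study: 20 Mb genome, 50 variants, 10x clone
    coverage (pair count set from the donor genome size)."""
    genome = benchmark_genome()
    variants = benchmark_variants(
        variant_seed if variant_seed is not None else seed, genome
    )
    probe = SimulationConfig(genome=genome, variants=variants, n_pairs=1,
                             seed=0)
    n_pairs = int(round(coverage * donor_genome_size(probe) / probe.insert_mean))
    return SimulationConfig(
        genome=genome, variants=variants, n_pairs=n_pairs,
        seed=abs(int(seed)), clonal_rate=clonal_rate,
        tumor_fraction=tumor_fraction,
    )


@dataclass
class RecoveryStudy:
    config: SimulationConfig
    dataset: SimulatedDataset
    calls: List[Breakpoint]
    n_junctions: int
    eligible: List[str]             # junctions with >= 3 non-clonal spanning pairs
    recovered_eligible: List[str]
    recovered_all: List[str]
    false_calls: int
    predicted: Dict[str, bool]      # junction -> thinned spanning support >= 3
    pct_i_min: int                  # percentile-estimated bounds on same data
    pct_i_max: int
    pct_within: float               # fraction of inserts inside the bounds


def run_recovery_study(
    config: SimulationConfig, min_support: int = 3
) -> RecoveryStudy:
    """Simulate, call with the true insert bounds, and score against truth.

    A junction counts as recovered when a call of the same class and strand
    signature overlaps it under the min-of-four-distances rule at the true
    maximum insert size; a call is false when it overlaps no truth junction
    at all.
    """
    dataset = simulate(config)
    model = build_insert_model(dataset.pairs, override=config.insert_bounds)
    calls = call_breakpoints(
        dataset.pairs, model, CallerConfig(min_support=min_support)
    )
    i_max = config.insert_bounds[1]
    matches = match_calls(
        calls, dataset.truth.breakpoints, i_max,
        require_class=True, require_strands=True,
    )
    counts = dataset.spanning_counts()
    truth = dataset.truth.breakpoints
    eligible = [bp.name for bp in truth if counts[bp.name] >= min_support]
    recovered_all = [truth[ti].name for ti, hits in matches.items() if hits]
    recovered_eligible = [
        name for name in recovered_all if counts[name] >= min_support
    ]
    false_calls = sum(
        1
        for call in calls
        if not any(breakpoints_overlap(call, t, i_max) for t in truth)
    )
    predicted = predicted_recovery(dataset, min_support=min_support)
    pct_model = build_insert_model(dataset.pairs)
    inside = sum(
        c
        for s, c in pct_model.histogram.items()
        if pct_model.i_min <= s <= pct_model.i_max
    )
    return RecoveryStudy(
        config=config,
        dataset=dataset,
        calls=calls,
        n_junctions=len(truth),
        eligible=eligible,
        recovered_eligible=recovered_eligible,
        recovered_all=recovered_all,
        false_calls=false_calls,
        predicted=predicted,
        pct_i_min=pct_model.i_min,
        pct_i_max=pct_model.i_max,
        pct_within=inside / pct_model.n_pairs_used,
    )


def predicted_recovery(
    dataset: SimulatedDataset,
    min_support: int = 3,
    min_end_spread: int = 50,
) -> Dict[str, bool]:
    """Junction-level recovery predicted from its own spanning pairs.

    A junction should be called iff its non-clonal spanning pairs, after
    clonal dedup and the read-end diversity thinning, still number at least
    ``min_support`` — an independent per-junction computation that bypasses
    the clustering machinery entirely.
    """
    by_id = {p.pair_id: p for p in dataset.pairs}
    out: Dict[str, bool] = {}
    for label, ids in dataset.truth_spanning.items():
        members = dedup_clonal(by_id[i] for i in ids)
        if not members:
            out[label] = False
            continue
        buckets = partition_by_chrom_pair(members)
        oriented = max(buckets.values(), key=len)
        out[label] = len(thin_members(oriented, min_end_spread)) >= min_support
    return out


def junction_poisson_expectation(
    config: SimulationConfig, min_support: int = 3
) -> Dict[str, float]:
    """P(spanning-pair count >= min_support) per junction under the
    fragment-process model.

    Fragments spanning a junction with both reads clear of it arrive as a
    Poisson process with rate tumor_fraction * n_pairs * w / G_donor, where
    w is the fragment length minus two read lengths, further reduced by the
    novel-sequence length for insertion junctions.
    """
    from .simulate import truth_breakpoints

    g_donor = donor_genome_size(config)
    penalties = {
        v.var_id: v.length for v in config.variants if v.kind == INSERTION
    }
    out: Dict[str, float] = {}
    for label, _bp in truth_breakpoints(config):
        pen = penalties.get(label.split("/")[0], 0)
        window = max(config.insert_mean - 2 * config.read_len - pen, 0)
        lam = config.tumor_fraction * config.n_pairs * window / g_donor
        out[label] = float(stats.poisson.sf(min_support - 1, lam))
    return out


@dataclass
class CalibrationStudy:
    n_replicates: int
    n_significant: int
    alpha_nominal: float
    alpha_exact: float              # achievable rejection rate given the p floor
    envelope: Tuple[int, int]       # exact binomial 99% envelope on counts
    planted_fold: float
    planted_p: float


def run_calibration_study(
    seed: int,
    n_replicates: int = 200,
    n_perm: int = 500,
    alpha: float = 0.05,
    n_breakpoints: int = 40,
    n_features: int = 120,
    genome: Optional[Dict[str, int]] = None,
) -> CalibrationStudy:
    """Type-I error of the permutation test under full independence.

    Breakpoints and features are placed independently and uniformly; the
    fraction of replicates with p_enrich at or below alpha is compared to
    the exact rejection probability floor(alpha*(n_perm+1))/(n_perm+1) via
    its binomial 99% envelope.  A final replicate with features planted
    inside the true windows verifies power (fold > 1, small p).
    """
    if genome is None:
        genome = {"chr1": 10_000_000, "chr2": 10_000_000}
    chroms = sorted(genome)
    master = np.random.default_rng([abs(int(seed)), 6])
    n_sig = 0
    for _ in range(n_replicates):
        bps = _uniform_breakpoints(master, genome, chroms, n_breakpoints)
        track = _uniform_track(master, genome, chroms, n_features)
        config = EnrichmentConfig(
            radius=50_000, n_perm=n_perm,
            seed=int(master.integers(0, 2**31)), genome=genome,
        )
        (res,) = permutation_enrichment(
            SvSet("rep", bps, 5800), track, config, classes=["all"]
        )
        if res.p_enrich <= alpha:
            n_sig += 1
    alpha_exact = np.floor(alpha * (n_perm + 1)) / (n_perm + 1)
    lo = int(stats.binom.ppf(0.005, n_replicates, alpha_exact))
    hi = int(stats.binom.ppf(0.995, n_replicates, alpha_exact))

    bps = _uniform_breakpoints(master, genome, chroms, n_breakpoints)
    planted = FeatureTrack(
        "planted",
        [(b.chromA, (b.b1 + b.e1) // 2 + 1000, (b.b1 + b.e1) // 2 + 2000)
         for b in bps],
    )
    config = EnrichmentConfig(
        radius=50_000, n_perm=1000, seed=int(master.integers(0, 2**31)),
        genome=genome,
    )
    (res,) = permutation_enrichment(
        SvSet("planted", bps, 5800), planted, config, classes=["all"]
    )
    return CalibrationStudy(
        n_replicates=n_replicates,
        n_significant=n_sig,
        alpha_nominal=alpha,
        alpha_exact=float(alpha_exact),
        envelope=(lo, hi),
        planted_fold=res.fold,
        planted_p=res.p_enrich,
    )


def _uniform_breakpoints(rng, genome, chroms, n):
    bps = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        p = int(rng.integers(0, genome[chrom]))
        q = int(rng.integers(0, genome[chrom]))
        lo, hi = sorted((p, q))
        bps.append(
            Breakpoint(chromA=chrom, b1=lo, e1=lo + 200, chromB=chrom,
                       b2=hi, e2=hi + 200, support=5, effective_support=5,
                       variant_class="deletion", sample="rep", name=f"b{i}")
        )
    return bps


def _uniform_track(rng, genome, chroms, n, width: int = 1000):
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, genome[chrom] - width))
        ivs.append((chrom, s, s + width))
    return FeatureTrack("null", ivs)
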