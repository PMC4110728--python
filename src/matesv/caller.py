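"""Breakpoint calling from inconsistent mate pairs.

Pipeline: clonal dedup -> pair classification -> partition by chromosome
pair -> coarse greedy clustering on a sliding-window grid -> single-linkage
hierarchical refinement in rearrangement hotspots -> support/diversity
filtering -> variant-class assignment.

The grid window ``w`` must exceed the maximum consistent insert size, so
pairs from one physical breakpoint cannot straddle more windows than the
greedy sweep tolerates; refinement then corrects any over-merging with an
exact single-linkage cut.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ConfigError
from .model import (
    INCONSISTENT,
    InsertSizeModel,
    MatePair,
    classify_pair,
    dedup_clonal,
)

DELETION = "deletion"
INSERTION = "insertion"
INVERSION = "inversion"
TRANSLOCATION = "translocation"
VARIANT_CLASSES = (DELETION, INSERTION, INVERSION, TRANSLOCATION)

END_SPREAD_THIN = "thin"
END_SPREAD_VETO = "veto"


@dataclass(frozen=True, slots=True)
class CallerConfig:
    """Tunable parameters of the caller.

    ``w`` and ``refine_cut`` default to 2*i_max and i_max respectively when
    left unset; ``min_support`` is the minimum mate pairs per reported
    variant and ``min_end_spread`` the read-end diversity radius (bp) used
    against PCR stacking.
    """

    w: Optional[int] = None
    min_support: int = 3
    min_end_spread: int = 50
    refine_cut: Optional[int] = None
    end_spread_mode: str = END_SPREAD_THIN
    chrom_order: Optional[Tuple[str, ...]] = None

    def resolved(self, model: InsertSizeModel) -> "CallerConfig":
        w = self.w if self.w is not None else 2 * model.i_max
        cut = self.refine_cut if self.refine_cut is not None else model.i_max
        cfg = replace(self, w=w, refine_cut=cut)
        cfg.validate(model)
        return cfg

    def validate(self, model: InsertSizeModel) -> None:
        if self.w is None or self.w <= model.i_max:
            raise ConfigError(f"window w={self.w} must exceed i_max={model.i_max}")
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")
        if self.min_end_spread < 0:
            raise ConfigError("min_end_spread must be >= 0")
        if self.refine_cut is None or self.refine_cut <= 0:
            raise ConfigError("refine_cut must be > 0")
        if self.end_spread_mode not in (END_SPREAD_THIN, END_SPREAD_VETO):
            raise ConfigError(f"unknown end_spread_mode {self.end_spread_mode!r}")


@dataclass(frozen=True, slots=True)
class OrientedPair:
    """A mate pair with sides in canonical (chromA, chromB) order."""

    pair: MatePair
    chromA: str
    startA: int
    endA: int
    strandA: str
    roleA: str
    chromB: str
    startB: int
    endB: int
    strandB: str

    @property
    def signature(self) -> Tuple[str, str]:
        """Canonical oriented strand pair; mirror forms coincide."""
        return (self.strandA, self.strandB)

    @property
    def pair_id(self) -> str:
        return self.pair.pair_id


def _chrom_rank(order: Optional[Tuple[str, ...]]):
    if order is None:
        return lambda c: (0, c)
    idx = {c: i for i, c in enumerate(order)}
    # chromosomes missing from the dictionary sort after known ones
    return lambda c: (0, idx[c]) if c in idx else (1, c)


def orient_pair(pair: MatePair, rank) -> OrientedPair:
    f, r = pair.fwd, pair.rev
    f_key = (rank(f.chrom), f.start, f.end)
    r_key = (rank(r.chrom), r.start, r.end)
    a, b = (f, r) if f_key <= r_key else (r, f)
    return OrientedPair(
        pair=pair,
        chromA=a.chrom, startA=a.start, endA=a.end, strandA=a.strand, roleA=a.role,
        chromB=b.chrom, startB=b.start, endB=b.end, strandB=b.strand,
    )


def partition_by_chrom_pair(
    pairs: Iterable[MatePair], chrom_order: Optional[Tuple[str, ...]] = None
) -> Dict[Tuple[str, str], List[OrientedPair]]:
    """Bucket pairs by their canonically ordered chromosome pair."""
    rank = _chrom_rank(chrom_order)
    buckets: Dict[Tuple[str, str], List[OrientedPair]] = {}
    for p in pairs:
        op = orient_pair(p, rank)
        buckets.setdefault((op.chromA, op.chromB), []).append(op)
    return buckets


@dataclass(slots=True)
class BreakpointCluster:
    chromA: str
    chromB: str
    members: List[OrientedPair]
    signature: Tuple[str, str]

    @property
    def footprintA(self) -> Tuple[int, int]:
        return (min(m.startA for m in self.members), max(m.endA for m in self.members))

    @property
    def footprintB(self) -> Tuple[int, int]:
        return (min(m.startB for m in self.members), max(m.endB for m in self.members))


@dataclass(frozen=True, slots=True)
class Breakpoint:
    """A called breakpoint: paired footprints chrA:[b1,e1]-chrB:[b2,e2]."""

    chromA: str
    b1: int
    e1: int
    chromB: str
    b2: int
    e2: int
    support: int
    effective_support: int
    variant_class: str
    sample: str
    strandA: str = "."
    strandB: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.b1 <= self.e1 and self.b2 <= self.e2):
            raise ValueError("footprint bounds must satisfy b <= e")
        # called breakpoints always have effective_support >= 1; truth
        # records from the simulator may carry 0 realized spanning pairs
        if not (self.support >= self.effective_support >= 0):
            raise ValueError("require support >= effective_support >= 0")


class _SweepCluster:
    __slots__ = ("members", "maxA", "minB", "maxB")

    def __init__(self, first: OrientedPair):
        self.members = [first]
        self.maxA = first.startA
        self.minB = first.startB
        self.maxB = first.startB

    def add(self, p: OrientedPair) -> None:
        self.members.append(p)
        self.maxA = max(self.maxA, p.startA)
        self.minB = min(self.minB, p.startB)
        self.maxB = max(self.maxB, p.startB)


def coarse_cluster(
    bucket: List[OrientedPair], config: CallerConfig
) -> List[BreakpointCluster]:
    """Greedy sweep clustering of one chromosome-pair bucket.

    Pairs are first split by orientation signature; within a signature they
    are swept in (side-A start, side-B start) order and join the first open
    cluster whose side-A and side-B start footprints are both within ``w``;
    a cluster closes once the sweep passes its side-A footprint by more
    than ``w``.
    """
    w = config.w
    assert w is not None
    out: List[BreakpointCluster] = []
    by_sig: Dict[Tuple[str, str], List[OrientedPair]] = {}
    for p in bucket:
        by_sig.setdefault(p.signature, []).append(p)
    for sig in sorted(by_sig):
        members = sorted(by_sig[sig], key=lambda p: (p.startA, p.startB, p.pair_id))
        open_clusters: List[_SweepCluster] = []
        closed: List[_SweepCluster] = []
        for p in members:
            still = []
            for c in open_clusters:
                if p.startA - c.maxA > w:
                    closed.append(c)
                else:
                    still.append(c)
            open_clusters = still
            for c in open_clusters:
                if max(0, c.minB - p.startB, p.startB - c.maxB) <= w:
                    c.add(p)
                    break
            else:
                open_clusters.append(_SweepCluster(p))
        closed.extend(open_clusters)
        chromA, chromB = members[0].chromA, members[0].chromB
        out.extend(
            BreakpointCluster(chromA, chromB, c.members, sig) for c in closed
        )
    return out


def refine_cluster(
    cluster: BreakpointCluster, config: CallerConfig
) -> List[BreakpointCluster]:
    """Single-linkage refinement of a coarse cluster.

    Members are agglomerated under the Chebyshev distance on their
    (side-A start, side-B start) coordinates and the dendrogram is cut at
    ``refine_cut``; the result equals the connected components of the
    threshold graph d(p,q) <= refine_cut.
    """
    members = cluster.members
    if len(members) <= 1:
        return [cluster]
    coords = np.array([[m.startA, m.startB] for m in members], dtype=float)
    labels = fcluster(
        linkage(pdist(coords, metric="chebyshev"), method="single"),
        t=config.refine_cut,
        criterion="distance",
    )
    groups: Dict[int, List[OrientedPair]] = {}
    for lab, m in zip(labels, members):
        groups.setdefault(int(lab), []).append(m)
    subs = [
        BreakpointCluster(cluster.chromA, cluster.chromB, ms, cluster.signature)
        for ms in groups.values()
    ]
    subs.sort(key=lambda c: (c.footprintA, c.footprintB))
    return subs


def thin_members(
    members: List[OrientedPair], min_end_spread: int
) -> List[OrientedPair]:
    """Greedy diversity thinning implementing the read-end spread rule.

    Scanned in (side-A start, side-B start, pair_id) order, a member is
    redundant iff BOTH its side starts lie within ``min_end_spread`` bp
    (strictly) of a previously kept member's corresponding starts, i.e.
    reads at least ``min_end_spread`` apart on either side count as
    independent evidence.
    """
    kept: List[OrientedPair] = []
    for m in sorted(members, key=lambda p: (p.startA, p.startB, p.pair_id)):
        redundant = any(
            abs(m.startA - k.startA) < min_end_spread
            and abs(m.startB - k.startB) < min_end_spread
            for k in kept
        )
        if not redundant:
            kept.append(m)
    return kept


def classify_variant(
    signature: Tuple[str, str],
    chromA: str,
    chromB: str,
    span: float,
    model: InsertSizeModel,
) -> str:
    """Assign a variant class from chromosomes, orientation and span.

    Different chromosomes -> translocation; a strand pair differing from the
    library's expected oriented strands -> inversion (one end flipped);
    expected strands with span beyond i_max -> deletion, below i_min ->
    insertion.  Border-line clusters of range-discordant pairs whose
    footprint-midpoint span falls back inside [i_min, i_max] (pair
    consistency is judged on the outer distance, which differs from the
    midpoint span by about a read length) are resolved toward the nearer
    range edge.
    """
    if chromA != chromB:
        return TRANSLOCATION
    exp = model.expected_orientation.oriented_strands()
    if signature != exp:
        return INVERSION
    if span > model.i_max:
        return DELETION
    if span < model.i_min:
        return INSERTION
    return DELETION if 2 * span >= model.i_min + model.i_max else INSERTION


def cluster_to_breakpoint(
    cluster: BreakpointCluster,
    config: CallerConfig,
    model: InsertSizeModel,
    sample: str,
) -> Optional[Breakpoint]:
    """Apply support/diversity filtering and emit a breakpoint, or nothing.

    In the default ``thin`` mode the support threshold applies to the
    diversity-thinned count; in ``veto`` mode raw support is thresholded but
    clusters with no end diversity at all are vetoed.
    """
    kept = thin_members(cluster.members, config.min_end_spread)
    eff = len(kept)
    if config.end_spread_mode == END_SPREAD_THIN:
        if eff < config.min_support:
            return None
    else:
        if len(cluster.members) < config.min_support:
            return None
        if eff < min(2, config.min_support):
            return None
    b1, e1 = cluster.footprintA
    b2, e2 = cluster.footprintB
    span = abs(((b2 + e2) / 2.0) - ((b1 + e1) / 2.0))
    vclass = classify_variant(
        cluster.signature, cluster.chromA, cluster.chromB, span, model
    )
    return Breakpoint(
        chromA=cluster.chromA, b1=b1, e1=e1,
        chromB=cluster.chromB, b2=b2, e2=e2,
        support=len(cluster.members), effective_support=eff,
        variant_class=vclass, sample=sample,
        strandA=cluster.signature[0], strandB=cluster.signature[1],
    )


def call_breakpoints(
    pairs: Iterable[MatePair],
    model: InsertSizeModel,
    config: CallerConfig = CallerConfig(),
    sample: str = "sample",
    counts: Optional[dict] = None,
) -> List[Breakpoint]:
    """Full pipeline; output sorted, invariant to input order and batching.

    ``counts``, when given, is filled with per-stage tallies for logging.
    """
    cfg = config.resolved(model)
    deduped = dedup_clonal(pairs)
    inconsistent = [
        p for p in deduped if classify_pair(p, model).label == INCONSISTENT
    ]
    buckets = partition_by_chrom_pair(inconsistent, cfg.chrom_order)
    rank = _chrom_rank(cfg.chrom_order)
    calls: List[Breakpoint] = []
    for key in sorted(buckets, key=lambda k: (rank(k[0]), rank(k[1]))):
        for coarse in coarse_cluster(buckets[key], cfg):
            for sub in refine_cluster(coarse, cfg):
                bp = cluster_to_breakpoint(sub, cfg, model, sample)
                if bp is not None:
                    calls.append(bp)
    calls.sort(key=lambda b: (rank(b.chromA), b.b1, rank(b.chromB), b.b2, b.e1, b.e2))
    calls = [
        replace(bp, name=f"bp_{i + 1:05d}") for i, bp in enumerate(calls)
    ]
    if counts is not None:
        counts.update(
            n_input=len(deduped),
            n_inconsistent=len(inconsistent),
            n_chrom_pairs=len(buckets),
            n_calls=len(calls),
        )
    return calls
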