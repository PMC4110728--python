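"""Mate-pair domain model.

A long-insert mate pair is two reads sequenced from the ends of a ~4-6 kb
DNA fragment.  Pairs whose mappings sit on the same chromosome, in the
library's expected relative orientation, and at an outer distance inside the
bulk of the insert-size distribution are *consistent*; everything else is
*inconsistent* and is the raw evidence for structural variation.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from the 1-based SAM convention happens only at the file boundary
(:mod:`matesv.samio`).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .errors import ModelError, ParameterError

FORWARD = "forward"
REVERSE = "reverse"

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"

REASON_OK = "ok"
REASON_INTER = "inter_chromosomal"
REASON_ORIENT = "orientation"
REASON_TOO_FAR = "too_far"
REASON_TOO_CLOSE = "too_close"


@dataclass(frozen=True, slots=True)
class ReadMapping:
    """A single uniquely-mapped read end.

    ``start``/``end`` are 0-based half-open reference coordinates.
    """

    chrom: str
    start: int
    end: int
    strand: str
    read_id: str
    role: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"read {self.read_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: bad strand {self.strand!r}")
        if self.role not in (FORWARD, REVERSE):
            raise ValueError(f"read {self.read_id}: bad role {self.role!r}")


@dataclass(frozen=True, slots=True)
class OrientationSignature:
    """Relative orientation of a mate pair.

    ``upstream_role`` names the role (forward/reverse) whose mapping sits
    5'-ward on the reference; only defined for intra-chromosomal pairs.
    Together with the two strands this is a finite 2x2x2 enumeration.
    """

    fwd_strand: str
    rev_strand: str
    upstream_role: str

    def as_tuple(self) -> Tuple[str, str, str]:
        return (self.fwd_strand, self.rev_strand, self.upstream_role)

    def mirror(self) -> "OrientationSignature":
        """The signature of the same library read off the opposite strand.

        Reverse-complementing a fragment flips both read strands and swaps
        which role maps upstream; a real duplex library emits both mirror
        forms, and a pair lying fully inside an inverted segment is
        indistinguishable from the mirror of a normal pair.
        """
        flip = {"+": "-", "-": "+"}
        other = {FORWARD: REVERSE, REVERSE: FORWARD}
        return OrientationSignature(
            flip[self.fwd_strand], flip[self.rev_strand], other[self.upstream_role]
        )

    def oriented_strands(self) -> Tuple[str, str]:
        """(upstream read strand, downstream read strand); mirror-invariant."""
        if self.upstream_role == FORWARD:
            return (self.fwd_strand, self.rev_strand)
        return (self.rev_strand, self.fwd_strand)


@dataclass(frozen=True, slots=True)
class MatePair:
    pair_id: str
    fwd: ReadMapping
    rev: ReadMapping

    def __post_init__(self) -> None:
        if self.fwd.role != FORWARD or self.rev.role != REVERSE:
            raise ValueError(f"pair {self.pair_id}: roles must be forward/reverse")

    @property
    def intra(self) -> bool:
        return self.fwd.chrom == self.rev.chrom

    def insert_size(self) -> int:
        """Outer distance: leftmost start to rightmost end."""
        return max(self.fwd.end, self.rev.end) - min(self.fwd.start, self.rev.start)

    def signature(self) -> OrientationSignature:
        if not self.intra:
            raise ValueError(
                f"pair {self.pair_id}: orientation signature is defined for "
                "intra-chromosomal pairs only"
            )
        if (self.fwd.start, self.fwd.end) <= (self.rev.start, self.rev.end):
            upstream = FORWARD
        else:
            upstream = REVERSE
        return OrientationSignature(self.fwd.strand, self.rev.strand, upstream)


@dataclass(frozen=True, slots=True)
class PairClass:
    label: str
    reason: str

    def __post_init__(self) -> None:
        if (self.label == CONSISTENT) != (self.reason == REASON_OK):
            raise ValueError("label=consistent iff reason=ok")


@dataclass(slots=True)
class InsertSizeModel:
    """Insert-size distribution with consistency bounds.

    ``i_min``/``i_max`` bracket the central 0.5-99.5 percentile range of the
    outer-distance distribution (or user overrides); ``expected_orientation``
    is the library's majority signature.
    """

    histogram: dict[int, int]
    i_min: int
    i_max: int
    expected_orientation: OrientationSignature
    n_pairs_used: int

    def __post_init__(self) -> None:
        if not (0 < self.i_min < self.i_max):
            raise ValueError("require 0 < i_min < i_max")
        if self.n_pairs_used < 1:
            raise ValueError("n_pairs_used must be >= 1")
        if sum(self.histogram.values()) != self.n_pairs_used:
            raise ValueError("histogram total must equal n_pairs_used")

    # -- flat key/value serialization -------------------------------------

    def to_file(self, path) -> None:
        sig = self.expected_orientation
        with open(path, "w") as fh:
            fh.write(f"i_min\t{self.i_min}\n")
            fh.write(f"i_max\t{self.i_max}\n")
            fh.write(f"n_pairs_used\t{self.n_pairs_used}\n")
            fh.write(f"orientation\t{sig.fwd_strand},{sig.rev_strand},{sig.upstream_role}\n")
            for size in sorted(self.histogram):
                fh.write(f"H\t{size}\t{self.histogram[size]}\n")

    @classmethod
    def from_file(cls, path) -> "InsertSizeModel":
        fields: dict[str, str] = {}
        hist: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "H":
                    hist[int(parts[1])] = int(parts[2])
                else:
                    fields[parts[0]] = parts[1]
        f, r, u = fields["orientation"].split(",")
        return cls(
            histogram=hist,
            i_min=int(fields["i_min"]),
            i_max=int(fields["i_max"]),
            expected_orientation=OrientationSignature(f, r, u),
            n_pairs_used=int(fields["n_pairs_used"]),
        )


def nearest_rank(sorted_values: Sequence[int], p: float) -> int:
    """ceil(p*n)-th order statistic (1-based) of an ascending sequence."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty sequence")
    rank = max(1, math.ceil(p * n))
    return sorted_values[min(rank, n) - 1]


def build_insert_model(
    pairs: Iterable[MatePair],
    lo_pct: float = 0.005,
    hi_pct: float = 0.995,
    override: Optional[Tuple[int, int]] = None,
    expected_orientation: Optional[OrientationSignature] = None,
    gross_cap_factor: float = 10.0,
) -> InsertSizeModel:
    """Build the insert-size model from intra-chromosomal pairs.

    The expected orientation is the majority signature among
    intra-chromosomal pairs whose outer distance does not exceed
    ``gross_cap_factor`` times the median (keeps grossly discordant pairs
    from voting); it can be forced for platforms with a known chemistry.
    Percentile bounds are nearest-rank order statistics of the outer
    distances of expected-orientation intra-chromosomal pairs.
    """
    if not 0 <= lo_pct < hi_pct <= 1:
        raise ParameterError("require 0 <= lo_pct < hi_pct <= 1")
    intra = [p for p in pairs if p.intra]
    if not intra:
        raise ModelError("no intra-chromosomal pairs; cannot build insert model")

    inserts_all = sorted(p.insert_size() for p in intra)
    median = inserts_all[(len(inserts_all) - 1) // 2]
    cap = gross_cap_factor * max(median, 1)

    if expected_orientation is None:
        # mirror forms (opposite-strand reads of the same library) vote
        # together; the stored representative is the commoner raw signature
        votes: Counter = Counter()
        raw: Counter = Counter()
        for p in intra:
            if p.insert_size() > cap:
                continue
            sig = p.signature()
            raw[sig.as_tuple()] += 1
            votes[min(sig.as_tuple(), sig.mirror().as_tuple())] += 1
        if not votes:
            raise ModelError("no pairs eligible for orientation inference")
        best_class = max(sorted(votes), key=lambda sig: votes[sig])
        rep = OrientationSignature(*best_class)
        candidates = sorted([rep.as_tuple(), rep.mirror().as_tuple()])
        best = max(candidates, key=lambda sig: raw[sig])
        expected_orientation = OrientationSignature(*best)

    accepted = {expected_orientation, expected_orientation.mirror()}
    dist = sorted(
        p.insert_size() for p in intra if p.signature() in accepted
    )
    if not dist:
        raise ModelError("no intra-chromosomal pairs in the expected orientation")

    if override is not None:
        i_min, i_max = int(override[0]), int(override[1])
        if i_min >= i_max:
            raise ParameterError(f"override i_min={i_min} >= i_max={i_max}")
    else:
        i_min = nearest_rank(dist, lo_pct)
        i_max = nearest_rank(dist, hi_pct)
        if i_min >= i_max:
            raise ModelError("degenerate insert distribution: i_min >= i_max")

    return InsertSizeModel(
        histogram=dict(Counter(dist)),
        i_min=i_min,
        i_max=i_max,
        expected_orientation=expected_orientation,
        n_pairs_used=len(dist),
    )


def classify_pair(pair: MatePair, model: InsertSizeModel) -> PairClass:
    """Consistent iff same chromosome, expected orientation, in-range insert.

    The expected orientation and its mirror (the same library sequenced off
    the opposite strand) both count as expected.  Inconsistent pairs carry
    the first failing reason in the order inter_chromosomal, orientation,
    too_close/too_far.
    """
    if not pair.intra:
        return PairClass(INCONSISTENT, REASON_INTER)
    sig = pair.signature()
    exp = model.expected_orientation
    if sig != exp and sig != exp.mirror():
        return PairClass(INCONSISTENT, REASON_ORIENT)
    insert = pair.insert_size()
    if insert < model.i_min:
        return PairClass(INCONSISTENT, REASON_TOO_CLOSE)
    if insert > model.i_max:
        return PairClass(INCONSISTENT, REASON_TOO_FAR)
    return PairClass(CONSISTENT, REASON_OK)


def _clone_key(pair: MatePair) -> tuple:
    return (
        pair.fwd.chrom,
        pair.fwd.start,
        pair.fwd.strand,
        pair.rev.chrom,
        pair.rev.start,
        pair.rev.strand,
    )


def dedup_clonal(pairs: Iterable[MatePair]) -> list[MatePair]:
    """Collapse clonal (PCR/optical) copies to one representative pair.

    Copies share both mapping coordinates and strands; the representative
    with the smallest pair_id is kept.  Output order is deterministic and
    independent of input order; the operation is idempotent.
    """
    best: dict[tuple, MatePair] = {}
    for p in pairs:
        key = _clone_key(p)
        cur = best.get(key)
        if cur is None or p.pair_id < cur.pair_id:
            best[key] = p
    return [best[k] for k in sorted(best)]
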