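"""Coordinate-level mate-pair simulator with planted structural variants.

The simulator operates on mapping coordinates, not sequence: a donor
haplotype is modelled as, per donor chromosome, a list of reference segments
(deletions drop a segment, inversions flip one, insertions add an unmapped
novel segment, translocations add a derived fusion chromosome joining two
reference chromosomes).  Fragments with truncated-normal lengths are placed
uniformly on the donor (variant haplotype with probability
``tumor_fraction``, otherwise the unmodified reference), and each read end
is mapped back through the segment map to reference coordinates and
strands.  Fragments whose read ends straddle a junction or fall in novel
sequence are resampled, mimicking reads that would fail unique mapping.
Pairs away from junctions are consistent; pairs spanning a junction carry
the canonical discordant signature of their variant class.  Truth records
every junction with its realized non-clonal spanning-pair count.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .caller import (
    DELETION,
    INSERTION,
    INVERSION,
    TRANSLOCATION,
    Breakpoint,
)
from .errors import ConfigError
from .model import FORWARD, REVERSE, MatePair, ReadMapping
from .svset import SvSet


@dataclass(frozen=True, slots=True)
class PlantedVariant:
    """A structural variant planted on the donor haplotype.

    ``start``/``end`` are reference coordinates on ``chrom``; insertions use
    ``start == end`` plus ``length`` (novel bp); translocations fuse
    chrom[0, start) to chrom2[pos2, end-of-chrom2).
    """

    kind: str
    chrom: str
    start: int
    end: int
    var_id: str
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (DELETION, INSERTION, INVERSION, TRANSLOCATION):
            raise ConfigError(f"unknown variant kind {self.kind!r}")
        if self.kind == INSERTION:
            if self.start != self.end or self.length <= 0:
                raise ConfigError(f"{self.var_id}: insertion needs start==end and length>0")
        elif self.kind == TRANSLOCATION:
            if self.chrom2 is None or self.pos2 is None:
                raise ConfigError(f"{self.var_id}: translocation needs chrom2/pos2")
        elif not self.start < self.end:
            raise ConfigError(f"{self.var_id}: start must be < end")


@dataclass(slots=True)
class SimulationConfig:
    genome: Dict[str, int]
    variants: List[PlantedVariant]
    n_pairs: int
    insert_mean: int = 5000
    insert_sd: int = 300
    read_len: int = 50
    clonal_rate: float = 0.0
    noise_rate: float = 0.0
    tumor_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genome:
            raise ConfigError("empty genome")
        min_len = min(self.genome.values())
        if not (2 * self.read_len < self.insert_mean < min_len):
            raise ConfigError("insert_mean must lie in (2*read_len, min chrom length)")
        for rate in (self.clonal_rate, self.noise_rate):
            if not 0 <= rate <= 1:
                raise ConfigError("rates must be in [0, 1]")
        if not 0 < self.tumor_fraction <= 1:
            raise ConfigError("tumor_fraction must be in (0, 1]")
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        for v in self.variants:
            chroms = [v.chrom] + ([v.chrom2] if v.chrom2 else [])
            for c in chroms:
                if c not in self.genome:
                    raise ConfigError(f"{v.var_id}: chromosome {c} not in genome")
            if v.kind == TRANSLOCATION:
                if not (0 < v.start < self.genome[v.chrom]):
                    raise ConfigError(f"{v.var_id}: breakend outside chromosome")
                if not (0 < v.pos2 < self.genome[v.chrom2]):
                    raise ConfigError(f"{v.var_id}: breakend outside chromosome")
            else:
                if not (0 <= v.start and v.end <= self.genome[v.chrom]):
                    raise ConfigError(f"{v.var_id}: variant outside chromosome")

    @property
    def insert_bounds(self) -> Tuple[int, int]:
        """True truncation range of the fragment length distribution."""
        return (
            int(self.insert_mean - 4 * self.insert_sd),
            int(self.insert_mean + 4 * self.insert_sd),
        )

    def to_yaml(self, path) -> None:
        doc = {
            "genome": dict(self.genome),
            "n_pairs": self.n_pairs,
            "insert_mean": self.insert_mean,
            "insert_sd": self.insert_sd,
            "read_len": self.read_len,
            "clonal_rate": self.clonal_rate,
            "noise_rate": self.noise_rate,
            "tumor_fraction": self.tumor_fraction,
            "seed": self.seed,
            "variants": [
                {k: v for k, v in asdict(var).items() if v not in (None,)}
                for var in self.variants
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        variants = [PlantedVariant(**v) for v in doc.pop("variants", [])]
        return cls(variants=variants, **doc)


# -- donor haplotype ------------------------------------------------------


@dataclass(frozen=True, slots=True)
class _Segment:
    ref_chrom: Optional[str]  # None => novel (unmappable) sequence
    ref_start: int
    ref_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(slots=True)
class _DonorChrom:
    name: str
    segments: List[_Segment]
    junctions: List[Optional[str]]  # junctions[i] between segments[i], [i+1]
    offsets: List[int] = field(default_factory=list)  # cumulative donor starts

    def finalize(self) -> None:
        self.offsets = [0]
        for seg in self.segments:
            self.offsets.append(self.offsets[-1] + seg.length)

    @property
    def length(self) -> int:
        return self.offsets[-1]

    def locate(self, pos: int) -> int:
        return bisect.bisect_right(self.offsets, pos) - 1


def _build_donor(config: SimulationConfig) -> List[_DonorChrom]:
    intra: Dict[str, List[PlantedVariant]] = {}
    fusions: List[PlantedVariant] = []
    for v in config.variants:
        if v.kind == TRANSLOCATION:
            fusions.append(v)
        else:
            intra.setdefault(v.chrom, []).append(v)

    donors: List[_DonorChrom] = []
    for chrom in sorted(config.genome):
        length = config.genome[chrom]
        evs = sorted(intra.get(chrom, []), key=lambda v: v.start)
        for prev, cur in zip(evs, evs[1:]):
            if prev.end > cur.start:
                raise ConfigError(f"overlapping variants {prev.var_id}/{cur.var_id}")
        segments: List[_Segment] = []
        junctions: List[Optional[str]] = []

        def push(seg: _Segment, junction_before: Optional[str]) -> None:
            if segments:
                junctions.append(junction_before)
            segments.append(seg)

        cursor = 0
        pending: Optional[str] = None
        for v in evs:
            if v.start > cursor:
                push(_Segment(chrom, cursor, v.start, "+"), pending)
                pending = None
            elif pending is not None:
                raise ConfigError(f"{v.var_id}: variants must not be adjacent")
            if v.kind == DELETION:
                pending = v.var_id
                cursor = v.end
            elif v.kind == INVERSION:
                push(_Segment(chrom, v.start, v.end, "-"), f"{v.var_id}/L")
                pending = f"{v.var_id}/R"
                cursor = v.end
            elif v.kind == INSERTION:
                push(_Segment(None, 0, v.length, "+"), v.var_id)
                pending = v.var_id
                cursor = v.start
        if cursor < length:
            push(_Segment(chrom, cursor, length, "+"), pending)
        elif pending is not None:
            raise ConfigError(f"variant on {chrom} touches the chromosome end")
        dc = _DonorChrom(chrom, segments, junctions)
        dc.finalize()
        donors.append(dc)

    for v in fusions:
        dc = _DonorChrom(
            v.var_id,
            [
                _Segment(v.chrom, 0, v.start, "+"),
                _Segment(v.chrom2, v.pos2, config.genome[v.chrom2], "+"),
            ],
            [v.var_id],
        )
        dc.finalize()
        donors.append(dc)
    return donors


def _reference_donor(config: SimulationConfig) -> List[_DonorChrom]:
    donors = []
    for chrom in sorted(config.genome):
        dc = _DonorChrom(chrom, [_Segment(chrom, 0, config.genome[chrom], "+")], [])
        dc.finalize()
        donors.append(dc)
    return donors


def _junction_points(left: _Segment, right: _Segment) -> Tuple[Tuple[str, int], Tuple[str, int]]:
    pl = (left.ref_chrom, left.ref_end if left.strand == "+" else left.ref_start)
    pr = (right.ref_chrom, right.ref_start if right.strand == "+" else right.ref_end)
    return pl, pr


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def truth_breakpoints(config: SimulationConfig) -> List[Tuple[str, Breakpoint]]:
    """One truth record per junction of the donor haplotype.

    Returns (junction label, breakpoint) with zero support counts; the
    simulation fills in realized spanning-pair counts.  Inversions produce
    two junctions (one per edge) with distinct strand signatures.
    """
    out: List[Tuple[str, Breakpoint]] = []
    class_of = {}
    for v in config.variants:
        class_of[v.var_id] = v.kind
    for dc in _build_donor(config):
        for i, label in enumerate(dc.junctions):
            if label is None:
                continue
            left, right = dc.segments[i], dc.segments[i + 1]
            if left.ref_chrom is None or right.ref_chrom is None:
                # novel-segment gaps: the variant junction is recorded once,
                # between the flanks (handled by the flank-to-flank entry)
                if left.ref_chrom is None:
                    continue
                right = dc.segments[i + 2]
            (cl, pl), (cr, pr) = _junction_points(left, right)
            strand_l = left.strand
            strand_r = _flip(right.strand)
            if (cl, pl) <= (cr, pr):
                ca, pa, cb, pb = cl, pl, cr, pr
                sa, sb = strand_l, strand_r
            else:
                ca, pa, cb, pb = cr, pr, cl, pl
                sa, sb = strand_r, strand_l
            base = label.split("/")[0]
            out.append(
                (
                    label,
                    Breakpoint(
                        chromA=ca, b1=pa, e1=pa, chromB=cb, b2=pb, e2=pb,
                        support=0, effective_support=0,
                        variant_class=class_of[base], sample="truth", name=label,
                        strandA=sa, strandB=sb,
                    ),
                )
            )
    return out


# -- simulation -----------------------------------------------------------


@dataclass(slots=True)
class SimulatedDataset:
    pairs: List[MatePair]
    truth: SvSet
    truth_spanning: Dict[str, List[str]]  # junction label -> non-clonal pair ids
    config: SimulationConfig

    def spanning_counts(self) -> Dict[str, int]:
        return {label: len(ids) for label, ids in self.truth_spanning.items()}


def _map_read(
    dc: _DonorChrom, a: int, b: int
) -> Optional[Tuple[str, int, int, str, int]]:
    """Map donor interval [a, b) to reference; None if novel or straddling.

    Returns (chrom, start, end, strand, segment index).
    """
    i = dc.locate(a)
    seg = dc.segments[i]
    if b > dc.offsets[i + 1]:
        return None
    if seg.ref_chrom is None:
        return None
    off_a = a - dc.offsets[i]
    off_b = b - dc.offsets[i]
    if seg.strand == "+":
        return (seg.ref_chrom, seg.ref_start + off_a, seg.ref_start + off_b, "+", i)
    return (
        seg.ref_chrom,
        seg.ref_start + (seg.length - off_b),
        seg.ref_start + (seg.length - off_a),
        "-",
        i,
    )


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the simulation; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    tumor_donor = _build_donor(config)
    ref_donor = _reference_donor(config)
    truth = truth_breakpoints(config)
    spanning: Dict[str, List[str]] = {label: [] for label, _ in truth}

    def haplotype(tumor: bool) -> List[_DonorChrom]:
        return tumor_donor if tumor else ref_donor

    lengths = {
        True: np.array([dc.length for dc in tumor_donor], dtype=float),
        False: np.array([dc.length for dc in ref_donor], dtype=float),
    }
    probs = {k: v / v.sum() for k, v in lengths.items()}
    lo, hi = config.insert_bounds
    rl = config.read_len

    pairs: List[MatePair] = []
    for i in range(config.n_pairs):
        for _attempt in range(1000):
            tumor = bool(rng.random() < config.tumor_fraction)
            donors = haplotype(tumor)
            ci = int(rng.choice(len(donors), p=probs[tumor]))
            dc = donors[ci]
            flen = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            flen = min(max(flen, lo), hi)
            if flen > dc.length:
                continue
            start = int(rng.integers(0, dc.length - flen + 1))
            m1 = _map_read(dc, start, start + rl)
            m2 = _map_read(dc, start + flen - rl, start + flen)
            if m1 is None or m2 is None:
                continue
            pid = f"sim{i:07d}"
            # read1 is donor-forward at the fragment 5' end, read2
            # donor-reverse at the 3' end; mapped strands flip inside
            # inverted segments
            fwd = ReadMapping(m1[0], m1[1], m1[2], m1[3], f"{pid}/1", FORWARD)
            rev = ReadMapping(m2[0], m2[1], m2[2], _flip(m2[3]), f"{pid}/2", REVERSE)
            if (fwd.chrom, fwd.start, fwd.end) == (rev.chrom, rev.start, rev.end):
                continue
            pairs.append(MatePair(pid, fwd, rev))
            si, sj = m1[4], m2[4]
            if tumor and sj > si:
                label = None
                if sj == si + 1:
                    label = dc.junctions[si]
                elif sj == si + 2 and dc.segments[si + 1].ref_chrom is None:
                    label = dc.junctions[si]
                if label is not None and label in spanning:
                    spanning[label].append(pid)
            break
        else:
            raise ConfigError("could not place a fragment; check variant sizes")

    n_noise = int(round(config.noise_rate * config.n_pairs))
    ref_chroms = sorted(config.genome)
    for i in range(n_noise):
        pid = f"noise{i:06d}"
        reads = []
        for role in (FORWARD, REVERSE):
            chrom = ref_chroms[int(rng.integers(0, len(ref_chroms)))]
            pos = int(rng.integers(0, config.genome[chrom] - rl))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(
                ReadMapping(chrom, pos, pos + rl, strand, f"{pid}/{role[0]}", role)
            )
        if (reads[0].chrom, reads[0].start) == (reads[1].chrom, reads[1].start):
            continue
        pairs.append(MatePair(pid, reads[0], reads[1]))

    if config.clonal_rate > 0:
        dup_flags = rng.random(len(pairs)) < config.clonal_rate
        clones = []
        for flag, p in zip(dup_flags, pairs):
            if flag:
                dup_id = f"{p.pair_id}.dup"
                clones.append(
                    MatePair(
                        dup_id,
                        ReadMapping(
                            p.fwd.chrom, p.fwd.start, p.fwd.end, p.fwd.strand,
                            f"{dup_id}/1", FORWARD,
                        ),
                        ReadMapping(
                            p.rev.chrom, p.rev.start, p.rev.end, p.rev.strand,
                            f"{dup_id}/2", REVERSE,
                        ),
                    )
                )
        pairs.extend(clones)

    truth_bps = [
        Breakpoint(
            chromA=bp.chromA, b1=bp.b1, e1=bp.e1,
            chromB=bp.chromB, b2=bp.b2, e2=bp.e2,
            support=len(spanning[label]), effective_support=len(spanning[label]),
            variant_class=bp.variant_class, sample="truth", name=label,
            strandA=bp.strandA, strandB=bp.strandB,
        )
        for label, bp in truth
    ]
    truth_set = SvSet("truth", truth_bps, i_max=hi)
    return SimulatedDataset(
        pairs=pairs, truth=truth_set, truth_spanning=spanning, config=config
    )


def donor_genome_size(config: SimulationConfig) -> int:
    """Total length of the variant-bearing haplotype (fusions included)."""
    return sum(dc.length for dc in _build_donor(config))


def pairs_to_tsv(pairs: Sequence[MatePair], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pair_id\tchrom1\tstart1\tend1\tstrand1\tchrom2\tstart2\tend2\tstrand2\n"
        )
        for p in pairs:
            fh.write(
                f"{p.pair_id}\t{p.fwd.chrom}\t{p.fwd.start}\t{p.fwd.end}\t{p.fwd.strand}"
                f"\t{p.rev.chrom}\t{p.rev.start}\t{p.rev.end}\t{p.rev.strand}\n"
            )


# -- random study designs -------------------------------------------------


def random_variants(
    genome: Dict[str, int],
    rng: np.random.Generator,
    n_deletions: int = 0,
    n_insertions: int = 0,
    n_inversions: int = 0,
    n_translocations: int = 0,
    size_range: Tuple[int, int] = (20_000, 40_000),
    insertion_size_range: Tuple[int, int] = (2_500, 3_500),
    spacing: int = 60_000,
    margin: int = 100_000,
    fusion_arm: int = 150_000,
) -> List[PlantedVariant]:
    """Draw non-overlapping variants with breakends well separated.

    ``spacing`` keeps breakpoint footprints of distinct variants from
    merging in the caller; ``margin`` keeps variants clear of chromosome
    ends; fusion breakends sit ``fusion_arm`` bp into each chromosome so
    fusion chromosomes stay short.
    """
    chroms = sorted(genome)
    reserved: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}

    def free(chrom: str, lo: int, hi: int) -> bool:
        return all(
            hi + spacing <= s or lo - spacing >= e for s, e in reserved[chrom]
        )

    out: List[PlantedVariant] = []
    counter = 0

    def place_intra(kind: str, n: int) -> None:
        nonlocal counter
        for _ in range(n):
            for _attempt in range(10_000):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                if kind == INSERTION:
                    size = 0
                    length = int(rng.integers(*insertion_size_range))
                else:
                    size = int(rng.integers(*size_range))
                    length = 0
                hi_start = genome[chrom] - margin - size
                if hi_start <= margin:
                    continue
                start = int(rng.integers(margin, hi_start))
                end = start + size if kind != INSERTION else start
                if not free(chrom, start, max(end, start + 1)):
                    continue
                reserved[chrom].append((start, max(end, start + 1)))
                counter += 1
                out.append(
                    PlantedVariant(
                        kind=kind, chrom=chrom, start=start, end=end,
                        var_id=f"{kind[:3]}_{counter:03d}", length=length,
                    )
                )
                break
            else:
                raise ConfigError("could not place variants; genome too crowded")

    place_intra(DELETION, n_deletions)
    place_intra(INSERTION, n_insertions)
    place_intra(INVERSION, n_inversions)

    for _ in range(n_translocations):
        for _attempt in range(10_000):
            ca, cb = rng.choice(len(chroms), size=2, replace=False)
            ca, cb = chroms[int(ca)], chroms[int(cb)]
            pos_a = fusion_arm + int(rng.integers(0, 4 * spacing))
            pos_b = genome[cb] - fusion_arm - int(rng.integers(0, 4 * spacing))
            if not (free(ca, pos_a, pos_a + 1) and free(cb, pos_b, pos_b + 1)):
                continue
            reserved[ca].append((pos_a, pos_a + 1))
            reserved[cb].append((pos_b, pos_b + 1))
            counter += 1
            out.append(
                PlantedVariant(
                    kind=TRANSLOCATION, chrom=ca, start=pos_a, end=pos_a,
                    chrom2=cb, pos2=pos_b, var_id=f"tra_{counter:03d}",
                )
            )
            break
        else:
            raise ConfigError("could not place translocations")
    return out
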