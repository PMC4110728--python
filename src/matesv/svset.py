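"""Breakpoint set algebra, multi-sample reporting, somatic triage, benchmarks.

Two breakpoints B1 = chrA:[b1,e1]-chrB:[b2,e2] and B2 = chrA:[b1',e1']-
chrB:[b2',e2'] overlap iff they connect the same canonical chromosome pair
and, on each side, the minimum of the four endpoint distances
min(|b-b'|, |e-e'|, |b-e'|, |e-b'|) does not exceed I_max, where I_max is
the larger of the two experiments' maximum insert sizes.  Overlapping
breakpoints are treated as identical for set operations; the relation is
symmetric and reflexive but NOT transitive, so intersection/difference never
chain overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .caller import Breakpoint
from .errors import FormatError
from .tracks import FeatureTrack

BEDPE_COLUMNS = (
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "variant_class", "effective_support", "sample",
)


@dataclass
class SvSet:
    """A named collection of breakpoints plus the i_max used at calling time."""

    name: str
    breakpoints: List[Breakpoint]
    i_max: int

    def __post_init__(self) -> None:
        if self.i_max <= 0:
            raise ValueError("i_max must be > 0")

    def __len__(self) -> int:
        return len(self.breakpoints)


def _side_overlap(b: int, e: int, b2: int, e2: int, i_max: int) -> bool:
    return min(abs(b - b2), abs(e - e2), abs(b - e2), abs(e - b2)) <= i_max


def breakpoints_overlap(x: Breakpoint, y: Breakpoint, i_max: int) -> bool:
    """Min-of-four-distances overlap on both sides; symmetric in x, y."""
    if (x.chromA, x.chromB) != (y.chromA, y.chromB):
        return False
    return _side_overlap(x.b1, x.e1, y.b1, y.e1, i_max) and _side_overlap(
        x.b2, x.e2, y.b2, y.e2, i_max
    )


class BreakpointIndex:
    """Interval index over side-A footprints for fast overlap candidates.

    The index is a prefilter only (expanded-interval intersection is a
    strict superset of the endpoint-distance predicate, e.g. for nested
    footprints); every candidate is re-checked with the exact formula, so
    results equal the all-pairs evaluation.
    """

    def __init__(self, breakpoints: Sequence[Breakpoint], i_max: int):
        self.i_max = i_max
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for bp in breakpoints:
            tree = self._trees.setdefault((bp.chromA, bp.chromB), IntervalTree())
            tree.addi(bp.b1, bp.e1 + 1, bp)

    def overlapping(self, query: Breakpoint) -> List[Breakpoint]:
        tree = self._trees.get((query.chromA, query.chromB))
        if tree is None:
            return []
        hits = tree.overlap(query.b1 - self.i_max, query.e1 + self.i_max + 1)
        return [
            iv.data for iv in hits if breakpoints_overlap(query, iv.data, self.i_max)
        ]

    def any_overlap(self, query: Breakpoint) -> bool:
        return bool(self.overlapping(query))


def pooled_i_max(*sets: SvSet) -> int:
    return max(s.i_max for s in sets)


def intersect_sets(a: SvSet, b: SvSet) -> Tuple[SvSet, SvSet]:
    """Partition A into (A n B, A \\ B) under the overlap predicate.

    Defined on A's elements (swap arguments for the other direction);
    I_max is the max of the two sets' values.
    """
    i_max = pooled_i_max(a, b)
    index = BreakpointIndex(b.breakpoints, i_max)
    both = [bp for bp in a.breakpoints if index.any_overlap(bp)]
    only = [bp for bp in a.breakpoints if not index.any_overlap(bp)]
    return (
        SvSet(f"{a.name}_and_{b.name}", both, a.i_max),
        SvSet(f"{a.name}_not_{b.name}", only, a.i_max),
    )


def triage_somatic(tumor: SvSet, panels: Sequence[SvSet]) -> Tuple[SvSet, SvSet]:
    """Split tumor breakpoints into germline-like vs putatively somatic.

    A breakpoint overlapping any breakpoint of any panel (population
    polymorphism) set is likely inherited; the rest are putatively somatic.
    """
    if not panels:
        return (
            SvSet(f"{tumor.name}_germline_like", [], tumor.i_max),
            SvSet(f"{tumor.name}_putative_somatic", list(tumor.breakpoints), tumor.i_max),
        )
    i_max = max(tumor.i_max, max(p.i_max for p in panels))
    indices = [BreakpointIndex(p.breakpoints, i_max) for p in panels]
    germ, soma = [], []
    for bp in tumor.breakpoints:
        (germ if any(ix.any_overlap(bp) for ix in indices) else soma).append(bp)
    return (
        SvSet(f"{tumor.name}_germline_like", germ, tumor.i_max),
        SvSet(f"{tumor.name}_putative_somatic", soma, tumor.i_max),
    )


def _footprint_gene_gap(bp: Breakpoint, chrom: str, gs: int, ge: int) -> Optional[int]:
    gaps = []
    for c, lo, hi in ((bp.chromA, bp.b1, bp.e1), (bp.chromB, bp.b2, bp.e2)):
        if c == chrom:
            gaps.append(max(0, gs - hi, lo - ge))
    return min(gaps) if gaps else None


def report_multiple(
    sets: Sequence[SvSet],
    genes: Optional[FeatureTrack] = None,
    gene_window: int = 2000,
) -> pd.DataFrame:
    """Breakpoint-level overlap counts across sets plus nearby gene names.

    One row per breakpoint of every input set; ``overlap_<set>`` columns
    count overlapping breakpoints in each other set (pooled I_max), and
    ``genes`` lists annotation intervals within ``gene_window`` bp of either
    footprint (distance 0 for direct overlap).
    """
    if not sets:
        raise ValueError("need at least one breakpoint set")
    i_max = pooled_i_max(*sets)
    indices = {s.name: BreakpointIndex(s.breakpoints, i_max) for s in sets}
    gene_trees = genes.trees() if genes is not None and len(genes) else {}

    rows = []
    for s in sets:
        for bp in s.breakpoints:
            row = {
                "set": s.name,
                "name": bp.name,
                "chrom1": bp.chromA, "start1": bp.b1, "end1": bp.e1,
                "chrom2": bp.chromB, "start2": bp.b2, "end2": bp.e2,
                "variant_class": bp.variant_class,
                "support": bp.support,
            }
            for other in sets:
                if other.name == s.name:
                    continue
                row[f"overlap_{other.name}"] = len(
                    indices[other.name].overlapping(bp)
                )
            nearby: set[str] = set()
            for chrom, lo, hi in ((bp.chromA, bp.b1, bp.e1), (bp.chromB, bp.b2, bp.e2)):
                tree = gene_trees.get(chrom)
                if tree is None:
                    continue
                for iv in tree.overlap(lo - gene_window, hi + gene_window + 1):
                    gap = _footprint_gene_gap(bp, chrom, iv.begin, iv.end)
                    if gap is not None and gap <= gene_window:
                        nearby.add(iv.data[1])
            row["genes"] = ",".join(sorted(nearby))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BenchmarkCurve:
    """Sensitivity/specificity trade-off across support thresholds.

    ``points`` holds (min_support, total_calls, true_positives); the total
    call count serves as a surrogate for the unknown false-positive rate.
    """

    points: List[Tuple[int, int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["min_support", "total_calls", "true_positives"]
        )


def benchmark_curve(
    calls: SvSet, truth: SvSet, thresholds: Sequence[int]
) -> BenchmarkCurve:
    """Vary the minimum supporting-pair threshold and count calls/recovered truth."""
    i_max = pooled_i_max(calls, truth)
    points = []
    for t in sorted(thresholds):
        retained = [bp for bp in calls.breakpoints if bp.support >= t]
        index = BreakpointIndex(retained, i_max)
        tp = sum(1 for bp in truth.breakpoints if index.any_overlap(bp))
        points.append((t, len(retained), tp))
    return BenchmarkCurve(points)


def match_calls(
    calls: Sequence[Breakpoint],
    truth: Sequence[Breakpoint],
    i_max: int,
    require_class: bool = True,
    require_strands: bool = False,
) -> Dict[int, List[int]]:
    """truth index -> list of call indices overlapping it (optionally same class/strands)."""
    out: Dict[int, List[int]] = {}
    for ti, t in enumerate(truth):
        hits = []
        for ci, c in enumerate(calls):
            if require_class and c.variant_class != t.variant_class:
                continue
            if require_strands and (c.strandA, c.strandB) != (t.strandA, t.strandB):
                continue
            if breakpoints_overlap(c, t, i_max):
                hits.append(ci)
        out[ti] = hits
    return out


# -- BEDPE ----------------------------------------------------------------


def write_bedpe(svset: SvSet, path) -> None:
    """Write breakpoints as 13-column BEDPE (0-based half-open)."""
    with open(path, "w") as fh:
        for bp in svset.breakpoints:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        bp.chromA, bp.b1, bp.e1, bp.chromB, bp.b2, bp.e2,
                        bp.name, bp.support, bp.strandA, bp.strandB,
                        bp.variant_class, bp.effective_support, bp.sample,
                    )
                )
                + "\n"
            )


def read_bedpe(path, name: Optional[str] = None, i_max: int = 1) -> SvSet:
    """Read a BEDPE file; the extra class/support/sample columns are optional."""
    import os

    breakpoints: List[Breakpoint] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(
                    f"{path}:{lineno}: BEDPE needs >= 10 columns, got {len(parts)}"
                )
            try:
                support = int(parts[7])
                bp = Breakpoint(
                    chromA=parts[0], b1=int(parts[1]), e1=int(parts[2]),
                    chromB=parts[3], b2=int(parts[4]), e2=int(parts[5]),
                    name=parts[6], support=support,
                    strandA=parts[8], strandB=parts[9],
                    variant_class=parts[10] if len(parts) > 10 else "unknown",
                    effective_support=int(parts[11]) if len(parts) > 11 else support,
                    sample=parts[12] if len(parts) > 12 else "unknown",
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            breakpoints.append(bp)
    set_name = name if name is not None else os.path.basename(str(path))
    return SvSet(set_name, breakpoints, i_max=i_max)
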