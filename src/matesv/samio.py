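"""SAM/BAM ingestion and emission of mate pairs (via pysam).

The caller's input contract is *uniquely mapped* mate pairs: records flagged
secondary/supplementary and records with mapping quality 0 (the conventional
multi-mapper marker) are dropped and counted.  Name grouping is performed
internally, so coordinate- and name-sorted inputs both work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import pysam

from .errors import FormatError
from .model import FORWARD, REVERSE, MatePair, ReadMapping


@dataclass(slots=True)
class SkipReport:
    """Counts of records/pairs excluded during parsing."""

    n_records: int = 0
    n_unpaired_flag: int = 0
    n_secondary: int = 0
    n_unmapped: int = 0
    n_mapq0: int = 0
    n_no_cigar: int = 0
    n_incomplete_pairs: int = 0
    n_self_pairs: int = 0
    n_pairs: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(slots=True)
class ParsedPairs:
    pairs: list[MatePair]
    skipped: SkipReport
    chrom_order: list[str]


def read_mate_pairs(path) -> ParsedPairs:
    """Read uniquely mapped mate pairs from a SAM or BAM file.

    Returns one :class:`MatePair` per read name with exactly two usable
    primary ends (read1 -> forward role, read2 -> reverse role); 1-based SAM
    positions become 0-based half-open internally.  Skipped records are
    tallied in the report rather than raised, so a file with no usable pairs
    yields an empty collection.
    """
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot open {path}: {exc}") from exc

    report = SkipReport()
    ends: dict[str, dict[str, ReadMapping]] = {}
    with af:
        chrom_order = list(af.references)
        try:
            for rec in af.fetch(until_eof=True):
                report.n_records += 1
                if not rec.is_paired:
                    report.n_unpaired_flag += 1
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    report.n_secondary += 1
                    continue
                if rec.is_unmapped or rec.reference_id < 0:
                    report.n_unmapped += 1
                    continue
                if rec.mapping_quality == 0:
                    report.n_mapq0 += 1
                    continue
                if rec.reference_end is None:
                    report.n_no_cigar += 1
                    continue
                role = FORWARD if rec.is_read1 else REVERSE
                mapping = ReadMapping(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    read_id=f"{rec.query_name}/{1 if rec.is_read1 else 2}",
                    role=role,
                )
                slot = ends.setdefault(rec.query_name, {})
                # a second primary record for the same end would be malformed;
                # keep the first occurrence
                slot.setdefault(role, mapping)
        except ValueError as exc:
            raise FormatError(f"unparseable alignment stream {path}: {exc}") from exc

    pairs: list[MatePair] = []
    for qname in sorted(ends):
        slot = ends[qname]
        if FORWARD not in slot or REVERSE not in slot:
            report.n_incomplete_pairs += 1
            continue
        fwd, rev = slot[FORWARD], slot[REVERSE]
        if (fwd.chrom, fwd.start, fwd.end) == (rev.chrom, rev.start, rev.end):
            report.n_self_pairs += 1
            continue
        pairs.append(MatePair(pair_id=qname, fwd=fwd, rev=rev))
    report.n_pairs = len(pairs)
    return ParsedPairs(pairs=pairs, skipped=report, chrom_order=chrom_order)


def write_sam(pairs: Iterable[MatePair], path, genome: dict[str, int]) -> None:
    """Write mate pairs as a SAM file with placeholder sequences.

    Round-trips through :func:`read_mate_pairs` coordinate-exactly.
    """
    names = list(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(genome[c])} for c in names],
    }
    tid = {c: i for i, c in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for pair in pairs:
            for mapping, mate in ((pair.fwd, pair.rev), (pair.rev, pair.fwd)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = pair.pair_id
                a.is_paired = True
                a.is_read1 = mapping.role == FORWARD
                a.is_read2 = mapping.role == REVERSE
                a.is_reverse = mapping.strand == "-"
                a.mate_is_reverse = mate.strand == "-"
                a.reference_id = tid[mapping.chrom]
                a.reference_start = mapping.start
                a.mapping_quality = 60
                length = mapping.end - mapping.start
                a.cigartuples = [(0, length)]
                a.query_sequence = "N" * length
                a.next_reference_id = tid[mate.chrom]
                a.next_reference_start = mate.start
                if mapping.chrom == mate.chrom:
                    outer = max(mapping.end, mate.end) - min(mapping.start, mate.start)
                    a.template_length = outer if mapping.start <= mate.start else -outer
                out.write(a)
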