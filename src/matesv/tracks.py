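"""Genomic feature tracks (peaks, genes) and their file formats."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .errors import FormatError


@dataclass
class FeatureTrack:
    """A named collection of genomic intervals (0-based half-open).

    Per-chromosome sorted-endpoint arrays (for vectorized window counting)
    and interval trees (for identity-preserving queries) are built lazily
    and cached.
    """

    name: str
    intervals: List[Tuple[str, int, int]]
    names: Optional[List[str]] = None
    source: str = ""
    _arrays: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = field(
        default=None, repr=False, compare=False
    )
    _trees: Optional[Dict[str, IntervalTree]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not start < end:
                raise ValueError(f"track {self.name}: empty interval {chrom}:{start}-{end}")
        if self.names is not None and len(self.names) != len(self.intervals):
            raise ValueError("names must parallel intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """chrom -> (sorted starts, sorted ends) of the intervals there."""
        if self._arrays is None:
            by_chrom: Dict[str, List[Tuple[int, int]]] = {}
            for chrom, start, end in self.intervals:
                by_chrom.setdefault(chrom, []).append((start, end))
            self._arrays = {
                chrom: (
                    np.sort(np.array([s for s, _ in ivs], dtype=np.int64)),
                    np.sort(np.array([e for _, e in ivs], dtype=np.int64)),
                )
                for chrom, ivs in by_chrom.items()
            }
        return self._arrays

    def trees(self) -> Dict[str, IntervalTree]:
        if self._trees is None:
            trees: Dict[str, IntervalTree] = {}
            for i, (chrom, start, end) in enumerate(self.intervals):
                label = self.names[i] if self.names else f"{self.name}_{i}"
                trees.setdefault(chrom, IntervalTree()).addi(start, end, (i, label))
            self._trees = trees
        return self._trees


def read_bed(path, name: Optional[str] = None) -> FeatureTrack:
    """Read a BED3+ file; column 4 is used as the feature name when present."""
    intervals: List[Tuple[str, int, int]] = []
    names: List[str] = []
    have_names = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            intervals.append((parts[0], start, end))
            if len(parts) >= 4:
                have_names = True
                names.append(parts[3])
            else:
                names.append(f"feature_{lineno}")
    import os

    track_name = name if name is not None else os.path.basename(str(path))
    return FeatureTrack(
        name=track_name,
        intervals=intervals,
        names=names if have_names else None,
        source=str(path),
    )


def read_genes_gff3(path, name: Optional[str] = None) -> FeatureTrack:
    """Extract gene features from a GFF3 file as a track."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    intervals: List[Tuple[str, int, int]] = []
    names: List[str] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_name = (
            feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        )
        intervals.append((feat.seqid, feat.start - 1, feat.end))  # GFF is 1-based closed
        names.append(gene_name)
    import os

    return FeatureTrack(
        name=name if name is not None else os.path.basename(str(path)),
        intervals=intervals,
        names=names,
        source=str(path),
    )


def read_gene_track(path, name: Optional[str] = None) -> FeatureTrack:
    """Dispatch BED vs GFF3 gene annotation on file extension."""
    p = str(path).lower()
    if p.endswith((".gff", ".gff3")):
        return read_genes_gff3(path, name=name)
    return read_bed(path, name=name)


def write_bed(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(track.intervals):
            label = track.names[i] if track.names else f"{track.name}_{i}"
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column chrom<TAB>length file -> {chrom: length}."""
    genome: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom<TAB>length")
            genome[parts[0]] = int(parts[1])
    if not genome:
        raise FormatError(f"{path}: empty chrom sizes file")
    return genome


def write_chrom_sizes(genome: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")
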