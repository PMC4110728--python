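"""Permutation-based enrichment of epigenomic features around breakpoints.

Each breakpoint contributes a window of +/- ``radius`` bp (default 50 kb)
around the midpoint of each of its two footprints (merged into one window
when both sides sit on the same chromosome and the windows overlap).  The
observed statistic is the number of (feature, window) incidences.  The null
re-places every window uniformly at random on its own chromosome, keeping
the feature track fixed, so the track's spatial clustering — the dominant
source of spurious enrichment — is preserved.  Enrichment is computed
separately per variant class; both tails are reported because depletion of
repressive marks is as interpretable as enrichment of active ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .caller import Breakpoint, VARIANT_CLASSES
from .errors import ParameterError
from .svset import SvSet
from .tracks import FeatureTrack

ALL_CLASSES = "all"
_CLASS_ORDER = VARIANT_CLASSES + (ALL_CLASSES,)


@dataclass(slots=True)
class EnrichmentConfig:
    radius: int = 50_000
    n_perm: int = 1000
    seed: int = 0
    genome: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("radius must be > 0")
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")


@dataclass(slots=True)
class EnrichmentResult:
    track: str
    variant_class: str
    observed: int
    null_mean: float
    null_sd: float
    fold: float
    p_enrich: float
    p_deplete: float
    n_windows: int
    n_breakpoints: int


@dataclass(frozen=True, slots=True)
class Window:
    """A breakpoint-anchored counting window: center +/- halfwidth, clipped."""

    chrom: str
    center: int
    halfwidth: int


def breakpoint_windows(
    breakpoints: Sequence[Breakpoint], radius: int
) -> List[Window]:
    """Two windows per breakpoint (footprint midpoints), merged when they
    overlap on one chromosome; sorted for order-independence."""
    windows: List[Window] = []
    for bp in breakpoints:
        la = (bp.b1 + bp.e1) // 2
        lb = (bp.b2 + bp.e2) // 2
        if bp.chromA == bp.chromB and abs(lb - la) <= 2 * radius:
            lo, hi = min(la, lb), max(la, lb)
            windows.append(
                Window(bp.chromA, (lo + hi) // 2, (hi - lo + 1) // 2 + radius)
            )
        else:
            windows.append(Window(bp.chromA, la, radius))
            windows.append(Window(bp.chromB, lb, radius))
    windows.sort(key=lambda w: (w.chrom, w.center, w.halfwidth))
    return windows


def _count_windows_multiplicity(
    track: FeatureTrack,
    chrom: str,
    a: np.ndarray,
    b: np.ndarray,
) -> np.ndarray:
    """Features intersecting each half-open window [a, b) on one chromosome."""
    arrays = track.arrays().get(chrom)
    if arrays is None:
        return np.zeros(a.shape, dtype=np.int64)
    starts, ends = arrays
    return np.searchsorted(starts, b, side="left") - np.searchsorted(
        ends, a, side="right"
    )


def count_features_near(
    breakpoints: Sequence[Breakpoint],
    track: FeatureTrack,
    radius: int,
    genome: Optional[Dict[str, int]] = None,
    unique: bool = False,
) -> int:
    """Observed feature incidences in the breakpoint windows.

    Default counting is with multiplicity (a feature near two windows counts
    twice; the statistic stays additive over breakpoints); ``unique`` counts
    distinct features instead.
    """
    windows = breakpoint_windows(breakpoints, radius)
    return _count_for_windows(windows, track, genome, unique)


def _clip_bounds(
    centers: np.ndarray, halfwidths: np.ndarray, length: Optional[int]
) -> Tuple[np.ndarray, np.ndarray]:
    a = centers - halfwidths
    b = centers + halfwidths
    if length is not None:
        a = np.clip(a, 0, length)
        b = np.clip(b, 0, length)
    return a, b


def _count_for_windows(
    windows: Sequence[Window],
    track: FeatureTrack,
    genome: Optional[Dict[str, int]],
    unique: bool,
) -> int:
    if unique:
        hit: set = set()
        trees = track.trees()
        for w in windows:
            tree = trees.get(w.chrom)
            if tree is None:
                continue
            length = genome.get(w.chrom) if genome else None
            a, b = w.center - w.halfwidth, w.center + w.halfwidth
            if length is not None:
                a, b = max(0, a), min(length, b)
            for iv in tree.overlap(a, b):
                hit.add(iv.data[0])
        return len(hit)
    total = 0
    by_chrom: Dict[str, List[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = by_chrom[chrom]
        centers = np.array([w.center for w in ws], dtype=np.int64)
        hws = np.array([w.halfwidth for w in ws], dtype=np.int64)
        a, b = _clip_bounds(centers, hws, genome.get(chrom) if genome else None)
        total += int(_count_windows_multiplicity(track, chrom, a, b).sum())
    return int(total)


def _null_counts(
    windows: Sequence[Window],
    track: FeatureTrack,
    genome: Dict[str, int],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation null: each window re-centered uniformly on its own chromosome."""
    null = np.zeros(n_perm, dtype=np.int64)
    by_chrom: Dict[str, List[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = by_chrom[chrom]
        length = genome[chrom]
        hws = np.array([w.halfwidth for w in ws], dtype=np.int64)
        centers = rng.integers(0, length, size=(n_perm, len(ws)))
        a, b = _clip_bounds(centers, hws[None, :], length)
        null += _count_windows_multiplicity(track, chrom, a, b).sum(axis=1)
    return null


def permutation_enrichment(
    svset: SvSet,
    track: FeatureTrack,
    config: EnrichmentConfig,
    classes: Optional[Sequence[str]] = None,
    unique: bool = False,
) -> List[EnrichmentResult]:
    """Enrichment/depletion per variant class present in the set.

    p_enrich = (1 + #{null >= observed}) / (n_perm + 1) and p_deplete
    analogously, so p values are never 0 and floor at 1/(n_perm+1).
    Classes with zero breakpoints are omitted.  Results depend only on
    (breakpoint content, track, config), not on input record order.
    """
    if not config.genome:
        raise ParameterError("enrichment requires chromosome lengths")
    for bp in svset.breakpoints:
        for chrom in (bp.chromA, bp.chromB):
            if chrom not in config.genome:
                raise ParameterError(f"chromosome {chrom} missing from genome")
    wanted = list(classes) if classes is not None else list(_CLASS_ORDER)
    results: List[EnrichmentResult] = []
    for vclass in wanted:
        if vclass == ALL_CLASSES:
            bps = list(svset.breakpoints)
        else:
            bps = [b for b in svset.breakpoints if b.variant_class == vclass]
        if not bps:
            continue
        results.append(
            _enrichment_one_class(bps, vclass, track, config, unique)
        )
    return results


def _enrichment_one_class(
    bps: Sequence[Breakpoint],
    vclass: str,
    track: FeatureTrack,
    config: EnrichmentConfig,
    unique: bool,
    rng: Optional[np.random.Generator] = None,
) -> EnrichmentResult:
    windows = breakpoint_windows(bps, config.radius)
    observed = _count_for_windows(windows, track, config.genome, unique)
    if rng is None:
        class_idx = _CLASS_ORDER.index(vclass) if vclass in _CLASS_ORDER else 99
        rng = np.random.default_rng([abs(int(config.seed)), class_idx])
    if unique:
        null = np.array(
            [
                _count_for_windows(
                    _permute_windows(windows, config.genome, rng),
                    track,
                    config.genome,
                    True,
                )
                for _ in range(config.n_perm)
            ]
        )
    else:
        null = _null_counts(windows, track, config.genome, config.n_perm, rng)
    null_mean = float(null.mean())
    null_sd = float(null.std())
    if null_mean > 0:
        fold = observed / null_mean
    else:
        fold = float("inf") if observed > 0 else 1.0
    n = config.n_perm
    p_enrich = (1 + int((null >= observed).sum())) / (n + 1)
    p_deplete = (1 + int((null <= observed).sum())) / (n + 1)
    return EnrichmentResult(
        track=track.name,
        variant_class=vclass,
        observed=int(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        fold=float(fold),
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        n_windows=len(windows),
        n_breakpoints=len(bps),
    )


def _permute_windows(
    windows: Sequence[Window], genome: Dict[str, int], rng: np.random.Generator
) -> List[Window]:
    out = []
    by_chrom: Dict[str, List[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = by_chrom[chrom]
        centers = rng.integers(0, genome[chrom], size=len(ws))
        out.extend(
            Window(chrom, int(c), w.halfwidth) for c, w in zip(centers, ws)
        )
    return out


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track": r.track,
                "variant_class": r.variant_class,
                "observed": r.observed,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "fold": r.fold,
                "p_enrich": r.p_enrich,
                "p_deplete": r.p_deplete,
                "n_windows": r.n_windows,
                "n_breakpoints": r.n_breakpoints,
            }
            for r in results
        ]
    )


@dataclass
class EnrichmentMatrix:
    """Fold-enrichment (and p) per (feature track, sample) for one class."""

    fold: pd.DataFrame
    p_enrich: pd.DataFrame
    p_deplete: pd.DataFrame
    variant_class: str

    def to_tsv(self, path) -> None:
        self.fold.to_csv(path, sep="\t", index_label="track")

    @classmethod
    def from_tsv(cls, path, variant_class: str = ALL_CLASSES) -> "EnrichmentMatrix":
        fold = pd.read_csv(path, sep="\t", index_col="track")
        empty = fold * float("nan")
        return cls(fold=fold, p_enrich=empty, p_deplete=empty, variant_class=variant_class)


def enrichment_matrix(
    samples: Sequence[SvSet],
    tracks: Sequence[FeatureTrack],
    config: EnrichmentConfig,
    variant_class: str = ALL_CLASSES,
    unique: bool = False,
) -> EnrichmentMatrix:
    """Fold/p matrix with tracks as rows and samples as columns.

    Cell RNG streams are seeded from (config.seed, track index) only, so two
    samples containing identical breakpoints yield identical columns.
    """
    if not samples or not tracks:
        raise ParameterError("need at least one sample and one track")
    fold = {}
    p_en = {}
    p_de = {}
    class_idx = _CLASS_ORDER.index(variant_class) if variant_class in _CLASS_ORDER else 99
    for s in samples:
        col_f, col_pe, col_pd = [], [], []
        for ti, track in enumerate(tracks):
            if variant_class == ALL_CLASSES:
                bps = list(s.breakpoints)
            else:
                bps = [b for b in s.breakpoints if b.variant_class == variant_class]
            if not bps:
                col_f.append(float("nan"))
                col_pe.append(float("nan"))
                col_pd.append(float("nan"))
                continue
            rng = np.random.default_rng([abs(int(config.seed)), ti, class_idx])
            r = _enrichment_one_class(bps, variant_class, track, config, unique, rng=rng)
            col_f.append(r.fold)
            col_pe.append(r.p_enrich)
            col_pd.append(r.p_deplete)
        fold[s.name] = col_f
        p_en[s.name] = col_pe
        p_de[s.name] = col_pd
    index = [t.name for t in tracks]
    return EnrichmentMatrix(
        fold=pd.DataFrame(fold, index=index),
        p_enrich=pd.DataFrame(p_en, index=index),
        p_deplete=pd.DataFrame(p_de, index=index),
        variant_class=variant_class,
    )


RANKSUM = "ranksum"
TTEST = "ttest"


def discriminating_features(
    matrix: EnrichmentMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    method: str = RANKSUM,
    alpha: float = 0.05,
    min_fold_change: Optional[float] = None,
) -> pd.DataFrame:
    """Feature tracks whose fold enrichment differs between sample groups.

    Per track, the two groups' fold values are compared with a two-sample
    rank-sum (Mann-Whitney) or t test; tracks with p < alpha (and, when
    ``min_fold_change`` is set, higher/lower group-mean ratio >= the
    threshold) are reported with the direction of the higher group.
    """
    cols = set(matrix.fold.columns)
    for label in list(group_a) + list(group_b):
        if label not in cols:
            raise ParameterError(f"sample {label!r} not a matrix column")
    if not group_a or not group_b:
        raise ParameterError("both groups must be non-empty")
    if method == TTEST and (len(group_a) < 2 or len(group_b) < 2):
        raise ParameterError("t-test requires >= 2 samples per group")
    if method == RANKSUM and (len(group_a) < 2 or len(group_b) < 2):
        warnings.warn("rank-sum with a single-sample group has little power")
    if method not in (RANKSUM, TTEST):
        raise ParameterError(f"unknown method {method!r}")

    rows = []
    for track in matrix.fold.index:
        a = matrix.fold.loc[track, list(group_a)].to_numpy(dtype=float)
        b = matrix.fold.loc[track, list(group_b)].to_numpy(dtype=float)
        if np.isnan(a).any() or np.isnan(b).any():
            continue
        if method == RANKSUM:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            p = float(stats.ttest_ind(a, b).pvalue)
        if not np.isfinite(p) or p >= alpha:
            continue
        mean_a, mean_b = float(a.mean()), float(b.mean())
        hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
        if min_fold_change is not None:
            ratio = float("inf") if lo <= 0 else hi / lo
            if ratio < min_fold_change:
                continue
        rows.append(
            {
                "track": track,
                "direction": "A" if mean_a > mean_b else "B",
                "p": p,
                "mean_a": mean_a,
                "mean_b": mean_b,
            }
        )
    return pd.DataFrame(rows, columns=["track", "direction", "p", "mean_a", "mean_b"])
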