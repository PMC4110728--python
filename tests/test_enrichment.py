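"""Permutation enrichment, matrix construction, discriminating features."""

import numpy as np
import pytest

from matesv.enrichment import (
    EnrichmentConfig,
    count_features_near,
    discriminating_features,
    enrichment_matrix,
    permutation_enrichment,
)
from matesv.errors import ParameterError
from matesv.svset import SvSet
from matesv.tracks import FeatureTrack

from conftest import make_breakpoint

GENOME = {"chr1": 10_000_000, "chr2": 10_000_000}


def uniform_breakpoints(rng, n=40, vclass="deletion"):
    bps = []
    for i in range(n):
        chrom = "chr1" if i % 2 else "chr2"
        p = int(rng.integers(200_000, 9_800_000))
        q = int(rng.integers(200_000, 9_800_000))
        lo, hi = sorted((p, q))
        bps.append(
            make_breakpoint(chrom, lo, lo + 200, chrom, hi, hi + 200,
                            variant_class=vclass, name=f"u{i}")
        )
    return bps


def uniform_track(rng, n=150, width=1000, name="t"):
    ivs = []
    for i in range(n):
        chrom = "chr1" if i % 2 else "chr2"
        s = int(rng.integers(0, 9_990_000))
        ivs.append((chrom, s, s + width))
    return FeatureTrack(name, ivs)


class TestCounting:
    def test_feature_inside_window_counts_once(self):
        """A translocation locus at 100 kb sees a feature at 120-121 kb
        within a 50 kb radius; the far side sees nothing."""
        bp = make_breakpoint("chr1", 99_950, 100_050, "chr2", 5_000_000, 5_000_100,
                             variant_class="translocation")
        track = FeatureTrack("t", [("chr1", 120_000, 121_000)])
        assert count_features_near([bp], track, radius=50_000, genome=GENOME) == 1

    def test_empty_track_counts_zero(self):
        bp = make_breakpoint("chr1", 0, 100, "chr2", 0, 100)
        assert count_features_near([bp], FeatureTrack("e", []), 50_000, GENOME) == 0

    def test_overlapping_side_windows_merge(self):
        """Both footprints on one chromosome 30 kb apart: one merged window,
        a feature between them counts once, not twice."""
        bp = make_breakpoint("chr1", 100_000, 100_100, "chr1", 130_000, 130_100)
        track = FeatureTrack("t", [("chr1", 114_000, 115_000)])
        assert count_features_near([bp], track, radius=50_000, genome=GENOME) == 1

    def test_multiplicity_vs_unique(self):
        bps = [
            make_breakpoint("chr1", 100_000, 100_100, "chr2", 5_000_000, 5_000_100),
            make_breakpoint("chr1", 110_000, 110_100, "chr2", 7_000_000, 7_000_100),
        ]
        track = FeatureTrack("t", [("chr1", 120_000, 121_000)])
        assert count_features_near(bps, track, 50_000, GENOME) == 2
        assert count_features_near(bps, track, 50_000, GENOME, unique=True) == 1

    def test_chromosome_absent_from_track_contributes_zero(self):
        bp = make_breakpoint("chr2", 100_000, 100_100, "chr2", 4_000_000, 4_000_100)
        track = FeatureTrack("t", [("chr1", 100_000, 101_000)])
        assert count_features_near([bp], track, 50_000, GENOME) == 0

    def test_clipping_matches_unclipped_away_from_edges(self):
        rng = np.random.default_rng(31)
        bps = uniform_breakpoints(rng)
        track = uniform_track(rng)
        huge = {"chr1": 10**12, "chr2": 10**12}
        assert count_features_near(bps, track, 50_000, GENOME) == count_features_near(
            bps, track, 50_000, huge
        ) == count_features_near(bps, track, 50_000, genome=None)


class TestPermutationTest:
    def test_genome_tiling_features_give_fold_one(self):
        """One feature covering each chromosome: every window hits exactly
        its own chromosome's feature wherever it lands."""
        rng = np.random.default_rng(1)
        sv = SvSet("s", uniform_breakpoints(rng), 5800)
        tile = FeatureTrack("tile", [("chr1", 0, 10_000_000), ("chr2", 0, 10_000_000)])
        config = EnrichmentConfig(n_perm=300, seed=2, genome=GENOME)
        (r,) = permutation_enrichment(sv, tile, config, classes=["deletion"])
        assert r.fold == 1.0
        assert r.p_enrich == 1.0 and r.p_deplete == 1.0

    def test_planted_features_detected_as_enriched(self):
        rng = np.random.default_rng(2)
        bps = uniform_breakpoints(rng)
        planted = FeatureTrack(
            "pl", [(b.chromA, b.b1 + 2000, b.b1 + 3000) for b in bps]
        )
        sv = SvSet("s", bps, 5800)
        config = EnrichmentConfig(n_perm=1000, seed=3, genome=GENOME)
        (r,) = permutation_enrichment(sv, planted, config, classes=["deletion"])
        assert r.fold > 1
        assert r.p_enrich <= 0.05

    def test_p_values_never_zero_and_floor(self):
        rng = np.random.default_rng(4)
        bps = uniform_breakpoints(rng)
        planted = FeatureTrack(
            "pl", [(b.chromA, b.b1 + 2000, b.b1 + 3000) for b in bps]
        )
        config = EnrichmentConfig(n_perm=200, seed=5, genome=GENOME)
        (r,) = permutation_enrichment(
            SvSet("s", bps, 5800), planted, config, classes=["deletion"]
        )
        assert r.p_enrich >= 1 / 201
        assert r.p_deplete > 0

    def test_seed_determinism_and_stability(self):
        rng = np.random.default_rng(6)
        sv = SvSet("s", uniform_breakpoints(rng), 5800)
        track = uniform_track(rng)
        c1 = EnrichmentConfig(n_perm=400, seed=7, genome=GENOME)
        r1 = permutation_enrichment(sv, track, c1, classes=["deletion"])[0]
        r1b = permutation_enrichment(sv, track, c1, classes=["deletion"])[0]
        assert (r1.null_mean, r1.p_enrich) == (r1b.null_mean, r1b.p_enrich)
        c2 = EnrichmentConfig(n_perm=400, seed=8, genome=GENOME)
        r2 = permutation_enrichment(sv, track, c2, classes=["deletion"])[0]
        se = max(r1.null_sd, r2.null_sd) / np.sqrt(400)
        assert abs(r1.null_mean - r2.null_mean) <= 3 * se

    def test_input_order_does_not_change_results(self):
        rng = np.random.default_rng(9)
        bps = uniform_breakpoints(rng)
        track = uniform_track(rng)
        config = EnrichmentConfig(n_perm=300, seed=10, genome=GENOME)
        r_fwd = permutation_enrichment(SvSet("s", bps, 5800), track, config)
        r_rev = permutation_enrichment(SvSet("s", bps[::-1], 5800), track, config)
        assert [(x.variant_class, x.observed, x.null_mean, x.p_enrich) for x in r_fwd] == [
            (x.variant_class, x.observed, x.null_mean, x.p_enrich) for x in r_rev
        ]

    def test_class_with_zero_breakpoints_omitted(self):
        rng = np.random.default_rng(12)
        sv = SvSet("s", uniform_breakpoints(rng, vclass="inversion"), 5800)
        track = uniform_track(rng)
        config = EnrichmentConfig(n_perm=100, seed=13, genome=GENOME)
        classes = [r.variant_class for r in permutation_enrichment(sv, track, config)]
        assert classes == ["inversion", "all"]

    def test_missing_chromosome_length_is_an_error(self):
        bp = make_breakpoint("chrX", 0, 100, "chrX", 5000, 5100)
        config = EnrichmentConfig(n_perm=10, seed=1, genome=GENOME)
        with pytest.raises(ParameterError):
            permutation_enrichment(
                SvSet("s", [bp], 100), FeatureTrack("t", []), config
            )


class TestMatrixAndDiscrimination:
    def test_one_by_one_matrix_matches_single_run(self):
        rng = np.random.default_rng(14)
        bps = uniform_breakpoints(rng)
        sv = SvSet("s1", bps, 5800)
        track = uniform_track(rng)
        config = EnrichmentConfig(n_perm=300, seed=15, genome=GENOME)
        matrix = enrichment_matrix([sv], [track], config, variant_class="deletion")
        assert matrix.fold.shape == (1, 1)
        assert np.isfinite(matrix.fold.iloc[0, 0])

    def test_identical_samples_identical_columns(self):
        rng = np.random.default_rng(16)
        bps = uniform_breakpoints(rng)
        s1 = SvSet("alpha", bps, 5800)
        s2 = SvSet("beta", list(bps), 5800)
        tracks = [uniform_track(rng, name="t1"), uniform_track(rng, name="t2")]
        config = EnrichmentConfig(n_perm=200, seed=17, genome=GENOME)
        matrix = enrichment_matrix([s1, s2], tracks, config)
        assert (matrix.fold["alpha"] == matrix.fold["beta"]).all()
        assert (matrix.p_enrich["alpha"] == matrix.p_enrich["beta"]).all()

    def test_planted_asymmetry_between_samples(self):
        rng = np.random.default_rng(18)
        bps1 = uniform_breakpoints(rng)
        bps2 = uniform_breakpoints(rng)
        near_s1 = FeatureTrack(
            "X", [(b.chromA, b.b1 + 1000, b.b1 + 2000) for b in bps1]
        )
        config = EnrichmentConfig(n_perm=300, seed=19, genome=GENOME)
        matrix = enrichment_matrix(
            [SvSet("s1", bps1, 5800), SvSet("s2", bps2, 5800)], [near_s1], config
        )
        assert matrix.fold.loc["X", "s1"] > matrix.fold.loc["X", "s2"]

    def _shifted_matrix(self):
        import pandas as pd
        from matesv.enrichment import EnrichmentMatrix

        rng = np.random.default_rng(20)
        base = rng.normal(1.0, 0.05, size=(3, 10))
        base[0, :5] += 2.0  # track "up_in_A" strongly higher in group A
        fold = pd.DataFrame(
            base,
            index=["up_in_A", "flat1", "flat2"],
            columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)],
        )
        return EnrichmentMatrix(fold, fold * np.nan, fold * np.nan, "all")

    def test_planted_shift_found_by_ranksum(self):
        matrix = self._shifted_matrix()
        hits = discriminating_features(
            matrix, [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)],
            method="ranksum", min_fold_change=1.25,
        )
        assert list(hits["track"]) == ["up_in_A"]
        assert hits.iloc[0]["direction"] == "A"

    def test_identical_groups_give_no_hits(self):
        import pandas as pd
        from matesv.enrichment import EnrichmentMatrix

        fold = pd.DataFrame(
            np.ones((4, 6)),
            index=[f"t{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(6)],
        )
        matrix = EnrichmentMatrix(fold, fold * np.nan, fold * np.nan, "all")
        hits = discriminating_features(
            matrix, ["s0", "s1", "s2"], ["s3", "s4", "s5"], method="ranksum"
        )
        assert len(hits) == 0

    def test_ttest_requires_two_per_group(self):
        matrix = self._shifted_matrix()
        with pytest.raises(ParameterError):
            discriminating_features(matrix, ["a0"], ["b0", "b1"], method="ttest")
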