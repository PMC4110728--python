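"""Grid clustering, refinement, thinning, and end-to-end calling."""

import random

import numpy as np
import pytest

from matesv.caller import (
    Breakpoint,
    CallerConfig,
    classify_variant,
    cluster_to_breakpoint,
    coarse_cluster,
    call_breakpoints,
    partition_by_chrom_pair,
    refine_cluster,
    thin_members,
)
from matesv.model import InsertSizeModel, OrientationSignature, build_insert_model
from matesv.simulate import SimulationConfig, PlantedVariant, simulate
from matesv.svset import match_calls

from conftest import make_pair, normal_pairs


def model_4000_6000():
    return InsertSizeModel(
        histogram={5000: 10}, i_min=4000, i_max=6000,
        expected_orientation=OrientationSignature("+", "-", "forward"),
        n_pairs_used=10,
    )


def clustering_model():
    """A short-insert model so example window sizes satisfy w > i_max."""
    return InsertSizeModel(
        histogram={3000: 10}, i_min=2000, i_max=3000,
        expected_orientation=OrientationSignature("+", "-", "forward"),
        n_pairs_used=10,
    )


def resolved_config(**kwargs):
    return CallerConfig(**kwargs).resolved(clustering_model())


def oriented(pairs):
    buckets = partition_by_chrom_pair(pairs)
    assert len(buckets) == 1
    return next(iter(buckets.values()))


class TestPartition:
    def test_canonical_bucket_for_reversed_chromosomes(self):
        pairs = [
            make_pair("a", "chr2", 100, "chr3", 200),
            make_pair("b", "chr3", 300, "chr2", 400),
        ]
        buckets = partition_by_chrom_pair(pairs)
        assert set(buckets) == {("chr2", "chr3")}
        for op in buckets[("chr2", "chr3")]:
            assert op.chromA == "chr2"

    def test_intra_pairs_side_a_has_smaller_start(self):
        pairs = [make_pair("a", "chr1", 9000, "chr1", 1000)]
        (op,) = partition_by_chrom_pair(pairs)[("chr1", "chr1")]
        assert op.startA == 1000 and op.startB == 9000

    def test_partition_conserves_pairs(self):
        rng = np.random.default_rng(0)
        chroms = ["chr1", "chr2", "chr3", "chr4"]
        pairs = [
            make_pair(
                f"p{i}",
                chroms[int(rng.integers(0, 4))], int(rng.integers(0, 10_000)),
                chroms[int(rng.integers(0, 4))], int(rng.integers(0, 10_000)),
            )
            for i in range(100)
        ]
        buckets = partition_by_chrom_pair(pairs)
        assert sum(len(v) for v in buckets.values()) == 100
        assert partition_by_chrom_pair([]) == {}


class TestCoarseCluster:
    def test_nearby_pairs_form_one_cluster(self):
        pairs = [
            make_pair("a", "chr1", 10_000, "chr1", 50_000),
            make_pair("b", "chr1", 10_400, "chr1", 50_300),
            make_pair("c", "chr1", 10_900, "chr1", 50_800),
        ]
        clusters = coarse_cluster(oriented(pairs), resolved_config(w=5000))
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_window_predicate_splits_distant_pairs(self):
        w = 7000
        pairs = [
            make_pair("a", "chr1", 10_000, "chr1", 50_000),
            make_pair("b", "chr1", 10_000 + w + 1, "chr1", 50_000),
        ]
        clusters = coarse_cluster(oriented(pairs), resolved_config(w=w))
        assert len(clusters) == 2

    def test_signature_split_precedes_clustering(self):
        pairs = [
            make_pair("a", "chr1", 10_000, "chr1", 50_000),
            make_pair("b", "chr1", 10_000, "chr1", 50_000, strand2="+"),
        ]
        clusters = coarse_cluster(oriented(pairs), resolved_config(w=7000))
        assert len(clusters) == 2

    def test_side_b_distance_also_gates_membership(self):
        w = 7000
        pairs = [
            make_pair("a", "chr1", 10_000, "chr1", 50_000),
            make_pair("b", "chr1", 10_100, "chr1", 50_000 + w + 1),
        ]
        clusters = coarse_cluster(oriented(pairs), resolved_config(w=w))
        assert len(clusters) == 2


def brute_force_single_linkage(members, cut):
    """Independent oracle: connected components of the threshold graph
    d(p,q) = max(|dA|, |dB|) <= cut, via union-find."""
    n = len(members)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = max(
                abs(members[i].startA - members[j].startA),
                abs(members[i].startB - members[j].startB),
            )
            if d <= cut:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(members[i].pair_id)
    return {frozenset(c) for c in comps.values()}


class TestRefineCluster:
    def test_tight_cluster_unchanged(self):
        pairs = [
            make_pair(f"p{i}", "chr1", 10_000 + 100 * i, "chr1", 50_000 + 100 * i)
            for i in range(5)
        ]
        config = resolved_config()
        (coarse,) = coarse_cluster(oriented(pairs), config)
        assert len(refine_cluster(coarse, config)) == 1

    def test_two_groups_split_at_double_cut(self):
        cut = 6000
        pairs = [
            make_pair(f"a{i}", "chr1", 10_000 + 10 * i, "chr1", 100_000 + 10 * i)
            for i in range(3)
        ] + [
            make_pair(f"b{i}", "chr1", 10_000 + 2 * cut + 10 * i,
                      "chr1", 100_000 + 2 * cut + 10 * i)
            for i in range(3)
        ]
        config = resolved_config(w=30_000, refine_cut=cut)
        (coarse,) = coarse_cluster(oriented(pairs), config)
        subs = refine_cluster(coarse, config)
        assert sorted(len(s.members) for s in subs) == [3, 3]

    def test_matches_brute_force_oracle_on_random_clusters(self):
        rng = np.random.default_rng(5)
        config = resolved_config(w=1_000_000, refine_cut=6000)
        for rep in range(30):
            pairs = [
                make_pair(
                    f"r{rep}_{i:02d}",
                    "chr1", int(rng.integers(0, 60_000)),
                    "chr1", int(rng.integers(200_000, 260_000)),
                )
                for i in range(20)
            ]
            clusters = coarse_cluster(oriented(pairs), config)
            refined = [
                frozenset(m.pair_id for m in sub.members)
                for c in clusters
                for sub in refine_cluster(c, config)
            ]
            members = oriented(pairs)
            assert set(refined) == brute_force_single_linkage(members, 6000)


class TestThinningAndSupport:
    def test_spread_members_all_count(self):
        pairs = [
            make_pair("a", "chr1", 1000, "chr1", 9000),
            make_pair("b", "chr1", 1060, "chr1", 9070),
            make_pair("c", "chr1", 1120, "chr1", 9150),
        ]
        config = resolved_config()
        (coarse,) = coarse_cluster(oriented(pairs), config)
        bp = cluster_to_breakpoint(coarse, config, model_4000_6000(), "s")
        assert bp is not None
        assert bp.effective_support == 3
        assert bp.support == 3

    def test_stacked_members_thin_to_one_and_no_call(self):
        pairs = [
            make_pair(f"s{i}", "chr1", 1000 + i, "chr1", 9000 + 2 * i)
            for i in range(5)  # all within 10 bp on both sides
        ]
        config = resolved_config()
        (coarse,) = coarse_cluster(oriented(pairs), config)
        assert len(thin_members(coarse.members, 50)) == 1
        assert cluster_to_breakpoint(coarse, config, model_4000_6000(), "s") is None

    def test_diversity_on_one_side_is_independent_evidence(self):
        # side A stacked, side B spread: pairs are not redundant
        pairs = [
            make_pair(f"d{i}", "chr1", 1000, "chr1", 9000 + 80 * i) for i in range(3)
        ]
        (coarse,) = coarse_cluster(oriented(pairs), resolved_config())
        assert len(thin_members(coarse.members, 50)) == 3

    def test_default_thresholds(self):
        config = CallerConfig()
        assert config.min_support == 3
        assert config.min_end_spread == 50


class TestClassifyVariant:
    def test_rule_table(self):
        model = model_4000_6000()
        assert classify_variant(("+", "-"), "chr2", "chr3", 0, model) == "translocation"
        assert classify_variant(("+", "-"), "chr1", "chr1", 20_000, model) == "deletion"
        assert classify_variant(("+", "-"), "chr1", "chr1", 1000, model) == "insertion"
        assert classify_variant(("+", "+"), "chr1", "chr1", 20_000, model) == "inversion"
        assert classify_variant(("-", "-"), "chr1", "chr1", 20_000, model) == "inversion"


class TestCallBreakpoints:
    def test_planted_translocation_recovered_with_full_support(self):
        rng = np.random.default_rng(13)
        background = normal_pairs(1500, rng)
        cross = [
            make_pair(f"t{i}", "chr1", 500_000 + 600 * i, "chr5", 800_000 + 600 * i)
            for i in range(8)
        ]
        model = build_insert_model(background)
        calls = call_breakpoints(background + cross, model, CallerConfig())
        trans = [c for c in calls if c.variant_class == "translocation"]
        assert len(trans) == 1
        assert trans[0].support == 8
        assert (trans[0].chromA, trans[0].chromB) == ("chr1", "chr5")

    def test_consistent_only_input_gives_no_calls(self):
        rng = np.random.default_rng(17)
        pairs = normal_pairs(1200, rng)
        model = build_insert_model(pairs, override=(3000, 7000))
        assert call_breakpoints(pairs, model, CallerConfig()) == []

    def test_order_and_batching_invariance(self, small_sim_config):
        dataset = simulate(small_sim_config)
        model = build_insert_model(dataset.pairs)
        baseline = call_breakpoints(dataset.pairs, model, CallerConfig())
        shuffled = list(dataset.pairs)
        random.Random(99).shuffle(shuffled)
        assert call_breakpoints(shuffled, model, CallerConfig()) == baseline
        # batch decomposition: concatenate three arbitrary batches
        third = len(shuffled) // 3
        batches = shuffled[2 * third:] + shuffled[:third] + shuffled[third:2 * third]
        assert call_breakpoints(batches, model, CallerConfig()) == baseline

    def test_membership_conservation(self, small_sim_config):
        from matesv.model import INCONSISTENT, classify_pair, dedup_clonal

        dataset = simulate(small_sim_config)
        model = build_insert_model(dataset.pairs)
        config = CallerConfig().resolved(model)
        deduped = dedup_clonal(dataset.pairs)
        incons = [p for p in deduped if classify_pair(p, model).label == INCONSISTENT]
        buckets = partition_by_chrom_pair(incons)
        total = 0
        for bucket in buckets.values():
            for coarse in coarse_cluster(bucket, config):
                for sub in refine_cluster(coarse, config):
                    total += len(sub.members)
        assert total == len(incons)

    def test_raising_min_support_never_adds_calls(self, small_sim_config):
        dataset = simulate(small_sim_config)
        model = build_insert_model(dataset.pairs)
        previous = None
        for ms in (1, 2, 3, 5, 8):
            calls = call_breakpoints(
                dataset.pairs, model, CallerConfig(min_support=ms)
            )
            if previous is not None:
                assert len(calls) <= previous
            previous = len(calls)

    def test_footprints_are_exact_min_max_over_members(self):
        rng = np.random.default_rng(23)
        background = normal_pairs(1500, rng)
        cross = [
            make_pair(f"t{i}", "chr1", 500_000 + 700 * i, "chr5", 800_000 + 700 * i)
            for i in range(5)
        ]
        model = build_insert_model(background)
        calls = call_breakpoints(background + cross, model, CallerConfig())
        (bp,) = [c for c in calls if c.variant_class == "translocation"]
        assert bp.b1 == 500_000 and bp.e1 == 500_000 + 700 * 4 + 50
        assert bp.b2 == 800_000 and bp.e2 == 800_000 + 700 * 4 + 50

    def test_simulated_truth_recovery(self, small_sim_config):
        """All planted junctions with >= 3 spanning pairs are found; no
        calls away from the planted junctions (noise-free input)."""
        dataset = simulate(small_sim_config)
        model = build_insert_model(
            dataset.pairs, override=small_sim_config.insert_bounds
        )
        calls = call_breakpoints(dataset.pairs, model, CallerConfig())
        i_max = small_sim_config.insert_bounds[1]
        matches = match_calls(
            calls, dataset.truth.breakpoints, i_max, require_strands=True
        )
        counts = dataset.spanning_counts()
        for ti, bp in enumerate(dataset.truth.breakpoints):
            if counts[bp.name] >= 3:
                assert matches[ti], f"junction {bp.name} not recovered"
        matched = {ci for hits in matches.values() for ci in hits}
        assert matched == set(range(len(calls)))
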