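import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    base_resolution_diversity,
    brute_sdp_catalog,
    brute_segments,
    positional_class_count,
    stab_intervals,
)
from conftest import random_table
from strainmapqtl.errors import InvalidArgumentError, InvalidInputError
from strainmapqtl.hapmap import (
    MONOMORPHIC,
    GenotypeTable,
    HaplotypeSegment,
    SegmentationParams,
    build_region_map,
    classify_cis,
    detect_segments,
    enumerate_sdps,
    pairwise_diversity,
)


def table_from_calls(calls, pos=None, chrom=None):
    calls = np.asarray(calls, dtype=np.uint8)
    n_strains, n_variants = calls.shape
    if pos is None:
        pos = np.arange(1, n_variants + 1) * 10
    if chrom is None:
        chrom = np.full(n_variants, "1", dtype=object)
    return GenotypeTable(
        strains=[f"S{i+1:02d}" for i in range(n_strains)],
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        ref=np.full(n_variants, "A", dtype=object),
        alt=np.full(n_variants, "T", dtype=object),
        calls=calls,
    )


class TestGenotypeTable:
    def test_rejects_non_binary_calls(self):
        with pytest.raises(InvalidInputError, match="heterozygous"):
            table_from_calls(np.array([[0, 2], [1, 0]]))

    def test_rejects_unsorted_positions(self):
        with pytest.raises(InvalidInputError, match="increasing"):
            table_from_calls(np.array([[0, 1], [1, 0]]), pos=[5, 5])

    def test_subset_strains_reorders(self, small_table):
        sub = small_table.subset_strains(["S03", "S01"])
        assert sub.strains == ["S03", "S01"]
        np.testing.assert_array_equal(sub.calls[0], small_table.calls[2])

    def test_subset_unknown_strain(self, small_table):
        with pytest.raises(InvalidArgumentError):
            small_table.subset_strains(["nope"])


class TestEnumerateSdps:
    def test_monomorphic_table_gives_empty_catalog(self):
        geno = table_from_calls(np.zeros((4, 10), dtype=np.uint8))
        catalog, assignment = enumerate_sdps(geno)
        assert catalog == []
        assert (assignment == MONOMORPHIC).all()

    def test_all_alt_is_monomorphic_too(self):
        geno = table_from_calls(np.ones((4, 5), dtype=np.uint8))
        catalog, _ = enumerate_sdps(geno)
        assert catalog == []

    def test_complement_patterns_share_an_id(self):
        # 0110 and 1001 are the same bipartition under ref/alt flip
        geno = table_from_calls(np.array([[0, 1], [1, 0], [1, 0], [0, 1]]))
        catalog, assignment = enumerate_sdps(geno)
        assert len(catalog) == 1
        assert assignment[0] == assignment[1] == 0
        assert catalog[0].pattern == (0, 1, 1, 0)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            geno = random_table(rng, n_strains=8, n_variants=500)
            catalog, assignment = enumerate_sdps(geno)
            patterns, brute_assign = brute_sdp_catalog(geno.calls)
            assert [s.pattern for s in catalog] == patterns
            assert assignment.tolist() == brute_assign

    def test_single_strain_rejected(self):
        geno = table_from_calls(np.array([[0, 1, 0]]))
        with pytest.raises(InvalidArgumentError):
            enumerate_sdps(geno)


class TestDetectSegments:
    def test_below_min_run_no_segment(self):
        calls = np.array([[0] * 19, [1] * 19])
        geno = table_from_calls(calls)
        catalog, assignment = enumerate_sdps(geno)
        assert detect_segments(geno, assignment, SegmentationParams()) == []

    def test_min_run_exactly_met(self):
        calls = np.array([[0] * 20, [1] * 20])
        geno = table_from_calls(calls)
        _, assignment = enumerate_sdps(geno)
        segs = detect_segments(geno, assignment, SegmentationParams())
        assert len(segs) == 1
        assert segs[0].n_support == 20

    def test_gap_of_99_keeps_run_together(self):
        # 20 focal variants each separated by exactly 99 variants of other SDPs
        blocks = []
        for i in range(20):
            blocks.append([0, 1, 1])  # focal SDP over 3 strains
            if i < 19:
                blocks.extend([[0, 0, 1]] * 99)
        calls = np.array(blocks).T
        geno = table_from_calls(calls)
        catalog, assignment = enumerate_sdps(geno)
        focal = [s.id for s in catalog if s.pattern == (0, 1, 1)][0]
        segs = [
            s
            for s in detect_segments(geno, assignment, SegmentationParams())
            if s.sdp_id == focal
        ]
        assert len(segs) == 1
        assert segs[0].n_support == 20

    def test_gap_of_100_splits_run(self):
        blocks = []
        for i in range(40):
            blocks.append([0, 1, 1])
            if i == 19:
                blocks.extend([[0, 0, 1]] * 100)  # exactly max_gap: strict split
        calls = np.array(blocks).T
        geno = table_from_calls(calls)
        catalog, assignment = enumerate_sdps(geno)
        focal = [s.id for s in catalog if s.pattern == (0, 1, 1)][0]
        segs = [
            s
            for s in detect_segments(geno, assignment, SegmentationParams())
            if s.sdp_id == focal
        ]
        assert [s.n_support for s in segs] == [20, 20]

    def test_monomorphic_variants_do_not_count_toward_gap(self):
        blocks = [[0, 1, 1]]
        blocks.extend([[0, 0, 0]] * 500)  # monomorphic filler
        blocks.extend([[0, 1, 1]] * 19)
        calls = np.array(blocks).T
        geno = table_from_calls(calls)
        _, assignment = enumerate_sdps(geno)
        segs = detect_segments(geno, assignment, SegmentationParams())
        assert len(segs) == 1 and segs[0].n_support == 20

    def test_matches_brute_force_on_random_assignments(self, rng):
        for _ in range(25):
            n_strains = int(rng.integers(3, 14))
            n_variants = int(rng.integers(50, 400))
            geno = random_table(rng, n_strains=n_strains, n_variants=n_variants,
                                chroms=("1", "2"))
            _, assignment = enumerate_sdps(geno)
            params = SegmentationParams(
                min_run=int(rng.integers(2, 6)), max_gap=int(rng.integers(1, 8))
            )
            got = {
                (s.chrom, s.start, s.end, s.sdp_id, s.n_support)
                for s in detect_segments(geno, assignment, params)
            }
            want = brute_segments(
                geno.chrom, geno.pos, assignment, params.min_run, params.max_gap
            )
            assert got == want

    def test_invariant_to_strain_reordering_and_allele_flip(self, rng):
        geno = random_table(rng, n_strains=6, n_variants=300)
        params = SegmentationParams(min_run=3, max_gap=5)
        _, assignment = enumerate_sdps(geno)
        base = {(s.chrom, s.start, s.end, s.n_support)
                for s in detect_segments(geno, assignment, params)}
        # flip ref/alt labels at random variants
        flip = rng.integers(0, 2, size=geno.n_variants).astype(np.uint8)
        flipped = table_from_calls(geno.calls ^ flip, pos=geno.pos, chrom=geno.chrom)
        _, a2 = enumerate_sdps(flipped)
        assert {(s.chrom, s.start, s.end, s.n_support)
                for s in detect_segments(flipped, a2, params)} == base
        # reorder strains
        perm = rng.permutation(geno.n_strains)
        reordered = table_from_calls(geno.calls[perm], pos=geno.pos, chrom=geno.chrom)
        _, a3 = enumerate_sdps(reordered)
        assert {(s.chrom, s.start, s.end, s.n_support)
                for s in detect_segments(reordered, a3, params)} == base

    def test_params_validation(self):
        with pytest.raises(InvalidArgumentError):
            SegmentationParams(min_run=1)
        with pytest.raises(InvalidArgumentError):
            SegmentationParams(max_gap=0)


def _random_segments(rng, catalog_size, n_strains, length=2000, n=8):
    from strainmapqtl.hapmap import SDP

    catalog = []
    for i in range(catalog_size):
        while True:
            pat = tuple([0] + rng.integers(0, 2, size=n_strains - 1).tolist())
            if 0 < sum(pat) < n_strains:
                break
        catalog.append(SDP(id=i, pattern=pat))
    segments = []
    for _ in range(n):
        a, b = sorted(rng.integers(1, length + 1, size=2).tolist())
        segments.append(
            HaplotypeSegment(
                chrom="1", start=a, end=b,
                sdp_id=int(rng.integers(0, catalog_size)), n_support=20,
            )
        )
    return catalog, segments


class TestBuildRegionMap:
    def test_empty_segments_single_region(self):
        rmap, table = build_region_map([], {"1": 1000, "2": 500}, [])
        assert table == {1: 1500}
        assert [len(v) for v in rmap.regions.values()] == [1, 1]
        assert rmap.total_length() == 1500

    def test_nested_sdps_give_three_classes(self):
        from strainmapqtl.hapmap import SDP

        catalog = [SDP(id=0, pattern=(0, 1, 1)), SDP(id=1, pattern=(0, 0, 1))]
        segments = [
            HaplotypeSegment("1", 100, 500, 0, 20),
            HaplotypeSegment("1", 200, 400, 1, 20),
        ]
        rmap, _ = build_region_map(segments, {"1": 1000}, catalog)
        mid = [r for r in rmap.regions["1"] if r.start == 200][0]
        assert mid.class_count_paper == 3
        assert mid.class_count_joint == 3  # (0,0), (1,0), (1,1)

    def test_regions_tile_chromosome_exactly(self, rng):
        catalog, segments = _random_segments(rng, 4, 6)
        rmap, _ = build_region_map(segments, {"1": 2000}, catalog)
        regs = rmap.regions["1"]
        assert regs[0].start == 1 and regs[-1].end == 2000
        for a, b in zip(regs[:-1], regs[1:]):
            assert b.start == a.end + 1
        assert rmap.total_length() == 2000

    def test_joint_count_matches_positional_oracle(self, rng):
        for _ in range(20):
            catalog, segments = _random_segments(rng, 5, 7)
            rmap, _ = build_region_map(segments, {"1": 2000}, catalog)
            for r in rmap.regions["1"]:
                for bp in (r.start, (r.start + r.end) // 2, r.end):
                    assert r.class_count_joint == positional_class_count(
                        segments, catalog, 7, "1", bp
                    )

    def test_segment_beyond_chromosome_rejected(self):
        from strainmapqtl.hapmap import SDP

        catalog = [SDP(id=0, pattern=(0, 1))]
        seg = HaplotypeSegment("1", 100, 5000, 0, 20)
        with pytest.raises(InvalidInputError):
            build_region_map([seg], {"1": 1000}, catalog)


class TestPairwiseDiversity:
    def test_no_divergent_segments(self):
        from strainmapqtl.hapmap import SDP

        catalog = [SDP(id=0, pattern=(0, 0, 1))]
        segs = [HaplotypeSegment("1", 1, 100, 0, 20)]
        strains = ["a", "b", "c"]
        assert pairwise_diversity(segs, catalog, strains, "a", "b", {"1": 1000}) == 0.0

    def test_single_segment_fraction(self):
        from strainmapqtl.hapmap import SDP

        catalog = [SDP(id=0, pattern=(0, 1))]
        segs = [HaplotypeSegment("1", 1, 17_000_000, 0, 20)]
        d = pairwise_diversity(segs, catalog, ["a", "b"], "a", "b", {"1": 100_000_000})
        assert d == pytest.approx(0.17)

    def test_unknown_strain(self):
        with pytest.raises(InvalidArgumentError):
            pairwise_diversity([], [], ["a", "b"], "a", "zzz", {"1": 100})

    def test_matches_base_resolution_oracle(self, rng):
        strains = [f"s{i}" for i in range(6)]
        for _ in range(15):
            catalog, segments = _random_segments(rng, 4, 6, length=500)
            a, b = "s0", "s3"
            got = pairwise_diversity(segments, catalog, strains, a, b, {"1": 500})
            want = base_resolution_diversity(segments, catalog, strains, a, b, {"1": 500})
            assert got == pytest.approx(want, abs=1e-12)

    def test_covered_normalization(self):
        from strainmapqtl.hapmap import SDP

        catalog = [SDP(id=0, pattern=(0, 1)), SDP(id=1, pattern=(0, 1))]
        segs = [
            HaplotypeSegment("1", 1, 100, 0, 20),
            HaplotypeSegment("1", 201, 300, 1, 20),
        ]
        d = pairwise_diversity(segs, catalog, ["a", "b"], "a", "b", {"1": 1000},
                               normalize="covered")
        assert d == pytest.approx(1.0)


class TestClassifyCis:
    def test_outside_all_segments(self):
        from strainmapqtl.hapmap import SDP

        catalog = [SDP(id=0, pattern=(0, 1))]
        segs = [HaplotypeSegment("1", 100, 200, 0, 20)]
        assert not classify_cis(("1", 50), segs, catalog, ["a", "b"], "a", "b")

    def test_inside_non_splitting_segment(self):
        from strainmapqtl.hapmap import SDP

        catalog = [SDP(id=0, pattern=(0, 0, 1))]
        segs = [HaplotypeSegment("1", 100, 200, 0, 20)]
        assert not classify_cis(("1", 150), segs, catalog, ["a", "b", "c"], "a", "b")

    def test_matches_stabbing_oracle(self, rng):
        strains = [f"s{i}" for i in range(6)]
        catalog, segments = _random_segments(rng, 4, 6, length=1000, n=10)
        for _ in range(100):
            pos = ("1", int(rng.integers(1, 1001)))
            got = classify_cis(pos, segments, catalog, strains, "s1", "s4")
            assert got == stab_intervals(pos, segments, catalog, strains, "s1", "s4")


@settings(max_examples=30, deadline=None)
@given(data=st.data())
def test_property_segments_never_span_chromosomes(data):
    seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    geno = random_table(rng, n_strains=4, n_variants=120, chroms=("1", "2", "3"))
    _, assignment = enumerate_sdps(geno)
    segs = detect_segments(geno, assignment, SegmentationParams(min_run=2, max_gap=3))
    chrom_pos = {c: geno.pos[geno.chrom == c] for c in geno.chromosomes}
    for s in segs:
        p = chrom_pos[s.chrom]
        assert s.start in p and s.end in p
        # every supporting variant inside the span carries the segment's SDP
        inside = (geno.chrom == s.chrom) & (geno.pos >= s.start) & (geno.pos <= s.end)
        n_same = int((assignment[inside] == s.sdp_id).sum())
        assert n_same == s.n_support
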