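"""Insertion path: support scan, regions, merging, voting, split mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alucall.insertion import (BreakpointCall, CandidateRegion,
                               InformativeRead, SplitHit, build_regions,
                               merge_regions_multi, scan_support,
                               split_map_c_read, support_at, vote_breakpoints)

WINDOW = 390  # E[Y] + 3 sigma for the canonical 300 +/- 30 library


def la(begin, end, sample="s1"):
    return InformativeRead(kind="D", sample=sample, chrom="chr1",
                           begin=begin, end=end, orientation="la")


def ra(begin, end, sample="s1"):
    return InformativeRead(kind="D", sample=sample, chrom="chr1",
                           begin=begin, end=end, orientation="ra")


class TestScanSupport:
    def test_six_concordant_anchors_pass_threshold(self):
        reads = [la(900, 1000) for _ in range(6)]
        out = scan_support(reads, WINDOW, n=4)
        assert out == [(1000, 6)]

    def test_support_must_strictly_exceed_n(self):
        reads = [la(900, 1000) for _ in range(4)]
        assert scan_support(reads, WINDOW, n=4) == []

    def test_mixed_orientations_combine(self):
        # three la ending at p and three ra starting just right of p
        reads = [la(900 + i, 1000 + i) for i in range(3)]
        reads += [ra(1050, 1150, ) for _ in range(3)]
        out = scan_support(reads, WINDOW, n=4)
        assert out  # pooled support exceeds the threshold at some position
        for p, s in out:
            assert s == support_at(p, reads, WINDOW)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_sweep_equals_brute_force(self, seed):
        """The rank-query sweep equals the O(m*g) brute force scan."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 200))
        reads = []
        for _ in range(m):
            b = int(rng.integers(0, 50_000))
            e = b + 100
            reads.append(la(b, e) if rng.random() < 0.5 else ra(b, e))
        n = int(rng.integers(0, 6))
        got = scan_support(reads, WINDOW, n=n)
        cands = sorted({r.end for r in reads})
        expected = [(p, support_at(p, reads, WINDOW)) for p in cands]
        expected = [(p, s) for p, s in expected if s > n]
        assert got == expected


def _positions(*ps):
    return [(p, 5) for p in ps]


class TestBuildRegions:
    def test_greedy_grouping_matches_quoted_loop(self):
        regions = build_regions(_positions(100, 150, 290, 600), "chr1", "s1",
                                region_len=200)
        spans = [(r.begin, r.end) for r in regions]
        assert spans == [(100, 290), (600, 600)]

    def test_single_position_gives_point_region(self):
        regions = build_regions(_positions(42), "chr1", "s1")
        assert [(r.begin, r.end) for r in regions] == [(42, 42)]

    def test_empty_input(self):
        assert build_regions([], "chr1", "s1") == []

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=1,
                    max_size=50))
    def test_oracle_simulation_of_greedy_loop(self, raw):
        positions = sorted(set(raw))
        regions = build_regions([(p, 1) for p in positions], "chr1", "s1",
                                region_len=200)
        # direct simulation of the grouping loop
        expected = []
        for p in positions:
            if expected and p - expected[-1][0] < 200:
                expected[-1][1] = p
            else:
                expected.append([p, p])
        assert [(r.begin, r.end) for r in regions] \
            == [(b, e) for b, e in expected]
        # every region spans less than the cap and positions are covered
        for r in regions:
            assert r.end - r.begin < 200


def region(b, e, sample, support=5):
    return CandidateRegion("chr1", b, e, {sample}, {sample: support})


class TestMergeRegions:
    def test_overlapping_regions_from_two_samples_merge(self):
        merged = merge_regions_multi([[region(100, 180, "A")],
                                      [region(150, 250, "B")]],
                                     region_len=200)
        assert len(merged) == 1
        assert (merged[0].begin, merged[0].end) == (100, 250)
        assert merged[0].samples == {"A", "B"}

    def test_disjoint_regions_unchanged(self):
        merged = merge_regions_multi([[region(100, 180, "A")],
                                      [region(400, 450, "B")]])
        assert [(r.begin, r.end) for r in merged] == [(100, 180), (400, 450)]

    def test_identical_regions_from_three_samples(self):
        merged = merge_regions_multi([[region(100, 180, s)]
                                      for s in "ABC"])
        assert len(merged) == 1
        assert merged[0].samples == {"A", "B", "C"}
        assert merged[0].total_support == 15

    def test_merge_respects_length_cap(self):
        # b_l < e_k holds but the merged span would reach the cap
        merged = merge_regions_multi([[region(100, 180, "A")],
                                      [region(170, 310, "B")]],
                                     region_len=200)
        assert len(merged) == 2


class TestVoting:
    def hit(self, sample, side, pos, n=1, fam="AluSyn1"):
        return [SplitHit(sample=sample, side=side, position=pos,
                         alu_name=fam, score=50.0)] * n

    def test_modal_positions_elected_per_side(self):
        hits = (self.hit("s1", "AL", 5_000, 3) + self.hit("s1", "AL", 5_003)
                + self.hit("s2", "AL", 5_000, 2)
                + self.hit("s1", "AR", 4_996, 2)
                + self.hit("s2", "AR", 4_996, 2))
        bp = vote_breakpoints(hits)
        assert bp.AL == 5_000
        assert bp.AR == 4_996
        assert bp.tsd_length == 4  # AL right of AR: target-site duplication

    def test_second_level_is_one_individual_one_vote(self):
        # s1 has many reads at 5003, but s2 and s3 each elect 5000
        hits = (self.hit("s1", "AL", 5_003, 10)
                + self.hit("s2", "AL", 5_000)
                + self.hit("s3", "AL", 5_000))
        assert vote_breakpoints(hits).AL == 5_000

    def test_distant_sides_keep_majority_side(self):
        hits = (self.hit("s1", "AL", 5_000) + self.hit("s2", "AL", 5_000)
                + self.hit("s3", "AR", 5_200))
        bp = vote_breakpoints(hits)
        assert bp.AL == 5_000
        assert bp.AR is None

    def test_no_hits_no_breakpoint(self):
        assert vote_breakpoints([]) is None

    @settings(max_examples=30, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_vote_invariant_under_permutation(self, rnd):
        hits = (self.hit("s1", "AL", 5_000, 2) + self.hit("s1", "AL", 5_001)
                + self.hit("s2", "AL", 5_001, 2)
                + self.hit("s3", "AR", 5_000, 3)
                + self.hit("s2", "AR", 4_990, 1))
        baseline = vote_breakpoints(hits)
        shuffled = list(hits)
        rnd.shuffle(shuffled)
        permuted = vote_breakpoints(shuffled)
        assert (permuted.AL, permuted.AR) == (baseline.AL, baseline.AR)


class TestSplitMapCRead:
    def c_read(self, clip_seq, side="right", anchor_len=60, pos=5_000):
        return InformativeRead(
            kind="C", sample="s1", chrom="chr1", begin=pos - anchor_len,
            end=pos, clip_side=side, clip_pos=pos, clip_seq=clip_seq,
            anchor_len=anchor_len)

    def test_alu_matching_clip_votes_left_breakpoint(self, panel):
        alu = next(iter(panel.values()))
        hit = split_map_c_read(self.c_read(alu[:40]), panel)
        assert hit is not None
        assert hit.side == "AL"
        assert hit.position == 5_000

    def test_reverse_strand_clip_recognized(self, panel):
        from alucall.split import revcomp
        alu = next(iter(panel.values()))
        hit = split_map_c_read(self.c_read(revcomp(alu[:40])), panel)
        assert hit is not None

    def test_left_clip_votes_right_breakpoint(self, panel):
        alu = next(iter(panel.values()))
        read = InformativeRead(
            kind="C", sample="s1", chrom="chr1", begin=5_000, end=5_060,
            clip_side="left", clip_pos=5_000, clip_seq=alu[-40:],
            anchor_len=60)
        hit = split_map_c_read(read, panel)
        assert hit is not None and hit.side == "AR"

    def test_non_alu_clip_rejected(self, panel):
        from conftest import random_seq
        assert split_map_c_read(self.c_read(random_seq(40, seed=9)),
                                panel) is None

    def test_short_clip_rejected(self, panel):
        alu = next(iter(panel.values()))
        assert split_map_c_read(self.c_read(alu[:15]), panel) is None


def test_simulated_insertions_recovered(simins_small, panel):
    """End-to-end discovery and genotyping on a small SimIns population."""
    from alucall.insertion import call_insertions
    from alucall.loci import read_alu_bed
    from alucall.vcfio import read_genotypes_vcf

    loci = read_alu_bed(simins_small.known_alus_bed)
    samples, calls = call_insertions(simins_small.reference_fasta,
                                     simins_small.bam_paths, loci, panel)
    truth_points = {t.position: t.name for t in simins_small.simref.targets}
    # polymorphic loci present in at least one individual
    _, trecs = read_genotypes_vcf(simins_small.truth_vcf)
    truth = {r["id"]: r["genotypes"] for r in trecs}
    carried = {p: n for p, n in truth_points.items()
               if any(g != "G0" for g in truth[n].values())}
    found = 0
    for call in calls:
        near = [p for p in carried if abs(p - call.breakpoint.position) <= 50]
        if near:
            found += 1
            assert abs(near[0] - call.breakpoint.position) <= 5
    assert found >= max(1, int(0.8 * len(carried)))
    # no calls far away from every true site
    for call in calls:
        assert any(abs(p - call.breakpoint.position) <= 50 for p in carried)
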