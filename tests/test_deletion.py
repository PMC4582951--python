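"""Deletion path: windows, pair classification, split realignment,
locus genotyping on a simulated population."""

import pytest

from alucall.deletion import (ClassifiedPair, classify_pair,
                              pair_allele_likelihoods, split_realign)
from alucall.genotype import GenotypeModel
from alucall.insert_model import DENSITY_FLOOR
from alucall.loci import AluLocus, AnalysisWindow, build_window, read_alu_bed
from alucall.pairs import ReadPairRecord

from conftest import random_seq


@pytest.fixture(scope="module")
def window(narrow_model_module):
    locus = AluLocus("chr1", 10_000, 10_300, "alu1")
    return build_window(locus, narrow_model_module)


@pytest.fixture(scope="module")
def narrow_model_module():
    import numpy as np
    from alucall.insert_model import model_from_lengths
    rng = np.random.default_rng(11)
    ys = np.round(rng.normal(300, 30, 5000)).astype(int).tolist()
    return model_from_lengths({"default": ys}, min_pairs_per_library=100)


def test_window_flanks_are_mean_plus_three_sd(narrow_model_module):
    locus = AluLocus("chr1", 10_000, 10_300, "alu1")
    w = narrow_model_module.flank_width()
    win = build_window(locus, narrow_model_module)
    assert win.locus.AL - win.FL == w
    assert win.FR - win.locus.AR == w
    mean, sd = narrow_model_module.mean_sd()
    assert w == int(round(mean + 3 * sd))


def test_window_clipped_at_chromosome_start(narrow_model_module):
    locus = AluLocus("chr1", 100, 400, "alu_edge")
    win = build_window(locus, narrow_model_module, chrom_length=5_000)
    assert win.FL == 0
    assert win.FR <= 5_000


def test_degenerate_sd_window():
    from alucall.insert_model import model_from_lengths
    model = model_from_lengths({"default": [300] * 50},
                               min_pairs_per_library=10)
    # sd 0 is replaced by 1 bp, so the flank is E[Y] + 3
    assert model.flank_width() == 303


def _pair(bL, eL, bR, eR, **kw):
    return ReadPairRecord(pair_id="p", chrom="chr1", begin_L=bL, end_L=eL,
                          begin_R=bR, end_R=eR, **kw)


class TestClassifyPair:
    """Placement rules for I (internal) and A (across) evidence."""

    def test_left_flank_and_inside_is_internal(self, window):
        cp = classify_pair(_pair(9_700, 9_800, 10_050, 10_150), window)
        assert cp.type == "I"

    def test_inside_and_right_flank_is_internal(self, window):
        cp = classify_pair(_pair(10_050, 10_150, 10_350, 10_450), window)
        assert cp.type == "I"

    def test_flank_to_flank_is_across(self, window):
        cp = classify_pair(_pair(9_700, 9_800, 10_350, 10_450), window)
        assert cp.type == "A"

    def test_both_mates_inside_alu_dropped(self, window):
        assert classify_pair(_pair(10_050, 10_150, 10_160, 10_260),
                             window) is None

    def test_wrong_orientation_dropped(self, window):
        assert classify_pair(_pair(9_700, 9_800, 10_350, 10_450,
                                   strand_L="-", strand_R="+"),
                             window) is None

    def test_pair_outside_window_dropped(self, window):
        assert classify_pair(_pair(100, 200, 400, 500), window) is None


class TestSplitRealign:
    def setup_method(self):
        self.ref_seq = random_seq(12_000, seed=5)
        self.reference = {"chr1": self.ref_seq}
        self.locus = AluLocus("chr1", 10_000, 10_300, "alu1")
        self.window = AnalysisWindow(self.locus, 9_610, 10_690)

    def read_across(self, left, right):
        return (self.ref_seq[10_000 - left:10_000]
                + self.ref_seq[10_300:10_300 + right])

    def test_perfect_split_accepted(self):
        detail = split_realign(self.read_across(50, 50), self.window,
                               self.reference)
        assert detail is not None
        assert detail.left_aligned >= 20 and detail.right_aligned >= 20
        assert detail.clip_pos == 50

    def test_short_flank_rejected(self):
        assert split_realign(self.read_across(85, 15), self.window,
                             self.reference) is None

    def test_mismatched_split_still_accepted(self):
        seq = self.read_across(50, 50)
        mutated = list(seq)
        for i in (5, 20, 40):  # 3 mismatches in the left flank
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        detail = split_realign("".join(mutated), self.window, self.reference)
        assert detail is not None
        assert detail.score >= 25

    def test_contiguous_reference_read_rejected(self):
        seq = self.ref_seq[9_900:10_000] + ""
        assert split_realign(seq, self.window, self.reference) is None


def test_allele_likelihoods_by_type(narrow_model_module):
    gm = GenotypeModel(pe=0.001)
    i_pair = ClassifiedPair(_pair(9_700, 9_800, 10_050, 10_150), "I")
    assert pair_allele_likelihoods(i_pair, narrow_model_module, 300,
                                   gm.pe) == (1.0, 0.001)
    mean = narrow_model_module.mean_sd()[0]
    # spanning pair at the distribution mode: strongly supports H0
    a_ref = ClassifiedPair(
        _pair(9_700, 9_800, 9_700 + int(mean) - 100, 9_700 + int(mean)), "A")
    lh0, lh1 = pair_allele_likelihoods(a_ref, narrow_model_module, 300, 0.001)
    assert lh0 > lh1
    assert lh1 == DENSITY_FLOOR
    # spanning pair shifted by l_Alu: strongly supports H1
    a_del = ClassifiedPair(
        _pair(9_700, 9_800, 9_700 + int(mean) + 200, 9_700 + int(mean) + 300),
        "A")
    lh0, lh1 = pair_allele_likelihoods(a_del, narrow_model_module, 300, 0.001)
    assert lh1 > lh0
    assert lh0 == DENSITY_FLOOR


def test_simulated_population_genotypes_recovered(simdel_small):
    """Deletion calling on a small simulated population matches truth."""
    from alucall.deletion import call_deletions
    from alucall.vcfio import read_genotypes_vcf

    loci = read_alu_bed(simdel_small.targets_bed)
    samples, calls = call_deletions(simdel_small.reference_fasta,
                                    simdel_small.bam_paths, loci)
    _, trecs = read_genotypes_vcf(simdel_small.truth_vcf)
    truth = {r["id"]: r["genotypes"] for r in trecs}
    total = correct = 0
    for name, locus_calls in calls.items():
        for call in locus_calls:
            total += 1
            correct += call.genotype == truth[name][call.sample]
    assert total == len(loci) * len(samples)
    assert correct / total >= 0.9
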