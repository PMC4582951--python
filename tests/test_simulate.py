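"""Simulator: placement constraints, determinism, truth consistency,
and the read-level signals the callers depend on."""

import numpy as np
import pysam
import pytest

from alucall.simulate import (SimConfig, SimConfigError, make_reference,
                              simulate_population)


def small_cfg(**kw):
    base = dict(mode="SimDel", reference_length=80_000, n_loci=3,
                n_haplotypes=4, coverage=10.0, n_decoys=8, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestMakeReference:
    def test_spacing_constraint_holds(self, panel):
        simref = make_reference(small_cfg(), panel)
        alus = sorted([(t.position, t.end) for t in simref.targets]
                      + [(d.AL, d.AR) for d in simref.decoys])
        for (_, e1), (b2, _) in zip(alus, alus[1:]):
            assert b2 - e1 >= 600
        assert len(simref.targets) == 3

    def test_planted_targets_spell_their_sequence(self, panel):
        simref = make_reference(small_cfg(), panel)
        for t in simref.targets:
            assert simref.seq[t.position:t.end] == t.seq

    def test_seeded_determinism(self, panel):
        a = make_reference(small_cfg(seed=9), panel)
        b = make_reference(small_cfg(seed=9), panel)
        assert a.seq == b.seq
        assert [(t.position, t.seq) for t in a.targets] \
            == [(t.position, t.seq) for t in b.targets]

    def test_infeasible_config_raises(self, panel):
        with pytest.raises(SimConfigError):
            make_reference(small_cfg(reference_length=10_000, n_loci=100),
                           panel)

    def test_simins_reference_excludes_targets(self, panel):
        cfg = small_cfg(mode="SimIns")
        simref = make_reference(cfg, panel)
        # the target sequence is absent at its insertion point
        for t in simref.targets:
            assert simref.seq[t.position:t.end] != t.seq


class TestPopulation:
    def test_genotypes_are_carrier_dosages(self, panel):
        cfg = small_cfg()
        simref = make_reference(cfg, panel)
        truth = simulate_population(cfg, simref)
        for name, carry in truth.carriers.items():
            dosage = carry[0::2].astype(int) + carry[1::2].astype(int)
            assert [f"G{d}" for d in dosage] == truth.genotypes[name]

    def test_mean_heterozygosity_matches_uniform_frequency_law(self, panel):
        """E[2p(1-p)] = 1/3 under p ~ U(0,1): with many loci the mean
        heterozygote count per individual approaches n_loci / 3."""
        cfg = small_cfg(reference_length=3_000_000, n_loci=100, n_decoys=10,
                        n_haplotypes=200)
        simref = make_reference(cfg, panel)
        truth = simulate_population(cfg, simref)
        hets = [h for h, _ in truth.het_hom_counts()]
        assert np.mean(hets) == pytest.approx(100 / 3, rel=0.25)


@pytest.fixture(scope="module")
def dataset(tmp_path_factory, panel):
    from alucall.simulate import simulate_dataset
    cfg = small_cfg(coverage=20.0, seed=7)
    return simulate_dataset(cfg, str(tmp_path_factory.mktemp("ds")), panel)


class TestAlignments:

    def test_outputs_exist_and_are_indexed(self, dataset):
        assert len(dataset.bam_paths) == 2
        for path in dataset.bam_paths:
            with pysam.AlignmentFile(path) as bam:
                assert bam.has_index()

    def test_non_carrier_locus_has_no_junction_clips(self, dataset):
        """An individual with genotype G0 shows no soft-clipped reads and
        normally distributed spanning inserts at its locus."""
        found = False
        for idx, sample in enumerate(dataset.truth.samples):
            for t in dataset.simref.targets:
                if dataset.truth.genotypes[t.name][idx] != "G0":
                    continue
                found = True
                with pysam.AlignmentFile(dataset.bam_paths[idx]) as bam:
                    for read in bam.fetch(dataset.simref.chrom,
                                          t.position - 50, t.end + 50):
                        assert "S" not in (read.cigarstring or "")
        assert found

    def test_carrier_spanning_inserts_shift_by_alu_length(self, dataset):
        """A G2 individual's pairs spanning the deleted Alu measure about
        l_Alu more insert than the library mean."""
        cfg = dataset.cfg
        shifts = []
        for idx, sample in enumerate(dataset.truth.samples):
            for t in dataset.simref.targets:
                if dataset.truth.genotypes[t.name][idx] != "G2":
                    continue
                with pysam.AlignmentFile(dataset.bam_paths[idx]) as bam:
                    for read in bam.fetch(dataset.simref.chrom,
                                          t.position - 200, t.position):
                        if (read.is_reverse or read.cigartuples is None
                                or len(read.cigartuples) != 1):
                            continue
                        mate_end = read.next_reference_start + cfg.read_length
                        if read.next_reference_start >= t.end:
                            shifts.append(mate_end - read.reference_start
                                          - t.length)
        if shifts:  # spanning pairs exist unless coverage fluctuated low
            assert np.mean(shifts) == pytest.approx(cfg.insert_mean, abs=60)

    def test_read_sequences_match_reference_where_aligned(self, dataset):
        """Cleanly mapped reads mostly spell the reference (SNP + error
        rates put expected identity above 99%)."""
        ref = dataset.simref.seq
        checked = mismatches = bases = 0
        with pysam.AlignmentFile(dataset.bam_paths[0]) as bam:
            for read in bam.fetch():
                if len(read.cigartuples) != 1 or read.cigartuples[0][0] != 0:
                    continue
                seq = read.query_sequence
                refpart = ref[read.reference_start:
                              read.reference_start + len(seq)]
                mismatches += sum(a != b for a, b in zip(seq, refpart))
                bases += len(seq)
                checked += 1
                if checked >= 2_000:
                    break
        assert checked > 100
        assert mismatches / bases < 0.01

    def test_coverage_matches_request(self, dataset):
        cfg = dataset.cfg
        ref_len = len(dataset.simref.seq)
        with pysam.AlignmentFile(dataset.bam_paths[0]) as bam:
            bases = sum(read.query_alignment_length for read in bam.fetch())
        assert bases / ref_len == pytest.approx(cfg.coverage, rel=0.1)

    def test_seeded_alignment_determinism(self, tmp_path, panel):
        from alucall.simulate import simulate_dataset
        cfg = small_cfg(reference_length=40_000, n_loci=1, n_decoys=4,
                        coverage=5.0, seed=21)
        ds1 = simulate_dataset(cfg, str(tmp_path / "a"), panel)
        ds2 = simulate_dataset(cfg, str(tmp_path / "b"), panel)
        for p1, p2 in zip(ds1.bam_paths, ds2.bam_paths):
            with pysam.AlignmentFile(p1) as b1, pysam.AlignmentFile(p2) as b2:
                r1 = [r.to_string() for r in b1.fetch()]
                r2 = [r.to_string() for r in b2.fetch()]
        assert r1 == r2
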