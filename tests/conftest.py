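"""Shared fixtures: tiny references, hand-built BAMs, small simulated sets."""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
import pytest

from alucall.insert_model import InsertLengthModel, model_from_lengths
from alucall.panel import load_panel, default_panel_path


@pytest.fixture(scope="session")
def panel() -> Dict[str, str]:
    return load_panel(default_panel_path())


@pytest.fixture(scope="session")
def narrow_model() -> InsertLengthModel:
    """Insert-length model around 300 +/- 30 bp, built from raw lengths."""
    rng = np.random.default_rng(11)
    ys = np.round(rng.normal(300, 30, 5000)).astype(int).tolist()
    return model_from_lengths({"default": ys}, min_pairs_per_library=100)


def random_seq(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class SamBuilder:
    """Assemble a small coordinate-sorted indexed BAM from explicit rows."""

    def __init__(self, chrom: str = "chr1", length: int = 100_000,
                 sample: str = "s1"):
        self.chrom = chrom
        self.length = length
        self.sample = sample
        self.rows: List[str] = []

    def add(self, name: str, pos: int, cigar: str, seq: str,
            flag: int = 99, mate_pos: Optional[int] = None, tlen: int = 0,
            mapq: int = 60, qual: Optional[str] = None) -> "SamBuilder":
        qual = qual or chr(35 + 33) * len(seq)
        mate_pos = pos if mate_pos is None else mate_pos
        self.rows.append(
            f"{name}\t{flag}\t{self.chrom}\t{pos + 1}\t{mapq}\t{cigar}\t=\t"
            f"{mate_pos + 1}\t{tlen}\t{seq}\t{qual}\tRG:Z:{self.sample}")
        return self

    def add_pair(self, name: str, pos1: int, pos2: int, seq1: str, seq2: str,
                 cigar1: Optional[str] = None, cigar2: Optional[str] = None,
                 proper: bool = True) -> "SamBuilder":
        """A forward/reverse FR pair with consistent flags and TLEN."""
        base = 1 + (2 if proper else 0)
        tlen = (pos2 + len(seq2)) - pos1
        self.add(name, pos1, cigar1 or f"{len(seq1)}M", seq1,
                 flag=base + 32 + 64, mate_pos=pos2, tlen=tlen if proper else 0)
        self.add(name, pos2, cigar2 or f"{len(seq2)}M", seq2,
                 flag=base + 16 + 128, mate_pos=pos1,
                 tlen=-tlen if proper else 0)
        return self

    def write(self, path: str) -> str:
        header = [
            "@HD\tVN:1.6\tSO:unsorted",
            f"@SQ\tSN:{self.chrom}\tLN:{self.length}",
            f"@RG\tID:{self.sample}\tSM:{self.sample}\tLB:{self.sample}_lib",
        ]
        tmp = path + ".sam"
        with open(tmp, "w") as fh:
            fh.write("\n".join(header + self.rows) + "\n")
        pysam.sort("-o", path, tmp)
        os.remove(tmp)
        pysam.index(path)
        return path


def write_fasta(path: str, chrom: str, seq: str) -> str:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")
    pysam.faidx(path)
    return path


@pytest.fixture(scope="session")
def simdel_small(tmp_path_factory):
    """A small SimDel population shared by integration tests."""
    from alucall.simulate import SimConfig, simulate_dataset

    out = tmp_path_factory.mktemp("simdel_small")
    cfg = SimConfig(mode="SimDel", reference_length=150_000, n_loci=4,
                    n_haplotypes=8, coverage=25.0, seed=42)
    return simulate_dataset(cfg, str(out))


@pytest.fixture(scope="session")
def simins_small(tmp_path_factory):
    """A small SimIns population shared by integration tests."""
    from alucall.simulate import SimConfig, simulate_dataset

    out = tmp_path_factory.mktemp("simins_small")
    cfg = SimConfig(mode="SimIns", reference_length=150_000, n_loci=4,
                    n_haplotypes=8, coverage=25.0, seed=43)
    return simulate_dataset(cfg, str(out))
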