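"""Truth-known simulation of Alu-polymorphic populations and their reads.

Two designs are supported. ``SimDel`` plants target Alu elements in a
synthetic reference and deletes each from haplotypes at a locus frequency
drawn uniformly on (0, 1). ``SimIns`` removes the target elements from
the working reference and re-inserts them into haplotypes at such
frequencies, so the events are insertions relative to the reference used
for calling. Haplotypes are paired consecutively into diploids. Decoy Alu
copies (diverged panel sequences) are scattered through the background so
that reads from inserted Alus have somewhere to mismap, as they do with a
real aligner, and serve as the "known Alu" annotation the insertion
caller requires.

Reads are emitted as truth-aware alignments directly in working-reference
coordinates: junction-crossing reads become single soft-clipped primary
records, pairs spanning a deleted Alu measure an extra l_Alu of insert,
reads inside an inserted Alu are placed on a random decoy copy with their
pair flagged discordant. No external aligner or download is involved.
All outputs are deterministic under the configured seed.
"""

from __future__ import annotations

import math
import os
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .loci import AluLocus, write_alu_bed
from .panel import load_panel, default_panel_path

_BASES = np.array(list("ACGT"))
_COMPL = str.maketrans("ACGTN", "TGCAN")

#: base quality assigned to every simulated base (constant-quality model)
BASE_QUAL = 35


class SimConfigError(ValueError):
    """The simulation configuration is infeasible."""


@dataclass
class SimConfig:
    """Study design of one simulated dataset.

    Defaults mirror the reference design: 100 polymorphic loci at
    frequencies uniform on (0,1), 200 haplotypes paired into 100
    diploids, Alu spacing of at least 600 bp, paired-end reads with
    SNP/indel noise at ~10x or ~25x coverage.
    """

    mode: str = "SimDel"              # "SimDel" or "SimIns"
    reference_length: int = 5_000_000
    n_loci: int = 100
    min_spacing: int = 600
    n_haplotypes: int = 200
    coverage: float = 25.0
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    snp_rate: float = 1e-3
    indel_rate: float = 1e-4
    error_rate: float = 1e-3
    n_decoys: int = 30
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("SimDel", "SimIns"):
            raise SimConfigError(f"unknown mode {self.mode!r}")
        if self.n_haplotypes % 2:
            raise SimConfigError("n_haplotypes must be even (diploid pairing)")
        if self.insert_mean < 2 * self.read_length:
            raise SimConfigError("insert_mean must exceed twice the read length")

    @property
    def n_individuals(self) -> int:
        return self.n_haplotypes // 2


@dataclass
class TargetAlu:
    """A planted polymorphic Alu: an interval in SimDel, a point in SimIns."""

    name: str
    position: int          # AL (SimDel) or insertion point (SimIns)
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        """AR in SimDel coordinates; equals position in SimIns."""
        return self.position + self.length


@dataclass
class SimReference:
    chrom: str
    seq: str
    mode: str
    targets: List[TargetAlu]
    decoys: List[AluLocus]

    def target_loci(self) -> List[AluLocus]:
        """Target intervals as BED-able loci (SimDel annotation)."""
        return [AluLocus(self.chrom, t.position, t.end, t.name)
                for t in self.targets]


@dataclass
class TruthSet:
    """Drawn frequencies, per-haplotype carriers and diploid genotypes."""

    mode: str
    chrom: str
    frequencies: Dict[str, float]
    carriers: Dict[str, np.ndarray]          # locus -> bool per haplotype
    genotypes: Dict[str, List[str]]          # locus -> G0/G1/G2 per individual
    samples: List[str] = field(default_factory=list)

    def het_hom_counts(self) -> List[Tuple[int, int]]:
        """(heterozygote, homozygote-carrier) count per individual."""
        out = []
        for i in range(len(self.samples)):
            het = sum(1 for g in self.genotypes.values() if g[i] == "G1")
            hom = sum(1 for g in self.genotypes.values() if g[i] == "G2")
            out.append((het, hom))
        return out


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    k = int(round(rate * arr.size))
    if k:
        pos = rng.choice(arr.size, size=k, replace=False)
        arr[pos] = _BASES[rng.integers(0, 4, size=k)]
    return "".join(arr)


def make_reference(cfg: SimConfig, panel: Optional[Dict[str, str]] = None,
                   ) -> SimReference:
    """Build the working reference with decoy and target Alu elements.

    Insertion points for decoys and targets are drawn on a random
    background so that no two Alus lie within ``min_spacing`` of each
    other; decoys carry 5-15% divergence from their panel consensus.
    In SimIns mode the working reference contains only the decoys and
    each target is recorded as an insertion point.
    """
    rng = np.random.default_rng(cfg.seed)
    if panel is None:
        panel = load_panel(default_panel_path())
    names = sorted(panel)
    max_alu = max(len(s) for s in panel.values())
    slot = cfg.min_spacing + max_alu
    n_slots = cfg.n_loci + cfg.n_decoys
    if n_slots * slot >= cfg.reference_length:
        raise SimConfigError(
            f"cannot place {n_slots} Alus with {cfg.min_spacing} bp spacing "
            f"on a {cfg.reference_length} bp reference")
    background = _random_seq(rng, cfg.reference_length)
    # stratified placement: one point per slot-sized bin keeps spacing
    bins = np.linspace(0, cfg.reference_length - max_alu, n_slots + 1).astype(int)
    points = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        points.append(int(rng.integers(lo, max(lo + 1, hi - slot))))
    points = sorted(points)
    roles = np.array(["T"] * cfg.n_loci + ["D"] * cfg.n_decoys)
    rng.shuffle(roles)

    pieces: List[str] = []
    cursor = 0
    targets: List[TargetAlu] = []
    decoys: List[AluLocus] = []
    shift = 0  # working-reference offset accumulated so far
    t_idx = d_idx = 0
    for pt, role in zip(points, roles):
        pieces.append("".join(background[cursor:pt]))
        cursor = pt
        src = names[int(rng.integers(len(names)))]
        if role == "T":
            seq = _diverge(rng, panel[src], 0.02)
            pos = pt + shift
            t_idx += 1
            if cfg.mode == "SimDel":
                targets.append(TargetAlu(f"target_{t_idx:03d}", pos, seq))
                pieces.append(seq)
                shift += len(seq)
            else:
                targets.append(TargetAlu(f"target_{t_idx:03d}", pos, seq))
        else:
            seq = _diverge(rng, panel[src], float(rng.uniform(0.05, 0.15)))
            pos = pt + shift
            d_idx += 1
            decoys.append(AluLocus(cfg.chrom, pos, pos + len(seq),
                                   f"decoy_{d_idx:03d}"))
            pieces.append(seq)
            shift += len(seq)
    pieces.append("".join(background[cursor:]))
    return SimReference(chrom=cfg.chrom, seq="".join(pieces), mode=cfg.mode,
                        targets=targets, decoys=decoys)


def simulate_population(cfg: SimConfig, simref: SimReference) -> TruthSet:
    """Draw locus frequencies and haplotype carrier states.

    Each locus gets a frequency p ~ U(0, 1); every haplotype carries the
    event independently with probability p. Haplotypes 2i and 2i+1 form
    individual i, whose genotype is the carrier dosage: G0 none, G1 one,
    G2 both. In SimDel "carrier" means carrying the deletion, so G0 is
    the homozygous-Alu (reference) state, matching the caller's output.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    samples = [f"ind{i:03d}" for i in range(cfg.n_individuals)]
    truth = TruthSet(mode=cfg.mode, chrom=simref.chrom, frequencies={},
                     carriers={}, genotypes={}, samples=samples)
    for tgt in simref.targets:
        p = float(rng.uniform(0.0, 1.0))
        carry = rng.random(cfg.n_haplotypes) < p
        dosage = carry[0::2].astype(int) + carry[1::2].astype(int)
        truth.frequencies[tgt.name] = p
        truth.carriers[tgt.name] = carry
        truth.genotypes[tgt.name] = [f"G{d}" for d in dosage]
    return truth


# ---------------------------------------------------------------------------
# haplotype assembly and truth-aware read placement

@dataclass
class _Segment:
    hap_start: int
    hap_end: int
    kind: str              # "ref" or "alu"
    ref_start: int         # reference coordinate of hap_start ("ref" only)
    alu_offset: int = 0    # offset into the inserted Alu ("alu" only)
    junction_left: int = 0  # reference position where an "alu" segment breaks


def _haplotype(simref: SimReference, truth: TruthSet, hap: int,
               cfg: SimConfig, rng: np.random.Generator,
               ) -> Tuple[str, List[_Segment]]:
    """Assemble one haplotype sequence and its hap->reference segment map."""
    ref = simref.seq
    events = [t for t in simref.targets if truth.carriers[t.name][hap]]
    events.sort(key=lambda t: t.position)
    parts: List[str] = []
    segs: List[_Segment] = []
    cursor = 0          # reference coordinate
    hap_pos = 0
    for t in events:
        if cfg.mode == "SimDel":
            span = t.position - cursor
            parts.append(ref[cursor:t.position])
            segs.append(_Segment(hap_pos, hap_pos + span, "ref", cursor))
            hap_pos += span
            cursor = t.end  # skip the deleted Alu
        else:
            span = t.position - cursor
            parts.append(ref[cursor:t.position])
            segs.append(_Segment(hap_pos, hap_pos + span, "ref", cursor))
            hap_pos += span
            parts.append(t.seq)
            segs.append(_Segment(hap_pos, hap_pos + t.length, "alu",
                                 ref_start=t.position,
                                 junction_left=t.position))
            hap_pos += t.length
            cursor = t.position
    parts.append(ref[cursor:])
    segs.append(_Segment(hap_pos, hap_pos + len(ref) - cursor, "ref", cursor))
    seq = "".join(parts)
    # haplotype SNVs: substitutions at snp_rate, in haplotype coordinates
    arr = bytearray(seq, "ascii")
    n_snp = rng.binomial(len(arr), cfg.snp_rate)
    if n_snp:
        pos = rng.choice(len(arr), size=n_snp, replace=False)
        subs = _BASES[rng.integers(0, 4, size=n_snp)]
        for p, b in zip(pos, subs):
            arr[p] = ord(b)
    return arr.decode("ascii"), segs


@dataclass
class _Placed:
    """A simulated read placed on the working reference."""

    pos: int = -1
    cigar: Optional[List[Tuple[int, int]]] = None
    in_alu: bool = False
    alu_offset: int = 0

    @property
    def mapped(self) -> bool:
        return self.cigar is not None


def _place_read(a: int, b: int, segs: List[_Segment], starts: List[int],
                ) -> Optional[_Placed]:
    """Map a haplotype interval [a, b) to reference coordinates."""
    i = bisect_right(starts, a) - 1
    j = bisect_right(starts, b - 1) - 1
    rl = b - a
    if i == j:
        seg = segs[i]
        if seg.kind == "ref":
            return _Placed(pos=seg.ref_start + (a - seg.hap_start),
                           cigar=[(0, rl)])
        return _Placed(in_alu=True, alu_offset=a - seg.hap_start)
    if j - i != 1:
        return None  # read spans more than one junction: drop
    s1, s2 = segs[i], segs[j]
    k = s2.hap_start - a          # bases in the first segment
    if s1.kind == "ref" and s2.kind == "ref":
        # deletion junction: first part ends at AL, second starts at AR
        if k >= rl - k:
            return _Placed(pos=s1.ref_start + (a - s1.hap_start),
                           cigar=[(0, k), (4, rl - k)])
        return _Placed(pos=s2.ref_start, cigar=[(4, k), (0, rl - k)])
    if s1.kind == "ref":          # enters an inserted Alu: clip the tail
        if k == 0:
            return _Placed(in_alu=True, alu_offset=0)
        return _Placed(pos=s1.ref_start + (a - s1.hap_start),
                       cigar=[(0, k), (4, rl - k)])
    # leaves an inserted Alu: clip the head, map from the insertion point
    if rl - k == 0:
        return _Placed(in_alu=True, alu_offset=a - s1.hap_start)
    return _Placed(pos=s2.ref_start, cigar=[(4, k), (0, rl - k)])


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def _apply_errors(seq: str, n_err: int, rng: np.random.Generator) -> str:
    if n_err == 0:
        return seq
    arr = bytearray(seq, "ascii")
    pos = rng.integers(0, len(arr), size=n_err)
    subs = _BASES[rng.integers(0, 4, size=n_err)]
    for p, b in zip(pos, subs):
        arr[p] = ord(b)
    return arr.decode("ascii")


def _apply_indel(seq: str, cigar: List[Tuple[int, int]],
                 rng: np.random.Generator) -> Tuple[str, List[Tuple[int, int]]]:
    """Inject one small indel into a fully aligned read (geometric length)."""
    if len(cigar) != 1 or cigar[0][0] != 0:
        return seq, cigar
    rl = len(seq)
    length = min(5, 1 + rng.geometric(0.7))
    at = int(rng.integers(10, rl - 10 - length))
    if rng.random() < 0.5:  # insertion in the read
        ins = "".join(_BASES[rng.integers(0, 4, size=length)])
        seq = seq[:at] + ins + seq[at + length:]  # keep read length constant
        cigar = [(0, at), (1, length), (0, rl - at - length)]
    else:                    # deletion from the reference
        cigar = [(0, at), (2, length), (0, rl - at)]
    return seq, cigar


def simulate_alignments(
    truth: TruthSet,
    simref: SimReference,
    cfg: SimConfig,
    out_dir: str,
) -> List[str]:
    """Write one coordinate-sorted, indexed BAM per individual.

    Fragments are drawn per haplotype at half the individual coverage
    with insert length ~ Normal(mean, sd) truncated above twice the read
    length. Reads are placed in working-reference coordinates with
    truth-aware CIGARs and flags; pairs with both mates cleanly mapped in
    FR orientation within the concordant insert bound carry the
    proper-pair flag.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 2)
    rl = cfg.read_length
    ref_len = len(simref.seq)
    decoys = [d for d in simref.decoys if d.length >= rl]
    if cfg.mode == "SimIns" and not decoys:
        raise SimConfigError("SimIns requires decoy Alus at least one read long")
    proper_max = cfg.insert_mean + 4.0 * cfg.insert_sd
    paths: List[str] = []
    for ind, sample in enumerate(truth.samples):
        lines: List[str] = [
            "@HD\tVN:1.6\tSO:unsorted",
            f"@SQ\tSN:{simref.chrom}\tLN:{ref_len}",
            f"@RG\tID:{sample}\tSM:{sample}\tLB:{sample}_lib",
        ]
        for hap in (2 * ind, 2 * ind + 1):
            seq, segs = _haplotype(simref, truth, hap, cfg, rng)
            starts = [s.hap_start for s in segs]
            hap_len = len(seq)
            n_frag = int(round(cfg.coverage / 2.0 * hap_len / (2.0 * rl)))
            frags = np.maximum(
                2 * rl + 1,
                np.round(rng.normal(cfg.insert_mean, cfg.insert_sd,
                                    n_frag)).astype(int))
            frags = np.minimum(frags, hap_len)
            starts_f = (rng.random(n_frag) * (hap_len - frags + 1)).astype(int)
            err_counts = rng.binomial(rl, cfg.error_rate, size=(n_frag, 2))
            indel_p = 1.0 - (1.0 - cfg.indel_rate) ** rl
            has_indel = rng.random((n_frag, 2)) < indel_p
            for fi in range(n_frag):
                s, f = int(starts_f[fi]), int(frags[fi])
                a1, b1 = s, s + rl
                a2, b2 = s + f - rl, s + f
                p1 = _place_read(a1, b1, segs, starts)
                p2 = _place_read(a2, b2, segs, starts)
                if p1 is None or p2 is None:
                    continue
                if p1.in_alu and p2.in_alu:
                    continue  # fragment entirely inside the insertion
                seq1 = seq[a1:b1]
                seq2 = seq[a2:b2]
                name = f"{sample}_h{hap}_{fi}"
                _emit_pair(lines, name, sample, seq1, seq2, p1, p2, decoys,
                           rng, simref.chrom, rl, proper_max,
                           err_counts[fi], has_indel[fi])
        path = os.path.join(out_dir, f"{sample}.bam")
        tmp = path + ".unsorted.sam"
        with open(tmp, "w") as out:
            out.write("\n".join(lines) + "\n")
        pysam.sort("-o", path, tmp)
        os.remove(tmp)
        pysam.index(path)
        paths.append(path)
    return paths


_CIGAR_OP = "MIDNSHP=X"


def _cigar_str(cigar: List[Tuple[int, int]]) -> str:
    return "".join(f"{n}{_CIGAR_OP[op]}" for op, n in cigar)


def _emit_pair(lines, name, sample, seq1, seq2, p1, p2, decoys, rng,
               chrom, rl, proper_max, err_counts, has_indel):
    """Append the two SAM records of one fragment to ``lines``."""
    placements = (p1, p2)
    seqs = [seq1, seq2]
    # a read inside an inserted Alu mismaps to a random decoy copy
    for pl in placements:
        if pl.in_alu:
            d = decoys[int(rng.integers(len(decoys)))]
            off = min(pl.alu_offset, d.length - rl)
            pl.pos = d.AL + off
            pl.cigar = [(0, rl)]
    any_in_alu = p1.in_alu or p2.in_alu
    clean = len(p1.cigar) == 1 and len(p2.cigar) == 1
    y = (p2.pos + rl) - p1.pos  # outer span if both simple
    proper = (not any_in_alu and clean and p1.pos <= p2.pos
              and 2 * rl <= y <= proper_max)
    qual = _QUAL_CACHE.get(rl)
    if qual is None:
        qual = chr(BASE_QUAL + 33) * rl
        _QUAL_CACHE[rl] = qual
    # flag bits: 1 paired, 2 proper, 16/32 read/mate reverse, 64/128 read1/2
    base_flag = 1 + (2 if proper else 0)
    flags = (base_flag + 32 + 64, base_flag + 16 + 128)
    tlens = (y, -y) if proper else (0, 0)
    for idx, pl in enumerate(placements):
        # SEQ is stored on the reference forward strand, so the reverse
        # mate keeps the haplotype-forward sequence; only the flag flips.
        seq = seqs[idx]
        cigar = pl.cigar
        if err_counts[idx]:
            seq = _apply_errors(seq, int(err_counts[idx]), rng)
        if has_indel[idx] and not pl.in_alu:
            seq, cigar = _apply_indel(seq, cigar, rng)
        lines.append(
            f"{name}\t{flags[idx]}\t{chrom}\t{pl.pos + 1}\t60\t"
            f"{_cigar_str(cigar)}\t=\t{placements[1 - idx].pos + 1}\t"
            f"{tlens[idx]}\t{seq}\t{qual}\tRG:Z:{sample}")


_QUAL_CACHE: Dict[int, str] = {}


# ---------------------------------------------------------------------------
# dataset assembly

@dataclass
class SimDataset:
    """All artifacts of one simulated dataset."""

    cfg: SimConfig
    reference_fasta: str
    targets_bed: str
    known_alus_bed: str
    truth_vcf: str
    bam_paths: List[str]
    truth: TruthSet
    simref: SimReference


def write_reference_fasta(simref: SimReference, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{simref.chrom}\n")
        for i in range(0, len(simref.seq), 70):
            fh.write(simref.seq[i:i + 70] + "\n")
    pysam.faidx(path)


def write_truth_vcf(truth: TruthSet, simref: SimReference, path: str) -> None:
    """Truth genotypes as a minimal VCF 4.2 (1-based positions)."""
    svtype = "DEL" if truth.mode == "SimDel" else "INS"
    gt_map = {"G0": "0/0", "G1": "0/1", "G2": "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={truth.chrom},length={len(simref.seq)}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description='
                 '"Structural variant type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description='
                 '"End of the variant">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description='
                 '"Signed length of the variant">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description='
                 '"Simulated allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(truth.samples) + "\n")
        for tgt in sorted(simref.targets, key=lambda t: t.position):
            gts = truth.genotypes[tgt.name]
            freq = truth.frequencies[tgt.name]
            if svtype == "DEL":
                info = (f"SVTYPE=DEL;END={tgt.end};SVLEN=-{tgt.length};"
                        f"AF={freq:.4f}")
            else:
                info = f"SVTYPE=INS;SVLEN={tgt.length};AF={freq:.4f}"
            row = [truth.chrom, str(tgt.position + 1), tgt.name, "N",
                   f"<{svtype}>", ".", "PASS", info, "GT"]
            row += [gt_map[g] for g in gts]
            fh.write("\t".join(row) + "\n")


def simulate_dataset(cfg: SimConfig, out_dir: str,
                     panel: Optional[Dict[str, str]] = None) -> SimDataset:
    """Generate a complete dataset: reference, annotations, truth, BAMs."""
    os.makedirs(out_dir, exist_ok=True)
    simref = make_reference(cfg, panel)
    truth = simulate_population(cfg, simref)
    fasta = os.path.join(out_dir, "reference.fa")
    write_reference_fasta(simref, fasta)
    targets_bed = os.path.join(out_dir, "targets.bed")
    write_alu_bed(simref.target_loci(), targets_bed)
    known_bed = os.path.join(out_dir, "known_alus.bed")
    write_alu_bed(simref.decoys, known_bed)
    truth_vcf = os.path.join(out_dir, "truth.vcf")
    write_truth_vcf(truth, simref, truth_vcf)
    bams = simulate_alignments(truth, simref, cfg, os.path.join(out_dir, "bam"))
    return SimDataset(cfg=cfg, reference_fasta=fasta, targets_bed=targets_bed,
                      known_alus_bed=known_bed, truth_vcf=truth_vcf,
                      bam_paths=bams, truth=truth, simref=simref)
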