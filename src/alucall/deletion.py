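"""Genotyping Alu deletions at annotated reference loci.

For every annotated Alu [AL, AR) on the reference, concordantly oriented
read pairs with at least one mate in the window [FL, FR) are classified
into three evidence types:

* ``I`` (internal) — one mate in a flank, the other inside the Alu:
  evidence for the Alu-present allele H0.
* ``S`` (split) — a read that realigns across the deletion junction, at
  least 20 bp on each side of the Alu: evidence for the Alu-absent
  allele H1.
* ``A`` (across) — mates in opposite flanks; the insert length arbitrates
  between the alleles (H1 fragments measure l_Alu longer on the reference).

Pairs matching no type are dropped. A confirmed split takes precedence
over I/A: it is the strongest single-read signal and prevents
double-typing. The per-pair likelihoods feed the diploid mixture model in
:mod:`alucall.genotype`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pysam
from pyfaidx import Fasta

from . import bamio
from .genotype import (DEFAULT_PE, GenotypeCall, GenotypeModel, call_genotype,
                       genotype_log_likelihoods, pair_likelihood_for_type)
from .insert_model import InsertLengthModel
from .loci import AluLocus, AnalysisWindow, build_window
from .pairs import ReadPairRecord, insert_length
from .split import MIN_FLANK, MIN_SCORE, SplitDetail, align_across_junction

#: minimum soft-clip length for a read to be tried as a split candidate
MIN_CLIP_TRY = 10


@dataclass
class ClassifiedPair:
    pair: ReadPairRecord
    type: str  # "I", "S" or "A"
    split_detail: Optional[SplitDetail] = None

    def __post_init__(self) -> None:
        if self.type not in ("I", "S", "A"):
            raise ValueError(f"bad pair type {self.type!r}")
        if (self.type == "S") != (self.split_detail is not None):
            raise ValueError("split_detail present iff type S")


def _contained(begin: int, end: int, lo: int, hi: int) -> bool:
    return lo <= begin and end <= hi


def split_realign(
    read_seq: str,
    window: AnalysisWindow,
    reference,
    min_score: float = MIN_SCORE,
    min_flank: int = MIN_FLANK,
) -> Optional[SplitDetail]:
    """Try to realign a read across the Alu: one part ending at AL, the
    other starting at AR (Smith-Waterman, mismatches and small gaps
    allowed, >= ``min_flank`` bases on each side)."""
    loc = window.locus
    margin = len(read_seq) + 10
    left = str(reference[loc.chrom][max(0, loc.AL - margin):loc.AL])
    right = str(reference[loc.chrom][loc.AR:loc.AR + margin])
    return align_across_junction(read_seq, left, right,
                                 min_score=min_score, min_flank=min_flank)


def classify_read_group(
    reads: Sequence[pysam.AlignedSegment],
    window: AnalysisWindow,
    reference,
    libmap: Dict[str, str],
    sample: str,
    min_score: float = MIN_SCORE,
    min_flank: int = MIN_FLANK,
) -> Optional[ClassifiedPair]:
    """Classify one query-name group of alignments fetched from the window."""
    loc = window.locus
    # split evidence first: it needs only one clipped mate
    for read in reads:
        lc, rc = bamio.clip_lengths(read)
        if max(lc, rc) < MIN_CLIP_TRY or read.query_sequence is None:
            continue
        detail = split_realign(read.query_sequence, window, reference,
                               min_score=min_score, min_flank=min_flank)
        if detail is not None:
            rec = _record_for_split(read, reads, libmap, sample)
            return ClassifiedPair(rec, "S", detail)
    if len(reads) != 2:
        return None
    pair = bamio.pair_from_reads(reads[0], reads[1], libmap, sample)
    return classify_pair(pair, window)


def classify_pair(pair: ReadPairRecord, window: AnalysisWindow) -> Optional[ClassifiedPair]:
    """Type a mapped pair as I or A from mate placement, or drop it.

    Only +/- oriented pairs on one chromosome are considered; the aligner's
    proper-pair flag is ignored here because H1-supporting type-A pairs
    exceed the concordant insert bound by construction.
    """
    if not pair.same_chrom or pair.strand_L != "+" or pair.strand_R != "-":
        return None
    loc, FL, FR = window.locus, window.FL, window.FR
    L_in_left = _contained(pair.begin_L, pair.end_L, FL, loc.AL)
    L_in_alu = _contained(pair.begin_L, pair.end_L, loc.AL, loc.AR)
    R_in_alu = _contained(pair.begin_R, pair.end_R, loc.AL, loc.AR)
    R_in_right = _contained(pair.begin_R, pair.end_R, loc.AR, FR)
    if (L_in_left and R_in_alu) or (L_in_alu and R_in_right):
        return ClassifiedPair(pair, "I")
    if L_in_left and R_in_right:
        return ClassifiedPair(pair, "A")
    return None


def _record_for_split(read, reads, libmap, sample) -> ReadPairRecord:
    mate = next((r for r in reads if r is not read), None)
    if mate is not None:
        return bamio.pair_from_reads(read, mate, libmap, sample)
    return ReadPairRecord(
        pair_id=read.query_name, chrom=read.reference_name,
        begin_L=read.reference_start, end_L=read.reference_end,
        begin_R=read.reference_start, end_R=read.reference_end,
        strand_L="-" if read.is_reverse else "+", strand_R="-",
        library=bamio.read_library(read, libmap), sample=sample,
        mate_unmapped=read.mate_is_unmapped)


def pair_allele_likelihoods(
    cp: ClassifiedPair,
    model: InsertLengthModel,
    l_alu: int,
    pe: float = DEFAULT_PE,
) -> Tuple[float, float]:
    """(L(r|H0), L(r|H1)) for one classified pair.

    Type A evaluates the pair's own library density: under H0 the observed
    insert follows Y, under H1 it follows Y + l_Alu, so the H1 likelihood
    is f_Y at the observed insert shifted back by l_Alu.
    """
    if cp.type == "A":
        y = insert_length(cp.pair)
        lib = cp.pair.library
        return pair_likelihood_for_type(
            "A", pe,
            density_h0=model.density(y, lib),
            density_h1=model.density(y - l_alu, lib))
    return pair_likelihood_for_type(cp.type, pe)


def genotype_likelihoods(
    classified: Sequence[ClassifiedPair],
    gm: GenotypeModel,
    model: InsertLengthModel,
    l_alu: int,
) -> Tuple[float, float, float]:
    """Log-likelihoods (G0, G1, G2) of a classified pair set; empty -> zeros."""
    liks = [pair_allele_likelihoods(cp, model, l_alu, gm.pe) for cp in classified]
    return genotype_log_likelihoods(liks, gm, l_alu)


def genotype_locus(
    bam: pysam.AlignmentFile,
    window: AnalysisWindow,
    reference,
    model: InsertLengthModel,
    gm: GenotypeModel,
    sample: str,
    min_evidence: int = 2,
    min_score: float = MIN_SCORE,
    min_flank: int = MIN_FLANK,
) -> GenotypeCall:
    """Classify and genotype one sample at one annotated Alu."""
    loc = window.locus
    libmap = bamio.library_map(bam)
    groups = bamio.fetch_read_groups(bam, loc.chrom, window.FL, window.FR)
    classified: List[ClassifiedPair] = []
    for reads in groups.values():
        cp = classify_read_group(reads, window, reference, libmap, sample,
                                 min_score=min_score, min_flank=min_flank)
        if cp is not None:
            classified.append(cp)
    lls = genotype_likelihoods(classified, gm, model, loc.length)
    counts = {"I": 0, "S": 0, "A": 0}
    for cp in classified:
        counts[cp.type] += 1
    return call_genotype(lls, sample=sample, locus_id=loc.name,
                         n_I=counts["I"], n_S=counts["S"], n_A=counts["A"],
                         min_evidence=min_evidence)


def call_deletions(
    reference_path: str,
    bam_paths: Sequence[str],
    loci: Sequence[AluLocus],
    pe: float = DEFAULT_PE,
    min_evidence: int = 2,
    min_score: float = MIN_SCORE,
    min_flank: int = MIN_FLANK,
    insert_models: Optional[Dict[str, InsertLengthModel]] = None,
) -> Tuple[List[str], Dict[str, List[GenotypeCall]]]:
    """Genotype every annotated locus in every sample.

    Returns the ordered sample names and, per locus name, one call per
    sample. Per-library insert models are estimated from each BAM unless
    supplied; the heterozygote allele prior uses each sample's modal read
    length.
    """
    reference = Fasta(reference_path)
    samples: List[str] = []
    calls: Dict[str, List[GenotypeCall]] = {loc.name: [] for loc in loci}
    for path in bam_paths:
        with bamio.open_bam(path) as bam:
            sample = bamio.sample_name(bam, fallback=path)
            samples.append(sample)
            model = (insert_models or {}).get(sample) \
                or bamio.estimate_model_from_bam(path)
            gm = GenotypeModel(pe=pe, read_len=bamio.modal_read_length(path))
            for loc in loci:
                chrom_len = len(reference[loc.chrom])
                window = build_window(loc, model, chrom_length=chrom_len)
                calls[loc.name].append(
                    genotype_locus(bam, window, reference, model, gm, sample,
                                   min_evidence=min_evidence,
                                   min_score=min_score, min_flank=min_flank))
    return samples, calls
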