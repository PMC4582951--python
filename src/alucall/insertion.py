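"""Discovery and genotyping of Alu insertions absent from the reference.

Two read signals mark an insertion site. A *D* read pair is discordant
with one mate inside an annotated Alu elsewhere in the reference; its
other mate (the *anchor*) flanks the insertion — mapping forward (*la*)
just left of the site or reverse-complemented (*ra*) just right of it. A
*C* read is soft-clipped at the insertion junction, its clipped tail
matching Alu sequence.

The caller scans each individual for anchor clusters, pools candidate
regions across individuals (low-frequency events gain power from
pooling), pinpoints breakpoints by a two-level vote of split-mapped C
reads — reads vote within an individual, individuals vote across the
cohort — and genotypes every sample by reusing the deletion mixture model
with the Alu inserted in silico: D pairs act as internal (I) evidence for
the Alu-present allele, split-confirmed C reads as junction (S) evidence,
and spanning pairs as insert-length (A) evidence with ``delta`` (default
300 bp) added to the carrier allele's insert distribution.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pysam
from intervaltree import IntervalTree

from . import bamio
from .genotype import (DEFAULT_PE, GenotypeCall, GenotypeModel, call_genotype,
                       genotype_log_likelihoods)
from .insert_model import InsertLengthModel
from .loci import AluLocus
from .split import MIN_FLANK, MIN_SCORE, local_align, revcomp

#: cluster-support threshold: a pooled region must have support(p) > n
DEFAULT_N = 4

#: per-sample seed threshold for candidate positions (pooling across
#: samples applies the full threshold n afterwards)
DEFAULT_N_SINGLE = 1

#: maximum candidate-region span, so one region holds one insertion
DEFAULT_REGION_LEN = 200

#: basepairs added to the insert distribution for the insertion allele
DEFAULT_DELTA = 300

#: AL and AR may differ by up to this much (target-site duplication or
#: target-site deletion)
MAX_AL_AR_DIFF = 50

MIN_CLIP = 10          # minimum soft-clip length for a C read
MIN_CLIP_QUAL = 20.0   # minimum mean base quality of the clipped segment
MIN_ANCHOR_MAPQ = 20   # minimum anchor mapping quality


@dataclass
class InformativeRead:
    """A D-pair anchor or a clipped C read supporting an insertion."""

    kind: str                      # "D" or "C"
    sample: str
    chrom: str
    begin: int
    end: int
    orientation: Optional[str] = None   # "la"/"ra" (D only)
    clip_side: Optional[str] = None     # "left"/"right" (C only)
    clip_pos: Optional[int] = None      # reference position of the clip (C)
    clip_seq: str = ""
    anchor_len: int = 0

    def __post_init__(self) -> None:
        if self.kind == "D" and self.orientation not in ("la", "ra"):
            raise ValueError("D reads carry an la/ra orientation")
        if self.kind == "C" and self.clip_side not in ("left", "right"):
            raise ValueError("C reads carry a clip side")


@dataclass
class CandidateRegion:
    chrom: str
    begin: int
    end: int
    samples: Set[str] = field(default_factory=set)
    support: Dict[str, int] = field(default_factory=dict)

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass
class BreakpointCall:
    """Voted breakpoints of one insertion site."""

    AL: Optional[int]
    AR: Optional[int]
    votes_AL: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    votes_AR: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    alu_family: str = "."

    @property
    def position(self) -> int:
        """Representative insertion point (AL if known, else AR)."""
        if self.AL is not None:
            return self.AL
        assert self.AR is not None
        return self.AR

    @property
    def tsd_length(self) -> Optional[int]:
        """Target-site duplication length when AL lies right of AR."""
        if self.AL is not None and self.AR is not None and self.AL > self.AR:
            return self.AL - self.AR
        return None


def build_alu_tree(loci: Sequence[AluLocus]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for loc in loci:
        trees[loc.chrom].addi(loc.AL, loc.AR, loc.name)
    return dict(trees)


def _in_alu(trees: Dict[str, IntervalTree], chrom: str, begin: int, end: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlap(begin, end))


def collect_informative(
    bam_path: str,
    alu_trees: Dict[str, IntervalTree],
    sample: Optional[str] = None,
    min_clip: int = MIN_CLIP,
    min_clip_qual: float = MIN_CLIP_QUAL,
    min_mapq: int = MIN_ANCHOR_MAPQ,
    mate_span: int = 150,
) -> List[InformativeRead]:
    """One streaming pass over a BAM emitting D anchors and C reads.

    D: discordant pair whose mate overlaps an annotated Alu while the
    anchor itself does not; the anchor is classed la (forward) or ra
    (reverse). C: a read with a soft clip of at least ``min_clip`` bases
    of mean quality ``min_clip_qual``, anchored outside annotated Alus.
    """
    out: List[InformativeRead] = []
    with pysam.AlignmentFile(bam_path) as bam:
        if sample is None:
            sample = bamio.sample_name(bam, fallback=bam_path)
        for read in bam.fetch(until_eof=True):
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.mapping_quality < min_mapq):
                continue
            chrom = read.reference_name
            if _in_alu(alu_trees, chrom, read.reference_start, read.reference_end):
                continue  # anchors inside annotated Alus are discarded
            lc, rc = bamio.clip_lengths(read)
            if max(lc, rc) >= min_clip and read.query_sequence:
                side = "right" if rc >= lc else "left"
                cl = rc if side == "right" else lc
                seq = read.query_sequence
                quals = read.query_qualities
                clip_seq = seq[-cl:] if side == "right" else seq[:cl]
                cq = quals[-cl:] if side == "right" else quals[:cl]
                if sum(cq) / len(cq) >= min_clip_qual:
                    out.append(InformativeRead(
                        kind="C", sample=sample, chrom=chrom,
                        begin=read.reference_start, end=read.reference_end,
                        clip_side=side,
                        clip_pos=(read.reference_end if side == "right"
                                  else read.reference_start),
                        clip_seq=clip_seq,
                        anchor_len=len(seq) - cl))
            if (read.mate_is_unmapped or read.is_proper_pair
                    or read.next_reference_id < 0):
                continue
            mate_chrom = read.next_reference_name
            mate_start = read.next_reference_start
            if _in_alu(alu_trees, mate_chrom, mate_start, mate_start + mate_span):
                out.append(InformativeRead(
                    kind="D", sample=sample, chrom=chrom,
                    begin=read.reference_start, end=read.reference_end,
                    orientation="ra" if read.is_reverse else "la"))
    return out


def support_at(
    p: int, anchors: Sequence[InformativeRead], window: int
) -> int:
    """Brute-force support(p): la anchors with p in [end, begin+w] plus
    ra anchors with p in [end-w, begin]."""
    s = 0
    for r in anchors:
        if r.orientation == "la":
            if r.end <= p <= r.begin + window:
                s += 1
        else:
            if r.end - window <= p <= r.begin:
                s += 1
    return s


def scan_support(
    anchors: Sequence[InformativeRead],
    window: int,
    n: int = DEFAULT_N,
) -> List[Tuple[int, int]]:
    """Positions p with support(p) > n, in increasing order.

    Only positions p = end(la) or p = end(ra) are evaluated. The sweep
    sorts the m admissible anchor windows once and answers each candidate
    by rank queries, equivalent to the O(m*g) scan over the genome.
    """
    if not anchors:
        return []
    starts: List[int] = []
    ends: List[int] = []
    cands: Set[int] = set()
    for r in anchors:
        cands.add(r.end)
        if r.orientation == "la":
            lo, hi = r.end, r.begin + window
        elif r.orientation == "ra":
            lo, hi = r.end - window, r.begin
        else:
            raise ValueError("scan_support expects D anchors")
        if lo <= hi:
            starts.append(lo)
            ends.append(hi)
    starts.sort()
    ends.sort()
    out: List[Tuple[int, int]] = []
    for p in sorted(cands):
        s = bisect_right(starts, p) - bisect_left(ends, p)
        if s > n:
            out.append((p, s))
    return out


def build_regions(
    positions: Sequence[Tuple[int, int]],
    chrom: str,
    sample: str,
    region_len: int = DEFAULT_REGION_LEN,
) -> List[CandidateRegion]:
    """Greedy left-to-right grouping of passing positions into regions.

    A region (b_i, e_i) absorbs the next position p_j while p_j - b_i <
    region_len; otherwise a new region starts at p_j. Every region spans
    less than ``region_len``.
    """
    regions: List[CandidateRegion] = []
    for p, s in positions:
        if regions and p - regions[-1].begin < region_len:
            reg = regions[-1]
            reg.end = max(reg.end, p)
            reg.support[sample] = max(reg.support[sample], s)
        else:
            regions.append(CandidateRegion(chrom, p, p, {sample}, {sample: s}))
    return regions


def merge_regions_multi(
    per_sample_regions: Iterable[List[CandidateRegion]],
    region_len: int = DEFAULT_REGION_LEN,
) -> List[CandidateRegion]:
    """Pool per-sample regions and merge adjacent ones.

    Traversing by increasing begin position, regions (b_k, e_k) and
    (b_l, e_l) merge when b_l < e_k and e_l - b_k < region_len; sample
    sets are unioned and per-sample supports keep their maximum.
    """
    pooled: List[CandidateRegion] = []
    for regions in per_sample_regions:
        pooled.extend(regions)
    pooled.sort(key=lambda r: (r.chrom, r.begin, r.end))
    merged: List[CandidateRegion] = []
    for reg in pooled:
        if merged:
            prev = merged[-1]
            if (reg.chrom == prev.chrom and reg.begin < prev.end
                    and reg.end - prev.begin < region_len):
                prev.end = max(prev.end, reg.end)
                prev.samples |= reg.samples
                for smp, s in reg.support.items():
                    prev.support[smp] = max(prev.support.get(smp, 0), s)
                continue
        merged.append(CandidateRegion(reg.chrom, reg.begin, reg.end,
                                      set(reg.samples), dict(reg.support)))
    return merged


@dataclass
class SplitHit:
    """A C read split-mapped to reference + Alu consensus."""

    sample: str
    side: str        # "AL" (right-clipped read) or "AR" (left-clipped read)
    position: int
    alu_name: str
    score: float


def split_map_c_read(
    read: InformativeRead,
    panel: Dict[str, str],
    min_flank: int = MIN_FLANK,
    min_score: float = MIN_SCORE,
) -> Optional[SplitHit]:
    """Validate a C read's clipped tail against the Alu consensus panel.

    The anchor part is already placed on the reference by the input
    alignment, fixing the candidate breakpoint at the clip position; the
    clipped part must align locally (either strand) to one of the panel
    sequences with at least ``min_flank`` bases at ``min_score``. A
    right-side clip votes for AL, a left-side clip for AR.
    """
    if read.kind != "C" or read.clip_pos is None:
        return None
    if read.anchor_len < min_flank or len(read.clip_seq) < min_flank:
        return None
    best: Optional[Tuple[float, str]] = None
    for name, seq in panel.items():
        for query in (read.clip_seq, revcomp(read.clip_seq)):
            score, _tspan, qspan = local_align(query, seq)
            if score < min_score or (qspan[1] - qspan[0]) < min_flank:
                continue
            if best is None or score > best[0]:
                best = (score, name)
    if best is None:
        return None
    side = "AL" if read.clip_side == "right" else "AR"
    return SplitHit(sample=read.sample, side=side, position=read.clip_pos,
                    alu_name=best[1], score=best[0])


def vote_breakpoints(hits: Sequence[SplitHit]) -> Optional[BreakpointCall]:
    """Two-level vote: reads vote within a sample, samples vote across.

    AL and AR are voted independently. Level 1 picks each sample's modal
    position per side (ties toward the smaller position); level 2 picks
    the modal level-1 position across samples (ties toward the larger
    total read support, then the smaller position). If both breakpoints
    are set but differ by more than 50 bp, only the side with more
    level-2 votes is kept. Returns None when no side can be determined.
    """
    if not hits:
        return None

    def level2(side: str):
        by_sample: Dict[str, Counter] = defaultdict(Counter)
        for h in hits:
            if h.side == side:
                by_sample[h.sample][h.position] += 1
        if not by_sample:
            return None, {}, 0
        firsts: Dict[str, Tuple[int, int]] = {}
        for smp, counter in by_sample.items():
            pos = min(counter, key=lambda p: (-counter[p], p))
            firsts[smp] = (pos, counter[pos])
        tally: Counter = Counter(pos for pos, _cnt in firsts.values())
        reads_at: Counter = Counter()
        for pos, cnt in firsts.values():
            reads_at[pos] += cnt
        final = min(tally, key=lambda p: (-tally[p], -reads_at[p], p))
        return final, firsts, tally[final]

    al, votes_al, n_al = level2("AL")
    ar, votes_ar, n_ar = level2("AR")
    if al is None and ar is None:
        return None
    if al is not None and ar is not None and abs(al - ar) > MAX_AL_AR_DIFF:
        if n_al >= n_ar:
            ar, votes_ar = None, {}
        else:
            al, votes_al = None, {}
    fams = Counter(h.alu_name for h in hits)
    family = min(fams, key=lambda f: (-fams[f], f))
    return BreakpointCall(AL=al, AR=ar, votes_AL=votes_al, votes_AR=votes_ar,
                         alu_family=family)


def _d_read_covers(read: InformativeRead, pos: int, window: int) -> bool:
    if read.orientation == "la":
        return read.end <= pos <= read.begin + window
    return read.end - window <= pos <= read.begin


def genotype_insertion(
    region: CandidateRegion,
    bp: BreakpointCall,
    d_reads: Sequence[InformativeRead],
    split_hits: Sequence[SplitHit],
    bam_path: str,
    model: InsertLengthModel,
    gm: GenotypeModel,
    sample: str,
    delta: int = DEFAULT_DELTA,
    min_evidence: int = 2,
) -> GenotypeCall:
    """Genotype one sample at a voted insertion site.

    The Alu is inserted in silico: H0 becomes the Alu-present (carrier)
    allele of length delta. D anchors covering the breakpoint count as
    internal (I) evidence, split-confirmed C reads as junction (S)
    evidence — both likelihood 1 under the carrier allele and PE under
    the reference allele — and concordant pairs whose mates straddle the
    breakpoint as spanning (A) evidence with carrier density f_Y(Y +
    delta) against reference density f_Y(Y). Calls are reported on the
    insertion-dosage scale: G0 non-carrier, G1 heterozygous, G2
    homozygous carrier.
    """
    pos = bp.position
    window = model.flank_width()
    pair_liks: List[Tuple[float, float]] = []  # ordered (L|carrier, L|ref)
    n_i = n_s = n_a = 0
    for r in d_reads:
        if r.sample == sample and _d_read_covers(r, pos, window):
            pair_liks.append((1.0, gm.pe))
            n_i += 1
    for h in split_hits:
        if h.sample == sample:
            pair_liks.append((1.0, gm.pe))
            n_s += 1
    with bamio.open_bam(bam_path) as bam:
        libmap = bamio.library_map(bam)
        groups = bamio.fetch_read_groups(
            bam, region.chrom, max(0, pos - window), pos + window)
        for reads in groups.values():
            if len(reads) != 2:
                continue
            if any(max(bamio.clip_lengths(r)) >= MIN_CLIP for r in reads):
                continue  # clipped reads are C evidence, not spanning pairs
            pair = bamio.pair_from_reads(reads[0], reads[1], libmap, sample)
            if pair.strand_L != "+" or pair.strand_R != "-":
                continue
            if not (pair.end_L <= pos <= pair.begin_R):
                continue
            y = pair.end_R - pair.begin_L
            lib = pair.library
            pair_liks.append((model.density(y + delta, lib),
                              model.density(y, lib)))
            n_a += 1
    lls = genotype_log_likelihoods(pair_liks, gm, delta)
    dosage_lls = (lls[2], lls[1], lls[0])  # -> (non-carrier, het, hom)
    return call_genotype(dosage_lls, sample=sample,
                         locus_id=f"{region.chrom}:{pos}",
                         n_I=n_i, n_S=n_s, n_A=n_a,
                         min_evidence=min_evidence)


@dataclass
class InsertionCall:
    """A discovered, breakpoint-resolved, genotyped insertion site."""

    chrom: str
    breakpoint: BreakpointCall
    region: CandidateRegion
    genotypes: List[GenotypeCall] = field(default_factory=list)


def call_insertions(
    reference_path: str,
    bam_paths: Sequence[str],
    alu_loci: Sequence[AluLocus],
    panel: Dict[str, str],
    n: int = DEFAULT_N,
    n_single: int = DEFAULT_N_SINGLE,
    region_len: int = DEFAULT_REGION_LEN,
    delta: int = DEFAULT_DELTA,
    min_flank: int = MIN_FLANK,
    min_score: float = MIN_SCORE,
    pe: float = DEFAULT_PE,
    min_evidence: int = 2,
    insert_models: Optional[Dict[str, InsertLengthModel]] = None,
) -> Tuple[List[str], List[InsertionCall]]:
    """Full multi-sample insertion pipeline.

    Candidate positions are found per individual with the seed threshold
    ``n_single``, grouped into regions, merged across individuals, and
    the merged region kept when its pooled support exceeds ``n`` — so a
    site backed by few reads in each of several individuals is still
    discovered. Regions without a voted breakpoint are excluded.
    """
    alu_trees = build_alu_tree(alu_loci)
    samples: List[str] = []
    models: Dict[str, InsertLengthModel] = {}
    gms: Dict[str, GenotypeModel] = {}
    informative: Dict[str, List[InformativeRead]] = {}
    sample_bam: Dict[str, str] = {}
    for path in bam_paths:
        with bamio.open_bam(path) as bam:
            sample = bamio.sample_name(bam, fallback=path)
        samples.append(sample)
        sample_bam[sample] = path
        models[sample] = (insert_models or {}).get(sample) \
            or bamio.estimate_model_from_bam(path)
        gms[sample] = GenotypeModel(pe=pe, read_len=bamio.modal_read_length(path))
        informative[sample] = collect_informative(path, alu_trees, sample=sample)

    chroms = sorted({r.chrom for reads in informative.values() for r in reads})
    calls: List[InsertionCall] = []
    for chrom in chroms:
        per_sample_regions: List[List[CandidateRegion]] = []
        for sample in samples:
            anchors = [r for r in informative[sample]
                       if r.kind == "D" and r.chrom == chrom]
            window = models[sample].flank_width()
            positions = scan_support(anchors, window, n=n_single)
            per_sample_regions.append(
                build_regions(positions, chrom, sample, region_len=region_len))
        merged = merge_regions_multi(per_sample_regions, region_len=region_len)
        hit_cache: Dict[int, Optional[SplitHit]] = {}
        sites: Dict[int, Tuple[CandidateRegion, "BreakpointCall", List[SplitHit]]] = {}
        for region in merged:
            if region.total_support <= n:
                continue
            hits = []
            for r in c_reads_in_region(informative, region):
                key = id(r)
                if key not in hit_cache:
                    hit_cache[key] = split_map_c_read(
                        r, panel, min_flank=min_flank, min_score=min_score)
                if hit_cache[key] is not None:
                    hits.append(hit_cache[key])
            bp = vote_breakpoints(hits)
            if bp is None:
                continue  # no determinable breakpoint: region excluded
            # neighbouring capped regions can elect the same breakpoint;
            # keep the best-supported region per voted site
            prev = sites.get(bp.position)
            if prev is None or region.total_support > prev[0].total_support:
                sites[bp.position] = (region, bp, hits)
        # collapse voted sites closer than the AL/AR tolerance: they are
        # one event seen from adjacent regions
        kept: List[int] = []
        for pos in sorted(sites):
            if kept and pos - kept[-1] <= MAX_AL_AR_DIFF:
                if sites[pos][0].total_support > sites[kept[-1]][0].total_support:
                    kept[-1] = pos
            else:
                kept.append(pos)
        for pos in kept:
            region, bp, hits = sites[pos]
            call = InsertionCall(chrom=chrom, breakpoint=bp, region=region)
            for sample in samples:
                d_reads = [r for r in informative[sample]
                           if r.kind == "D" and r.chrom == chrom]
                sample_hits = [h for h in hits if h.sample == sample]
                call.genotypes.append(genotype_insertion(
                    region, bp, d_reads, sample_hits, sample_bam[sample],
                    delta=delta, min_evidence=min_evidence,
                    model=models[sample], gm=gms[sample], sample=sample))
            calls.append(call)
    calls.sort(key=lambda c: (c.chrom, c.breakpoint.position))
    return samples, calls


def c_reads_in_region(
    informative: Dict[str, List[InformativeRead]],
    region: CandidateRegion,
    margin: int = MAX_AL_AR_DIFF,
) -> List[InformativeRead]:
    """All samples' C reads whose clip falls within the region (padded)."""
    out: List[InformativeRead] = []
    for reads in informative.values():
        for r in reads:
            if r.kind != "C" or r.chrom != region.chrom:
                continue
            if region.begin - margin <= r.clip_pos <= region.end + margin:
                out.append(r)
    return out
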