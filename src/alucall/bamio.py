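"""Reading coordinate-sorted, indexed BAM/SAM files into pair records.

The library of a read is taken from its read group's LB tag, falling back
to the read group's SM tag, falling back to "default". Alignments are
trusted as given: no realignment or duplicate marking is performed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Dict, Iterator, List, Optional, Tuple

import pysam

from .insert_model import (InsertLengthModel, MAX_PAIRS, MIN_PAIRS,
                           model_from_lengths)
from .pairs import ReadPairRecord


def open_bam(path: str) -> pysam.AlignmentFile:
    bam = pysam.AlignmentFile(path)
    if not bam.has_index():
        raise FileNotFoundError(f"{path}: BAM index (.bai) not found")
    return bam


def library_map(bam: pysam.AlignmentFile) -> Dict[str, str]:
    """Read-group ID -> library name (LB, else SM, else 'default')."""
    out: Dict[str, str] = {}
    for rg in bam.header.get("RG", []):
        out[rg.get("ID", "")] = rg.get("LB") or rg.get("SM") or "default"
    return out


def sample_name(bam: pysam.AlignmentFile, fallback: str = "sample") -> str:
    for rg in bam.header.get("RG", []):
        if rg.get("SM"):
            return rg["SM"]
    return fallback


def read_library(read: pysam.AlignedSegment, libmap: Dict[str, str]) -> str:
    try:
        rg = read.get_tag("RG")
    except KeyError:
        return "default"
    return libmap.get(rg, "default")


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_duplicate)


def estimate_model_from_bam(
    path: str,
    max_pairs_per_library: int = MAX_PAIRS,
    min_pairs_per_library: int = MIN_PAIRS,
) -> InsertLengthModel:
    """Estimate the per-library insert-length model from proper pairs.

    Uses the aligner's proper-pair flag (the model does not exist yet on
    this pass) and each left-forward mate's template length as Y(r), so a
    single streaming pass over the BAM suffices.
    """
    lengths: Dict[str, List[int]] = defaultdict(list)
    done: set = set()
    with pysam.AlignmentFile(path) as bam:
        libmap = library_map(bam)
        for read in bam.fetch(until_eof=True):
            if not _usable(read) or not read.is_proper_pair:
                continue
            if read.is_reverse or read.template_length <= 0:
                continue  # count each pair once, from its forward mate
            lib = read_library(read, libmap)
            if lib in done:
                continue
            bucket = lengths[lib]
            bucket.append(read.template_length)
            if len(bucket) >= max_pairs_per_library:
                done.add(lib)
    return model_from_lengths(lengths, min_pairs_per_library)


def modal_read_length(path: str, sample_reads: int = 10_000) -> int:
    """Most common aligned read length in the first reads of the BAM."""
    counts: Counter = Counter()
    with pysam.AlignmentFile(path) as bam:
        for read in bam.fetch(until_eof=True):
            if not _usable(read) or read.query_length == 0:
                continue
            counts[read.query_length] += 1
            if sum(counts.values()) >= sample_reads:
                break
    if not counts:
        raise ValueError(f"{path}: no mapped reads")
    # ties broken toward the larger length
    return max(sorted(counts), key=lambda k: (counts[k], k))


def clip_lengths(read: pysam.AlignedSegment) -> Tuple[int, int]:
    """(left, right) soft-clip lengths of an alignment."""
    cig = read.cigartuples or []
    left = cig[0][1] if cig and cig[0][0] == 4 else 0
    right = cig[-1][1] if cig and cig[-1][0] == 4 else 0
    return left, right


def fetch_read_groups(
    bam: pysam.AlignmentFile, chrom: str, start: int, end: int
) -> Dict[str, List[pysam.AlignedSegment]]:
    """Primary alignments overlapping [start, end), grouped by query name."""
    groups: Dict[str, List[pysam.AlignedSegment]] = defaultdict(list)
    for read in bam.fetch(chrom, max(0, start), end):
        if _usable(read):
            groups[read.query_name].append(read)
    return groups


def pair_from_reads(
    left: pysam.AlignedSegment,
    right: pysam.AlignedSegment,
    libmap: Dict[str, str],
    sample: str,
) -> ReadPairRecord:
    """Build a :class:`ReadPairRecord` from two mates (order arbitrary)."""
    if right.reference_start < left.reference_start:
        left, right = right, left
    return ReadPairRecord(
        pair_id=left.query_name,
        chrom=left.reference_name,
        begin_L=left.reference_start,
        end_L=left.reference_end,
        begin_R=right.reference_start,
        end_R=right.reference_end,
        strand_L="-" if left.is_reverse else "+",
        strand_R="-" if right.is_reverse else "+",
        mapq_L=left.mapping_quality,
        mapq_R=right.mapping_quality,
        cigar_L=left.cigarstring or "",
        cigar_R=right.cigarstring or "",
        library=read_library(left, libmap),
        sample=sample,
        proper_pair=left.is_proper_pair,
        chrom_R=(right.reference_name
                 if right.reference_name != left.reference_name else None),
    )
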