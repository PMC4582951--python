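"""Local-alignment helpers for split-read evidence.

Split reads are realigned with the Smith-Waterman algorithm (mismatches and
small gaps allowed) under a +1/-2 match/mismatch scheme with -3/-1 affine
gaps. A split is accepted only if a minimal score is reached and at least
``min_flank`` (default 20) bases align on each side of the breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from Bio import Align

MATCH = 1
MISMATCH = -2
GAP_OPEN = -3
GAP_EXTEND = -1

#: default minimal Smith-Waterman score for an accepted split
MIN_SCORE = 25

#: minimum aligned bases required on each side of a breakpoint
MIN_FLANK = 20


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = MATCH
    aln.mismatch_score = MISMATCH
    aln.open_gap_score = GAP_OPEN
    aln.extend_gap_score = GAP_EXTEND
    return aln


_ALIGNER = _aligner()

_COMPL = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def local_align(query: str, target: str) -> Tuple[float, Tuple[int, int], Tuple[int, int]]:
    """Best local alignment of query against target.

    Returns (score, (target_begin, target_end), (query_begin, query_end));
    score 0 and empty spans when nothing aligns.
    """
    if not query or not target:
        return 0.0, (0, 0), (0, 0)
    alns = _ALIGNER.align(target, query)
    if len(alns) == 0:
        return 0.0, (0, 0), (0, 0)
    best = alns[0]
    tblocks, qblocks = best.aligned
    if len(tblocks) == 0:
        return 0.0, (0, 0), (0, 0)
    tspan = (int(tblocks[0][0]), int(tblocks[-1][1]))
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    return float(best.score), tspan, qspan


@dataclass
class SplitDetail:
    """Evidence of a read aligning across a breakpoint junction."""

    clip_pos: int          # offset within the read where it switches sides
    left_aligned: int      # reference bases aligned left of the junction
    right_aligned: int     # reference bases aligned right of the junction
    score: float


def align_across_junction(
    read_seq: str,
    left_flank: str,
    right_flank: str,
    min_score: float = MIN_SCORE,
    min_flank: int = MIN_FLANK,
) -> Optional[SplitDetail]:
    """Realign a read across the junction left_flank + right_flank.

    ``left_flank`` ends at the left breakpoint and ``right_flank`` starts at
    the right breakpoint; a read sampled from a haplotype in which the
    intervening sequence is absent aligns contiguously across their join.
    Returns the split evidence, or None if the alignment does not span the
    junction with ``min_flank`` aligned bases on both sides at ``min_score``.
    """
    junction = len(left_flank)
    target = left_flank + right_flank
    if not read_seq:
        return None
    alns = _ALIGNER.align(target, read_seq)
    if len(alns) == 0:
        return None
    best = alns[0]
    if best.score < min_score:
        return None
    tblocks, qblocks = best.aligned
    if len(tblocks) == 0:
        return None
    left_cov = 0
    right_cov = 0
    clip_pos = 0
    for (tb, te), (qb, qe) in zip(tblocks, qblocks):
        left_cov += max(0, min(te, junction) - tb)
        right_cov += max(0, te - max(tb, junction))
        if tb < junction <= te:
            clip_pos = qb + (junction - tb)
        elif te <= junction:
            clip_pos = max(clip_pos, qe)
    if left_cov < min_flank or right_cov < min_flank:
        return None
    return SplitDetail(clip_pos=clip_pos, left_aligned=left_cov,
                       right_aligned=right_cov, score=float(best.score))
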