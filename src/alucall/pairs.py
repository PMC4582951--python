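"""Read-pair primitives: records, insert length, and concordance.

A read pair ``r`` consists of a left read and a right read mapped to the
reference. The insert length of a pair, measured on the reference, is

    Y(r) = end(right) - begin(left)

i.e. the outer distance of the two mates. All coordinates are 0-based
half-open; conversion to 1-based happens only when writing VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class UndefinedInsertError(ValueError):
    """Insert length is undefined (unmapped mate or cross-chromosome pair)."""


@dataclass
class ReadPairRecord:
    """A mapped paired-end fragment.

    ``begin_*``/``end_*`` are 0-based half-open reference positions of the
    aligned portion of each mate. ``strand_*`` is '+' or '-'. The left mate
    is the one with the smaller begin position.
    """

    pair_id: str
    chrom: str
    begin_L: int
    end_L: int
    begin_R: int
    end_R: int
    strand_L: str = "+"
    strand_R: str = "-"
    mapq_L: int = 60
    mapq_R: int = 60
    cigar_L: str = ""
    cigar_R: str = ""
    library: str = "default"
    sample: str = "default"
    seq_L: str = ""
    seq_R: str = ""
    qual_L: str = ""
    qual_R: str = ""
    proper_pair: Optional[bool] = None
    mate_unmapped: bool = False
    chrom_R: Optional[str] = None  # set when mates map to different chromosomes

    def __post_init__(self) -> None:
        if not self.library:
            self.library = self.sample or "default"

    @property
    def same_chrom(self) -> bool:
        return self.chrom_R is None or self.chrom_R == self.chrom


def insert_length(pair: ReadPairRecord) -> int:
    """Insert length Y(r) = end(right mate) - begin(left mate).

    Raises
    ------
    UndefinedInsertError
        If a mate is unmapped or the mates map to different chromosomes.
    """
    if pair.mate_unmapped:
        raise UndefinedInsertError(f"pair {pair.pair_id}: mate unmapped")
    if not pair.same_chrom:
        raise UndefinedInsertError(
            f"pair {pair.pair_id}: mates on {pair.chrom} and {pair.chrom_R}"
        )
    return pair.end_R - pair.begin_L


def classify_concordance(pair: ReadPairRecord, model=None) -> str:
    """Label a pair ``"concordant"`` or ``"discordant"``.

    A pair is concordant when both mates map to the same chromosome on
    opposite strands, the forward mate is leftmost, and the insert length is
    positive and within E[Y] + 3*sigma(Y) of the pair's library model.
    Before an insert-length model exists (the bootstrap pass over the BAM)
    the aligner's proper-pair flag is trusted instead.
    """
    if pair.mate_unmapped or not pair.same_chrom:
        return "discordant"
    if pair.strand_L == pair.strand_R:
        return "discordant"
    if pair.strand_L != "+":  # forward mate must be leftmost (FR orientation)
        return "discordant"
    if model is None:
        if pair.proper_pair is None:
            return "discordant"
        return "concordant" if pair.proper_pair else "discordant"
    y = insert_length(pair)
    mean, sd = model.mean_sd(pair.library)
    if 0 < y <= mean + 3.0 * sd:
        return "concordant"
    return "discordant"
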