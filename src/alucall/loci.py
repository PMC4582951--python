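"""Alu loci and their analysis windows."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Optional

from .insert_model import InsertLengthModel


@dataclass(frozen=True)
class AluLocus:
    """An Alu element on the reference, bounded by breakpoints AL < AR."""

    chrom: str
    AL: int
    AR: int
    name: str = "."

    def __post_init__(self) -> None:
        if not self.AL < self.AR:
            raise ValueError(f"{self.name}: AL={self.AL} must be < AR={self.AR}")

    @property
    def length(self) -> int:
        """l_Alu = AR - AL."""
        return self.AR - self.AL


@dataclass(frozen=True)
class AnalysisWindow:
    """An Alu locus with flanks [FL, AL] and [AR, FR] of width E[Y]+3*sigma."""

    locus: AluLocus
    FL: int
    FR: int

    def __post_init__(self) -> None:
        if not (self.FL <= self.locus.AL and self.locus.AR <= self.FR):
            raise ValueError("window must contain the locus")


def build_window(
    locus: AluLocus,
    model: InsertLengthModel,
    chrom_length: Optional[int] = None,
    library: str = "default",
) -> AnalysisWindow:
    """Flank the locus by w = round(E[Y] + 3*sigma(Y)) on each side,
    clipped to the chromosome bounds."""
    w = model.flank_width(library)
    FL = max(0, locus.AL - w)
    FR = locus.AR + w
    if chrom_length is not None:
        FR = min(FR, chrom_length)
    return AnalysisWindow(locus=locus, FL=FL, FR=FR)


def read_alu_bed(path: str) -> List[AluLocus]:
    """Load a BED3+ annotation (chrom, start, end[, name]) of Alu elements."""
    loci: List[AluLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"alu_{lineno}"
            loci.append(AluLocus(chrom=chrom, AL=start, AR=end, name=name))
    return loci


def write_alu_bed(loci: List[AluLocus], path: str) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.AL}\t{loc.AR}\t{loc.name}\n")
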