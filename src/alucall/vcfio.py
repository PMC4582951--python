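"""VCF 4.2 output for deletion and insertion call sets, and truth parsing.

Internally all coordinates are 0-based half-open; VCF positions are
1-based. Genotypes are written on the carrier-dosage scale used in each
path: for deletions G0 (Alu present, like the reference) is 0/0 and G2
(Alu absent from both haplotypes) is 1/1; for insertions G0 is the
non-carrier 0/0 and G2 the homozygous carrier 1/1.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

from .genotype import GenotypeCall
from .insertion import InsertionCall
from .loci import AluLocus

_GT_STR = {"G0": "0/0", "G1": "0/1", "G2": "1/1", None: "./."}


def _pl_fields(call: GenotypeCall) -> str:
    """Phred-scaled likelihoods relative to the best genotype."""
    lls = call.log_likelihoods
    m = max(lls)
    pls = [min(999, int(round(-10.0 * (ll - m) / math.log(10)))) for ll in lls]
    return ",".join(str(p) for p in pls)


def _sample_field(call: GenotypeCall) -> str:
    gt = _GT_STR[call.genotype]
    return (f"{gt}:{int(round(call.quality))}:{_pl_fields(call)}:"
            f"{call.n_I},{call.n_S},{call.n_A}")


def _header(chrom_lengths: Dict[str, int], samples: Sequence[str],
            params: Dict[str, object]) -> List[str]:
    lines = ["##fileformat=VCFv4.2", "##source=alucall"]
    for key in sorted(params):
        lines.append(f"##alucall_{key}={params[key]}")
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##ALT=<ID=DEL,Description="Alu deletion relative to the reference">',
        '##ALT=<ID=INS,Description="Alu insertion absent from the reference">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">',
        '##INFO=<ID=ALUFAM,Number=1,Type=String,Description='
        '"Best-matching Alu consensus">',
        '##INFO=<ID=AL,Number=1,Type=Integer,Description='
        '"Voted left breakpoint (1-based)">',
        '##INFO=<ID=AR,Number=1,Type=Integer,Description='
        '"Voted right breakpoint (1-based)">',
        '##INFO=<ID=TSDLEN,Number=1,Type=Integer,Description='
        '"Target-site duplication length">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
        '"Phred-scaled genotype likelihoods">',
        '##FORMAT=<ID=EV,Number=3,Type=Integer,Description='
        '"Evidence pair counts: internal, split, spanning">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    return lines


def write_deletion_vcf(
    path: str,
    loci: Sequence[AluLocus],
    samples: Sequence[str],
    calls: Dict[str, List[GenotypeCall]],
    chrom_lengths: Dict[str, int],
    params: Optional[Dict[str, object]] = None,
) -> None:
    """One record per annotated locus with SVTYPE=DEL."""
    lines = _header(chrom_lengths, samples, params or {})
    for loc in sorted(loci, key=lambda l: (l.chrom, l.AL)):
        info = f"SVTYPE=DEL;END={loc.AR};SVLEN=-{loc.length}"
        row = [loc.chrom, str(loc.AL + 1), loc.name, "N", "<DEL>", ".",
               "PASS", info, "GT:GQ:PL:EV"]
        row += [_sample_field(c) for c in calls[loc.name]]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_insertion_vcf(
    path: str,
    samples: Sequence[str],
    calls: Sequence[InsertionCall],
    chrom_lengths: Dict[str, int],
    params: Optional[Dict[str, object]] = None,
) -> None:
    """One record per discovered insertion site with SVTYPE=INS."""
    lines = _header(chrom_lengths, samples, params or {})
    for call in calls:
        bp = call.breakpoint
        info = [f"SVTYPE=INS", f"ALUFAM={bp.alu_family}"]
        if bp.AL is not None:
            info.append(f"AL={bp.AL + 1}")
        if bp.AR is not None:
            info.append(f"AR={bp.AR + 1}")
        if bp.tsd_length is not None:
            info.append(f"TSDLEN={bp.tsd_length}")
        row = [call.chrom, str(bp.position + 1),
               f"ins_{call.chrom}_{bp.position}", "N", "<INS>", ".", "PASS",
               ";".join(info), "GT:GQ:PL:EV"]
        row += [_sample_field(c) for c in call.genotypes]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_GT_PARSE = {"0/0": "G0", "0|0": "G0", "0/1": "G1", "1/0": "G1", "0|1": "G1",
             "1|0": "G1", "1/1": "G2", "1|1": "G2"}


def read_genotypes_vcf(path: str) -> Tuple[List[str], List[dict]]:
    """Parse a (plain-text) VCF into sample names and per-record maps.

    Each record dict carries chrom, pos (0-based), id and a genotype map
    sample -> "G0"/"G1"/"G2"/None (missing). Sufficient for truth and
    call files written by this package.
    """
    samples: List[str] = []
    records: List[dict] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            gts = {}
            for sample, cell in zip(samples, fields[9:]):
                gt = cell.split(":")[0]
                gts[sample] = _GT_PARSE.get(gt)
            records.append({
                "chrom": fields[0],
                "pos": int(fields[1]) - 1,
                "id": fields[2],
                "info": fields[7],
                "genotypes": gts,
            })
    return samples, records
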