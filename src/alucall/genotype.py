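"""Diploid genotype likelihoods for an Alu polymorphism.

At a locus with alleles H0 (Alu present relative to the reference) and H1
(Alu absent), the three genotypes are G0 (homozygous H0), G1 (heterozygous)
and G2 (homozygous H1). Each classified read pair r contributes a mixture
term, and assuming pairs are independent,

    L(R | G_g, C(R)) = prod_r [ L(r|H0) P(H0|G_g) + L(r|H1) (1 - P(H0|G_g)) ]

with P(H0|G0) = 1, P(H0|G2) = 0 and, for the heterozygote,

    P(H0|G1) = (2 ||r|| + l_Alu) / (4 ||r|| + l_Alu)

where ||r|| is the read length: under uniform coverage the H0 haplotype
presents 2*||r|| + l_Alu positions from which an informative read can start
against 2*||r|| for H1, so H0 draws proportionally more reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

GENOTYPES = ("G0", "G1", "G2")

#: probability of observing type-I/S evidence from the wrong allele
#: (misalignment or sequencing error)
DEFAULT_PE = 0.001

_LOG_TINY = -745.0  # log of the smallest positive double; avoids -inf


def allele_given_genotype(g: str, read_len: int, l_alu: int) -> float:
    """P(H0 | G_g) for g in {G0, G1, G2}."""
    if g == "G0":
        return 1.0
    if g == "G2":
        return 0.0
    if g == "G1":
        if read_len <= 0:
            raise ValueError("read_len must be positive")
        return (2.0 * read_len + l_alu) / (4.0 * read_len + l_alu)
    raise ValueError(f"invalid genotype label {g!r}")


@dataclass
class GenotypeModel:
    """Parameters of the per-pair mixture likelihood."""

    pe: float = DEFAULT_PE
    read_len: int = 100

    def p_h0(self, g: str, l_alu: int) -> float:
        return allele_given_genotype(g, self.read_len, l_alu)


@dataclass
class GenotypeCall:
    sample: str
    locus_id: str
    log_likelihoods: Tuple[float, float, float]
    genotype: Optional[str]      # "G0"/"G1"/"G2", or None for a no-call
    quality: float
    n_I: int = 0
    n_S: int = 0
    n_A: int = 0

    @property
    def is_call(self) -> bool:
        return self.genotype is not None


def genotype_log_likelihoods(
    pair_likelihoods: Sequence[Tuple[float, float]],
    gm: GenotypeModel,
    l_alu: int,
) -> Tuple[float, float, float]:
    """Log of the joint mixture likelihood for G0, G1, G2.

    ``pair_likelihoods`` holds per-pair (L(r|H0), L(r|H1)); an empty set
    yields (0, 0, 0) — no information, all genotypes equally likely.
    """
    out = []
    for g in GENOTYPES:
        p0 = gm.p_h0(g, l_alu)
        total = 0.0
        for lh0, lh1 in pair_likelihoods:
            term = lh0 * p0 + lh1 * (1.0 - p0)
            total += math.log(term) if term > 0.0 else _LOG_TINY
        out.append(total)
    return tuple(out)  # type: ignore[return-value]


def pair_likelihood_for_type(
    pair_type: str,
    pe: float,
    density_h0: Optional[float] = None,
    density_h1: Optional[float] = None,
) -> Tuple[float, float]:
    """Per-pair (L(r|H0), L(r|H1)) by evidence class.

    Type I pairs (one mate internal to the Alu) fix L(r|H0)=1, L(r|H1)=pe;
    type S (split across the breakpoints) the reverse; type A (spanning)
    uses the insert-length density under each allele.
    """
    if pair_type == "I":
        return 1.0, pe
    if pair_type == "S":
        return pe, 1.0
    if pair_type == "A":
        if density_h0 is None or density_h1 is None:
            raise ValueError("type A requires both insert-length densities")
        return density_h0, density_h1
    raise ValueError(f"unknown pair type {pair_type!r}")


def call_genotype(
    log_likelihoods: Tuple[float, float, float],
    sample: str = "sample",
    locus_id: str = ".",
    n_I: int = 0,
    n_S: int = 0,
    n_A: int = 0,
    min_evidence: int = 2,
    max_quality: float = 99.0,
) -> GenotypeCall:
    """Pick the maximum-likelihood genotype with a phred-scaled quality.

    The quality is -10*log10(1 - posterior) under a uniform genotype prior,
    capped. A no-call results when fewer than ``min_evidence`` classified
    pairs support the locus or when all three likelihoods are equal; exact
    ties between distinct genotypes break toward the reference-supporting
    genotype G0.
    """
    lls = tuple(float(x) for x in log_likelihoods)
    evidence = n_I + n_S + n_A
    if evidence < min_evidence or len(set(lls)) == 1:
        return GenotypeCall(sample, locus_id, lls, None, 0.0, n_I, n_S, n_A)
    best = max(range(3), key=lambda i: (lls[i], i == 0))
    m = max(lls)
    weights = [math.exp(ll - m) for ll in lls]
    posterior = weights[best] / sum(weights)
    if posterior >= 1.0:
        quality = max_quality
    else:
        quality = min(max_quality, -10.0 * math.log10(1.0 - posterior))
    return GenotypeCall(sample, locus_id, lls, GENOTYPES[best],
                        max(0.0, quality), n_I, n_S, n_A)
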