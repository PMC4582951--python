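"""Alu consensus panel handling.

The insertion caller split-maps clipped reads against a panel of Alu
consensus sequences (FASTA, one or more entries). The packaged default
panel (``data/alu_panel_synthetic.fa``) is a synthetic stand-in generated
by :func:`make_synthetic_panel`: Alu-like ~300-bp dimeric sequences with a
GC-biased body, an A-rich linker between the monomers and a poly-A tail.
Any user-supplied FASTA of real consensus sequences can replace it.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import numpy as np
from Bio import SeqIO


def load_panel(path: str) -> Dict[str, str]:
    """Read a consensus panel FASTA into an ordered name -> sequence map."""
    panel = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not panel:
        raise ValueError(f"{path}: no sequences in panel FASTA")
    return panel


def default_panel_path() -> str:
    """Path of the packaged synthetic consensus panel."""
    return str(resources.files("alucall").joinpath("data/alu_panel_synthetic.fa"))


def make_synthetic_panel(n: int = 6, seed: int = 7, monomer: int = 132,
                         tail: int = 18) -> Dict[str, str]:
    """Generate a synthetic Alu-like consensus panel (deterministic).

    Each entry is a dimer of two GC-biased monomers joined by an A-rich
    linker and finished with a poly-A tail, mimicking the length and gross
    composition of Alu consensus sequences without reproducing any real
    one. Families share ~85% identity with the first entry, echoing
    divergence between Alu subfamilies.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    gc_probs = [0.18, 0.32, 0.32, 0.18]
    root = rng.choice(bases, size=2 * monomer, p=gc_probs)
    linker = np.array(list("AAAAA"))
    panel: Dict[str, str] = {}
    for i in range(n):
        body = root.copy()
        if i > 0:
            k = max(1, int(0.15 * body.size))
            pos = rng.choice(body.size, size=k, replace=False)
            body[pos] = rng.choice(bases, size=k)
        seq = np.concatenate([body[:monomer], linker, body[monomer:],
                              np.repeat(np.array(["A"]), tail)])
        panel[f"AluSyn{i + 1}"] = "".join(seq)
    return panel


def write_panel(panel: Dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in panel.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
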