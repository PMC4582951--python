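"""Benchmarking genotype calls against a truth set.

Accuracy is summarized by a 3x3 confusion matrix C_tp counting predictions
of genotype G_p at loci whose true genotype is G_t. True positives
tolerate genotyping errors between carrier states:

    TPN = C11 + C22 + C12 + C21
    sensitivity = TPN / (TPN + C10 + C20)
    FDR = (C01 + C02) / (TPN + C01 + C02)

A truth event with no matching call is scored as a G0 prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

GT_INDEX = {"G0": 0, "G1": 1, "G2": 2}

#: default matching window for insertion sites (breakpoint tolerance)
MATCH_WINDOW = 50


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (no calls / no truth events)."""


@dataclass
class ConfusionMatrix:
    counts: List[List[int]] = field(
        default_factory=lambda: [[0, 0, 0] for _ in range(3)])

    def add(self, truth: str, predicted: str, k: int = 1) -> None:
        self.counts[GT_INDEX[truth]][GT_INDEX[predicted]] += k

    def __getitem__(self, tp: Tuple[int, int]) -> int:
        return self.counts[tp[0]][tp[1]]

    @property
    def tpn(self) -> int:
        c = self.counts
        return c[1][1] + c[2][2] + c[1][2] + c[2][1]

    @classmethod
    def from_counts(cls, **ctp: int) -> "ConfusionMatrix":
        """Build from keyword counts like c11=3521, c10=132, ..."""
        cm = cls()
        for key, val in ctp.items():
            t, p = int(key[1]), int(key[2])
            cm.counts[t][p] = val
        return cm


def sensitivity(cm: ConfusionMatrix) -> float:
    denom = cm.tpn + cm[1, 0] + cm[2, 0]
    if denom == 0:
        raise UndefinedMetricError("sensitivity undefined: no true events")
    return cm.tpn / denom


def fdr(cm: ConfusionMatrix) -> float:
    fp = cm[0, 1] + cm[0, 2]
    denom = cm.tpn + fp
    if denom == 0:
        raise UndefinedMetricError("FDR undefined: no positive calls")
    return fp / denom


@dataclass(frozen=True)
class MatchedCall:
    """One (sample, locus) pair of truth genotype and predicted genotype."""

    sample: str
    locus: str
    truth: str
    predicted: str


def confusion(calls: Iterable[MatchedCall]) -> ConfusionMatrix:
    """Tally truth-matched calls; duplicates of (sample, locus) are errors."""
    cm = ConfusionMatrix()
    seen = set()
    for c in calls:
        key = (c.sample, c.locus)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
        cm.add(c.truth, c.predicted)
    return cm


def match_by_locus(
    truth: Dict[Tuple[str, str], str],
    predicted: Dict[Tuple[str, str], str],
) -> List[MatchedCall]:
    """Match deletion-path calls to truth by (sample, locus id).

    Loci in the truth set with no call are scored as predicted G0; calls
    at loci absent from the truth (false discoveries) get truth G0.
    """
    out: List[MatchedCall] = []
    for (sample, locus), t in truth.items():
        p = predicted.get((sample, locus), "G0")
        out.append(MatchedCall(sample, locus, t, p))
    for (sample, locus), p in predicted.items():
        if (sample, locus) not in truth:
            out.append(MatchedCall(sample, locus, "G0", p))
    return out


def match_by_position(
    truth_sites: Dict[int, Dict[str, str]],
    called_sites: Dict[int, Dict[str, str]],
    samples: Sequence[str],
    chrom_truth: Optional[Dict[int, str]] = None,
    window: int = MATCH_WINDOW,
) -> List[MatchedCall]:
    """Match insertion calls to truth sites within ``window`` basepairs.

    ``truth_sites`` and ``called_sites`` map breakpoint position to a
    per-sample genotype map ("G0"/"G1"/"G2"). Each called site matches the
    nearest unmatched truth site within the window; unmatched truth sites
    are scored as G0 predictions for every carrier, and unmatched called
    sites as discoveries at truth-G0 loci.
    """
    truth_pos = sorted(truth_sites)
    matched_truth: Dict[int, Optional[int]] = {p: None for p in truth_pos}
    out: List[MatchedCall] = []
    for cpos in sorted(called_sites):
        best = None
        for tpos in truth_pos:
            if matched_truth[tpos] is not None:
                continue
            d = abs(tpos - cpos)
            if d <= window and (best is None or d < abs(best - cpos)):
                best = tpos
        locus = f"site_{cpos}"
        if best is not None:
            matched_truth[best] = cpos
            locus = f"site_{best}"
        for sample in samples:
            t = truth_sites.get(best, {}).get(sample, "G0") if best is not None else "G0"
            p = called_sites[cpos].get(sample, "G0")
            if t == "G0" and p == "G0":
                continue  # uninformative double-negative at a called site
            out.append(MatchedCall(sample, locus, t, p))
    for tpos, m in matched_truth.items():
        if m is not None:
            continue
        for sample in samples:
            t = truth_sites[tpos].get(sample, "G0")
            out.append(MatchedCall(sample, f"site_{tpos}", t, "G0"))
    return out


_MENDEL_OK = {
    # (father dosage, mother dosage) -> feasible child dosages
    (0, 0): {0}, (0, 1): {0, 1}, (1, 0): {0, 1},
    (0, 2): {1}, (2, 0): {1}, (1, 1): {0, 1, 2},
    (1, 2): {1, 2}, (2, 1): {1, 2}, (2, 2): {2},
}


def mendelian_violations(
    father: Dict[str, str],
    mother: Dict[str, str],
    child: Dict[str, str],
) -> Tuple[int, List[str], float]:
    """Count trio calls incompatible with Mendelian inheritance.

    Calls private to the child count as violations (de-novo Alu insertions
    are rare enough to treat them as false positives). Returns the count,
    the flagged locus ids, and the implied FDR lower bound
    count / (number of child carrier calls).
    """
    flagged: List[str] = []
    child_calls = 0
    for locus, cg in child.items():
        cd = GT_INDEX.get(cg)
        if cd is None or cd == 0:
            continue
        child_calls += 1
        fd = GT_INDEX.get(father.get(locus, "G0"), 0)
        md = GT_INDEX.get(mother.get(locus, "G0"), 0)
        if fd == 0 and md == 0:
            flagged.append(locus)  # private to the child
        elif cd not in _MENDEL_OK[(fd, md)]:
            flagged.append(locus)
    bound = len(flagged) / child_calls if child_calls else 0.0
    return len(flagged), flagged, bound


def metrics_table(
    rows: Dict[str, ConfusionMatrix],
) -> str:
    """Render datasets' confusion counts and metrics as a TSV string."""
    header = ["dataset", "C11", "C22", "C10", "C20", "C01", "C02", "C12",
              "C21", "TPN", "sensitivity", "FDR"]
    lines = ["\t".join(header)]
    for name, cm in rows.items():
        try:
            sens = f"{100.0 * sensitivity(cm):.1f}%"
        except UndefinedMetricError:
            sens = "NA"
        try:
            rate = f"{100.0 * fdr(cm):.1f}%"
        except UndefinedMetricError:
            rate = "NA"
        lines.append("\t".join(str(x) for x in [
            name, cm[1, 1], cm[2, 2], cm[1, 0], cm[2, 0], cm[0, 1],
            cm[0, 2], cm[1, 2], cm[2, 1], cm.tpn, sens, rate]))
    return "\n".join(lines) + "\n"
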