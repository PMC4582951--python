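"""Per-library empirical insert-length distribution.

Every likelihood computation downstream conditions on the distribution of
the insert length Y of concordant read pairs, estimated separately per
sequencing library. The density is a normalized 1-bp histogram over
[max(0, E[Y] - 5*sigma), E[Y] + 5*sigma] with add-one smoothing inside the
support and a small floor outside it, so outlying inserts never receive a
zero likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import numpy as np

from .pairs import ReadPairRecord, classify_concordance, insert_length

#: density assigned to insert lengths outside the histogram support
DENSITY_FLOOR = 1e-6

#: default minimum number of concordant pairs needed to estimate a library
MIN_PAIRS = 1000

#: default cap on pairs used per library (single streaming pass)
MAX_PAIRS = 1_000_000


class InsertModelError(RuntimeError):
    """Raised when a library has too few concordant pairs for estimation."""


@dataclass
class LibraryModel:
    """Empirical insert-length distribution of one sequencing library."""

    mean: float
    sd: float
    count: int
    support_lo: int       # inclusive
    support_hi: int       # inclusive
    pmf: np.ndarray       # probability mass per 1-bp bin over the support

    def density(self, y: float) -> float:
        """Evaluate f_Y at an (integer) insert length; floored outside support."""
        yi = int(round(y))
        if yi < self.support_lo or yi > self.support_hi:
            return DENSITY_FLOOR
        return float(self.pmf[yi - self.support_lo])


@dataclass
class InsertLengthModel:
    """Map from library name to its empirical insert-length distribution."""

    libraries: Dict[str, LibraryModel] = field(default_factory=dict)

    def __contains__(self, library: str) -> bool:
        return library in self.libraries

    def _lib(self, library: str) -> LibraryModel:
        if library in self.libraries:
            return self.libraries[library]
        if len(self.libraries) == 1:
            return next(iter(self.libraries.values()))
        raise KeyError(f"no insert-length model for library {library!r}")

    def mean_sd(self, library: str = "default") -> Tuple[float, float]:
        lib = self._lib(library)
        return lib.mean, lib.sd

    def density(self, y: float, library: str = "default") -> float:
        return self._lib(library).density(y)

    def flank_width(self, library: str = "default") -> int:
        """E[Y] + 3*sigma(Y), rounded — the single source of truth for
        flank sizes and support windows downstream."""
        mean, sd = self.mean_sd(library)
        return int(round(mean + 3.0 * sd))


def _build_library(ys: List[int]) -> LibraryModel:
    # sorting first makes the estimate exactly order-invariant
    arr = np.sort(np.asarray(ys, dtype=float))
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    if sd == 0.0:
        sd = 1.0  # degenerate distribution: keep windows nonzero
    lo = max(0, int(round(mean - 5.0 * sd)))
    hi = int(round(mean + 5.0 * sd))
    counts = np.ones(hi - lo + 1, dtype=float)  # add-one smoothing
    inside = (arr >= lo) & (arr <= hi)
    idx = (arr[inside] - lo).astype(int)
    np.add.at(counts, idx, 1.0)
    pmf = counts / counts.sum()
    return LibraryModel(mean=mean, sd=sd, count=arr.size,
                        support_lo=lo, support_hi=hi, pmf=pmf)


def model_from_lengths(
    lengths_by_library: Dict[str, List[int]],
    min_pairs_per_library: int = MIN_PAIRS,
) -> InsertLengthModel:
    """Build an :class:`InsertLengthModel` from pre-collected insert lengths."""
    model = InsertLengthModel()
    for lib, vals in lengths_by_library.items():
        if len(vals) < min_pairs_per_library:
            raise InsertModelError(
                f"library {lib!r}: only {len(vals)} concordant pairs "
                f"(minimum {min_pairs_per_library})"
            )
    for lib, vals in sorted(lengths_by_library.items()):
        model.libraries[lib] = _build_library(vals)
    if not model.libraries:
        raise InsertModelError("no concordant pairs in input")
    return model


def estimate_insert_model(
    pairs: Iterable[ReadPairRecord],
    max_pairs_per_library: int = MAX_PAIRS,
    min_pairs_per_library: int = MIN_PAIRS,
) -> InsertLengthModel:
    """Estimate E[Y], sigma(Y) and the empirical density per library.

    Only concordant pairs contribute (judged by the aligner's proper-pair
    flag on this bootstrap pass). The first ``max_pairs_per_library``
    concordant pairs per library are used, so one streaming pass suffices.
    """
    ys: Dict[str, List[int]] = {}
    done = set()
    for pair in pairs:
        lib = pair.library
        if lib in done:
            continue
        if classify_concordance(pair, None) != "concordant":
            continue
        bucket = ys.setdefault(lib, [])
        bucket.append(insert_length(pair))
        if len(bucket) >= max_pairs_per_library:
            done.add(lib)
    return model_from_lengths(ys, min_pairs_per_library)
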