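"""Library-level quantitation: relative frequencies, detection summaries
and the hit-count abundance histogram.

Expression is measured by hit counts (reads assembled per contig); the
normalised measure is the relative frequency, a contig's hit count divided
by its library's total.  Most contigs in a typical two-library run carry
only a handful of hits, so the summary distinguishes the well-sampled
fraction (>= 5 hits) from the low-count fraction where the conditional test
has little power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acdge import DEResult, ac_test_arrays, classify_de
from .tabio import CountTable

__all__ = ["LibrarySummary", "HitHistogram", "compute_de_table", "summarize",
           "hit_histogram", "DEFAULT_BIN_UPPERS"]

DEFAULT_BIN_UPPERS: tuple[float, ...] = (1, 5, 10, 50, 100, 500, 1000, math.inf)


@dataclass(frozen=True)
class LibrarySummary:
    """Exhaustive detection/abundance counts over a two-library table."""

    detected_d: int
    detected_l: int
    at_least5_d: int
    at_least5_l: int
    at_least5_both: int
    at_most5_both: int
    singletons_d: int
    singletons_l: int
    more_abundant_d: int  # strictly higher relative frequency in D
    more_abundant_l: int
    significant_total: int
    significant_up: int
    significant_down: int


@dataclass(frozen=True)
class HitHistogram:
    """Per-library hit-count histogram with adjacent-upper-range bins.

    A count ``c`` falls into the first bin whose upper bound is >= ``c``
    (e.g. with uppers (1, 5, 10, ...) a contig with 2 hits lands in the
    2-5 bin).  Only detected contigs (>= 1 hit) contribute to a library's
    histogram.
    """

    bin_uppers: tuple[float, ...]
    counts_d: tuple[int, ...]
    counts_l: tuple[int, ...]


def compute_de_table(table: CountTable, alpha: float = 0.05) -> list[DEResult]:
    """Run the conditional count test on every record of a table.

    Relative frequencies and p-values use ``table.totals`` (the full
    library totals, possibly overridden); significance is p < alpha.
    """
    if not table.records:
        return []
    nd, nl = table.totals.n_d, table.totals.n_l
    if nd < 1 or nl < 1:
        raise ValueError("library totals must be positive to test")
    hd = np.array([r.hits_d for r in table.records], dtype=np.int64)
    hl = np.array([r.hits_l for r in table.records], dtype=np.int64)
    log10p, direction, ratio = ac_test_arrays(hd, hl, nd, nl)
    names = {-1: "down", 0: "tie", 1: "up"}
    out: list[DEResult] = []
    for i, rec in enumerate(table.records):
        res = DEResult(
            contig_id=rec.contig_id,
            hits_d=int(hd[i]),
            hits_l=int(hl[i]),
            rel_d=hd[i] / nd,
            rel_l=hl[i] / nl,
            direction=names[int(direction[i])],
            ratio=float(ratio[i]),
            p_value=10.0 ** float(log10p[i]),
            log10_p=float(log10p[i]),
        )
        out.append(classify_de(res, alpha))
    return out


def summarize(table: CountTable, de: list[DEResult]) -> LibrarySummary:
    """Exhaustively count detection, abundance and significance classes."""
    hd = np.array([r.hits_d for r in table.records], dtype=np.int64)
    hl = np.array([r.hits_l for r in table.records], dtype=np.int64)
    if hd.size == 0:
        return LibrarySummary(*([0] * 13))
    nd = max(table.totals.n_d, 1)
    nl = max(table.totals.n_l, 1)
    rel_d, rel_l = hd / nd, hl / nl
    sig = [r for r in de if r.significant]
    return LibrarySummary(
        detected_d=int(np.sum(hd >= 1)),
        detected_l=int(np.sum(hl >= 1)),
        at_least5_d=int(np.sum(hd >= 5)),
        at_least5_l=int(np.sum(hl >= 5)),
        at_least5_both=int(np.sum((hd >= 5) & (hl >= 5))),
        at_most5_both=int(np.sum((hd <= 5) & (hl <= 5))),
        singletons_d=int(np.sum(hd == 1)),
        singletons_l=int(np.sum(hl == 1)),
        more_abundant_d=int(np.sum(rel_d > rel_l)),
        more_abundant_l=int(np.sum(rel_l > rel_d)),
        significant_total=len(sig),
        significant_up=sum(1 for r in sig if r.direction == "up"),
        significant_down=sum(1 for r in sig if r.direction == "down"),
    )


def hit_histogram(table: CountTable,
                  bin_uppers: tuple[float, ...] = DEFAULT_BIN_UPPERS) -> HitHistogram:
    """Bin detected contigs' hit counts into adjacent upper ranges."""
    uppers = tuple(bin_uppers)
    if any(b >= a for b, a in zip(uppers, uppers[1:])):
        raise ValueError("bin_uppers must be strictly increasing")

    def _bin(counts: np.ndarray) -> tuple[int, ...]:
        counts = counts[counts >= 1]
        idx = np.searchsorted(np.asarray(uppers, dtype=float), counts, side="left")
        return tuple(int(np.sum(idx == k)) for k in range(len(uppers)))

    hd = np.array([r.hits_d for r in table.records], dtype=np.int64)
    hl = np.array([r.hits_l for r in table.records], dtype=np.int64)
    return HitHistogram(uppers, _bin(hd), _bin(hl))
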