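"""GO-term overrepresentation between two transcript sets.

Each GO term occurring on at least one annotated contig of either set is
tested with a two-tailed Fisher exact test on the 2x2 table (test-set
contigs with/without the term vs reference-set contigs with/without), and
the p-values are adjusted by the Benjamini-Hochberg step-up procedure.
Only contigs carrying at least one GO term participate; each contig counts
once per term regardless of how many of its terms match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .tabio import AnnotationRecord

__all__ = ["ContingencyTable2x2", "EnrichmentResult", "fisher_two_tailed",
           "bh_fdr", "go_enrichment"]

logger = logging.getLogger(__name__)

# relative tolerance for the "point probability <= observed" comparison
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Term-by-set contingency counts.

    ``a``: test-set contigs carrying the term, ``b``: test-set contigs
    without it; ``c``/``d`` likewise for the reference set.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    table: ContingencyTable2x2
    p_value: float
    fdr: float
    overrepresented_in: str  # "test" or "ref"
    reported: bool = False


def fisher_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p-value.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability is <= the observed one (within 1e-7
    relative tolerance), the convention shared by R and most enrichment
    tools.  Degenerate margins give p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b  # test-set size
    col1 = a + c  # contigs carrying the term
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    support = np.arange(max(0, col1 - (n - row1)), min(col1, row1) + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[np.searchsorted(support, a)]
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + _REL_TOL)]))
    return min(p, 1.0)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def go_enrichment(
    test_ids: Iterable[str],
    ref_ids: Iterable[str],
    annotations: Iterable[AnnotationRecord],
    fdr_threshold: float = 0.01,
) -> list[EnrichmentResult]:
    """Test every GO term for overrepresentation between two contig sets.

    ``test_ids`` and ``ref_ids`` must be disjoint (e.g. up- vs
    down-regulated transcripts).  The term universe is the union of terms
    over participating (GO-annotated) contigs of both sets; a result is
    flagged ``reported`` when its adjusted value falls below
    ``fdr_threshold`` (strict).
    """
    test_ids, ref_ids = set(test_ids), set(ref_ids)
    if test_ids & ref_ids:
        raise ValueError("test and reference sets must be disjoint")
    ann = {r.contig_id: r for r in annotations}

    def participating(ids: set[str]) -> list[AnnotationRecord]:
        return [ann[i] for i in sorted(ids) if i in ann and ann[i].go_terms]

    test_ann = participating(test_ids)
    ref_ann = participating(ref_ids)
    if not test_ann and not ref_ann:
        logger.warning("no GO-annotated contigs in either set; nothing to test")
        return []

    universe = sorted(set().union(*(r.go_terms for r in test_ann + ref_ann)))
    n_test, n_ref = len(test_ann), len(ref_ann)
    results: list[tuple[str, ContingencyTable2x2, float, str]] = []
    for term in universe:
        a = sum(1 for r in test_ann if term in r.go_terms)
        c = sum(1 for r in ref_ann if term in r.go_terms)
        tab = ContingencyTable2x2(a, n_test - a, c, n_ref - c)
        p = fisher_two_tailed(tab)
        prop_test = a / n_test if n_test else 0.0
        prop_ref = c / n_ref if n_ref else 0.0
        side = "test" if prop_test > prop_ref else "ref"
        results.append((term, tab, p, side))

    fdr = bh_fdr([r[2] for r in results])
    return [
        EnrichmentResult(term, tab, p, float(q), side, reported=float(q) < fdr_threshold)
        for (term, tab, p, side), q in zip(results, fdr)
    ]
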