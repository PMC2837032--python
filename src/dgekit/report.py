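"""Reporting artifacts: ranked DE tables, high-abundance lists, the
relative-frequency scatter export, and the global DE partition.

The ranked tables mirror the field's "top N most up/down-regulated
annotated transcripts" presentation: rows are filtered to significant,
annotated transcripts of one direction and ordered by the ratio of
relative frequencies (majority over minority library), with the p-value as
the admission filter rather than the sort key.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .acdge import DEResult
from .tabio import AnnotationRecord

__all__ = ["RankedRow", "top_ranked", "high_abundance", "scatter_export",
           "de_partition"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedRow:
    contig_id: str
    accession: str
    description: str
    hits_d: int
    hits_l: int
    ratio: float
    p_value: float


def top_ranked(
    de: Iterable[DEResult],
    annotations: Iterable[AnnotationRecord],
    direction: str,
    n: int = 20,
    alpha: float = 0.05,
    annotated_only: bool = True,
) -> list[RankedRow]:
    """Top-``n`` transcripts of one direction ranked by frequency ratio.

    Rows must be significant at ``alpha`` and (by default) carry a
    non-empty ortholog accession.  Sort key: ratio descending, then
    p-value ascending, then contig_id ascending.  Set
    ``annotated_only=False`` to rank unannotated transcripts too.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if n < 1:
        raise ValueError("n must be >= 1")
    ann = {r.contig_id: r for r in annotations}
    rows = []
    for r in de:
        if r.direction != direction or not (r.p_value < alpha):
            continue
        a = ann.get(r.contig_id)
        if annotated_only and (a is None or not a.annotated):
            continue
        rows.append(
            RankedRow(
                contig_id=r.contig_id,
                accession=a.accession if a else "",
                description=a.description if a else "",
                hits_d=r.hits_d,
                hits_l=r.hits_l,
                ratio=r.ratio,
                p_value=r.p_value,
            )
        )
    rows.sort(key=lambda w: (-w.ratio, w.p_value, w.contig_id))
    if len(rows) < n:
        logger.info("only %d qualifying rows for direction=%s (requested %d)",
                    len(rows), direction, n)
    return rows[:n]


def high_abundance(de: Iterable[DEResult], threshold: float = 0.005) -> list[DEResult]:
    """Transcripts whose relative frequency exceeds ``threshold`` (strict)
    in at least one library — the handful of very abundant species that
    dominate a scatter of the two libraries."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return [r for r in de if r.rel_d > threshold or r.rel_l > threshold]


def scatter_export(de: Iterable[DEResult], path) -> None:
    """Write the per-contig relative frequencies (both libraries), call
    direction and significance flag — sufficient to re-plot the classic
    relL-vs-relD scatter."""
    rows = [
        {
            "contig_id": r.contig_id,
            "rel_d": f"{r.rel_d:.12e}",
            "rel_l": f"{r.rel_l:.12e}",
            "direction": r.direction,
            "significant": r.significant,
        }
        for r in de
    ]
    pd.DataFrame(rows, columns=["contig_id", "rel_d", "rel_l", "direction",
                                "significant"]).to_csv(path, sep="\t", index=False)


def de_partition(de: Iterable[DEResult]) -> tuple[int, int, int]:
    """(significant_total, up_count, down_count) over a DE table.

    Ties carry p = 1 and are never significant, so the total always equals
    up + down.
    """
    up = sum(1 for r in de if r.significant and r.direction == "up")
    down = sum(1 for r in de if r.significant and r.direction == "down")
    return up + down, up, down


def ranked_rows_to_frame(rows: Iterable[RankedRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": r.contig_id,
                "accession": r.accession,
                "description": r.description,
                "hits_d": r.hits_d,
                "hits_l": r.hits_l,
                "ratio": "inf" if math.isinf(r.ratio) else f"{r.ratio:.4f}",
                "p_value": f"{r.p_value:.6e}",
            }
            for r in rows
        ],
        columns=["contig_id", "accession", "description", "hits_d", "hits_l",
                 "ratio", "p_value"],
    )
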