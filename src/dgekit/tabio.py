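"""Table and sequence I/O for the count-profiling pipeline.

All tabular formats are tab-separated with a header line; lines starting
with ``#`` are comments.  Count tables carry one row per contig with the
raw hit counts of the two libraries; annotation tables map contigs to an
ortholog accession, a free-text description, pipe-separated GO terms and an
optional KEGG ortholog; prior-interaction tables list undirected accession
pairs with an interaction probability in [0, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .acdge import LibraryPair

__all__ = [
    "TableFormatError",
    "TranscriptCounts",
    "CountTable",
    "AnnotationRecord",
    "PriorEdge",
    "read_count_table",
    "write_count_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_prior_edges",
    "read_fasta",
]

GO_PATTERN = re.compile(r"^GO:\d{7}$")


class TableFormatError(ValueError):
    """A table violates the expected dialect or an invariant."""


@dataclass(frozen=True)
class TranscriptCounts:
    """Raw read counts of one contig in the two libraries."""

    contig_id: str
    hits_d: int
    hits_l: int

    def __post_init__(self) -> None:
        if self.hits_d < 0 or self.hits_l < 0:
            raise ValueError(f"negative hit count for {self.contig_id!r}")


@dataclass
class CountTable:
    """Ordered collection of per-contig counts plus the library totals.

    Totals default to the column sums; they may be overridden when a subset
    of a larger table is analysed (p-values depend on the full totals).
    """

    records: list[TranscriptCounts]
    totals: LibraryPair
    totals_overridden: bool = False

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_records(
        cls, records: Iterable[TranscriptCounts], totals: LibraryPair | None = None
    ) -> "CountTable":
        recs = list(records)
        seen: set[str] = set()
        for r in recs:
            if r.contig_id in seen:
                raise TableFormatError(f"duplicate contig_id {r.contig_id!r}")
            seen.add(r.contig_id)
        if totals is None:
            nd = sum(r.hits_d for r in recs)
            nl = sum(r.hits_l for r in recs)
            return cls(recs, LibraryPair(nd, nl))
        return cls(recs, totals, totals_overridden=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": [r.contig_id for r in self.records],
                "hits_d": [r.hits_d for r in self.records],
                "hits_l": [r.hits_l for r in self.records],
            }
        )


@dataclass(frozen=True)
class AnnotationRecord:
    """Contig-to-ortholog mapping with GO terms and optional KEGG ortholog."""

    contig_id: str
    accession: str = ""
    description: str = ""
    go_terms: frozenset[str] = field(default_factory=frozenset)
    ko_id: str = ""

    @property
    def annotated(self) -> bool:
        return self.accession != ""


@dataclass(frozen=True)
class PriorEdge:
    """Undirected prior interaction between two ortholog accessions."""

    accession_a: str
    accession_b: str
    probability: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.accession_a == self.accession_b:
            raise TableFormatError(f"self-edge on {self.accession_a!r}")
        if not 0.0 <= self.probability <= 1.0:
            raise TableFormatError(
                f"probability {self.probability} outside [0,1] for edge "
                f"{self.accession_a}-{self.accession_b}"
            )

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.accession_a, self.accession_b))


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_count_table(path, totals: LibraryPair | None = None) -> CountTable:
    """Read a contig count table (columns contig_id, hits_d, hits_l).

    Pass ``totals`` to analyse a subset of a larger table against the full
    library totals.
    """
    df = _read_tsv(path, ["contig_id", "hits_d", "hits_l"])
    records: list[TranscriptCounts] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid = row.contig_id
        if cid in seen:
            raise TableFormatError(f"{path}: duplicate contig_id {cid!r} (line {i})")
        seen.add(cid)
        try:
            hd, hl = int(row.hits_d), int(row.hits_l)
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-integer count on line {i} ({cid!r})") from exc
        if hd < 0 or hl < 0:
            raise TableFormatError(f"{path}: negative count on line {i} ({cid!r})")
        records.append(TranscriptCounts(cid, hd, hl))
    if totals is not None:
        return CountTable(records, totals, totals_overridden=True)
    nd = sum(r.hits_d for r in records)
    nl = sum(r.hits_l for r in records)
    return CountTable(records, LibraryPair(nd, nl))


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> list[AnnotationRecord]:
    """Read contig annotations; GO terms are pipe-separated in one column."""
    df = _read_tsv(path, ["contig_id", "accession", "description", "go_terms"])
    records: list[AnnotationRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid = row.contig_id
        if cid in seen:
            raise TableFormatError(f"{path}: duplicate contig_id {cid!r} (line {i})")
        seen.add(cid)
        raw = row.go_terms.strip()
        terms: set[str] = set()
        if raw:
            for term in raw.split("|"):
                term = term.strip()
                if not GO_PATTERN.match(term):
                    raise TableFormatError(
                        f"{path}: malformed GO id {term!r} on line {i} ({cid!r})"
                    )
                terms.add(term)
        ko = getattr(row, "ko_id", "")
        records.append(
            AnnotationRecord(cid, row.accession.strip(), row.description.strip(),
                             frozenset(terms), ko.strip())
        )
    return records


def write_annotation_table(records: Iterable[AnnotationRecord], path) -> None:
    rows = [
        {
            "contig_id": r.contig_id,
            "accession": r.accession,
            "description": r.description,
            "go_terms": "|".join(sorted(r.go_terms)),
            "ko_id": r.ko_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["contig_id", "accession", "description",
                                "go_terms", "ko_id"]).to_csv(path, sep="\t", index=False)


def read_prior_edges(path) -> list[PriorEdge]:
    """Read an undirected prior-interaction edge list.

    Duplicate pairs (either orientation) are collapsed to a single edge
    keeping the maximum probability; self-edges are rejected.
    """
    df = _read_tsv(path, ["accession_a", "accession_b", "probability"])
    best: dict[frozenset[str], PriorEdge] = {}
    order: list[frozenset[str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            prob = float(row.probability)
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-numeric probability on line {i}") from exc
        edge = PriorEdge(row.accession_a.strip(), row.accession_b.strip(), prob,
                         getattr(row, "provenance", ""))
        if edge.key not in best:
            best[edge.key] = edge
            order.append(edge.key)
        elif prob > best[edge.key].probability:
            best[edge.key] = edge
    return [best[k] for k in order]


def read_fasta(path) -> Mapping[str, str]:
    """Read contig sequences; ids are the first token of each header."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise TableFormatError(f"{path}: empty sequence for record {rec.id!r}")
        out[rec.id] = seq
    return out
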