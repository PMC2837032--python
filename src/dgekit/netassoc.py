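"""Guilt-by-association network assembly.

Differentially expressed, annotated transcripts are linked through a
supplied table of prior ortholog-ortholog interaction probabilities
(curated or predicted elsewhere); co-expression direction is carried as a
node attribute so up- and down-regulated groups and the edges bridging
them are visible in downstream viewers.  Edges whose prior probability
exceeds the significance threshold (strictly) are flagged.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx

from .acdge import DEResult
from .tabio import AnnotationRecord, PriorEdge

__all__ = ["build_network", "export_graph", "select_contigs"]

logger = logging.getLogger(__name__)


def select_contigs(
    de: Iterable[DEResult],
    selection: str = "significant",
    alpha: float = 0.05,
    top_n: int = 20,
    relfreq_threshold: float = 0.005,
) -> list[DEResult]:
    """Choose the transcripts that become network nodes.

    ``significant``: p < alpha; ``top``: the top_n per direction by ratio
    among significant calls; ``relfreq``: relative frequency above the
    threshold in either library.
    """
    de = list(de)
    if selection == "significant":
        return [r for r in de if r.p_value < alpha]
    if selection == "top":
        out: list[DEResult] = []
        for direction in ("up", "down"):
            rows = [r for r in de if r.direction == direction and r.p_value < alpha]
            rows.sort(key=lambda r: (-r.ratio, r.p_value, r.contig_id))
            out.extend(rows[:top_n])
        return out
    if selection == "relfreq":
        return [r for r in de if r.rel_d > relfreq_threshold or r.rel_l > relfreq_threshold]
    raise ValueError(f"unknown selection rule {selection!r}")


def build_network(
    de: Iterable[DEResult],
    annotations: Iterable[AnnotationRecord],
    priors: Iterable[PriorEdge],
    selection: str = "significant",
    edge_threshold: float = 0.9,
    alpha: float = 0.05,
    top_n: int = 20,
    relfreq_threshold: float = 0.005,
) -> nx.Graph:
    """Assemble the association network over selected, annotated transcripts.

    Nodes are contigs with a non-empty ortholog accession; an edge exists
    iff a prior edge links the two contigs' accessions.  Node attributes:
    accession, direction, hits_d, hits_l.  Edge attributes: probability and
    ``significant`` (probability > edge_threshold, strict).  An accession
    shared by several contigs expands to all pairings (with a warning).
    """
    selected = select_contigs(de, selection, alpha, top_n, relfreq_threshold)
    ann = {r.contig_id: r for r in annotations}

    g = nx.Graph()
    acc_to_contigs: dict[str, list[str]] = {}
    for r in selected:
        a = ann.get(r.contig_id)
        if a is None or not a.annotated:
            logger.warning("contig %s has no ortholog accession; skipped", r.contig_id)
            continue
        g.add_node(r.contig_id, accession=a.accession, direction=r.direction,
                   hits_d=r.hits_d, hits_l=r.hits_l)
        acc_to_contigs.setdefault(a.accession, []).append(r.contig_id)

    for acc, contigs in acc_to_contigs.items():
        if len(contigs) > 1:
            logger.warning("accession %s maps to %d selected contigs; all pairings expanded",
                           acc, len(contigs))

    for edge in priors:
        for u in acc_to_contigs.get(edge.accession_a, []):
            for v in acc_to_contigs.get(edge.accession_b, []):
                g.add_edge(u, v, probability=edge.probability,
                           significant=edge.probability > edge_threshold)
    return g


def export_graph(net: nx.Graph, path, format: str = "sif") -> None:
    """Write the network as SIF ("id interacts id" lines, isolated nodes on
    their own line) or GraphML (all node/edge attributes preserved)."""
    fmt = format.lower()
    if fmt == "sif":
        lines = []
        written: set[str] = set()
        for u, v in net.edges():
            lines.append(f"{u}\tinteracts\t{v}")
            written.update((u, v))
        for node in net.nodes():
            if node not in written:
                lines.append(str(node))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown export format {format!r} (use 'sif' or 'graphml')")
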