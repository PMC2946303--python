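"""Thresholded disease-disease similarity maps.

A disease map connects all disease pairs whose shared-causal-gene evidence
passes a minimum overlap and a maximum combined P-value (the headline
construction uses overlap >= 2 and P <= 0.001).  Connected components of the
resulting graph are the mechanistic disease groups; the local neighborhood
of a single disease at a looser threshold (P < 0.01) is its *vicinity*.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from .associations import AssociationTable
from .overlap import PairResult


def build_map(
    pairs: Iterable[PairResult],
    p_max: float = 0.001,
    min_overlap: int = 2,
    include_isolated: bool = False,
    all_diseases: Iterable[str] | None = None,
) -> nx.Graph:
    """Build the disease graph from precomputed pair results.

    Edges are exactly the pairs with ``overlap >= min_overlap`` and
    ``p_combined <= p_max``; duplicates collapse.  Components are labeled on
    each node (attribute ``component``) in decreasing size order, ties
    broken by the lexicographically smallest member.  With
    ``include_isolated`` and ``all_diseases`` given, unconnected diseases
    are kept as nodes with ``component = None``.
    """
    G = nx.Graph()
    if include_isolated and all_diseases is not None:
        G.add_nodes_from(all_diseases, component=None)
    for r in pairs:
        if r.overlap >= min_overlap and r.p_combined <= p_max:
            G.add_edge(
                r.entity_a, r.entity_b,
                overlap=r.overlap, p_combined=r.p_combined,
            )
    comps = sorted(
        (c for c in nx.connected_components(G) if len(c) > 1),
        key=lambda c: (-len(c), min(c)),
    )
    for cid, comp in enumerate(comps):
        for node in comp:
            G.nodes[node]["component"] = cid
    for node in G.nodes:
        G.nodes[node].setdefault("component", None)
    return G


def estimate_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    The map construction applies this to the combined P-values of all pairs
    with at least the minimum gene overlap, to express the edge threshold as
    a false discovery rate.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def vicinity(
    disease: str,
    table: AssociationTable,
    pairs: Iterable[PairResult],
    p_max: float = 0.01,
    min_overlap: int = 2,
) -> list[dict]:
    """Diseases linked to *disease* at the stated similarity level.

    Returns one record per qualifying neighbor, sorted by combined P-value
    ascending: ``{"disease", "p_combined", "overlap", "shared_genes"}`` with
    the shared causal genes spelled out (the bipartite disease/gene
    neighborhood view).
    """
    if disease not in table.diseases:
        raise KeyError(f"unknown disease: {disease!r}")
    sets = table.gene_sets()
    out = []
    for r in pairs:
        if disease not in (r.entity_a, r.entity_b):
            continue
        if r.overlap < min_overlap or r.p_combined > p_max:
            continue
        other = r.entity_b if r.entity_a == disease else r.entity_a
        out.append(
            {
                "disease": other,
                "p_combined": r.p_combined,
                "overlap": r.overlap,
                "shared_genes": sorted(sets[disease] & sets[other]),
            }
        )
    out.sort(key=lambda rec: (rec["p_combined"], rec["disease"]))
    return out


def vicinity_graph(
    disease: str,
    table: AssociationTable,
    neighbors: Sequence[Mapping],
) -> nx.Graph:
    """Bipartite disease/gene subnetwork of a vicinity.

    Nodes carry ``node_type`` in {"disease", "gene"}; the query disease and
    each neighbor are joined to their shared causal genes.
    """
    G = nx.Graph()
    G.add_node(disease, node_type="disease", query=True)
    for rec in neighbors:
        G.add_node(rec["disease"], node_type="disease", query=False)
        for g in rec["shared_genes"]:
            G.add_node(g, node_type="gene")
            G.add_edge(disease, g)
            G.add_edge(rec["disease"], g)
    return G


def export_graphml(
    G: nx.Graph, path, include_isolated: bool = False
) -> None:
    """GraphML export (yED-compatible attribute types).

    Isolated nodes are dropped by default — the map shows connected diseases.
    """
    H = G
    if not include_isolated:
        H = G.subgraph([n for n, d in G.degree if d > 0]).copy()
    H = H.copy()
    for _, data in H.nodes(data=True):
        for k, v in list(data.items()):
            if v is None:
                data[k] = ""
    nx.write_graphml(H, path)


def export_sif(G: nx.Graph, path, relation: str = "shares_genes") -> None:
    """Simple interaction format: ``diseaseA<TAB>relation<TAB>diseaseB``."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
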