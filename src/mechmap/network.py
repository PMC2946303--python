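"""Molecular interaction networks: random walk with restart and path clusters.

Two complementary network analyses support gene prioritization:

* **Random walk with restart (RWR).**  Given seed genes (known causal genes
  of a disease, optionally extended by predicted ones), iterate
  ``p <- (1-r) W p + r p0`` with the column-stochastic adjacency W and the
  uniform seed distribution p0 until the L1 change falls below tolerance.
  Stationary scores measure global proximity to the seed module; ranks are
  reported as ``N - r_order`` (N network size, r_order the 1-based position
  in descending score order) so that larger means better.
* **Shortest-path network clusters.**  Seed molecules are linked whenever a
  directed shortest path of at most ``max_steps`` reaction steps (default 3)
  connects them; all nodes on all tied shortest paths are kept, non-seed
  nodes labeled as connectors.  Clusters are the connected groups containing
  at least two seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

DEFAULT_RESTART = 0.75
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000


def load_network(path: str | Path, directed: bool = False) -> nx.Graph | nx.DiGraph:
    """Load an edge-list TSV (``gene_a<TAB>gene_b``) or SIF file.

    SIF rows have three columns (``a relation b``); TSV rows two.  A header
    line starting with ``gene_a`` is skipped.  Self-loops are dropped.
    """
    G: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] in ("gene_a", "gene", ""):
                continue
            if len(parts) >= 3 and not parts[1].replace(".", "").isdigit():
                a, b = parts[0], parts[2]  # SIF: a relation b
            elif len(parts) >= 2:
                a, b = parts[0], parts[1]
            else:
                continue
            if a != b:
                G.add_edge(a, b)
    return G


def _column_stochastic(G: nx.Graph, nodes: list[str]) -> np.ndarray:
    A = nx.to_numpy_array(G, nodelist=nodes, dtype=float)
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=0)
    # dangling nodes keep probability mass via a self-loop
    for i in np.nonzero(deg == 0)[0]:
        A[i, i] = 1.0
        deg[i] = 1.0
    return A / deg


@dataclass(frozen=True)
class RWRResult:
    scores: dict[str, float]
    restart: float
    iterations: int
    converged: bool
    ranks: dict[str, int]  # N - r_order, larger is better


def rwr(
    G: nx.Graph,
    seeds: Iterable[str],
    restart: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RWRResult:
    """Random walk with restart from a seed gene set.

    Scores sum to 1; ranks are ``N - r_order`` with descending-score order
    (ties broken by node name for determinism).
    """
    if not 0.0 < restart < 1.0:
        raise ValueError("restart must be in (0, 1)")
    nodes = sorted(G.nodes)
    seed_set = frozenset(seeds) & set(nodes)
    if not seed_set:
        raise ValueError("no seed gene is present in the network")
    W = _column_stochastic(G, nodes)
    p0 = np.zeros(len(nodes))
    for i, n in enumerate(nodes):
        if n in seed_set:
            p0[i] = 1.0 / len(seed_set)
    p = p0.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p_next = (1.0 - restart) * (W @ p) + restart * p0
        if float(np.abs(p_next - p).sum()) < tol:
            p = p_next
            converged = True
            break
        p = p_next
    scores = {n: float(s) for n, s in zip(nodes, p)}
    order = sorted(nodes, key=lambda n: (-scores[n], n))
    N = len(nodes)
    ranks = {n: N - (i + 1) for i, n in enumerate(order)}
    return RWRResult(scores=scores, restart=restart, iterations=it,
                     converged=converged, ranks=ranks)


def rwr_exact(
    G: nx.Graph, seeds: Iterable[str], restart: float = DEFAULT_RESTART
) -> dict[str, float]:
    """Direct linear solve of the RWR fixed point (small graphs).

    Solves ``(I - (1-r) W) p = r p0`` exactly; used to verify the iterative
    solver.
    """
    nodes = sorted(G.nodes)
    seed_set = frozenset(seeds) & set(nodes)
    if not seed_set:
        raise ValueError("no seed gene is present in the network")
    W = _column_stochastic(G, nodes)
    p0 = np.array([1.0 / len(seed_set) if n in seed_set else 0.0 for n in nodes])
    p = np.linalg.solve(np.eye(len(nodes)) - (1.0 - restart) * W, restart * p0)
    return {n: float(s) for n, s in zip(nodes, p)}


def rank_comparison(
    G: nx.Graph,
    base_seeds: Iterable[str],
    added_seeds: Iterable[str],
    test_gene: str,
    restart: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
) -> tuple[float, float, int]:
    """Score and rank shift of *test_gene* when *added_seeds* join the seeds.

    Returns ``(score_without, score_with, rank_difference)`` with
    ``rank_difference = rank_with - rank_without`` under the ``N - r_order``
    convention — positive means the added genes improved the test gene's
    network rank.
    """
    base = frozenset(base_seeds)
    added = frozenset(added_seeds)
    if test_gene not in G:
        raise ValueError(f"test gene {test_gene!r} not in network")
    if test_gene in base | added:
        raise ValueError("test gene must not be a seed")
    without = rwr(G, base, restart=restart, tol=tol)
    if not added:
        return without.scores[test_gene], without.scores[test_gene], 0
    with_ = rwr(G, base | added, restart=restart, tol=tol)
    return (
        without.scores[test_gene],
        with_.scores[test_gene],
        with_.ranks[test_gene] - without.ranks[test_gene],
    )


def network_clusters(
    G: nx.DiGraph,
    seeds: Iterable[str],
    max_steps: int = 3,
) -> list[nx.DiGraph]:
    """Shortest-path clusters of seed molecules in a directed reaction graph.

    For every ordered seed pair with a directed shortest path of at most
    *max_steps* reactions, all nodes and edges on all tied shortest paths
    are collected; clusters are the weakly connected components of that
    subgraph containing at least two seeds.  Nodes carry a ``role``
    attribute: ``seed`` or ``connector``.  Output is independent of seed
    enumeration order.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    seed_set = sorted(frozenset(seeds) & set(G.nodes))
    sub = nx.DiGraph()
    for s in seed_set:
        lengths = nx.single_source_shortest_path_length(G, s, cutoff=max_steps)
        for t in seed_set:
            if t == s or t not in lengths:
                continue
            for path in nx.all_shortest_paths(G, s, t):
                nx.add_path(sub, path)
    clusters = []
    for comp in nx.weakly_connected_components(sub):
        members = sub.subgraph(comp).copy()
        n_seeds = sum(1 for n in members if n in seed_set)
        if n_seeds < 2:
            continue
        for n in members.nodes:
            members.nodes[n]["role"] = "seed" if n in seed_set else "connector"
        clusters.append(members)
    clusters.sort(key=lambda c: (-c.number_of_nodes(), min(c.nodes)))
    return clusters


def rwr_to_tsv(result: RWRResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tscore\trank\n")
        for g in sorted(result.scores, key=lambda n: (-result.scores[n], n)):
            fh.write(f"{g}\t{result.scores[g]:.6g}\t{result.ranks[g]}\n")


def clusters_to_graphml(clusters: list[nx.DiGraph], path) -> None:
    """All clusters in one GraphML file, each tagged with a cluster id."""
    merged = nx.DiGraph()
    for cid, c in enumerate(clusters):
        for n, data in c.nodes(data=True):
            merged.add_node(n, cluster=cid, **data)
        merged.add_edges_from(c.edges)
    nx.write_graphml(merged, path)
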