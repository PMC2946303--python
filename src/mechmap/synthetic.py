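"""Synthetic disease/gene association data, GO annotations and networks.

Real curated disease/gene knowledgebases are proprietary, so every stage of
the pipeline is exercised against generated data that reproduces the
statistical structure the method assumes:

* a heavy-tailed gene degree distribution — most genes touch a handful of
  diseases while a few hubs (TNF-like) link to dozens — modelled as a
  discrete power law truncated at a maximum degree;
* optional *planted modules*: groups of diseases drawing their causal genes
  from a shared pool, which guarantees elevated pairwise gene overlap and
  gives planted-structure recovery tests closed hypergeometric oracles.

Defaults emulate a curated instance of 375 diseases and 3051 genes whose
degree law puts ~86% of genes at no more than five disease links, with the
hub truncated at 78 links.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .associations import AssociationTable


class ConfigError(ValueError):
    """Infeasible synthetic configuration."""


@dataclass(frozen=True)
class PlantedModule:
    """A group of diseases sharing causal genes drawn from a common pool.

    Each listed disease draws ``per_disease_draw`` genes uniformly without
    replacement from a dedicated pool of ``shared_gene_pool_size`` genes, so
    the overlap between two module diseases is hypergeometric with expected
    value ``per_disease_draw**2 / shared_gene_pool_size``.
    """

    name: str
    disease_ids: tuple[str, ...]
    shared_gene_pool_size: int
    per_disease_draw: int

    def __post_init__(self) -> None:
        if self.per_disease_draw > self.shared_gene_pool_size:
            raise ConfigError(
                f"module {self.name!r}: draw {self.per_disease_draw} exceeds "
                f"pool size {self.shared_gene_pool_size}"
            )
        if len(self.disease_ids) < 1:
            raise ConfigError(f"module {self.name!r}: no diseases")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration.

    ``power_law_exponent`` > 1 controls the gene-degree tail (larger means
    fewer hubs); ``max_degree`` truncates it.  ``background_edge_rate`` adds
    independent uniform disease/gene edges on top of the degree-law
    attachment (default 0: the degree law alone sets the density).
    """

    n_diseases: int = 375
    n_genes: int = 3051
    power_law_exponent: float = 1.85
    max_degree: int = 78
    planted_modules: tuple[PlantedModule, ...] = ()
    background_edge_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diseases < 1 or self.n_genes < 1:
            raise ConfigError("need at least one disease and one gene")
        if self.power_law_exponent <= 1:
            raise ConfigError("power_law_exponent must be > 1")
        if not 1 <= self.max_degree <= self.n_diseases:
            raise ConfigError("need 1 <= max_degree <= n_diseases")
        if not 0.0 <= self.background_edge_rate <= 1.0:
            raise ConfigError("background_edge_rate must be in [0, 1]")


def truncated_power_law_pmf(exponent: float, max_degree: int) -> np.ndarray:
    """pmf over degrees 1..max_degree with P(d) proportional to d**-exponent."""
    d = np.arange(1, max_degree + 1, dtype=float)
    w = d ** (-exponent)
    return w / w.sum()


def generate_associations(config: SyntheticConfig) -> AssociationTable:
    """Generate a causal association table under *config*.

    Background genes are assigned target degrees from the truncated power
    law, then attached to uniformly chosen diseases without replacement.
    Planted modules add dedicated pool genes shared among their diseases.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    diseases = [f"D{i:04d}" for i in range(config.n_diseases)]
    genes = [f"G{i:04d}" for i in range(config.n_genes)]

    pmf = truncated_power_law_pmf(config.power_law_exponent, config.max_degree)
    degrees = rng.choice(np.arange(1, config.max_degree + 1), size=config.n_genes, p=pmf)

    edges: dict[tuple[str, str], str] = {}
    for g, k in zip(genes, degrees):
        for di in rng.choice(config.n_diseases, size=int(k), replace=False):
            edges[(diseases[di], g)] = "causal"

    if config.background_edge_rate > 0:
        mask = rng.random((config.n_diseases, config.n_genes)) < config.background_edge_rate
        for di, gi in zip(*np.nonzero(mask)):
            edges[(diseases[di], genes[gi])] = "causal"

    groups: dict[str, frozenset[str]] = {}
    for module in config.planted_modules:
        pool = [f"{module.name}_P{i:03d}" for i in range(module.shared_gene_pool_size)]
        for d in module.disease_ids:
            picked = rng.choice(
                module.shared_gene_pool_size, size=module.per_disease_draw, replace=False
            )
            for gi in picked:
                edges[(d, pool[gi])] = "causal"
        groups[module.name] = frozenset(pool)

    return AssociationTable(edges=edges, gene_groups=groups)


def generate_go_annotation(
    table: AssociationTable,
    n_terms: int,
    cluster_term_bias: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    background_rate: float = 0.05,
    gene_groups: Mapping[str, frozenset[str]] | None = None,
) -> dict[str, frozenset[str]]:
    """Annotate the table's genes with synthetic GO-like terms.

    Terms are named ``T000``..; every gene carries each term independently at
    ``background_rate``.  ``cluster_term_bias`` maps a gene-group name (by
    default the table's planted modules) to per-term odds ratios: genes of
    that group carry the biased term with probability

        p = OR * p0 / (1 - p0 + OR * p0)

    so an odds ratio of 1 reduces exactly to the background (null
    calibration), and large ratios plant detectable enrichment.
    """
    if n_terms < 1:
        raise ConfigError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    groups = dict(gene_groups if gene_groups is not None else table.gene_groups)
    bias = cluster_term_bias or {}
    terms = [f"T{i:03d}" for i in range(n_terms)]
    genes = sorted(table.genes)

    gene_to_group: dict[str, str] = {}
    for name, members in groups.items():
        for g in members:
            gene_to_group[g] = name

    p0 = background_rate
    annotation: dict[str, frozenset[str]] = {}
    for g in genes:
        probs = np.full(n_terms, p0)
        grp = gene_to_group.get(g)
        if grp is not None and grp in bias:
            for ti, term in enumerate(terms):
                odds = bias[grp].get(term)
                if odds is not None:
                    probs[ti] = odds * p0 / (1 - p0 + odds * p0)
        hit = rng.random(n_terms) < probs
        annotation[g] = frozenset(t for t, h in zip(terms, hit) if h)
    return annotation


def generate_network(
    genes: Sequence[str] | frozenset[str],
    edge_density: float,
    planted_neighbors: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Erdos-Renyi style undirected edge list with guaranteed planted edges.

    Each unordered gene pair is an edge with probability ``edge_density``;
    every pair listed in ``planted_neighbors`` is then forced present.
    """
    if not 0.0 <= edge_density <= 1.0:
        raise ConfigError("edge_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = sorted(genes)
    n = len(nodes)
    edges: set[tuple[str, str]] = set()
    if edge_density > 0 and n > 1:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < edge_density
        edges.update((nodes[i], nodes[j]) for i, j in zip(iu[mask], ju[mask]))
    for a, neighbors in (planted_neighbors or {}).items():
        for b in neighbors:
            if a == b:
                continue
            edges.add((min(a, b), max(a, b)))
    return sorted(edges)


def write_gene_term_map(annotation: Mapping[str, frozenset[str]], path) -> None:
    """Two-column TSV ``gene_symbol<TAB>term_id``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_symbol\tterm_id\n")
        for g in sorted(annotation):
            for t in sorted(annotation[g]):
                fh.write(f"{g}\t{t}\n")


def write_edge_list(edges: Sequence[tuple[str, str]], path) -> None:
    """Edge-list TSV ``gene_a<TAB>gene_b``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
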