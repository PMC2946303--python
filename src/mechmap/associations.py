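"""Disease/gene association tables.

The association table is the universe every statistic in this package is
computed against: a bipartite graph between disease identifiers and gene
symbols, with each edge carrying an evidence type (``causal``,
``preventative``, ``correlative`` or ``negative``).  Analyses of shared
molecular mechanisms keep only the causal and preventative types, since only
those support that a gene product's deranged activity entails the disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

ASSOCIATION_TYPES = frozenset({"causal", "preventative", "correlative", "negative"})
#: evidence types retained for mechanistic analyses
CAUSAL_TYPES = frozenset({"causal", "preventative"})

HEADER = ("disease_id", "disease_name", "gene_symbol", "association_type")


class AssociationError(ValueError):
    """Malformed or inconsistent association input."""


@dataclass(frozen=True)
class AssociationTable:
    """Bipartite disease <-> gene association table.

    Parameters
    ----------
    edges
        Mapping ``(disease_id, gene_symbol) -> association_type``; one entry
        per distinct pair (duplicates are collapsed upstream).
    disease_names
        Optional human-readable names per disease id.
    gene_groups
        Optional named gene groups (e.g. planted synthetic modules); carried
        as metadata, never used by the statistics.
    """

    edges: Mapping[tuple[str, str], str]
    disease_names: Mapping[str, str] = field(default_factory=dict)
    gene_groups: Mapping[str, frozenset[str]] = field(default_factory=dict)

    # -- derived views -------------------------------------------------
    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.edges)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def disease_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for d, _ in self.edges:
            deg[d] = deg.get(d, 0) + 1
        return deg

    @property
    def gene_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for _, g in self.edges:
            deg[g] = deg.get(g, 0) + 1
        return deg

    def gene_set(self, disease: str) -> frozenset[str]:
        """Causal gene set of one disease."""
        if disease not in self.diseases:
            raise KeyError(f"unknown disease: {disease!r}")
        return frozenset(g for d, g in self.edges if d == disease)

    def disease_set(self, gene: str) -> frozenset[str]:
        """Set of diseases a gene is associated with."""
        if gene not in self.genes:
            raise KeyError(f"unknown gene: {gene!r}")
        return frozenset(d for d, g in self.edges if g == gene)

    def gene_sets(self) -> dict[str, frozenset[str]]:
        """All per-disease gene sets in one pass."""
        out: dict[str, set[str]] = {}
        for d, g in self.edges:
            out.setdefault(d, set()).add(g)
        return {d: frozenset(s) for d, s in out.items()}

    def disease_sets(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for d, g in self.edges:
            out.setdefault(g, set()).add(d)
        return {g: frozenset(s) for g, s in out.items()}

    def transpose(self) -> "AssociationTable":
        """Swap the disease and gene roles.

        Every operation in the statistical core is role-symmetric; gene-gene
        similarity models are fitted by running the disease-side machinery on
        the transposed table.
        """
        return AssociationTable(
            edges={(g, d): t for (d, g), t in self.edges.items()},
        )

    def validate(self) -> None:
        for (d, g), t in self.edges.items():
            if t not in ASSOCIATION_TYPES:
                raise AssociationError(f"unknown association type {t!r} on ({d}, {g})")
        # degree maps are recomputed properties, so their consistency with the
        # edge set holds by construction; check the cross-sum identity anyway
        assert sum(self.disease_degree.values()) == self.n_edges
        assert sum(self.gene_degree.values()) == self.n_edges

    def __len__(self) -> int:
        return len(self.edges)


def _collapse_type(old: str, new: str) -> str:
    # presence/absence statistics: a pair seen as causal anywhere stays causal
    return "causal" if "causal" in (old, new) else old


def from_records(
    records: Iterable[tuple[str, str, str]],
    keep_types: Iterable[str] = CAUSAL_TYPES,
    disease_names: Mapping[str, str] | None = None,
) -> AssociationTable:
    """Build a table from ``(disease, gene, type)`` triples.

    Rows whose type is not in *keep_types* are dropped; duplicate
    ``(disease, gene)`` pairs collapse to a single edge.
    """
    keep = frozenset(keep_types)
    unknown = keep - ASSOCIATION_TYPES
    if unknown:
        raise AssociationError(f"unknown keep_types: {sorted(unknown)}")
    edges: dict[tuple[str, str], str] = {}
    for d, g, t in records:
        if t not in ASSOCIATION_TYPES:
            raise AssociationError(f"unknown association type {t!r} on ({d}, {g})")
        if t not in keep:
            continue
        key = (d, g)
        edges[key] = _collapse_type(edges[key], t) if key in edges else t
    return AssociationTable(edges=edges, disease_names=dict(disease_names or {}))


def load_associations(
    path: str | Path,
    keep_types: Iterable[str] = CAUSAL_TYPES,
) -> AssociationTable:
    """Load a TSV association table.

    The dialect is UTF-8 TSV with header
    ``disease_id<TAB>disease_name<TAB>gene_symbol<TAB>association_type``;
    ``disease_name`` may be empty.  A three-column variant without the name
    column is also accepted.

    Raises
    ------
    AssociationError
        On a malformed row (with its line number) or an unknown type label.
    """
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    names: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        four_col = len(header) >= 4
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if four_col and len(parts) >= 4:
                d, name, g, t = parts[0], parts[1], parts[2], parts[3]
            elif not four_col and len(parts) >= 3:
                d, name, g, t = parts[0], "", parts[1], parts[2]
            else:
                raise AssociationError(
                    f"{path}:{lineno}: expected {'4' if four_col else '3'} "
                    f"tab-separated columns, got {len(parts)}"
                )
            if t not in ASSOCIATION_TYPES:
                raise AssociationError(
                    f"{path}:{lineno}: unknown association type {t!r}"
                )
            if name:
                names[d] = name
            records.append((d, g, t))
    return from_records(records, keep_types=keep_types, disease_names=names)


def write_associations(table: AssociationTable, path: str | Path) -> None:
    """Write the TSV dialect that :func:`load_associations` reads."""
    rows = [
        (d, table.disease_names.get(d, ""), g, t)
        for (d, g), t in sorted(table.edges.items())
    ]
    df = pd.DataFrame(rows, columns=list(HEADER))
    df.to_csv(path, sep="\t", index=False)


def filter_min_degree(
    table: AssociationTable, side: str, min_degree: int
) -> AssociationTable:
    """Drop entities on *side* with fewer than *min_degree* partners.

    A single pass: entities on the requested side below the threshold are
    removed with their edges, then opposite-side entities left with zero
    edges disappear implicitly.  The thresholds are not iterated to a joint
    fixpoint — disease-side and gene-side universes are built independently
    (e.g. diseases with >= 5 causal genes for disease comparison; genes with
    >= 5 disease links for gene comparison).
    """
    if side not in ("disease", "gene"):
        raise ValueError(f"side must be 'disease' or 'gene', got {side!r}")
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    deg = table.disease_degree if side == "disease" else table.gene_degree
    keep = {e for e, k in deg.items() if k >= min_degree}
    idx = 0 if side == "disease" else 1
    edges = {pair: t for pair, t in table.edges.items() if pair[idx] in keep}
    kept_diseases = {d for d, _ in edges}
    return AssociationTable(
        edges=edges,
        disease_names={
            d: n for d, n in table.disease_names.items() if d in kept_diseases
        },
        gene_groups=table.gene_groups,
    )
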