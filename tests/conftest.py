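"""Shared fixtures: small hand tables and planted synthetic scenarios."""

from __future__ import annotations

import pytest

from mechmap.associations import AssociationTable, from_records, filter_min_degree
from mechmap.synthetic import PlantedModule, SyntheticConfig, generate_associations


@pytest.fixture
def tiny_table() -> AssociationTable:
    """Two diseases sharing two of their genes."""
    return from_records(
        [
            ("d1", "g1", "causal"),
            ("d1", "g2", "causal"),
            ("d1", "g3", "causal"),
            ("d2", "g2", "causal"),
            ("d2", "g3", "causal"),
            ("d2", "g4", "preventative"),
        ]
    )


def module_config(seed: int, n_modules: int = 2, module_size: int = 3,
                  pool: int = 20, draw: int = 10) -> SyntheticConfig:
    """Background table plus disjoint planted modules on dedicated diseases."""
    names = "AB"[:n_modules]
    modules = tuple(
        PlantedModule(
            name=f"M{m}",
            disease_ids=tuple(f"M{m}_D{i}" for i in range(module_size)),
            shared_gene_pool_size=pool,
            per_disease_draw=draw,
        )
        for m in names
    )
    return SyntheticConfig(
        n_diseases=100, n_genes=500, max_degree=50, seed=seed,
        planted_modules=modules,
    )


def nullconfig(seed: int) -> SyntheticConfig:
    """Module-free background table for null calibration."""
    return SyntheticConfig(n_diseases=100, n_genes=500, max_degree=50, seed=seed)


@pytest.fixture
def planted_table() -> AssociationTable:
    return generate_associations(module_config(seed=0))


@pytest.fixture
def filtered_planted(planted_table) -> AssociationTable:
    return filter_min_degree(planted_table, "disease", 5)
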