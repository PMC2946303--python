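"""Generate a synthetic disease/gene association table and inspect its shape.

The generator emulates a curated causal-association knowledgebase: 375
diseases, ~3000 genes, a heavy-tailed gene degree law (most genes touch at
most 5 diseases, a hub touches ~78) and, optionally, planted disease modules
sharing causal genes.
"""

from mechmap import SyntheticConfig, PlantedModule, generate_associations

config = SyntheticConfig(
    seed=1,
    planted_modules=(
        PlantedModule(
            name="MET",
            disease_ids=("MET_D0", "MET_D1", "MET_D2"),
            shared_gene_pool_size=20,
            per_disease_draw=10,
        ),
    ),
)
table = generate_associations(config)

deg = table.gene_degree
frac5 = sum(1 for v in deg.values() if v <= 5) / len(deg)
hub = max(deg, key=deg.get)

print(f"diseases:      {len(table.diseases)}")
print(f"genes:         {len(table.genes)}")
print(f"associations:  {table.n_edges}")
print(f"genes with <= 5 disease links: {100 * frac5:.1f}%")
print(f"strongest hub: {hub} with {deg[hub]} links")
print(f"module MET_D0 gene set size:   {len(table.gene_set('MET_D0'))}")

# The ~86% figure is the calibrated degree-law shape: overlap statistics must
# not treat a hub gene like a rarely annotated one, which is exactly what the
# frequency-preserving null model downstream accounts for.
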