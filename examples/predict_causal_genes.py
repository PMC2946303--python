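"""Two-step causal gene prediction with leave-5-out cross-validation.

A gene is deliberately removed from one module disease; step 1 finds the
sibling diseases, step 2 finds genes of those siblings that share enough
diseases with the query's remaining known genes — re-discovering the
removed gene.  Cross-validation repeats this over 20 random removals and
reports the recovery rate.
"""

from mechmap import (
    AssociationTable,
    EntityModels,
    PlantedModule,
    SyntheticConfig,
    Thresholds,
    cross_validate,
    filter_min_degree,
    gene_side_table,
    generate_associations,
    predict_genes,
)

module = PlantedModule("M", tuple(f"M_D{i}" for i in range(10)), 20, 12)
config = SyntheticConfig(
    n_diseases=80, n_genes=400, max_degree=40, seed=3,
    planted_modules=(module,),
)
table = generate_associations(config)

# remove one well-supported module gene from disease M_D0
degree = table.gene_degree
target = sorted(
    g for g in table.gene_set("M_D0") if g.startswith("M_P") and degree[g] >= 6
)[0]
perturbed = AssociationTable(
    edges={p: t for p, t in table.edges.items() if p != ("M_D0", target)},
    gene_groups=table.gene_groups,
)

disease_table = filter_min_degree(perturbed, "disease", 5)
gene_table = gene_side_table(perturbed, 5)
disease_models = EntityModels(disease_table, 20_000, seed=4)
gene_models = EntityModels(gene_table, 20_000, seed=5)

report = predict_genes(
    "M_D0", disease_table, gene_table, disease_models, gene_models,
    Thresholds(),  # P <= 0.01 and overlap >= 2 on both steps
)
print(f"removed gene:      {target}")
print(f"similar diseases:  {[d for d, _, _ in report.similar_diseases]}")
print(f"predicted genes:   {sorted(report.predicted_genes)}")
print(f"removed gene re-predicted: {target in report.predicted_genes}")

cv = cross_validate(
    "M_D0", table, Thresholds(), n_rounds=20, n_remove=5,
    n_sets_cv=20_000, seed=6,
)
print(f"cross-validation mean recovery over 20 rounds: {cv.mean_recovery:.2f}")

# Recovery well above 0.5 reflects the module's redundant support: each
# removed gene is still anchored by the remaining shared genes.
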