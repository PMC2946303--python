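"""Two-step causal gene prediction, threshold sweeps, and cross-validation.

Prediction for a query disease proceeds in two steps sharing one statistical
machinery:

* **Step 1 — similar diseases.**  All diseases passing the disease-similarity
  threshold (combined P-value and minimum shared-gene count) against the
  query are collected; their causal genes are the candidate pool.
* **Step 2 — gene similarity.**  Each candidate (restricted to the
  gene-comparison universe: genes with enough disease links, default 5) is
  compared against each known causal gene of the query using the transposed
  overlap statistic — the number of *diseases* two genes share.  Candidates
  passing the gene-similarity threshold with at least one known gene are
  predicted; the query's own known genes are never emitted.

Default thresholds are P <= 0.01 and overlap >= 2 on both steps.

Evaluation utilities sweep the (shared) P-value cut-off against a truth set
to produce ROC-style curves, and leave-k-out cross-validation removes known
genes, re-estimates both model axes on the perturbed table, and measures how
often the removed genes are re-predicted (the recovery rate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .associations import AssociationTable, filter_min_degree
from .overlap import EntityModels, OverlapModel, pair_pvalue

#: genes need at least this many disease links to enter gene-gene comparison
MIN_GENE_DISEASES = 5
#: diseases need at least this many causal genes to enter disease comparison
MIN_DISEASE_GENES = 5


@dataclass(frozen=True)
class Thresholds:
    """The four cut-offs of the two-step procedure."""

    p_disease: float = 0.01
    p_gene: float = 0.01
    min_overlap_disease: int = 2
    min_overlap_gene: int = 2


@dataclass(frozen=True)
class Candidate:
    """A predicted gene and the evidence that selected it."""

    gene: str
    anchors: tuple[tuple[str, float, int], ...]  # (known gene, p, shared diseases)
    best_p: float
    borderline: bool  # best anchor P within 10% of the gene cut-off


@dataclass(frozen=True)
class PredictionReport:
    disease: str
    thresholds: Thresholds
    similar_diseases: tuple[tuple[str, float, int], ...]  # (disease, p, overlap)
    candidates: tuple[Candidate, ...]
    excluded_known: tuple[str, ...]

    @property
    def predicted_genes(self) -> frozenset[str]:
        return frozenset(c.gene for c in self.candidates)


def gene_side_table(
    table: AssociationTable, min_gene_diseases: int = MIN_GENE_DISEASES
) -> AssociationTable:
    """Transposed gene-comparison universe: genes with enough disease links.

    Diseases incident to those genes are all retained, whatever their own
    gene count — the gene-side universe is built independently of the
    disease-side one.
    """
    return filter_min_degree(table, "gene", min_gene_diseases).transpose()


def predict_genes(
    disease: str,
    disease_table: AssociationTable,
    gene_table: AssociationTable,
    disease_models: Mapping[str, OverlapModel] | EntityModels,
    gene_models: Mapping[str, OverlapModel] | EntityModels,
    thresholds: Thresholds = Thresholds(),
) -> PredictionReport:
    """Run the two-step prediction for one query disease.

    ``disease_table`` is the disease-comparison universe, ``gene_table`` the
    transposed gene-comparison universe (see :func:`gene_side_table`); both
    model sets must have been fitted on the corresponding table.
    """
    dsets = disease_table.gene_sets()
    if disease not in dsets:
        raise KeyError(f"unknown disease: {disease!r}")
    known = dsets[disease]

    # step 1: similar diseases
    similar: list[tuple[str, float, int]] = []
    for other, oset in dsets.items():
        if other == disease:
            continue
        x = len(known & oset)
        if x < thresholds.min_overlap_disease:
            continue
        res = pair_pvalue(
            disease, other, disease_models[disease], disease_models[other],
            known, oset,
        )
        if res.p_combined <= thresholds.p_disease:
            similar.append((other, res.p_combined, res.overlap))
    similar.sort(key=lambda t: (t[1], t[0]))

    # step 2: gene similarity against the query's known genes
    gsets = gene_table.gene_sets()  # gene -> set of diseases
    anchors = sorted(g for g in known if g in gsets)
    pool: set[str] = set()
    for other, _, _ in similar:
        pool.update(dsets[other])
    excluded = tuple(sorted(pool & known))
    candidates: list[Candidate] = []
    for gene in sorted(pool - known):
        if gene not in gsets:
            continue  # below the gene-universe degree threshold
        support: list[tuple[str, float, int]] = []
        for anchor in anchors:
            x = len(gsets[gene] & gsets[anchor])
            if x < thresholds.min_overlap_gene:
                continue
            res = pair_pvalue(
                gene, anchor, gene_models[gene], gene_models[anchor],
                gsets[gene], gsets[anchor],
            )
            if res.p_combined <= thresholds.p_gene:
                support.append((anchor, res.p_combined, res.overlap))
        if support:
            support.sort(key=lambda t: (t[1], t[0]))
            best_p = support[0][1]
            candidates.append(
                Candidate(
                    gene=gene,
                    anchors=tuple(support),
                    best_p=best_p,
                    borderline=best_p > 0.9 * thresholds.p_gene,
                )
            )
    candidates.sort(key=lambda c: (c.best_p, c.gene))
    return PredictionReport(
        disease=disease,
        thresholds=thresholds,
        similar_diseases=tuple(similar),
        candidates=tuple(candidates),
        excluded_known=excluded,
    )


# ---------------------------------------------------------------------------
# threshold sweep / ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepPoint:
    p_threshold: float
    n_predicted: int
    tp: int
    fp: int
    tpr: float
    fpr: float
    fp_proportion: float


def threshold_sweep(
    disease: str,
    truth_set: Iterable[str],
    p_grid: Sequence[float],
    disease_table: AssociationTable,
    gene_table: AssociationTable,
    disease_models: Mapping[str, OverlapModel] | EntityModels,
    gene_models: Mapping[str, OverlapModel] | EntityModels,
    min_overlap: int = 2,
) -> list[SweepPoint]:
    """TPR/FPR/false-positive-proportion across a grid of P cut-offs.

    The same P cut-off is applied to disease similarity and gene similarity
    at each grid point; the overlap minimum stays fixed.  The false positive
    universe is the gene-comparison universe minus the query's known genes
    and the truth set.
    """
    truth = frozenset(truth_set)
    if not truth:
        raise ValueError("truth_set is empty")
    if len(p_grid) == 0:
        raise ValueError("empty threshold grid")
    known = disease_table.gene_set(disease)
    universe = frozenset(gene_table.diseases)  # gene-side entities are genes
    fp_universe = universe - known - truth
    out = []
    for p in p_grid:
        report = predict_genes(
            disease, disease_table, gene_table, disease_models, gene_models,
            Thresholds(
                p_disease=p, p_gene=p,
                min_overlap_disease=min_overlap, min_overlap_gene=min_overlap,
            ),
        )
        pred = report.predicted_genes
        tp = len(pred & truth)
        fp = len(pred - truth)
        out.append(
            SweepPoint(
                p_threshold=float(p),
                n_predicted=len(pred),
                tp=tp,
                fp=fp,
                tpr=tp / len(truth),
                fpr=fp / len(fp_universe) if fp_universe else 0.0,
                fp_proportion=fp / len(pred) if pred else 0.0,
            )
        )
    return out


def best_precision_threshold(points: Sequence[SweepPoint]) -> SweepPoint:
    """The cut-off maximizing precision among points with >= 1 false positive.

    Precision is tp / (tp + fp); ties resolve to the smaller threshold.
    """
    eligible = [p for p in points if p.fp >= 1]
    if not eligible:
        raise ValueError("no sweep point produced a false positive")
    return max(eligible, key=lambda p: (p.tp / (p.tp + p.fp), -p.p_threshold))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVReport:
    disease: str
    rounds: int
    removed_per_round: int
    baseline_predictions: frozenset[str]
    removed: tuple[frozenset[str], ...]          # per round
    predicted: tuple[frozenset[str], ...]        # per round
    gene_frequency: dict[str, float]             # fraction of rounds predicted
    per_round_recovery: tuple[float, ...]
    classification: dict[str, str]               # original-prediction | removed-known | new

    @property
    def mean_recovery(self) -> float:
        return float(np.mean(self.per_round_recovery)) if self.rounds else 0.0


def cross_validate(
    disease: str,
    table: AssociationTable,
    thresholds: Thresholds = Thresholds(),
    n_rounds: int = 20,
    n_remove: int = 5,
    n_sets_cv: int = 100_000,
    seed: int = 0,
    min_disease_genes: int = MIN_DISEASE_GENES,
    min_gene_diseases: int = MIN_GENE_DISEASES,
) -> CVReport:
    """Leave-*n_remove*-out cross-validation of gene prediction.

    Each round removes ``n_remove`` uniformly chosen causal genes of the
    query disease from the raw table, rebuilds both comparison universes,
    re-estimates both model axes from ``n_sets_cv`` fresh random sets on the
    perturbed data, and reruns the prediction.  Recovery is the fraction of
    removed genes re-predicted in the round.  Each predicted gene is
    classified as ``original-prediction`` (also predicted on the unperturbed
    table), ``removed-known`` (a deliberately removed known gene), or
    ``new``.

    With ``n_remove = 0`` the table is unchanged and the baseline models are
    reused, so every round reproduces the baseline prediction set.
    """
    known = sorted(table.gene_set(disease))
    if n_remove >= len(known):
        raise ValueError(
            f"n_remove={n_remove} must be smaller than the causal set "
            f"({len(known)} genes)"
        )
    rng = np.random.default_rng(seed)

    def build(tab: AssociationTable, sd: int, sg: int):
        dt = filter_min_degree(tab, "disease", min_disease_genes)
        gt = gene_side_table(tab, min_gene_diseases)
        dm = EntityModels(dt, n_sets_cv, seed=sd)
        gm = EntityModels(gt, n_sets_cv, seed=sg)
        return dt, gt, dm, gm

    base_sd, base_sg = (int(s) for s in rng.integers(2**31, size=2))
    base = build(table, base_sd, base_sg)
    baseline = predict_genes(disease, *base, thresholds).predicted_genes

    removed_rounds: list[frozenset[str]] = []
    predicted_rounds: list[frozenset[str]] = []
    recovery: list[float] = []
    for _ in range(n_rounds):
        if n_remove == 0:
            removed_rounds.append(frozenset())
            predicted_rounds.append(baseline)
            recovery.append(0.0)
            continue
        removed = frozenset(rng.choice(known, size=n_remove, replace=False))
        sd, sg = (int(s) for s in rng.integers(2**31, size=2))
        modified = AssociationTable(
            edges={
                pair: t for pair, t in table.edges.items()
                if not (pair[0] == disease and pair[1] in removed)
            },
            disease_names=table.disease_names,
            gene_groups=table.gene_groups,
        )
        dt, gt, dm, gm = build(modified, sd, sg)
        if disease in dt.diseases:
            pred = predict_genes(disease, dt, gt, dm, gm, thresholds).predicted_genes
        else:  # query fell below the disease-side degree threshold
            pred = frozenset()
        removed_rounds.append(removed)
        predicted_rounds.append(pred)
        recovery.append(len(pred & removed) / n_remove)

    all_pred = sorted(set().union(*predicted_rounds)) if predicted_rounds else []
    freq = {
        g: sum(g in p for p in predicted_rounds) / max(n_rounds, 1)
        for g in all_pred
    }
    ever_removed = set().union(*removed_rounds) if removed_rounds else set()
    classification = {
        g: (
            "removed-known" if g in ever_removed
            else "original-prediction" if g in baseline
            else "new"
        )
        for g in all_pred
    }
    return CVReport(
        disease=disease,
        rounds=n_rounds,
        removed_per_round=n_remove,
        baseline_predictions=baseline,
        removed=tuple(removed_rounds),
        predicted=tuple(predicted_rounds),
        gene_frequency=freq,
        per_round_recovery=tuple(recovery),
        classification=classification,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def report_to_json(report: PredictionReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(report), fh, indent=1, default=list)


def report_to_tsv(report: PredictionReport, path) -> None:
    """Flat TSV: one candidate/anchor pair per row."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tanchor\tp_combined\tshared_diseases\tborderline\n")
        for c in report.candidates:
            for anchor, p, x in c.anchors:
                fh.write(f"{c.gene}\t{anchor}\t{p:.6g}\t{x}\t{int(c.borderline)}\n")


def sweep_to_tsv(points: Sequence[SweepPoint], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("p_threshold\tn_predicted\ttp\tfp\ttpr\tfpr\tfp_proportion\n")
        for p in points:
            fh.write(
                f"{p.p_threshold:.6g}\t{p.n_predicted}\t{p.tp}\t{p.fp}\t"
                f"{p.tpr:.6g}\t{p.fpr:.6g}\t{p.fp_proportion:.6g}\n"
            )


def cv_to_json(report: CVReport, path) -> None:
    payload = {
        "disease": report.disease,
        "rounds": report.rounds,
        "removed_per_round": report.removed_per_round,
        "baseline_predictions": sorted(report.baseline_predictions),
        "removed": [sorted(r) for r in report.removed],
        "predicted": [sorted(p) for p in report.predicted],
        "gene_frequency": report.gene_frequency,
        "per_round_recovery": list(report.per_round_recovery),
        "mean_recovery": report.mean_recovery,
        "classification": report.classification,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
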