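"""Degree-preserving overlap statistics for entity pairs.

This is the statistical core of the package.  Shared-gene counts between two
diseases cannot be judged with a Fisher test, because that test gives every
gene the same sampling probability while real association data are heavily
skewed: a hub gene linked to a fifth of all diseases inflates overlaps far
more than a gene with a single link.  Instead the null model preserves each
gene's association frequency:

1.  Random gene sets are sampled so that gene *g* enters a set independently
    with probability ``gene_degree(g) / n_diseases`` (equivalently: one
    disease is drawn uniformly per gene, and the gene is kept if that
    disease carries it).
2.  For a focal gene set *A*, the mean overlap with random sets of size *X*
    is recorded as weighted regression data (X, Y, W) and fitted with a
    weighted least-squares model

        lambda(n) = c*b0 + sum_{k=1..k_max} b_k * n**(1/k)

    over all eight (c in {0,1}, k_max in {1..4}) combinations; the
    lowest-AIC model that is non-decreasing and strictly positive over the
    observed range of set sizes is selected.
3.  The overlap x between two entities is scored with two Poisson tail
    P-values — each entity's model evaluated at the other's set size — and
    combined by their geometric mean.

The machinery is role-symmetric: gene-gene similarity (number of shared
diseases) is computed by applying the identical procedure to the transposed
association table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special, sparse

from .associations import AssociationTable

#: lower floor for predicted Poisson rates, keeps tails defined
LAMBDA_FLOOR = 1e-9

#: default number of random sets for disease-side models
N_SETS_DISEASE = 200_000
#: default number of random sets for gene-side models and CV re-estimation
N_SETS_GENE = 100_000


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class RandomSetCollection:
    """A collection of frequency-preserving random gene sets.

    Stored as a sparse boolean membership matrix (sets x genes) so overlap
    curves against hundreds of focal sets reduce to one sparse product.
    """

    def __init__(self, matrix: sparse.csr_matrix, genes: Sequence[str]):
        self.matrix = matrix
        self.genes = list(genes)
        self.gene_index = {g: i for i, g in enumerate(self.genes)}
        self.sizes = np.asarray(matrix.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_sets(self) -> int:
        return self.matrix.shape[0]

    def inclusion_frequency(self, gene: str) -> float:
        """Fraction of sets containing *gene* (0.0 for unknown genes)."""
        i = self.gene_index.get(gene)
        if i is None:
            return 0.0
        return self.matrix[:, i].sum() / self.n_sets

    def overlap_counts(self, gene_set: Iterable[str]) -> np.ndarray:
        """|A intersect R| for every random set R, as an int array."""
        idx = [self.gene_index[g] for g in gene_set if g in self.gene_index]
        if not idx:
            return np.zeros(self.n_sets, dtype=np.int64)
        ind = np.zeros(len(self.genes), dtype=np.int64)
        ind[idx] = 1
        return np.asarray(self.matrix @ ind).ravel()

    def as_sets(self) -> list[frozenset[str]]:
        """Materialize as python sets (small collections / tests only)."""
        out = []
        m = self.matrix.tocsr()
        for i in range(self.n_sets):
            cols = m.indices[m.indptr[i]: m.indptr[i + 1]]
            out.append(frozenset(self.genes[c] for c in cols))
        return out


def sample_random_sets(
    table: AssociationTable,
    n_sets: int,
    seed: int = 0,
    chunk_size: int = 4096,
) -> RandomSetCollection:
    """Sample *n_sets* random gene sets preserving gene frequencies.

    For each set and each gene, a disease is drawn uniformly from all
    diseases of the table and the gene is included if the drawn disease is
    associated with it, i.e. gene g is a member independently with
    probability ``gene_degree(g) / n_diseases``.  Draws are made row-major
    over (set, gene), so results are reproducible for a given seed
    regardless of chunking.

    Applies unchanged to the transposed table for random *disease* sets.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not table.edges:
        raise ValueError("cannot sample from an empty table")
    genes = sorted(table.genes)
    deg = table.gene_degree
    n_dis = len(table.diseases)
    probs = np.array([deg[g] / n_dis for g in genes])

    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for start in range(0, n_sets, chunk_size):
        m = min(chunk_size, n_sets - start)
        hits = rng.random((m, len(genes))) < probs
        r, c = np.nonzero(hits)
        rows.append(r + start)
        cols.append(c)
    data = np.ones(sum(len(r) for r in rows), dtype=np.int8)
    matrix = sparse.csr_matrix(
        (data, (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_sets, len(genes)),
    )
    return RandomSetCollection(matrix, genes)


# ---------------------------------------------------------------------------
# regression data
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class RegressionPoint:
    """One weighted regression observation.

    X is a random-set size, Y the mean overlap of the focal set with random
    sets of that size, W the number of such sets.
    """

    X: int
    Y: float
    W: int

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ValueError("W must be >= 1")
        if self.Y < 0:
            raise ValueError("Y must be >= 0")


def aggregate_overlap_curve(
    gene_set: Iterable[str],
    random_sets: RandomSetCollection | Iterable[frozenset[str]],
) -> list[RegressionPoint]:
    """Aggregate overlaps of *gene_set* with random sets into (X, Y, W) points.

    One point per distinct random-set size; Y is the arithmetic mean overlap
    over sets of that size and W the number of contributing sets, so the W
    sum over all points equals the number of random sets.
    """
    A = frozenset(gene_set)
    if not A:
        raise ValueError("focal gene set is empty")
    if isinstance(random_sets, RandomSetCollection):
        sizes = random_sets.sizes
        overlaps = random_sets.overlap_counts(A)
    else:
        sets = list(random_sets)
        sizes = np.array([len(r) for r in sets], dtype=np.int64)
        overlaps = np.array([len(A & r) for r in sets], dtype=np.int64)
    n = int(sizes.max()) + 1 if sizes.size else 0
    W = np.bincount(sizes, minlength=n)
    S = np.bincount(sizes, weights=overlaps.astype(float), minlength=n)
    return [
        RegressionPoint(X=int(x), Y=float(S[x] / W[x]), W=int(W[x]))
        for x in np.nonzero(W)[0]
    ]


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapModel:
    """Fitted overlap-rate model lambda(n) = c*b0 + sum_k b_k * n**(1/k).

    ``betas[0]`` is the intercept (0.0 when ``c == 0``), ``betas[1:]`` the
    coefficients of n**(1/1) .. n**(1/k_max).  ``k_max == 0`` marks the
    constant fallback model used when no candidate satisfies the
    monotonicity/positivity constraints.  Predictions outside
    ``valid_range`` are clamped to the nearer boundary; predicted rates are
    floored at ``floor_epsilon``.
    """

    c: int
    k_max: int
    betas: tuple[float, ...]
    aic: float
    valid_range: tuple[int, int]
    floor_epsilon: float = LAMBDA_FLOOR
    fallback: bool = False

    def predict_raw(self, n: float) -> float:
        lam = self.betas[0] * self.c if self.c else 0.0
        for k in range(1, self.k_max + 1):
            lam += self.betas[k] * n ** (1.0 / k)
        if self.k_max == 0:  # constant fallback
            lam = self.betas[0]
        return lam

    def predict(self, n: float) -> tuple[float, bool]:
        """Predicted rate at set size *n*; second value flags range clamping."""
        lo, hi = self.valid_range
        clamped = n < lo or n > hi
        n_eff = min(max(n, lo), hi)
        return max(self.predict_raw(n_eff), self.floor_epsilon), clamped


def _design(x: np.ndarray, c: int, k_max: int) -> np.ndarray:
    cols = []
    if c:
        cols.append(np.ones_like(x, dtype=float))
    for k in range(1, k_max + 1):
        cols.append(x.astype(float) ** (1.0 / k))
    return np.column_stack(cols)


def _wls_aic(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted least squares and the Gaussian weighted-lm AIC.

    AIC = n*ln(RSS_w/n) + n*ln(2*pi) + n - sum(ln W) + 2*(p+1), the AIC of a
    Gaussian likelihood with per-point variance sigma^2/W — the convention
    mainstream statistical software applies to weighted linear models.
    """
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    rss_w = float(np.sum(w * resid**2))
    n = len(y)
    rss_w = max(rss_w, n * 1e-24)  # guard exact fits
    p = X.shape[1]
    aic = n * math.log(rss_w / n) + n * math.log(2 * math.pi) + n - float(
        np.sum(np.log(w))
    ) + 2 * (p + 1)
    return beta, aic


class FittingError(ValueError):
    """Degenerate regression design."""


def fit_overlap_model(
    points: Sequence[RegressionPoint],
    check_range: tuple[int, int],
) -> OverlapModel:
    """Fit all eight (c, k_max) models and select by constrained AIC.

    Every candidate is fitted by weighted least squares; candidates whose
    predicted rate is decreasing somewhere, or non-positive anywhere, on the
    integer grid ``check_range`` are rejected, and the lowest-AIC survivor is
    returned.  If no candidate survives, the intercept-free linear model is
    used as a fallback (or, if its slope is non-positive, the constant model
    at the global weighted mean overlap); the result is flagged.
    """
    xs = np.array([p.X for p in points], dtype=float)
    ys = np.array([p.Y for p in points], dtype=float)
    ws = np.array([p.W for p in points], dtype=float)
    if len(np.unique(xs)) < 2:
        raise FittingError("need at least 2 distinct set sizes to fit")
    lo, hi = int(check_range[0]), int(check_range[1])
    if lo > hi:
        raise FittingError("empty check range")
    grid = np.arange(max(lo, 0), hi + 1, dtype=float)

    best: OverlapModel | None = None
    for c in (0, 1):
        for k_max in (1, 2, 3, 4):
            if c + k_max > len(np.unique(xs)):
                continue  # more parameters than distinct sizes
            X = _design(xs, c, k_max)
            beta, aic = _wls_aic(X, ys, ws)
            betas = (0.0, *beta) if c == 0 else tuple(beta)
            betas = betas + (0.0,) * (k_max + 1 - len(betas))
            model = OverlapModel(
                c=c, k_max=k_max, betas=betas, aic=aic, valid_range=(lo, hi)
            )
            pred = np.array([model.predict_raw(n) for n in grid])
            if np.any(pred <= 0) or np.any(np.diff(pred) < -1e-9):
                continue
            if best is None or aic < best.aic:
                best = model
    if best is not None:
        return best

    # fallback: intercept-free linear, else constant at the weighted mean
    X = _design(xs, 0, 1)
    beta, aic = _wls_aic(X, ys, ws)
    if beta[0] > 0:
        return OverlapModel(
            c=0, k_max=1, betas=(0.0, float(beta[0])), aic=aic,
            valid_range=(lo, hi), fallback=True,
        )
    mean = float(np.average(ys, weights=ws))
    return OverlapModel(
        c=1, k_max=0, betas=(mean,), aic=math.inf,
        valid_range=(lo, hi), fallback=True,
    )


# ---------------------------------------------------------------------------
# P-values
# ---------------------------------------------------------------------------

def poisson_tail(x: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= x) at rate *lam*.

    Equals 1 - sum_{0 <= k < x} exp(-lam) lam^k / k!, evaluated through the
    regularized incomplete gamma function for numerical stability in both
    tails.  x = 0 returns 1 by the empty-sum convention.  Results are floored
    at 1e-320 so the returned value stays strictly positive (and log-safe)
    even where the true tail underflows double precision.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    if not lam > 0:
        raise ValueError("lam must be > 0")
    if x == 0:
        return 1.0
    return max(float(special.gammainc(x, lam)), 1e-320)


@dataclass(frozen=True)
class PairResult:
    """Overlap evidence for one unordered entity pair.

    ``p_a``/``p_b`` are the directional Poisson tails under each entity's
    model; ``p_combined`` their geometric mean.  ``clamped`` flags that a
    model was evaluated outside its fitted size range.
    """

    entity_a: str
    entity_b: str
    overlap: int
    p_a: float
    p_b: float
    p_combined: float
    clamped: bool = False


def pair_pvalue(
    entity_a: str,
    entity_b: str,
    model_a: OverlapModel,
    model_b: OverlapModel,
    set_a: frozenset[str],
    set_b: frozenset[str],
) -> PairResult:
    """Score the overlap of two entities' sets with both directional models."""
    x = len(set_a & set_b)
    if x == 0:
        return PairResult(entity_a, entity_b, 0, 1.0, 1.0, 1.0)
    lam_a, cl_a = model_a.predict(len(set_b))
    lam_b, cl_b = model_b.predict(len(set_a))
    p_a = poisson_tail(x, lam_a)
    p_b = poisson_tail(x, lam_b)
    p_comb = math.exp(0.5 * (math.log(p_a) + math.log(p_b)))
    return PairResult(entity_a, entity_b, x, p_a, p_b, p_comb, clamped=cl_a or cl_b)


def all_pairs(
    table: AssociationTable,
    models: Mapping[str, OverlapModel],
    min_overlap: int = 2,
    p_max: float = 1.0,
) -> list[PairResult]:
    """All unordered entity pairs with overlap >= min_overlap and
    p_combined <= p_max, each emitted once (entity_a < entity_b)."""
    sets = table.gene_sets()
    out: list[PairResult] = []
    for a, b in combinations(sorted(sets), 2):
        x = len(sets[a] & sets[b])
        if x < min_overlap:
            continue
        if a not in models or b not in models:
            raise KeyError(f"missing model for pair ({a}, {b})")
        res = pair_pvalue(a, b, models[a], models[b], sets[a], sets[b])
        if res.p_combined <= p_max:
            out.append(res)
    return out


# ---------------------------------------------------------------------------
# convenience pipeline + serialization
# ---------------------------------------------------------------------------

def fit_entity_models(
    table: AssociationTable,
    n_sets: int = N_SETS_DISEASE,
    seed: int = 0,
    check_range: tuple[int, int] | None = None,
) -> dict[str, OverlapModel]:
    """Sample one random-set collection and fit a model per entity.

    ``check_range`` defaults to the [min, max] of the observed entity set
    sizes, the range over which the constraints are enforced.
    """
    sets = table.gene_sets()
    if check_range is None:
        sizes = [len(s) for s in sets.values()]
        check_range = (min(sizes), max(sizes))
    coll = sample_random_sets(table, n_sets, seed=seed)
    return {
        e: fit_overlap_model(aggregate_overlap_curve(s, coll), check_range)
        for e, s in sets.items()
    }


class EntityModels:
    """Lazy per-entity model cache over one shared random-set collection.

    Sampling is done once at construction; individual entity models are
    fitted on first access.  Useful when only a subset of entities will be
    queried (e.g. gene-side models during prediction, where candidates are
    not known in advance).  Supports the mapping protocol used by
    :func:`all_pairs`.
    """

    def __init__(
        self,
        table: AssociationTable,
        n_sets: int,
        seed: int = 0,
        check_range: tuple[int, int] | None = None,
    ):
        self.table = table
        self.sets = table.gene_sets()
        if check_range is None:
            sizes = [len(s) for s in self.sets.values()]
            check_range = (min(sizes), max(sizes))
        self.check_range = check_range
        self.collection = sample_random_sets(table, n_sets, seed=seed)
        self._cache: dict[str, OverlapModel] = {}

    def __getitem__(self, entity: str) -> OverlapModel:
        if entity not in self._cache:
            curve = aggregate_overlap_curve(self.sets[entity], self.collection)
            self._cache[entity] = fit_overlap_model(curve, self.check_range)
        return self._cache[entity]

    def __contains__(self, entity: str) -> bool:
        return entity in self.sets

    def keys(self):
        return self.sets.keys()


def models_to_json(models: Mapping[str, OverlapModel], path, *,
                   n_sets: int | None = None, seed: int | None = None) -> None:
    payload = {
        "n_sets": n_sets,
        "seed": seed,
        "models": {
            e: {
                "c": m.c, "k_max": m.k_max, "betas": list(m.betas),
                "aic": m.aic if math.isfinite(m.aic) else None,
                "valid_range": list(m.valid_range), "fallback": m.fallback,
            }
            for e, m in models.items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def models_from_json(path) -> dict[str, OverlapModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {
        e: OverlapModel(
            c=d["c"], k_max=d["k_max"], betas=tuple(d["betas"]),
            aic=d["aic"] if d["aic"] is not None else math.inf,
            valid_range=tuple(d["valid_range"]), fallback=d["fallback"],
        )
        for e, d in payload["models"].items()
    }


def pairs_to_tsv(pairs: Sequence[PairResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_a\tentity_b\toverlap\tp_a\tp_b\tp_combined\n")
        for r in pairs:
            fh.write(
                f"{r.entity_a}\t{r.entity_b}\t{r.overlap}\t"
                f"{r.p_a:.6g}\t{r.p_b:.6g}\t{r.p_combined:.6g}\n"
            )
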