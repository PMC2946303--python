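"""The statistical core: sampling, regression curves, model selection,
Poisson tails and pair P-values, checked against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
import statsmodels.api as sm

from mechmap.associations import filter_min_degree, from_records
from mechmap.overlap import (
    EntityModels,
    FittingError,
    RegressionPoint,
    aggregate_overlap_curve,
    all_pairs,
    fit_entity_models,
    fit_overlap_model,
    models_from_json,
    models_to_json,
    pair_pvalue,
    poisson_tail,
    sample_random_sets,
)
from mechmap.synthetic import generate_associations
from tests.conftest import nullconfig


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def poisson_tail_by_summation(x: int, lam: float) -> float:
    """Term-by-term evaluation of 1 - sum_{k<x} e^-lam lam^k / k!."""
    s = 0.0
    term = math.exp(-lam)
    for k in range(x):
        if k > 0:
            term *= lam / k
        s += term
    return 1.0 - s


def poisson_binomial_tail(x: int, probs: list[float]) -> float:
    """Exact P(S >= x) for a sum of independent Bernoulli(p_i) by DP."""
    dist = np.zeros(len(probs) + 1)
    dist[0] = 1.0
    for p in probs:
        dist[1:] = dist[1:] * (1 - p) + dist[:-1] * p
        dist[0] *= 1 - p
    return float(dist[x:].sum())


def wls_oracle(points, c, k_max):
    """Independent WLS fit + AIC via statsmodels."""
    X = np.column_stack(
        ([np.ones(len(points))] if c else [])
        + [np.array([p.X for p in points], dtype=float) ** (1 / k)
           for k in range(1, k_max + 1)]
    )
    y = np.array([p.Y for p in points])
    w = np.array([p.W for p in points], dtype=float)
    res = sm.WLS(y, X, weights=w).fit()
    return res.params, -2 * res.llf + 2 * (X.shape[1] + 1)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class TestSampling:
    def test_full_coverage_gene_always_sampled(self):
        t = from_records(
            [(f"d{i}", "hub", "causal") for i in range(4)]
            + [("d0", "rare", "causal")]
        )
        coll = sample_random_sets(t, 500, seed=1)
        assert coll.inclusion_frequency("hub") == 1.0

    def test_inclusion_frequency_tracks_degree(self):
        # gene in 2 of 4 diseases -> inclusion probability 1/2
        t = from_records(
            [("d0", "g", "causal"), ("d1", "g", "causal")]
            + [(f"d{i}", f"x{i}", "causal") for i in range(4)]
        )
        coll = sample_random_sets(t, 20_000, seed=2)
        freq = coll.inclusion_frequency("g")
        sd = math.sqrt(0.5 * 0.5 / 20_000)
        assert abs(freq - 0.5) < 4 * sd

    def test_absent_gene_never_sampled(self, tiny_table):
        coll = sample_random_sets(tiny_table, 100, seed=3)
        assert coll.inclusion_frequency("nonexistent") == 0.0

    def test_deterministic_and_chunk_invariant(self, tiny_table):
        a = sample_random_sets(tiny_table, 300, seed=4, chunk_size=7)
        b = sample_random_sets(tiny_table, 300, seed=4, chunk_size=300)
        assert (a.matrix != b.matrix).nnz == 0

    def test_transposed_table_samples_disease_sets(self, filtered_planted):
        tt = filtered_planted.transpose()
        coll = sample_random_sets(tt, 2000, seed=5)
        # entities of the transposed table are genes; members are diseases
        assert set(coll.genes) <= tt.genes == filtered_planted.diseases


# ---------------------------------------------------------------------------
# curve aggregation
# ---------------------------------------------------------------------------

class TestCurve:
    def test_mean_of_equal_sizes(self):
        sets = [frozenset({"a", *{f"x{i}" for i in range(9)}}),
                frozenset({"a", "b", "c", *{f"y{i}" for i in range(7)}})]
        pts = aggregate_overlap_curve({"a", "b", "c"}, sets)
        assert pts == [RegressionPoint(X=10, Y=2.0, W=2)]

    def test_distinct_sizes_have_unit_weight(self):
        sets = [frozenset({"a"}), frozenset({"a", "b"}), frozenset({"a", "b", "c"})]
        pts = aggregate_overlap_curve({"a", "c"}, sets)
        assert all(p.W == 1 for p in pts)

    def test_matches_hand_enumeration(self):
        A = frozenset({"a", "b", "c", "d"})
        sets = [
            frozenset({"a", "x"}),
            frozenset({"b", "c", "x"}),
            frozenset({"a", "b", "c", "x", "y"}),
            frozenset({"x", "y"}),
            frozenset({"d", "y"}),
        ]
        by_size: dict[int, list[int]] = {}
        for r in sets:
            by_size.setdefault(len(r), []).append(len(A & r))
        expected = sorted(
            RegressionPoint(X=x, Y=sum(o) / len(o), W=len(o))
            for x, o in by_size.items()
        )
        assert sorted(aggregate_overlap_curve(A, sets)) == expected

    def test_weights_sum_to_n_sets(self, filtered_planted):
        coll = sample_random_sets(filtered_planted, 777, seed=6)
        pts = aggregate_overlap_curve(
            filtered_planted.gene_set("MA_D0"), coll
        )
        assert sum(p.W for p in pts) == 777

    def test_collection_and_set_list_agree(self, tiny_table):
        coll = sample_random_sets(tiny_table, 200, seed=7)
        A = tiny_table.gene_set("d1")
        assert aggregate_overlap_curve(A, coll) == \
            aggregate_overlap_curve(A, coll.as_sets())


# ---------------------------------------------------------------------------
# model fitting / selection
# ---------------------------------------------------------------------------

class TestFit:
    def test_exact_linear_recovered(self):
        pts = [RegressionPoint(x, 0.1 * x, 1000) for x in range(5, 41)]
        m = fit_overlap_model(pts, (5, 40))
        for n in range(5, 41):
            assert m.predict(n)[0] == pytest.approx(0.1 * n, abs=1e-6)

    def test_constant_data_predicts_constant(self):
        pts = [RegressionPoint(x, 3.0, 50) for x in range(5, 26)]
        m = fit_overlap_model(pts, (5, 25))
        for n in (5, 15, 25):
            assert m.predict(n)[0] == pytest.approx(3.0, rel=1e-6)

    def test_decreasing_best_model_rejected(self):
        # decreasing-then-flat data: the best unconstrained fit slopes down
        # and must be rejected; the oracle confirms the returned model is the
        # minimum-AIC candidate among the constrained ones
        xs = np.arange(5, 41)
        ys = 5.0 - 0.08 * xs + 0.002 * (xs - 20) ** 2
        pts = [RegressionPoint(int(x), float(y), 100) for x, y in zip(xs, ys)]
        aics = {}
        monotone = {}
        for c in (0, 1):
            for k_max in (1, 2, 3, 4):
                params, aic = wls_oracle(pts, c, k_max)
                aics[(c, k_max)] = aic
                grid = np.arange(5, 41, dtype=float)
                cols = ([np.ones_like(grid)] if c else []) + [
                    grid ** (1 / k) for k in range(1, k_max + 1)
                ]
                pred = np.column_stack(cols) @ params
                monotone[(c, k_max)] = bool(
                    np.all(np.diff(pred) >= -1e-9) and np.all(pred > 0)
                )
        global_best = min(aics, key=aics.get)
        assert not monotone[global_best]
        valid = {k: v for k, v in aics.items() if monotone[k]}
        m = fit_overlap_model(pts, (5, 40))
        if valid:
            assert (m.c, m.k_max) == min(valid, key=valid.get)
        else:
            assert m.fallback

    def test_aic_matches_statsmodels_convention(self):
        rng = np.random.default_rng(8)
        pts = [
            RegressionPoint(int(x), float(0.2 * x + rng.normal(0, 0.1)), int(w))
            for x, w in zip(range(5, 30), rng.integers(1, 500, 25))
        ]
        for c, k_max in [(0, 1), (1, 1), (1, 3)]:
            _, aic_oracle = wls_oracle(pts, c, k_max)
            from mechmap.overlap import _design, _wls_aic
            xs = np.array([p.X for p in pts], dtype=float)
            ys = np.array([p.Y for p in pts])
            ws = np.array([p.W for p in pts], dtype=float)
            _, aic = _wls_aic(_design(xs, c, k_max), ys, ws)
            assert aic == pytest.approx(aic_oracle, rel=1e-9)

    def test_single_size_is_degenerate(self):
        with pytest.raises(FittingError):
            fit_overlap_model([RegressionPoint(5, 1.0, 10)] * 3, (5, 5))

    def test_flat_zero_uses_floored_fallback(self):
        pts = [RegressionPoint(x, 0.0, 10) for x in range(5, 16)]
        m = fit_overlap_model(pts, (5, 15))
        assert m.fallback
        assert m.predict(10)[0] >= m.floor_epsilon

    def test_out_of_range_prediction_clamps(self):
        pts = [RegressionPoint(x, 0.1 * x, 100) for x in range(5, 21)]
        m = fit_overlap_model(pts, (5, 20))
        lam, clamped = m.predict(100)
        assert clamped and lam == pytest.approx(m.predict(20)[0])


# ---------------------------------------------------------------------------
# Poisson tail
# ---------------------------------------------------------------------------

class TestPoissonTail:
    def test_zero_overlap_is_certain(self):
        assert poisson_tail(0, 5.0) == 1.0

    def test_hand_value(self):
        assert poisson_tail(2, 1.0) == pytest.approx(1 - 2 / math.e, rel=1e-12)

    def test_small_lambda_limit(self):
        assert poisson_tail(1, 1e-12) == pytest.approx(1e-12, rel=1e-3)

    def test_agrees_with_summation_oracle(self):
        for lam in (0.1, 1.0, 4.5, 12.0, 30.0):
            for x in (1, 2, 5, 10, 25, 50):
                p = poisson_tail(x, lam)
                q = poisson_tail_by_summation(x, lam)
                if q > 1e-13:  # below that the subtraction oracle loses digits
                    assert p == pytest.approx(q, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            poisson_tail(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_tail(2, 0.0)

    def test_monotone_in_x_and_lambda(self):
        for lam in (0.5, 2.0, 9.0):
            tails = [poisson_tail(x, lam) for x in range(0, 15)]
            assert all(a > b for a, b in zip(tails, tails[1:]))
        for x in (1, 3, 8):
            tails = [poisson_tail(x, lam) for lam in (0.1, 0.5, 1, 3, 9)]
            assert all(a < b for a, b in zip(tails, tails[1:]))


# ---------------------------------------------------------------------------
# pair P-values
# ---------------------------------------------------------------------------

def _fit_small(table, n_sets=5000, seed=0):
    return fit_entity_models(table, n_sets=n_sets, seed=seed)


class TestPairs:
    def test_disjoint_sets_give_p_one(self, filtered_planted):
        models = _fit_small(filtered_planted)
        sets = filtered_planted.gene_sets()
        a = next(d for d in sorted(sets) if d.startswith("MA"))
        b = next(d for d in sorted(sets) if d.startswith("MB"))
        assert not sets[a] & sets[b]
        res = pair_pvalue(a, b, models[a], models[b], sets[a], sets[b])
        assert res.p_a == res.p_b == res.p_combined == 1.0

    def test_combined_is_geometric_mean_and_symmetric(self, filtered_planted):
        models = _fit_small(filtered_planted)
        sets = filtered_planted.gene_sets()
        pairs = [
            (a, b) for a, b in combinations(sorted(sets), 2)
            if len(sets[a] & sets[b]) >= 1
        ][:20]
        for a, b in pairs:
            r = pair_pvalue(a, b, models[a], models[b], sets[a], sets[b])
            s = pair_pvalue(b, a, models[b], models[a], sets[b], sets[a])
            assert r.p_combined == pytest.approx(
                math.sqrt(r.p_a * r.p_b), rel=1e-12
            )
            assert r.p_combined == pytest.approx(s.p_combined, rel=1e-12)
            assert min(r.p_a, r.p_b) <= r.p_combined <= max(r.p_a, r.p_b)

    def test_all_pairs_equals_brute_force(self):
        t = filter_min_degree(
            generate_associations(nullconfig(11)), "disease", 5
        )
        # restrict to <= 30 diseases for the exhaustive comparison
        keep = sorted(t.diseases)[:30]
        t = from_records([(d, g, ty) for (d, g), ty in t.edges.items() if d in keep])
        models = _fit_small(t)
        sets = t.gene_sets()
        got = {
            (r.entity_a, r.entity_b): r
            for r in all_pairs(t, models, min_overlap=2, p_max=0.5)
        }
        expected = {}
        for a in sets:
            for b in sets:
                if a >= b:
                    continue
                if len(sets[a] & sets[b]) < 2:
                    continue
                r = pair_pvalue(a, b, models[a], models[b], sets[a], sets[b])
                if r.p_combined <= 0.5:
                    expected[(a, b)] = r
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k].p_combined == pytest.approx(expected[k].p_combined)

    def test_min_overlap_excludes_single_shared_gene(self, filtered_planted):
        models = _fit_small(filtered_planted)
        res = all_pairs(filtered_planted, models, min_overlap=2, p_max=1.0)
        assert all(r.overlap >= 2 for r in res)

    def test_p_max_zero_empty(self, filtered_planted):
        models = _fit_small(filtered_planted)
        assert all_pairs(filtered_planted, models, min_overlap=2, p_max=0.0) == []


# ---------------------------------------------------------------------------
# statistical sanity of the fitted rate
# ---------------------------------------------------------------------------

class TestModelAnchors:
    def test_rate_at_mean_size_matches_closed_form(self):
        t = filter_min_degree(generate_associations(nullconfig(12)), "disease", 5)
        coll = sample_random_sets(t, 20_000, seed=13)
        deg = t.gene_degree
        n_dis = len(t.diseases)
        sets = t.gene_sets()
        sizes = [len(s) for s in sets.values()]
        cr = (min(sizes), max(sizes))
        mean_size = float(coll.sizes.mean())
        checked = 0
        for d in sorted(sets)[:25]:
            expected = sum(deg[g] / n_dis for g in sets[d])
            m = fit_overlap_model(aggregate_overlap_curve(sets[d], coll), cr)
            lam, _ = m.predict(mean_size)
            assert abs(lam - expected) / expected < 0.15
            checked += 1
        assert checked == 25

    def test_poisson_never_understates_poisson_binomial_tail(self):
        # for small sets the unconditional overlap count is exactly
        # Poisson-binomial; the Poisson surrogate at lam = sum(p_i) is
        # conservative (never smaller than half the exact tail anywhere with
        # mass >= 1e-6) and stays within a factor of 2 in the bulk.  Deep in
        # the tail it overestimates further when hub genes with large
        # inclusion probability dominate the set — the direction that keeps
        # reported P-values conservative.
        t = filter_min_degree(generate_associations(nullconfig(14)), "disease", 5)
        deg = t.gene_degree
        n_dis = len(t.diseases)
        sets = {d: s for d, s in t.gene_sets().items() if len(s) <= 12}
        assert sets, "fixture must contain small causal sets"
        for d, s in sorted(sets.items())[:10]:
            probs = [deg[g] / n_dis for g in s]
            lam = sum(probs)
            for x in range(1, len(s) + 1):
                exact = poisson_binomial_tail(x, probs)
                if exact < 1e-6:
                    break
                ratio = poisson_tail(x, lam) / exact
                assert ratio >= 0.5
                if exact >= 0.05:
                    assert ratio <= 2.0

    def test_entity_models_match_eager_fit(self, filtered_planted):
        eager = fit_entity_models(filtered_planted, n_sets=2000, seed=15)
        lazy = EntityModels(filtered_planted, 2000, seed=15)
        for d in sorted(filtered_planted.diseases)[:5]:
            assert eager[d].betas == lazy[d].betas

    def test_model_json_round_trip(self, filtered_planted, tmp_path):
        models = fit_entity_models(filtered_planted, n_sets=2000, seed=16)
        p = tmp_path / "models.json"
        models_to_json(models, p, n_sets=2000, seed=16)
        back = models_from_json(p)
        assert back.keys() == models.keys()
        for k in models:
            assert back[k] == models[k]
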