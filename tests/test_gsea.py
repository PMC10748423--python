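"""Preranked GSEA: ranking metric, running-sum statistic, permutation null,
and the minimal rank-sum differential expression — each against an
independent oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from screenrank import (
    GeneSet,
    GeneSetCollection,
    RankedMetric,
    enrichment_score,
    gsea_preranked,
    rank_metric,
    simple_de,
)


def make_metric(scores, genes=None):
    genes = genes or [chr(ord("a") + i) for i in range(len(scores))]
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], genes[i]))
    return RankedMetric(
        genes=tuple(genes[i] for i in order),
        scores=tuple(float(scores[i]) for i in order),
    )


def oracle_running_sum(scores, hit_mask, p_exp):
    """Independent running-sum: explicit per-position loop."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    m = int(np.sum(hit_mask))
    weights = np.abs(scores) ** p_exp
    total = weights[hit_mask].sum()
    if total == 0:
        weights = np.ones(n)
        total = float(m)
    running = [0.0]
    for i in range(n):
        if hit_mask[i]:
            running.append(running[-1] + weights[i] / total)
        else:
            running.append(running[-1] - 1.0 / (n - m))
    deviations = running[1:]
    es_pos, es_neg = max(deviations), min(deviations)
    es = es_pos if es_pos >= -es_neg else es_neg  # positive wins exact ties
    return es, running


class TestRankMetric:
    @pytest.mark.parametrize(
        "adj_p, fc, expected",
        [(0.01, 2.0, 4.0), (1.0, 3.5, 0.0), (0.1, -1.0, -1.0)],
    )
    def test_metric_arithmetic(self, adj_p, fc, expected):
        table = pd.DataFrame(
            {"gene": ["x"], "adjusted_p": [adj_p], "avg_log2FC": [fc]}
        )
        metric = rank_metric(table)
        assert metric.scores[0] == pytest.approx(expected)

    def test_sorted_descending_with_symbol_ties(self):
        table = pd.DataFrame(
            {
                "gene": ["b", "c", "a", "d"],
                "adjusted_p": [0.1, 1.0, 1.0, 0.01],
                "avg_log2FC": [1.0, 2.0, 1.0, -1.0],
            }
        )
        metric = rank_metric(table)
        assert metric.genes == ("b", "a", "c", "d")  # scores 1, 0, 0, -2

    def test_zero_p_clamped_finite(self):
        table = pd.DataFrame(
            {"gene": ["x"], "adjusted_p": [0.0], "avg_log2FC": [1.0]}
        )
        assert math.isfinite(rank_metric(table).scores[0])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="lacks column"):
            rank_metric(pd.DataFrame({"gene": ["x"], "adjusted_p": [0.5]}))


class TestEnrichmentScore:
    def test_single_top_gene_gives_es_one(self):
        metric = make_metric([5.0, 2.0, 1.0, 0.5])
        es, running = enrichment_score(metric, {metric.genes[0]})
        assert es == pytest.approx(1.0)
        assert running[1] == pytest.approx(1.0)

    def test_six_gene_hand_computation(self):
        """scores 5..0.5, set at positions 2 and 5: peak after the first hit."""
        metric = make_metric([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
        gene_set = {metric.genes[1], metric.genes[4]}  # weights 4 and 1
        es, running = enrichment_score(metric, gene_set, p_exp=1.0)
        # hand: -1/4, then +4/5 -> 0.55; -> 0.30, 0.05; +1/5 -> 0.25; -> 0.0
        assert es == pytest.approx(0.55)
        assert running == pytest.approx(
            [0.0, -0.25, 0.55, 0.30, 0.05, 0.25, 0.0]
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        scores = np.sort(rng.normal(size=n))[::-1]
        metric = make_metric(list(scores), genes=[f"g{i:02d}" for i in range(n)])
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[rng.choice(n, size=8, replace=False)] = True
        gene_set = {metric.genes[i] for i in np.flatnonzero(hit_mask)}
        for p_exp in (0.0, 1.0, 2.0):
            es, running = enrichment_score(metric, gene_set, p_exp=p_exp)
            es_oracle, running_oracle = oracle_running_sum(
                metric.scores, hit_mask, p_exp
            )
            assert es == pytest.approx(es_oracle, abs=1e-12)
            assert running == pytest.approx(np.array(running_oracle), abs=1e-12)
            assert abs(es) <= 1.0
            assert running[0] == 0.0 and running[-1] == pytest.approx(0.0, abs=1e-9)

    def test_p_exp_zero_equals_classic_ks(self):
        """Unweighted ES is the signed KS distance between hit and miss ECDFs."""
        rng = np.random.default_rng(4)
        n = 60
        scores = np.sort(rng.normal(size=n))[::-1]
        metric = make_metric(list(scores), genes=[f"g{i:02d}" for i in range(n)])
        hit_idx = np.sort(rng.choice(n, size=12, replace=False))
        gene_set = {metric.genes[i] for i in hit_idx}
        es, _ = enrichment_score(metric, gene_set, p_exp=0.0)
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[hit_idx] = True
        positions = np.arange(1, n + 1)
        ecdf_hit = np.cumsum(hit_mask) / hit_mask.sum()
        ecdf_miss = np.cumsum(~hit_mask) / (~hit_mask).sum()
        diff = ecdf_hit - ecdf_miss
        assert es == pytest.approx(diff[np.argmax(np.abs(diff))], abs=1e-12)

    def test_invariant_under_monotone_transform_when_unweighted(self):
        rng = np.random.default_rng(8)
        scores = np.sort(rng.normal(size=30))[::-1]
        metric1 = make_metric(list(scores), genes=[f"g{i:02d}" for i in range(30)])
        metric2 = make_metric(
            list(np.exp(scores / 2)), genes=[f"g{i:02d}" for i in range(30)]
        )
        gene_set = {metric1.genes[i] for i in (0, 3, 9, 20)}
        es1, _ = enrichment_score(metric1, gene_set, p_exp=0.0)
        es2, _ = enrichment_score(metric2, gene_set, p_exp=0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_errors(self):
        metric = make_metric([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="not represented"):
            enrichment_score(metric, {"absent"})
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(metric, set(metric.genes))


def single_set_collection(genes, name="SET"):
    coll = GeneSetCollection()
    coll.add(GeneSet(name, name, tuple(genes)))
    return coll


class TestGseaPreranked:
    def test_extreme_case_minimum_attainable_p(self):
        """Set occupying the top positions: ES = 1 (uniquely maximal, since
        every other placement suffers a miss decrement before its last hit)
        and nominal p sits on the add-one floor 1/(1 + #same-sign nulls)."""
        rng = np.random.default_rng(0)
        scores = np.sort(rng.random(100))[::-1] * 10
        metric = make_metric(list(scores), genes=[f"g{i:03d}" for i in range(100)])
        coll = single_set_collection(metric.genes[:5])
        result = gsea_preranked(metric, coll, n_perm=100, seed=1)[0]
        assert result.es == pytest.approx(1.0)
        # independent recount of the null: same generator protocol, ES by the
        # loop oracle
        oracle_rng = np.random.default_rng(1)
        n_nonneg = 0
        for _ in range(100):
            idx = np.sort(oracle_rng.choice(100, size=5, replace=False))
            mask = np.isin(np.arange(100), idx)
            if oracle_running_sum(metric.scores, mask, 1.0)[0] >= 0:
                n_nonneg += 1
        assert result.nominal_p == pytest.approx(1 / (1 + n_nonneg))
        assert result.nominal_p <= 1 / 51  # well under any sign split
        assert result.fdr_q == result.nominal_p  # single-set run

    def test_exhaustive_null_matches_enumeration_oracle(self):
        """6-gene metric, 2-gene set: all 15 placements enumerated both ways."""
        metric = make_metric([5.0, 4.0, 3.0, 2.0, 1.0, 0.5])
        gene_set = (metric.genes[1], metric.genes[4])
        result = gsea_preranked(
            metric, single_set_collection(gene_set), n_perm=1, seed=0,
            exhaustive=True,
        )[0]
        assert result.n_permutations == 15

        es_obs, _ = oracle_running_sum(
            metric.scores, np.isin(np.arange(6), [1, 4]), p_exp=1.0
        )
        null_es = []
        for combo in itertools.combinations(range(6), 2):
            mask = np.isin(np.arange(6), combo)
            null_es.append(oracle_running_sum(metric.scores, mask, 1.0)[0])
        same_sign = [e for e in null_es if (e >= 0) == (es_obs >= 0)]
        n_extreme = sum(abs(e) >= abs(es_obs) for e in same_sign)
        assert result.es == pytest.approx(es_obs)
        assert result.nominal_p == pytest.approx(
            (1 + n_extreme) / (1 + len(same_sign))
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        scores = np.sort(rng.normal(size=50))[::-1]
        metric = make_metric(list(scores), genes=[f"g{i:02d}" for i in range(50)])
        coll = single_set_collection(metric.genes[2:8])
        r1 = gsea_preranked(metric, coll, n_perm=200, seed=42)[0]
        r2 = gsea_preranked(metric, coll, n_perm=200, seed=42)[0]
        assert (r1.es, r1.nes, r1.nominal_p, r1.fdr_q) == (
            r2.es, r2.nes, r2.nominal_p, r2.fdr_q
        )
        assert np.array_equal(r1.running_sum, r2.running_sum)

    def test_result_invariants_and_sign_convention(self):
        rng = np.random.default_rng(9)
        scores = np.sort(rng.normal(size=80))[::-1]
        metric = make_metric(list(scores), genes=[f"g{i:02d}" for i in range(80)])
        coll = GeneSetCollection()
        coll.add(GeneSet("TOP", "top-ish", tuple(metric.genes[:10])))
        coll.add(GeneSet("BOTTOM", "bottom-ish", tuple(metric.genes[-10:])))
        results = gsea_preranked(metric, coll, n_perm=300, seed=3)
        for r in results:
            assert abs(r.es) <= 1.0
            assert 0.0 <= r.nominal_p <= 1.0
            assert 0.0 <= r.fdr_q <= 1.0
            if r.es != 0:
                assert math.copysign(1, r.nes) == math.copysign(1, r.es)
        assert results[0].es > 0 > results[1].es

    def test_set_larger_than_metric_rejected(self):
        metric = make_metric([2.0, 1.0])
        coll = single_set_collection(("a", "b", "c", "d"))
        with pytest.raises(ValueError, match="larger than"):
            gsea_preranked(metric, coll, n_perm=10, seed=0)


class TestSimpleDe:
    def test_permuted_identical_groups_have_zero_fc(self):
        rng = np.random.default_rng(1)
        base = rng.random((5, 4))
        expr = pd.DataFrame(
            np.hstack([base, base[:, [2, 0, 3, 1]]]),
            index=[f"g{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(8)],
        )
        de = simple_de(expr, ["A"] * 4 + ["B"] * 4)
        assert de["avg_log2FC"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_ranksum_matches_exact_enumeration(self):
        """3+3 samples: p from enumerating all 20 label splits."""
        rng = np.random.default_rng(6)
        values = rng.random((2, 6)) * 10
        expr = pd.DataFrame(values, index=["g1", "g2"], columns=list("abcdef"))
        labels = ["X"] * 3 + ["Y"] * 3
        de = simple_de(expr, labels)
        for row_idx in range(2):
            pooled = values[row_idx]
            obs_u = _u_statistic(pooled[:3], pooled[3:])
            null_u = [
                _u_statistic(pooled[list(c)], pooled[[i for i in range(6) if i not in c]])
                for c in itertools.combinations(range(6), 3)
            ]
            center = 9 / 2  # n1*n2/2
            p_exact = np.mean(
                [abs(u - center) >= abs(obs_u - center) - 1e-12 for u in null_u]
            )
            assert de["p_value"].iloc[row_idx] == pytest.approx(p_exact, abs=1e-9)

    def test_doubled_mean_gives_unit_log2fc(self):
        expr = pd.DataFrame(
            [[4.0, 4.0, 4.0, 2.0, 2.0, 2.0]],
            index=["g"],
            columns=list("abcdef"),
        )
        de = simple_de(expr, ["A"] * 3 + ["B"] * 3, eps=1e-12)
        assert de["avg_log2FC"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_group1_selection_flips_sign(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.random((3, 8)) + np.array([[1.0]] * 3) * np.r_[np.ones(4), np.zeros(4)],
            index=["g1", "g2", "g3"],
            columns=[f"c{i}" for i in range(8)],
        )
        labels = ["T"] * 4 + ["P"] * 4
        fc_t = simple_de(expr, labels, group1="T")["avg_log2FC"]
        fc_p = simple_de(expr, labels, group1="P")["avg_log2FC"]
        assert np.allclose(fc_t, -fc_p)

    def test_single_group_rejected(self):
        expr = pd.DataFrame(np.ones((2, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="two groups"):
            simple_de(expr, ["A"] * 4)
        with pytest.raises(ValueError, match="at least two samples"):
            simple_de(expr, ["A", "A", "A", "B"])


def _u_statistic(x, y):
    """Mann-Whitney U of x over y, by direct pair counting."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u
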