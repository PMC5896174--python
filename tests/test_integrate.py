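import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glrscope.core import ExpressionTable, ValidationError
from glrscope.integrate import (
    RankedList,
    enrich_gene_sets,
    enrichment_score,
    group_compare,
    normalized_enrichment,
    peak_gene_set,
    rank_by_log2fc,
    select_de_genes,
    strength_stratified_expression,
)


def expr_table(fc_by_gene, expressed=None):
    genes = sorted(fc_by_gene)
    df = pd.DataFrame({
        "gene_id": genes,
        "expr_ctrl": 10.0,
        "expr_trt": [10.0 * 2 ** fc_by_gene[g] for g in genes],
        "log2fc": [fc_by_gene[g] for g in genes],
    })
    if expressed is not None:
        df["expressed"] = [g in expressed for g in genes]
    return ExpressionTable(df)


def ranked_list(metric):
    order = np.argsort(-np.asarray(metric), kind="stable")
    return RankedList(
        [f"g{i}" for i in order], np.asarray(metric, dtype=float)[order]
    )


class TestSelectDeGenes:
    def test_all_zero_gives_empty_sets(self):
        up, down = select_de_genes(expr_table({"a": 0.0, "b": 0.0}))
        assert up == [] and down == []

    def test_boundary_inclusive(self):
        up, down = select_de_genes(expr_table({"a": 0.5, "b": -0.5, "c": 0.49}))
        assert up == ["a"] and down == ["b"]

    def test_only_expressed_genes_count(self):
        table = expr_table({"a": 1.0, "b": 1.0}, expressed={"a"})
        up, _ = select_de_genes(table)
        assert up == ["a"]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(0)
        fc = {f"g{i}": float(rng.normal(0, 0.6)) for i in range(200)}
        up, down = select_de_genes(expr_table(fc), threshold=0.5)
        assert set(up) == {g for g, v in fc.items() if v >= 0.5}
        assert set(down) == {g for g, v in fc.items() if v <= -0.5}
        assert not set(up) & set(down)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValidationError):
            select_de_genes(expr_table({"a": 0.0}), threshold=0)


def brute_force_es(genes, metric, members, exponent):
    """Direct enumeration of the weighted-KS running sum."""
    hits = [g in members for g in genes]
    n, nh = len(genes), sum(hits)
    wsum = sum(abs(m) ** exponent for g, m, h in zip(genes, metric, hits) if h)
    run, out = 0.0, []
    for g, m, h in zip(genes, metric, hits):
        run += (abs(m) ** exponent) / wsum if h else -1.0 / (n - nh)
        out.append(run)
    hi, lo = max(out), min(out)
    return hi if hi >= -lo else lo


class TestEnrichmentScore:
    def test_unweighted_es_equals_classical_ks(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(10, 51))
            metric = np.sort(rng.normal(0, 1, n))[::-1]
            k = int(rng.integers(1, n))
            members = set(rng.choice([f"g{i}" for i in range(n)], k, replace=False))
            ranked = RankedList([f"g{i}" for i in range(n)], metric)
            es, _, _ = enrichment_score(ranked, members, weight_exponent=0)
            hit_pos = [i for i, g in enumerate(ranked.genes) if g in members]
            miss_pos = [i for i, g in enumerate(ranked.genes) if g not in members]
            ks = stats.ks_2samp(hit_pos, miss_pos).statistic
            assert abs(es) == pytest.approx(ks, abs=1e-12)
            assert es == pytest.approx(
                brute_force_es(ranked.genes, metric, members, 0), abs=1e-12
            )

    def test_weighted_es_matches_enumeration(self):
        rng = np.random.default_rng(2)
        n = 40
        metric = np.sort(rng.normal(0, 1, n))[::-1]
        members = set(rng.choice([f"g{i}" for i in range(n)], 12, replace=False))
        ranked = RankedList([f"g{i}" for i in range(n)], metric)
        es, _, _ = enrichment_score(ranked, members, weight_exponent=1)
        assert es == pytest.approx(
            brute_force_es(ranked.genes, metric, members, 1), abs=1e-12
        )

    def test_bottom_concentrated_set_scores_negative(self):
        ranked = ranked_list(np.linspace(2, -2, 20))
        es, _, _ = enrichment_score(ranked, {"g16", "g17", "g18", "g19"},
                                    weight_exponent=0)
        assert es < 0

    def test_reversal_negates_unweighted_es(self):
        rng = np.random.default_rng(3)
        n = 30
        metric = np.sort(rng.normal(0, 1, n))[::-1]
        members = {f"g{i}" for i in rng.choice(n, 8, replace=False)}
        fwd = RankedList([f"g{i}" for i in range(n)], metric)
        rev = RankedList([f"g{i}" for i in range(n - 1, -1, -1)], -metric[::-1])
        es_f, _, _ = enrichment_score(fwd, members, 0)
        es_r, _, _ = enrichment_score(rev, members, 0)
        assert es_f == pytest.approx(-es_r, abs=1e-12)

    def test_empty_or_full_intersection_rejected(self):
        ranked = ranked_list([1.0, 0.5, -0.5])
        with pytest.raises(ValidationError):
            enrichment_score(ranked, {"nope"})
        with pytest.raises(ValidationError):
            enrichment_score(ranked, set(ranked.genes))


class TestNormalizedEnrichment:
    def test_seed_required(self):
        with pytest.raises(ValidationError):
            normalized_enrichment(ranked_list([1, 0.5, -1.0]), {"g0"})

    def test_fixed_seed_reproducible(self):
        ranked = ranked_list(np.linspace(2, -2, 50))
        members = {f"g{i}" for i in range(5)}
        a = normalized_enrichment(ranked, members, n_perm=200, seed=7)
        b = normalized_enrichment(ranked, members, n_perm=200, seed=7)
        assert (a.es, a.nes, a.p_value) == (b.es, b.nes, b.p_value)

    def test_top_concentrated_set_is_significant(self):
        ranked = ranked_list(np.linspace(2, -2, 200))
        members = {f"g{i}" for i in range(15)}
        res = normalized_enrichment(ranked, members, n_perm=500, seed=1)
        assert res.es > 0 and res.p_value < 0.05

    def test_bh_fdr_across_sets(self):
        ranked = ranked_list(np.linspace(2, -2, 100))
        sets = {"top": {f"g{i}" for i in range(8)},
                "rand": {f"g{i}" for i in range(3, 100, 13)}}
        results = enrich_gene_sets(ranked, sets, n_perm=200, seed=5)
        assert {r.gene_set_name for r in results} == {"rand", "top"}
        ps = {r.gene_set_name: r.p_value for r in results}
        qs = {r.gene_set_name: r.fdr_q for r in results}
        assert all(qs[k] >= ps[k] for k in ps)


class TestPeakGeneSet:
    def test_deduplicates_shared_genes(self):
        mapping = {"s1": "a", "s2": "a", "s3": "b", "s4": None}
        assert peak_gene_set(mapping) == {"a", "b"}

    def test_empty_mapping(self):
        assert peak_gene_set({}) == set()


class _Site:
    def __init__(self, sid, pileup):
        self.site_id = sid
        self.pileup = pileup


class TestStrata:
    def make_inputs(self):
        fc = {f"s{i}": 0.8 + 0.01 * i for i in range(6)}
        fc |= {f"w{i}": 0.1 + 0.01 * i for i in range(6)}
        fc |= {f"b{i}": 0.0 for i in range(8)}
        expr = expr_table(fc)
        sites = [_Site(f"S{i}", 50.0) for i in range(6)]
        sites += [_Site(f"W{i}", 10.0) for i in range(6)]
        mapping = {f"S{i}": f"s{i}" for i in range(6)}
        mapping |= {f"W{i}": f"w{i}" for i in range(6)}
        return sites, mapping, expr

    def test_planted_difference_detected(self):
        sites, mapping, expr = self.make_inputs()
        comp = strength_stratified_expression(sites, mapping, expr,
                                              pileup_threshold=35)
        assert comp.values["stronger"].mean() > comp.values["weaker"].mean()
        assert comp.anova_p < 0.05
        row = comp.posthoc.query(
            "group1 in ('stronger','weaker') and group2 in ('stronger','weaker')"
        )
        assert float(row["p_adj"].iloc[0]) < 0.05

    def test_threshold_boundary_inclusive(self):
        sites, mapping, expr = self.make_inputs()
        sites[0] = _Site("S0", 35.0)  # exactly at the threshold
        comp = strength_stratified_expression(sites, mapping, expr, 35)
        assert "s0" in comp.strata["stronger"]

    def test_empty_stratum_named_in_error(self):
        sites, mapping, expr = self.make_inputs()
        with pytest.raises(ValidationError, match="weaker"):
            strength_stratified_expression(sites, mapping, expr,
                                           pileup_threshold=1.0)


class TestGroupCompare:
    def test_identical_groups_t_zero(self):
        out = group_compare({"a": [1, 2, 3], "b": [1, 2, 3]}, "welch_t")
        assert out["statistic"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == 1.0

    def test_three_identical_groups_anova_f_zero(self):
        out = group_compare(
            {"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}, "anova_tukey"
        )
        assert out["anova_f"].iloc[0] == pytest.approx(0.0)

    def test_fisher_lsd_matches_textbook_pooled_t(self):
        # pooled variance of [1,2,3] and [4,5,6] is 1; se = sqrt(2/3)
        out = group_compare({"a": [1, 2, 3], "b": [4, 5, 6]}, "anova_fisher_lsd")
        expected_t = -3.0 / np.sqrt(2.0 / 3.0)
        assert out["statistic"].iloc[0] == pytest.approx(expected_t)
        assert out["p_value"].iloc[0] == pytest.approx(
            2 * stats.t.sf(abs(expected_t), df=4)
        )

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValidationError):
            group_compare({"a": [1], "b": [1, 2]}, "welch_t")


class TestRanking:
    def test_rank_by_log2fc_descending_unique(self):
        expr = expr_table({"a": 0.5, "b": 1.5, "c": -1.0})
        ranked = rank_by_log2fc(expr)
        assert ranked.genes == ["b", "a", "c"]
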