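import numpy as np
import pytest
from scipy.stats import ks_2samp

from coexnet.gsea import enrichment_score, normalize_es
from coexnet.ranking import GeneSet, RankedList

from oracles import walk_es


def make_ranked(scores, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(scores))]
    return RankedList(gene_ids=genes, scores=np.asarray(scores, float))


def descending(n, lo=0.5, hi=5.0):
    """Strictly descending positive scores (RankedList preserves the order)."""
    return np.linspace(hi, lo, n)


class TestEnrichmentScore:
    def test_single_member_ranked_first_gives_plus_one(self):
        ranked = make_ranked(descending(10))
        res = enrichment_score(ranked, GeneSet("s", {ranked.gene_ids[0]}), weight_p=0)
        assert res.es == pytest.approx(1.0)

    def test_single_member_ranked_last_gives_minus_one(self):
        ranked = make_ranked(descending(10))
        res = enrichment_score(ranked, GeneSet("s", {ranked.gene_ids[-1]}), weight_p=0)
        assert res.es == pytest.approx(-1.0)

    def test_fixed_instance_matches_explicit_walk(self):
        # N=10, hits at ranks 2 and 5 (1-based), p=0
        ranked = make_ranked(descending(10))
        hits = {ranked.gene_ids[1], ranked.gene_ids[4]}
        res = enrichment_score(ranked, GeneSet("s", hits), weight_p=0)
        hit_mask = [g in hits for g in ranked.gene_ids]
        es_oracle, running_oracle = walk_es(ranked.scores, hit_mask, 0)
        assert res.es == pytest.approx(es_oracle)
        np.testing.assert_allclose(res.running_sum, running_oracle, atol=1e-12)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 2.0])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_walk_oracle_on_random_instances(self, seed, weight_p):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        ranked = make_ranked(rng.standard_normal(n))
        k = int(rng.integers(1, n // 2))
        hits = set(rng.choice(ranked.gene_ids, size=k, replace=False))
        res = enrichment_score(ranked, GeneSet("s", hits), weight_p=weight_p)
        es_oracle, running_oracle = walk_es(
            ranked.scores, [g in hits for g in ranked.gene_ids], weight_p
        )
        assert res.es == pytest.approx(es_oracle, abs=1e-10)
        np.testing.assert_allclose(res.running_sum, running_oracle, atol=1e-10)
        # invariants: running sum closes at 0, |es| is the extremum, bounded
        assert abs(res.running_sum[-1]) < 1e-9
        assert abs(res.es) == pytest.approx(np.max(np.abs(res.running_sum)))
        assert -1.0 <= res.es <= 1.0

    @pytest.mark.parametrize("seed", range(25))
    def test_unweighted_es_equals_two_sample_ks_statistic(self, seed):
        """p=0 reduces to the classic KS statistic between hit and miss
        rank positions (independent empirical-CDF oracle)."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(20, 200))
        ranked = make_ranked(rng.standard_normal(n))
        k = int(rng.integers(2, n // 2))
        hits = set(rng.choice(ranked.gene_ids, size=k, replace=False))
        res = enrichment_score(ranked, GeneSet("s", hits), weight_p=0)
        pos = np.array([i for i, g in enumerate(ranked.gene_ids) if g in hits])
        neg = np.array([i for i, g in enumerate(ranked.gene_ids) if g not in hits])
        d = ks_2samp(pos, neg).statistic
        assert abs(res.es) == pytest.approx(d, abs=1e-10)

    def test_moving_hit_up_never_decreases_es_with_positive_scores(self, rng):
        ranked = make_ranked(descending(40))
        genes = ranked.gene_ids
        for seed in range(10):
            r = np.random.default_rng(seed)
            others = sorted(r.choice(range(5, 40), size=4, replace=False))
            for lower, higher in [(20, 10), (15, 6), (30, 2)]:
                if lower in others or higher in others:
                    continue
                es_low = enrichment_score(
                    ranked, GeneSet("s", {genes[i] for i in others + [lower]}), 1.0
                ).es
                es_high = enrichment_score(
                    ranked, GeneSet("s", {genes[i] for i in others + [higher]}), 1.0
                ).es
                assert es_high >= es_low - 1e-12

    def test_leading_edge_is_subset_of_present_members(self, rng):
        ranked = make_ranked(rng.standard_normal(50))
        hits = set(rng.choice(ranked.gene_ids, size=8, replace=False))
        res = enrichment_score(ranked, GeneSet("s", hits))
        assert res.leading_edge <= hits
        assert res.leading_edge  # extremum hit always included

    def test_no_overlap_rejected(self):
        ranked = make_ranked(descending(5))
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(ranked, GeneSet("s", {"absent1", "absent2"}))

    def test_set_covering_whole_list_rejected(self):
        ranked = make_ranked(descending(5))
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, GeneSet("s", set(ranked.gene_ids)))

    def test_absent_members_dropped_with_warning(self):
        ranked = make_ranked(descending(10))
        with pytest.warns(UserWarning, match="absent"):
            res = enrichment_score(
                ranked, GeneSet("s", {ranked.gene_ids[0], "missing"})
            )
        assert res.n_members == 1


class TestNormalizeES:
    def test_observed_more_extreme_than_all_permutations(self):
        """A set occupying the very top of a steep list beats every
        permutation, so p hits the pseudo-count floor 1/(n_same+1)."""
        scores = np.concatenate([[100.0, 90.0, 80.0], descending(47, 0.01, 0.5)])
        ranked = make_ranked(scores)
        gs = GeneSet("top3", set(ranked.gene_ids[:3]))
        res = normalize_es(ranked, [gs], n_perm=99, seed=5)[0]
        assert res.p_value == pytest.approx(1.0 / (1 + 99), abs=0.02)
        assert res.nes > 1.0

    def test_duplicate_gene_set_gets_identical_nes(self, rng):
        ranked = make_ranked(rng.standard_normal(100))
        members = set(rng.choice(ranked.gene_ids, size=10, replace=False))
        a, b = GeneSet("a", members), GeneSet("b", members)
        res = normalize_es(ranked, [a, b], n_perm=50, seed=3)
        assert res[0].nes == pytest.approx(res[1].nes)
        assert res[0].p_value == pytest.approx(res[1].p_value)

    def test_seeded_reproducibility(self, rng):
        ranked = make_ranked(rng.standard_normal(80))
        gs = GeneSet("s", set(ranked.gene_ids[10:20]))
        r1 = normalize_es(ranked, [gs], n_perm=50, seed=11)[0]
        r2 = normalize_es(ranked, [gs], n_perm=50, seed=11)[0]
        assert (r1.nes, r1.p_value, r1.fdr_q) == (r2.nes, r2.p_value, r2.fdr_q)

    def test_fdr_q_within_unit_interval(self, rng):
        ranked = make_ranked(rng.standard_normal(120))
        sets = [
            GeneSet(f"s{i}", set(rng.choice(ranked.gene_ids, 12, replace=False)))
            for i in range(6)
        ]
        for res in normalize_es(ranked, sets, n_perm=60, seed=2):
            assert 0.0 <= res.fdr_q <= 1.0
            assert 0.0 < res.p_value <= 1.0

    def test_phenotype_scheme_runs_and_is_seeded(self):
        import pandas as pd

        from coexnet.ranking import ExpressionMatrix, rank_by_class

        rng = np.random.default_rng(7)
        values = pd.DataFrame(
            rng.standard_normal((40, 6)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(6)],
        )
        expr = ExpressionMatrix(values=values, classes=["c"] * 3 + ["t"] * 3)
        ranked = rank_by_class(expr)
        gs = GeneSet("s", {f"g{i}" for i in range(5)})
        r1 = normalize_es(ranked, [gs], n_perm=20, scheme="phenotype",
                          seed=1, expr=expr)[0]
        r2 = normalize_es(ranked, [gs], n_perm=20, scheme="phenotype",
                          seed=1, expr=expr)[0]
        assert r1.p_value == r2.p_value

    def test_too_few_permutations_rejected(self, rng):
        ranked = make_ranked(rng.standard_normal(30))
        gs = GeneSet("s", set(ranked.gene_ids[:4]))
        with pytest.raises(ValueError, match="n_perm"):
            normalize_es(ranked, [gs], n_perm=5)
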