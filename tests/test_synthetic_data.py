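import itertools
import math

import numpy as np
import pytest
from scipy import stats

from coexnet.enrichment import read_gmt, write_gmt
from coexnet.network_build import filter_by_confidence
from coexnet.ranking import rank_by_index_gene, top_k
from coexnet.synthetic_data import (
    SimulationTruth,
    simulate_annotations,
    simulate_expression,
    simulate_interactions,
    write_bundle,
)


class TestSimulateExpression:
    def test_shape_and_class_labels(self):
        expr, truth = simulate_expression(n_genes=200, n_per_group=3, seed=1)
        assert expr.values.shape == (200, 6)
        assert expr.classes == ["control"] * 3 + ["stress"] * 3
        assert truth.index_gene in expr.gene_ids

    def test_zero_noise_full_rho_gives_exact_plus_one_correlation(self):
        expr, truth = simulate_expression(
            n_genes=100, n_per_group=3, pos_size=10, neg_size=10,
            rho=1.0, noise_sd=0.0, seed=7,
        )
        X = expr.values
        idx = X.loc[truth.index_gene]
        for g in truth.pos_module:
            r = np.corrcoef(X.loc[g], idx)[0, 1]
            assert r == pytest.approx(1.0)

    def test_zero_noise_full_rho_gives_exact_minus_one_for_neg_module(self):
        expr, truth = simulate_expression(
            n_genes=100, n_per_group=3, pos_size=10, neg_size=10,
            rho=1.0, noise_sd=0.0, seed=7,
        )
        X = expr.values
        idx = X.loc[truth.index_gene]
        for g in truth.neg_module:
            assert np.corrcoef(X.loc[g], idx)[0, 1] == pytest.approx(-1.0)

    def test_module_recovery_by_correlation_ranking(self):
        """With informative sample size, correlation ranking recovers the
        planted module nearly perfectly; at the 3-per-group study design
        small-sample correlation noise caps recovery (frozen regression)."""
        expr, truth = simulate_expression(
            n_genes=1000, n_per_group=10, pos_size=50, rho=0.9,
            noise_sd=1.0, seed=11,
        )
        ranked = rank_by_index_gene(expr, truth.index_gene)
        hits = len(top_k(ranked, 50).members & truth.pos_module)
        assert hits >= 45

        expr3, truth3 = simulate_expression(
            n_genes=1000, n_per_group=3, pos_size=50, rho=0.9,
            noise_sd=1.0, seed=11,
        )
        ranked3 = rank_by_index_gene(expr3, truth3.index_gene)
        hits3 = len(top_k(ranked3, 50).members & truth3.pos_module)
        assert hits3 == 38  # small-sample ceiling, frozen at this seed

    def test_de_genes_shift_in_stress_class(self):
        expr, truth = simulate_expression(
            n_genes=300, effect_size=5.0, noise_sd=0.5, seed=3
        )
        X = expr.values
        cls = np.asarray(expr.classes)
        up = X.loc[sorted(truth.de_up)]
        diff = up.loc[:, cls == "stress"].mean(1) - up.loc[:, cls == "control"].mean(1)
        assert (diff > 2.0).all()

    def test_identical_seed_gives_byte_identical_output(self, tmp_path):
        a, _ = simulate_expression(n_genes=150, seed=9)
        b, _ = simulate_expression(n_genes=150, seed=9)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_tsv(pa)
        b.to_tsv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_expression_tsv_round_trip(self, tmp_path):
        expr, _ = simulate_expression(n_genes=150, seed=2)
        p = tmp_path / "e.tsv"
        expr.to_tsv(p)
        from coexnet.ranking import ExpressionMatrix

        back = ExpressionMatrix.from_tsv(p)
        assert back.gene_ids == expr.gene_ids
        assert back.classes == expr.classes
        np.testing.assert_allclose(back.values.values, expr.values.values, rtol=1e-9)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_genes=50, pos_size=30, neg_size=30), "n_genes"),
            (dict(n_per_group=1), "n_per_group"),
            (dict(rho=1.5), "rho"),
            (dict(noise_sd=-0.1), "noise_sd"),
        ],
    )
    def test_invalid_parameters_rejected_naming_parameter(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            simulate_expression(**kwargs)

    def test_truth_invariants(self):
        _, truth = simulate_expression(n_genes=300, seed=5)
        assert not truth.pos_module & truth.neg_module
        assert truth.index_gene not in truth.pos_module | truth.neg_module


class TestSimulateInteractions:
    GENES = [f"g{i:02d}" for i in range(40)]

    def test_edge_count_forced_by_construction(self):
        edges, truth = simulate_interactions(
            self.GENES, hub_gene="g00", n_cliques=2,
            clique_size_range=(4, 4), decoy_fraction=0.0, seed=1,
        )
        # 2*C(4,2) clique edges + one hub attachment per clique
        assert len(edges) == 2 * math.comb(4, 2) + 2

    def test_cliques_fully_connected_internally(self):
        edges, truth = simulate_interactions(
            self.GENES, hub_gene="g00", n_cliques=3, decoy_fraction=0.2, seed=4
        )
        keys = {e.key for e in edges}
        for clique in truth.planted_cliques:
            for a, b in itertools.combinations(sorted(clique), 2):
                assert (a, b) in keys

    def test_hub_attains_top_degree(self):
        edges, truth = simulate_interactions(
            self.GENES, hub_gene="g00", n_cliques=6,
            clique_size_range=(4, 5), decoy_fraction=0.0, seed=2,
        )
        deg = {}
        for e in edges:
            deg[e.gene_a] = deg.get(e.gene_a, 0) + 1
            deg[e.gene_b] = deg.get(e.gene_b, 0) + 1
        assert deg["g00"] == max(deg.values())

    def test_point_mass_confidence_all_pass_filter(self):
        edges, _ = simulate_interactions(
            self.GENES, hub_gene="g00", n_cliques=2,
            conf_true=1.0, decoy_fraction=0.0, seed=3,
        )
        assert len(filter_by_confidence(edges, 0.7)) == len(edges)

    def test_filter_removes_exactly_the_decoys(self):
        edges, truth = simulate_interactions(
            self.GENES, hub_gene="g00", n_cliques=2,
            conf_true=0.9, conf_decoy=0.2, decoy_fraction=0.4, seed=8,
        )
        kept = {e.key for e in filter_by_confidence(edges, 0.7)}
        assert kept == truth.true_edges
        assert truth.decoy_edges and not kept & truth.decoy_edges

    def test_no_self_loops_or_duplicate_keys(self):
        edges, _ = simulate_interactions(
            self.GENES, hub_gene="g00", n_cliques=4, decoy_fraction=0.3, seed=5
        )
        keys = [e.key for e in edges]
        assert len(keys) == len(set(keys))
        assert all(a != b for a, b in keys)

    def test_missing_hub_rejected(self):
        with pytest.raises(ValueError, match="hub"):
            simulate_interactions(self.GENES, hub_gene="nope")

    def test_determinism(self):
        a, _ = simulate_interactions(self.GENES, "g00", n_cliques=3, seed=6)
        b, _ = simulate_interactions(self.GENES, "g00", n_cliques=3, seed=6)
        assert a == b


class TestSimulateAnnotations:
    @staticmethod
    def _truth(seed=0):
        genes = [f"g{i:02d}" for i in range(60)]
        _, truth = simulate_interactions(
            genes, hub_gene="g00", n_cliques=3,
            clique_size_range=(5, 5), decoy_fraction=0.0, seed=seed,
        )
        return truth

    def test_uncontaminated_term_equals_its_clique(self):
        truth = self._truth()
        coll = simulate_annotations(truth, n_background_terms=5, contamination=0, seed=1)
        planted = [s for s in coll if s.name.startswith("planted")]
        assert {s.members for s in planted} == set(map(frozenset, truth.planted_cliques))

    def test_no_term_exceeds_universe(self):
        truth = self._truth()
        coll = simulate_annotations(truth, n_background_terms=30, seed=2)
        for s in coll:
            assert s.members <= coll.universe

    def test_planted_term_achieves_smallest_hypergeometric_p(self):
        """With a clique as the query, exact hypergeometric arithmetic over
        every term puts the matching planted term first."""
        truth = self._truth(seed=3)
        coll = simulate_annotations(truth, n_background_terms=15, seed=3)
        clique = set(truth.planted_cliques[0])
        M = len(coll.universe)
        p_by_term = {}
        for term in coll:
            k = len(clique & term.members)
            p_by_term[term.name] = stats.hypergeom.sf(
                k - 1, M, len(term.members), len(clique)
            )
        best = min(p_by_term, key=p_by_term.get)
        match = [
            s.name for s in coll
            if s.name.startswith("planted") and s.members == frozenset(clique)
        ]
        assert best in match

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="clique"):
            simulate_annotations(SimulationTruth(universe=frozenset({"a"})), seed=0)

    def test_gmt_round_trip(self, tmp_path):
        truth = self._truth()
        coll = simulate_annotations(truth, n_background_terms=8, seed=5)
        p = tmp_path / "terms.gmt"
        write_gmt(coll, p)
        back = read_gmt(p)
        assert {s.name: s.members for s in back} == {s.name: s.members for s in coll}


def test_write_bundle_produces_consistent_files(tmp_path):
    bundle = write_bundle(tmp_path / "b", n_genes=200, n_cliques=4, seed=13)
    from coexnet.network_build import read_edges
    from coexnet.ranking import ExpressionMatrix

    expr = ExpressionMatrix.from_tsv(bundle["expression"])
    edges = read_edges(bundle["edges"])
    coll = read_gmt(bundle["gmt"])
    assert expr.values.shape[0] == 200
    assert edges and coll
    assert bundle["index_gene"] in expr.gene_ids
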