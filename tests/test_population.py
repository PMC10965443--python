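"""Population statistics: degrees, comparisons, trends, targeting, GSEA."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from scorpion.io import Network
from scorpion.population import (
    compare_networks,
    degrees,
    differential_targeting,
    edge_trend,
    preranked_gsea,
    tf_association,
)


def net_from(weights, tfs=None, genes=None):
    weights = np.asarray(weights, dtype=float)
    tfs = tfs or [f"T{i}" for i in range(weights.shape[0])]
    genes = genes or [f"g{j}" for j in range(weights.shape[1])]
    return Network(weights, tfs, genes)


def bh_bruteforce(p):
    """Step-up BH oracle, straight from the definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * n / rank)
        adj[idx] = running_min
    return adj


class TestDegrees:
    def test_worked_example(self):
        net = net_from([[1, 2], [3, 4]])
        np.testing.assert_array_equal(degrees(net, "indegree").to_numpy(), [4, 6])
        np.testing.assert_array_equal(degrees(net, "outdegree").to_numpy(), [3, 7])

    def test_zero_network(self):
        net = net_from(np.zeros((3, 5)))
        assert degrees(net, "indegree").sum() == 0
        assert degrees(net, "outdegree").sum() == 0

    def test_linearity(self, rng):
        W = rng.standard_normal((4, 7))
        total = degrees(net_from(W), "outdegree") + degrees(net_from(-W), "outdegree")
        np.testing.assert_allclose(total.to_numpy(), 0, atol=1e-12)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError):
            degrees(net_from([[1.0]]), "betweenness")


class TestCompareNetworks:
    def test_identical_networks(self, rng):
        net = net_from(rng.standard_normal((3, 10)))
        result = compare_networks(net, net, "T0")
        assert np.all(result.paired_deltas == 0)
        assert result.p_value == 1.0
        assert not result.outliers_up and not result.outliers_down
        assert result.spearman_rho == 1.0

    def test_antisymmetry(self, rng):
        a = net_from(rng.standard_normal((3, 10)))
        b = net_from(rng.standard_normal((3, 10)))
        ab = compare_networks(a, b, "T1")
        ba = compare_networks(b, a, "T1")
        np.testing.assert_allclose(ab.paired_deltas, -ba.paired_deltas)
        assert ab.mean_delta == pytest.approx(-ba.mean_delta)

    def test_outlier_fraction_matches_percentile_definition(self, rng):
        deltas = rng.standard_normal(1000)
        a = net_from(np.zeros((1, 1000)))
        b = net_from(deltas[None, :])
        result = compare_networks(a, b, "T0")
        n_out = len(result.outliers_up) + len(result.outliers_down)
        assert n_out == pytest.approx(0.05 * 1000, abs=2)
        assert set(result.outliers_up).isdisjoint(result.outliers_down)

    def test_gene_intersection_only(self):
        a = net_from([[1.0, 2.0, 3.0, 4.0]], genes=["g1", "g2", "g3", "g4"])
        b = net_from([[5.0, 2.0, 9.0]], genes=["g2", "g3", "g4"])
        result = compare_networks(a, b, "T0")
        assert list(result.genes) == ["g2", "g3", "g4"]
        np.testing.assert_array_equal(result.paired_deltas, [3.0, -1.0, 5.0])

    def test_missing_tf_names_network(self, rng):
        a = net_from(rng.standard_normal((2, 5)))
        b = Network(rng.standard_normal((2, 5)), ["X0", "X1"], [f"g{j}" for j in range(5)])
        with pytest.raises(ValueError, match="second"):
            compare_networks(a, b, "T0")

    def test_too_few_shared_genes_raises(self):
        a = net_from([[1.0, 2.0, 3.0]], genes=["g1", "g2", "g3"])
        b = net_from([[1.0, 2.0, 3.0]], genes=["g3", "g4", "g5"])
        with pytest.raises(ValueError, match="shared genes"):
            compare_networks(a, b, "T0")


class TestEdgeTrend:
    def test_perfect_linear_edge(self):
        nets = [net_from([[w]]) for w in (1.0, 2.0, 3.0, 4.0)]
        table = edge_trend(nets, [1, 2, 3, 4])
        row = table.iloc[0]
        assert row["beta"] == pytest.approx(1.0)
        assert row["p_value"] < 1e-12

    def test_constant_edge_gets_no_evidence_convention(self):
        nets = [net_from([[2.5]]) for _ in range(6)]
        table = edge_trend(nets, [1, 1, 2, 2, 3, 3])
        assert table.iloc[0]["beta"] == 0.0
        assert table.iloc[0]["p_value"] == 1.0

    def test_beta_matches_closed_form_on_random_edges(self, rng):
        stages = np.repeat([1, 2, 3, 4], 3)
        nets = [net_from(rng.standard_normal((10, 10))) for _ in stages]
        table = edge_trend(nets, stages)
        x = stages.astype(float)
        xc = x - x.mean()
        picks = rng.choice(len(table), 100, replace=False)
        for k in picks:
            tf, gene = table.iloc[k][["tf", "gene"]]
            y = np.array([n.to_frame().loc[tf, gene] for n in nets])
            beta_oracle = (xc @ (y - y.mean())) / (xc @ xc)
            assert table.iloc[k]["beta"] == pytest.approx(beta_oracle, abs=1e-12)

    def test_null_calibration(self, rng):
        stages = np.repeat([1, 2, 3, 4], 10)
        nets = [net_from(rng.standard_normal((50, 40))) for _ in stages]
        table = edge_trend(nets, stages)
        frac = (table["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        assert table["significant"].sum() <= 2

    def test_fdr_dominates_p(self, rng):
        stages = [1, 2, 3, 1, 2, 3]
        nets = [net_from(rng.standard_normal((5, 8))) for _ in stages]
        table = edge_trend(nets, stages)
        assert (table["fdr"] >= table["p_value"] - 1e-15).all()

    def test_single_stage_raises(self, rng):
        nets = [net_from(rng.standard_normal((2, 3))) for _ in range(4)]
        with pytest.raises(ValueError, match="single stage"):
            edge_trend(nets, [2, 2, 2, 2])


class TestTfAssociation:
    def test_sums_betas_per_tf(self):
        trend = pd.DataFrame(
            {
                "tf": ["A", "A", "B"],
                "gene": ["g1", "g2", "g1"],
                "beta": [0.5, -0.2, 1.0],
                "p_value": [0.01, 0.5, 0.9],
                "fdr": [0.03, 0.6, 0.9],
                "significant": [True, False, False],
            }
        )
        assoc = tf_association(trend)
        assert assoc["A"] == pytest.approx(0.3)
        assert assoc["B"] == pytest.approx(1.0)
        restricted = tf_association(trend, significant_only=True)
        assert restricted["A"] == pytest.approx(0.5)
        assert restricted["B"] == 0.0

    def test_linearity_in_beta(self, rng):
        trend = pd.DataFrame(
            {
                "tf": rng.choice(["A", "B", "C"], 30),
                "gene": [f"g{i}" for i in range(30)],
                "beta": rng.standard_normal(30),
                "p_value": rng.random(30),
                "fdr": rng.random(30),
                "significant": rng.random(30) < 0.2,
            }
        )
        doubled = trend.assign(beta=2 * trend["beta"])
        np.testing.assert_allclose(
            tf_association(doubled).to_numpy(), 2 * tf_association(trend).to_numpy()
        )

    def test_null_centered_at_zero(self, rng):
        stages = np.repeat([1, 2, 3, 4], 5)
        nets = [net_from(rng.standard_normal((20, 30))) for _ in stages]
        assoc = tf_association(edge_trend(nets, stages))
        assert abs(assoc.mean()) < 3 * assoc.std() / np.sqrt(len(assoc))


class TestDifferentialTargeting:
    def test_identical_groups_find_nothing(self, rng):
        base = [net_from(rng.standard_normal((6, 12))) for _ in range(4)]
        table = differential_targeting(base, [Network(n.weights, n.tf_ids, n.gene_ids) for n in base])
        assert (table["fdr"] >= 0.05).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_outdegree_shift_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = 50
        group_a = [net_from(rng.standard_normal((8, n_genes))) for _ in range(10)]
        group_b = []
        for _ in range(10):
            W = rng.standard_normal((8, n_genes))
            # shift TF 3's outdegree by +3 SD of the null outdegree
            W[3] += 3 * np.sqrt(n_genes) / n_genes
            group_b.append(net_from(W))
        table = differential_targeting(group_a, group_b)
        assert table.iloc[0]["tf"] == "T3"
        assert table.iloc[0]["fdr"] < 0.05

    def test_swapping_groups_flips_direction(self, rng):
        a = [net_from(rng.standard_normal((5, 9))) for _ in range(3)]
        b = [net_from(rng.standard_normal((5, 9))) for _ in range(3)]
        ab = differential_targeting(a, b).set_index("tf")
        ba = differential_targeting(b, a).set_index("tf")
        np.testing.assert_allclose(
            ab["p_value"].to_numpy(), ba.loc[ab.index, "p_value"].to_numpy()
        )
        np.testing.assert_array_equal(
            ab["direction"].to_numpy(), -ba.loc[ab.index, "direction"].to_numpy()
        )

    def test_small_group_raises(self, rng):
        nets = [net_from(rng.standard_normal((3, 5)))]
        with pytest.raises(ValueError, match=">= 2"):
            differential_targeting(nets, nets * 3)


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("seed", range(10))
    def test_statsmodels_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 200))
        adj = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, bh_bruteforce(p), atol=1e-12)


class TestPrerankedGsea:
    def make_ranking(self, rng, n=500):
        return pd.Series(
            rng.standard_normal(n), index=[f"g{i}" for i in range(n)]
        )

    def test_top_of_ranking_set_is_enriched(self, rng):
        ranking = self.make_ranking(rng).sort_values(ascending=False)
        top = list(ranking.index[:20])
        results = preranked_gsea(ranking, {"top": top}, n_perm=1000, seed=0)
        r = results[0]
        assert r.es > 0 and r.nes > 0
        assert r.p_value < 0.05
        assert set(r.leading_edge) <= set(top)

    def test_negating_ranking_negates_es(self, rng):
        ranking = self.make_ranking(rng, n=100)
        sets = {"s": [f"g{i}" for i in range(0, 40, 2)]}
        plus = preranked_gsea(ranking, sets, n_perm=50, seed=1)[0]
        minus = preranked_gsea(-ranking, sets, n_perm=50, seed=1)[0]
        assert plus.es == pytest.approx(-minus.es, abs=1e-12)

    def test_null_p_values_approximately_uniform(self):
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            ranking = pd.Series(
                rng.standard_normal(300), index=[f"g{i}" for i in range(300)]
            )
            members = list(rng.choice(ranking.index, 25, replace=False))
            res = preranked_gsea(ranking, {"rand": members}, n_perm=200, seed=rep)
            pvals.append(res[0].p_value)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_small_set_skipped_with_warning(self, rng):
        ranking = self.make_ranking(rng, n=50)
        with pytest.warns(UserWarning, match="skipped"):
            results = preranked_gsea(ranking, {"tiny": ["g1", "g2"]}, n_perm=20, seed=0)
        assert results == []

    def test_deterministic_given_seed(self, rng):
        ranking = self.make_ranking(rng, n=120)
        sets = {"s": [f"g{i}" for i in range(0, 120, 5)]}
        a = preranked_gsea(ranking, sets, n_perm=100, seed=9)[0]
        b = preranked_gsea(ranking, sets, n_perm=100, seed=9)[0]
        assert (a.es, a.nes, a.p_value) == (b.es, b.nes, b.p_value)

    def test_short_ranking_raises(self):
        ranking = pd.Series([1.0] * 5, index=list("abcde"))
        with pytest.raises(ValueError, match=">= 10"):
            preranked_gsea(ranking, {"s": ["a", "b", "c"]})
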