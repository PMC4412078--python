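import numpy as np
import pandas as pd
import pytest

import netentropy as ne
from netentropy.cohort import (
    Cohort,
    degree_bin_summary,
    expression_degree_correlation,
    gene_differentials,
    hub_skew_test,
    neighbor_rank_centile,
    per_sample_entropy,
    permutation_control,
    top_k_by_foldchange,
)
from netentropy.graphs import NetworkInputError


def identical_cohort(net, n=4, value_seed=0):
    """Same expression drawn once, repeated across all samples of both groups."""
    rng = np.random.default_rng(value_seed)
    e = rng.uniform(2, 16, net.V)
    cols = {f"A{i}": e for i in range(n)} | {f"B{i}": e for i in range(n)}
    expr = pd.DataFrame(cols, index=list(net.node_ids))
    return Cohort(expr, pd.Series({c: c[0] for c in cols}))


@pytest.fixture(scope="module")
def ba_net():
    return ne.generate_scale_free(300, 6, seed=21)


class TestCohortValidation:
    def test_small_group_rejected(self, ba_net):
        expr = pd.DataFrame(
            np.full((ba_net.V, 3), 5.0),
            index=list(ba_net.node_ids),
            columns=["A1", "A2", "B1"],
        )
        with pytest.raises(NetworkInputError):
            Cohort(expr, pd.Series({"A1": "A", "A2": "A", "B1": "B"}))

    def test_missing_label_rejected(self, ba_net):
        expr = pd.DataFrame(
            np.full((ba_net.V, 4), 5.0),
            index=list(ba_net.node_ids),
            columns=["A1", "A2", "B1", "B2"],
        )
        with pytest.raises(NetworkInputError):
            Cohort(expr, pd.Series({"A1": "A", "A2": "A", "B1": "B"}))


class TestPerSampleEntropy:
    def test_identical_groups_show_no_signal(self, ba_net):
        cohort = identical_cohort(ba_net)
        sr, stats = per_sample_entropy(cohort, ba_net)
        assert sr.SR.nunique() == 1
        assert stats["p_value"] > 0.05
        assert stats["auc"] == pytest.approx(0.5)

    def test_hub_up_cohort_separates_groups(self, small_cohort):
        net, cohort, _ = small_cohort
        _, stats = per_sample_entropy(cohort, net)
        assert stats["p_value"] < 0.05
        assert stats["median_B"] > stats["median_A"]

    def test_label_swap_flips_the_tail(self, small_cohort):
        net, cohort, _ = small_cohort
        _, stats = per_sample_entropy(cohort, net)
        swapped = Cohort(
            cohort.expression, cohort.groups.map({"A": "B", "B": "A"})
        )
        _, stats_sw = per_sample_entropy(swapped, net)
        # one-tailed p flips (up to the tie/continuity convention)
        assert stats_sw["p_value"] == pytest.approx(1 - stats["p_value"], abs=0.02)
        assert stats_sw["auc"] == pytest.approx(1 - stats["auc"], abs=1e-12)


class TestPermutationControl:
    def test_permutation_preserves_each_samples_multiset(self, small_cohort):
        net, cohort, _ = small_cohort
        rng_seed = 5
        expr = cohort.expression.loc[list(net.node_ids)]
        permuted = pd.DataFrame(
            expr.to_numpy()[np.random.default_rng(rng_seed).permutation(net.V)],
            index=expr.index, columns=expr.columns,
        )
        for s in expr.columns[:3]:
            assert sorted(expr[s]) == sorted(permuted[s])

    def test_identity_permutation_leaves_sr_unchanged(self, ba_net):
        cohort = identical_cohort(ba_net)
        sr0, _ = per_sample_entropy(cohort, ba_net)
        # degenerate path: permuting identical profiles of an identical cohort
        # still changes placement, so instead check a direct recompute
        sr1, _ = per_sample_entropy(cohort, ba_net)
        pd.testing.assert_frame_equal(sr0, sr1)

    def test_permutation_shrinks_the_group_difference(self, small_cohort):
        net, cohort, _ = small_cohort
        _, stats = per_sample_entropy(cohort, net)
        observed = abs(stats["median_B"] - stats["median_A"])
        wins = 0
        for seed in range(10):
            _, pstats = permutation_control(cohort, net, seed)
            wins += abs(pstats["median_B"] - pstats["median_A"]) < observed
        assert wins >= 8


class TestGeneDifferentials:
    def test_identical_groups_vanish(self, ba_net):
        diffs = gene_differentials(identical_cohort(ba_net), ba_net)
        for col in ("dE", "dLS", "dpi", "dLSR"):
            np.testing.assert_allclose(diffs[col], 0.0, atol=1e-14)

    def test_dpi_sums_to_zero(self, small_cohort):
        net, cohort, _ = small_cohort
        diffs = gene_differentials(cohort, net)
        assert diffs["dpi"].sum() == pytest.approx(0.0, abs=1e-10)

    def test_hub_bins_gain_more_entropy_rate_than_leaf_bins(self, small_cohort):
        net, cohort, _ = small_cohort
        diffs = gene_differentials(cohort, net)
        bins = degree_bin_summary(diffs)
        assert bins["dLSR_mean"].iloc[-1] > bins["dLSR_mean"].iloc[0]

    def test_ground_truth_shift_recovered(self, small_cohort):
        net, cohort, truth = small_cohort
        diffs = gene_differentials(cohort, net)
        assert np.corrcoef(diffs["dE"], truth)[0, 1] > 0.9


class TestHubSkew:
    def test_identical_groups_not_significant(self, ba_net):
        diffs = gene_differentials(identical_cohort(ba_net), ba_net)
        with pytest.warns(UserWarning):  # degree 316 exceeds this net's max
            res = hub_skew_test(diffs)
        assert res["p_value"] > 0.5

    def test_hub_up_cohort_is_skewed(self, small_cohort):
        net, cohort, _ = small_cohort
        diffs = gene_differentials(cohort, net)
        with pytest.warns(UserWarning):
            res = hub_skew_test(diffs)
        assert res["p_value"] < 0.05
        assert res["mean_dE_hubs"] > res["mean_dE_leaves"]

    def test_fallback_threshold_reported(self, small_cohort):
        net, cohort, _ = small_cohort
        diffs = gene_differentials(cohort, net)
        with pytest.warns(UserWarning, match="top-decile"):
            res = hub_skew_test(diffs, hub_threshold=10**6)
        assert res["hub_threshold"] <= diffs["degree"].max()


class TestDegreeCorrelation:
    def test_perfect_monotone(self):
        df = pd.DataFrame({"degree": np.arange(1, 51), "dE": np.arange(1, 51.0)})
        assert expression_degree_correlation(df)["rho"] == pytest.approx(1.0)

    def test_null_is_near_zero(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {"degree": rng.integers(1, 100, 5000), "dE": rng.normal(size=5000)}
        )
        assert abs(expression_degree_correlation(df)["rho"]) < 0.1

    def test_constant_input_rejected(self):
        df = pd.DataFrame({"degree": np.arange(1, 21), "dE": np.ones(20)})
        with pytest.raises(NetworkInputError):
            expression_degree_correlation(df)


class TestNeighborCentile:
    def test_uniquely_maximal_hub_ranks_first_everywhere(self):
        # hub connected to 60 mid-degree nodes, each with >=50 neighbours
        import networkx as nx

        g = nx.complete_graph(60)
        g.add_edges_from(("hub", i) for i in range(60))
        net = ne.Network.from_networkx(g)
        de = pd.Series(0.0, index=list(net.node_ids))
        de["hub"] = 5.0
        diffs = pd.DataFrame({"dE": de, "degree": net.degrees})
        res = neighbor_rank_centile(net, diffs, "hub")
        assert res["fraction_top_centile"] == 1.0

    def test_tied_differentials_rank_by_node_id(self, star4):
        diffs = pd.DataFrame(
            {"dE": 0.0, "degree": star4.degrees}, index=list(star4.node_ids)
        )
        res = neighbor_rank_centile(star4, diffs, "c", top_centile=1.0)
        # every leaf sees only the centre, centile 1.0 for all -> deterministic
        assert res["fraction_top_centile"] == 1.0
        assert all(v == 1.0 for v in res["centiles"].values())

    def test_fixture_hub_dominates_its_neighborhood(self, small_cohort):
        # centile feasibility: rank 1 in a degree-m neighbourhood is centile
        # 1/m, so the cut must exceed 1/min-degree (here m=3) to be meetable
        net, cohort, _ = small_cohort
        diffs = gene_differentials(cohort, net)
        hub = diffs["dE"].idxmax()
        res = neighbor_rank_centile(net, diffs, hub, top_centile=0.34)
        assert res["fraction_top_centile"] > 0.5


class TestTopK:
    def test_identical_groups_fall_back_to_id_order(self, ba_net):
        cohort = identical_cohort(ba_net)
        top = top_k_by_foldchange(cohort, 10)
        assert list(top.index) == sorted(net_id for net_id in ba_net.node_ids)[:10]

    def test_k_equals_gene_count(self, small_cohort):
        net, cohort, _ = small_cohort
        top = top_k_by_foldchange(cohort, len(cohort.expression))
        assert len(top) == len(cohort.expression)

    def test_overexpressed_top_genes_sit_on_higher_degree_nodes(self, small_cohort):
        net, cohort, _ = small_cohort
        top = top_k_by_foldchange(cohort, 100)
        k = pd.Series(net.degrees, index=list(net.node_ids))
        up = k[top.index[top.dE > 0]]
        down = k[top.index[top.dE < 0]]
        assert up.mean() > down.mean()

    def test_k_too_large_rejected(self, small_cohort):
        net, cohort, _ = small_cohort
        with pytest.raises(NetworkInputError):
            top_k_by_foldchange(cohort, net.V + 1)


class TestFig3BPattern:
    def test_top_gene_perturbations_from_mean_normal_profile(self, small_cohort):
        """Perturbing top fold-change genes from the mean group-A profile:
        SR increases concentrate among high-degree over-expressed genes."""
        net, cohort, _ = small_cohort
        mean_a = cohort.expression[cohort.samples("A")].mean(axis=1)
        top = top_k_by_foldchange(cohort, 60)
        k = pd.Series(net.degrees, index=list(net.node_ids))
        recs = []
        for gene, row in top.iterrows():
            rec = ne.perturb_profile(net, mean_a, gene, row.dE)
            recs.append((gene, k[gene], row.dE, rec.delta_SR))
        df = pd.DataFrame(recs, columns=["gene", "k", "dE", "dSR"])
        gainers = df[df.dSR > 0]
        others = df[df.dSR <= 0]
        assert not gainers.empty
        assert gainers.k.mean() > others.k.mean()
        # the strongest entropy gains come from over-expressed genes
        assert df.loc[df.dSR.idxmax(), "dE"] > 0


class TestCohortModel:
    def test_fit_and_summary(self, small_cohort):
        net, cohort, _ = small_cohort
        res = ne.CohortEntropy(net, cohort).fit()
        assert res.test["p_value"] < 0.05
        text = res.summary()
        assert "AUC" in text and "Spearman" in text
        assert res.top_hub() in net.node_ids
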