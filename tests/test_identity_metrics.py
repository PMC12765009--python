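import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hootid import (
    anova_decomposition,
    calc_bid,
    calc_ds,
    calc_hs,
    calc_ivs,
    calc_wid,
    individual_variation,
    pca_scores,
    signatures_from_hs,
    standardize,
    table_to_features,
)
from hootid.synthetic import SimConfig, simulate_population

AB = (np.array([0.0, 2.0, 4.0, 6.0]), np.array(["A", "A", "B", "B"]))


class TestAnovaDecomposition:
    def test_hand_example(self):
        dec = anova_decomposition(*AB)
        assert dec.ss_total == pytest.approx(20.0)
        assert dec.ss_within == pytest.approx(4.0)
        assert dec.ss_among == pytest.approx(16.0)
        assert dec.f_stat == pytest.approx(8.0)
        assert dec.p_value == pytest.approx(0.10557, abs=1e-4)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=24)
        labels = np.repeat(list("abcd"), 6)
        dec = anova_decomposition(x, labels)
        ref = stats.f_oneway(*(x[labels == g] for g in "abcd"))
        assert dec.f_stat == pytest.approx(ref.statistic, rel=1e-10)
        assert dec.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_no_between_signal(self):
        dec = anova_decomposition([0.0, 2.0, 0.0, 2.0], ["A", "A", "B", "B"])
        assert dec.ss_among == pytest.approx(0.0)
        assert dec.f_stat == 0.0

    def test_all_equal_is_degenerate_not_nan(self):
        dec = anova_decomposition([1.0] * 6, ["A", "A", "A", "B", "B", "B"])
        assert dec.ss_total == 0.0 and dec.f_stat == 0.0 and dec.p_value == 1.0

    def test_single_call_group_rejected(self):
        with pytest.raises(ValueError, match="B"):
            anova_decomposition([0.0, 1.0, 2.0], ["A", "A", "B"])


class TestHS:
    def test_one_component_hand_value(self):
        res = calc_hs(AB[0][:, None], AB[1], variant="all")
        assert res.hs_all == pytest.approx(0.5 * np.log2(20.0 / 4.0), abs=1e-6)

    def test_zero_information_when_groups_identical(self):
        res = calc_hs(np.array([0.0, 2.0, 0.0, 2.0])[:, None],
                      ["A", "A", "B", "B"], variant="all")
        assert res.hs_all == pytest.approx(0.0)

    def test_significant_sum_bounded_by_total(self, sim_scores):
        res = calc_hs(sim_scores)
        assert res.hs_significant <= res.hs_all + 1e-12
        assert res.hs_selected == res.hs_significant
        assert np.all(res.per_component_hs >= -1e-12)

    def test_ms_ratio_estimator_differs_but_tracks(self, sim_scores):
        ss = calc_hs(sim_scores, variant="all", estimator="ss_ratio")
        ms = calc_hs(sim_scores, variant="all", estimator="ms_ratio")
        # df correction shrinks the ratio slightly for k << N
        assert ms.hs_all < ss.hs_all
        assert ms.hs_all == pytest.approx(ss.hs_all, rel=0.25)

    def test_hs_monotone_in_total_variation(self):
        # with ss_within fixed, growing among-individual spread grows HS
        values = []
        for gap in (2.0, 4.0, 8.0):
            x = np.array([0.0, 2.0, gap, gap + 2.0])[:, None]
            values.append(calc_hs(x, ["A", "A", "B", "B"], variant="all").hs_all)
        assert values[0] < values[1] < values[2]

    def test_duplicated_calls_are_an_error(self):
        x = np.array([1.0, 1.0, 5.0, 5.0])[:, None]
        with pytest.raises(ValueError, match="within"):
            calc_hs(x, ["A", "A", "B", "B"])


class TestSignatures:
    @pytest.mark.parametrize("hs,expected", [
        (6.38, 83), (4.96, 31), (5.29, 39), (3.98, 15), (0.0, 1),
    ])
    def test_signature_capacity_is_floor_of_power(self, hs, expected):
        assert signatures_from_hs(hs) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            signatures_from_hs(-0.1)


class TestDS:
    def test_separable_clusters_classify_perfectly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, size=(10, 3))
        b = rng.normal(100.0, 1.0, size=(10, 3))
        labels = ["A"] * 10 + ["B"] * 10
        res = calc_ds(np.vstack([a, b]), labels)
        assert res.ds_percent == 100.0
        assert res.chance_percent == 50.0
        assert res.ivs == 2.0
        assert np.all(res.confusion.sum(axis=1) == 10)

    def test_null_simulation_near_chance(self):
        # no between-individual variance: LOO accuracy ~ 100/n_individuals
        values = []
        for seed in range(4):
            cfg = SimConfig(n_individuals=10, calls_per_individual=25,
                            sigma_b=0.0, sigma_w=np.array([60.0] * 10 + [0.04]),
                            seed=seed)
            table = simulate_population(cfg).table
            ps = pca_scores(standardize(table_to_features(table)))
            values.append(calc_ds(ps).ds_percent)
        assert np.mean(values) == pytest.approx(10.0, abs=3.0)

    def test_label_permutation_restores_chance(self):
        cfg = SimConfig(n_individuals=10, calls_per_individual=25, seed=11)
        ps = pca_scores(standardize(table_to_features(simulate_population(cfg).table)))
        assert calc_ds(ps).ds_percent > 50.0  # informative before shuffling
        rng = np.random.default_rng(1)
        values = [calc_ds(ps.values(), rng.permutation(ps.labels)).ds_percent
                  for _ in range(3)]
        assert np.mean(values) == pytest.approx(10.0, abs=3.0)

    def test_uniform_priors_supported(self, sim_scores):
        res = calc_ds(sim_scores, priors="uniform")
        assert 0.0 <= res.ds_percent <= 100.0

    def test_singular_pooled_covariance_advises_truncation(self):
        x = np.repeat(np.arange(8.0)[:, None], 2, axis=1)  # rank-1 features
        labels = np.repeat(["A", "B", "C", "D"], 2)
        with pytest.raises(ValueError, match="n_components"):
            calc_ds(x, labels)
        res = calc_ds(x, labels, n_components=1)
        assert res.n_individuals == 4


class TestIVS:
    @pytest.mark.parametrize("ds,n,expected", [
        (87.7, 22, 19.29), (79.4, 22, 17.47), (87.5, 14, 12.25),
        (78.9, 10, 7.89), (100.0, 10, 10.0),
    ])
    def test_printed_pairs(self, ds, n, expected):
        assert calc_ivs(ds, n) == pytest.approx(expected)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            calc_ivs(50.0, 1)


class TestWidBid:
    def test_wid_hand_example(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        (v,) = calc_wid(pts, ["A", "A"] )
        assert v.wid == pytest.approx(1.0)

    def test_identical_calls_have_zero_wid(self):
        (v,) = calc_wid(np.ones((3, 2)), ["A"] * 3)
        assert v.wid == 0.0

    def test_bid_hand_example(self):
        x = np.array([0.0, 2.0, 4.0, 6.0])[:, None]
        out = {v.individual_id: v.bid for v in calc_bid(x, ["A", "A", "B", "B"])}
        assert out == {"A": pytest.approx(2.0), "B": pytest.approx(2.0)}

    def test_population_centroid_is_call_weighted(self):
        # A has 4 calls at 0, B has 2 calls at 6: centroid 2, not 3
        x = np.array([0.0, 0.0, 0.0, 0.0, 6.0, 6.0])[:, None]
        out = {v.individual_id: v.bid for v in
               calc_bid(x, ["A"] * 4 + ["B"] * 2)}
        assert out["A"] == pytest.approx(2.0)
        assert out["B"] == pytest.approx(4.0)

    def test_rotation_invariance(self, sim_scores):
        X = sim_scores.values()
        labels = sim_scores.labels
        rng = np.random.default_rng(0)
        Q = np.linalg.qr(rng.normal(size=(X.shape[1],) * 2))[0]
        base = individual_variation(X, labels)
        rotated = individual_variation(X @ Q, labels)
        np.testing.assert_allclose(base.to_numpy(), rotated.to_numpy(), atol=1e-8)

    def test_scores_equal_standardized_features(self, small_table):
        # PCA is an orthogonal rotation, so WID/BID match either space
        feats = standardize(table_to_features(small_table))
        ps = pca_scores(feats)
        a = individual_variation(feats.to_numpy(), ps.labels)
        b = individual_variation(ps)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_single_call_individual_skipped_for_wid(self):
        x = np.array([0.0, 1.0, 5.0])[:, None]
        out = calc_wid(x, ["A", "A", "B"])
        assert [v.individual_id for v in out] == ["A"]
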