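"""Clustering, train/test split, Cox screening, K-means, log-rank."""

import json

import numpy as np
import pandas as pd
import pytest

from subspa import cohort
from subspa.errors import InputError

from conftest import grid_cox_coefficient, two_group_logrank_statistic


class TestUncenteredDistance:
    def test_identical_vectors_distance_zero(self):
        d = cohort.uncentered_correlation_distance(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors_distance_one(self):
        d = cohort.uncentered_correlation_distance(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d[0] == pytest.approx(1.0)

    def test_positive_rescaling_invariance(self):
        x = np.array([1.0, 3.0, 2.0])
        d = cohort.uncentered_correlation_distance(np.vstack([x, 7.5 * x]))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(InputError, match="all-zero"):
            cohort.uncentered_correlation_distance(np.array([[0.0, 0.0], [1.0, 2.0]]))


class TestHierarchicalCluster:
    def _profile(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(6, 1))
        left = base + rng.normal(scale=0.05, size=(6, 4))
        right = -base + rng.normal(scale=0.05, size=(6, 4))
        cols = [f"L{i}" for i in range(4)] + [f"R{i}" for i in range(4)]
        return pd.DataFrame(np.hstack([left, right]), columns=cols)

    def test_two_blocks_separate(self):
        result = cohort.hierarchical_cluster(self._profile(), axis="samples")
        cut = result.cut(2)
        left = {cut[f"L{i}"] for i in range(4)}
        right = {cut[f"R{i}"] for i in range(4)}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_cluster_invariant_to_per_sample_positive_rescaling(self):
        prof = self._profile()
        scaled = prof * np.abs(np.random.default_rng(1).normal(2, 0.3, size=prof.shape[1]))
        a = cohort.hierarchical_cluster(prof, axis="samples")
        b = cohort.hierarchical_cluster(scaled, axis="samples")
        assert a.leaf_order == b.leaf_order

    def test_newick_round_trip_leaf_set(self):
        result = cohort.hierarchical_cluster(self._profile(), axis="samples")
        nwk = cohort.to_newick(result)
        assert nwk.endswith(";")
        for label in result.labels:
            assert label in nwk

    def test_missing_values_rejected(self):
        prof = self._profile()
        prof.iloc[0, 0] = np.nan
        with pytest.raises(InputError, match="missing"):
            cohort.hierarchical_cluster(prof, axis="samples")


class TestSplitCohort:
    def _clinical(self, n):
        return pd.DataFrame(
            {"time": np.arange(1.0, n + 1), "event": [1, 0] * (n // 2)},
            index=[f"s{i}" for i in range(n)],
        )

    def test_equal_halves_and_partition(self):
        clin = self._clinical(10)
        train, test = cohort.split_cohort(clin.index, clin, seed=5)
        assert len(train) == len(test) == 5
        assert set(train) | set(test) == set(clin.index)
        assert set(train) & set(test) == set()

    def test_odd_count_extra_goes_to_train(self):
        clin = self._clinical(10).iloc[:9]
        train, test = cohort.split_cohort(clin.index, clin, seed=5)
        assert len(train) == 5 and len(test) == 4

    def test_same_seed_reproduces(self):
        clin = self._clinical(12)
        assert cohort.split_cohort(clin.index, clin, 7) == \
            cohort.split_cohort(clin.index, clin, 7)

    def test_samples_without_survival_excluded_with_warning(self):
        clin = self._clinical(8)
        with pytest.warns(UserWarning, match="lack survival"):
            train, test = cohort.split_cohort(list(clin.index) + ["ghost"], clin, 1)
        assert "ghost" not in train + test

    def test_stratified_split_balances_events(self):
        clin = self._clinical(20)
        train, test = cohort.split_cohort(clin.index, clin, 3, stratify_event=True)
        assert clin.loc[train, "event"].sum() == clin.loc[test, "event"].sum()


class TestUnivariateCox:
    def test_matches_grid_partial_likelihood_on_six_subjects(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=6)
        time = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        clin = pd.DataFrame({"time": time, "event": event},
                            index=[f"s{i}" for i in range(6)])
        res = cohort.univariate_cox(pd.Series(x, index=clin.index), clin)
        want = grid_cox_coefficient(x, time, event)
        assert res.coefficient == pytest.approx(want, abs=1e-4)
        assert res.hazard_ratio == pytest.approx(np.exp(res.coefficient))

    def test_negating_covariate_flips_sign(self):
        rng = np.random.default_rng(22)
        clin = pd.DataFrame(
            {"time": rng.exponential(10, size=40) + 0.1,
             "event": rng.integers(0, 2, size=40)},
            index=[f"s{i}" for i in range(40)],
        )
        x = pd.Series(rng.normal(size=40), index=clin.index)
        a = cohort.univariate_cox(x, clin)
        b = cohort.univariate_cox(-x, clin)
        assert a.coefficient == pytest.approx(-b.coefficient, abs=1e-6)
        assert a.wald_p == pytest.approx(b.wald_p, abs=1e-9)

    def test_constant_covariate_flagged(self):
        clin = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 0, 1]},
                            index=list("abcd"))
        res = cohort.univariate_cox(pd.Series(1.0, index=clin.index), clin)
        assert not res.available and "constant" in res.reason

    def test_too_few_events_flagged(self):
        clin = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 0, 0, 0]},
                            index=list("abcd"))
        res = cohort.univariate_cox(
            pd.Series([1.0, 2, 3, 4], index=clin.index), clin)
        assert not res.available


class TestSelectSignature:
    def _cox(self, pvals):
        return pd.DataFrame({
            "wald_p": pvals,
            "available": [True] * len(pvals),
            "coefficient": 0.0, "hazard_ratio": 1.0, "reason": "",
        }, index=[f"sub{i}" for i in range(len(pvals))])

    def test_threshold_boundary(self):
        out = cohort.select_signature(self._cox([0.009, 0.011]))
        assert out == ["sub0"]

    def test_empty_input(self):
        assert cohort.select_signature(self._cox([])) == []

    def test_threshold_one_keeps_all_available(self):
        assert len(cohort.select_signature(self._cox([0.5, 0.99]), 1.0)) == 2


class TestKmeansRiskGroups:
    def test_recovers_separated_blobs(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(30)
        a = rng.normal(0, 0.5, size=(3, 20))
        b = rng.normal(10, 0.5, size=(3, 20))
        prof = pd.DataFrame(np.hstack([a, b]),
                            columns=[f"s{i}" for i in range(40)])
        labels = cohort.kmeans_risk_groups(prof, k=2, seed=0)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels[prof.columns]) == 1.0

    def test_k_one_single_group(self):
        prof = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 6)),
                            columns=list("abcdef"))
        assert set(cohort.kmeans_risk_groups(prof, k=1, seed=0)) == {1}

    def test_deterministic_under_seed(self):
        prof = pd.DataFrame(np.random.default_rng(1).normal(size=(3, 12)),
                            columns=[f"s{i}" for i in range(12)])
        a = cohort.kmeans_risk_groups(prof, k=3, seed=4)
        b = cohort.kmeans_risk_groups(prof, k=3, seed=4)
        pd.testing.assert_series_equal(a, b)

    def test_k_exceeding_samples_rejected(self):
        prof = pd.DataFrame(np.ones((2, 3)), columns=list("abc"))
        with pytest.raises(InputError):
            cohort.kmeans_risk_groups(prof, k=4, seed=0)


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        clin = pd.DataFrame(
            {"time": [1.0, 2, 3, 1, 2, 3], "event": [1, 1, 0, 1, 1, 0]},
            index=list("abcdef"),
        )
        groups = pd.Series([1, 1, 1, 2, 2, 2], index=list("abcdef"))
        res = cohort.km_logrank(groups, clin)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_tabulated_two_group_statistic(self):
        clin = pd.DataFrame(
            {"time": [1.0, 2, 3, 4, 5, 6], "event": [1, 0, 1, 1, 0, 1]},
            index=list("abcdef"),
        )
        groups = pd.Series([1, 1, 1, 2, 2, 2], index=list("abcdef"))
        res = cohort.km_logrank(groups, clin)
        want = two_group_logrank_statistic(clin["time"], clin["event"], groups)
        assert res.statistic == pytest.approx(want, abs=1e-9)
        assert res.df == 1

    def test_df_is_groups_minus_one(self):
        rng = np.random.default_rng(31)
        n = 30
        clin = pd.DataFrame(
            {"time": rng.exponential(5, n) + 0.01, "event": rng.integers(0, 2, n)},
            index=[f"s{i}" for i in range(n)],
        )
        groups = pd.Series(rng.integers(0, 3, n), index=clin.index)
        assert cohort.km_logrank(groups, clin).df == 2

    def test_relabeling_groups_leaves_statistic_unchanged(self):
        clin = pd.DataFrame(
            {"time": [1.0, 2, 3, 4, 5, 6], "event": [1, 0, 1, 1, 0, 1]},
            index=list("abcdef"),
        )
        groups = pd.Series([1, 1, 1, 2, 2, 2], index=list("abcdef"))
        relabeled = groups.map({1: "x", 2: "w"})
        assert cohort.km_logrank(relabeled, clin).statistic == pytest.approx(
            cohort.km_logrank(groups, clin).statistic, abs=1e-12)

    def test_moving_post_event_censoring_later_leaves_statistic_unchanged(self):
        # the statistic depends on risk sets at event times only: a subject
        # already censored after the last event can be censored later still
        clin = pd.DataFrame(
            {"time": [1.0, 2, 3, 4, 5, 6, 8.0], "event": [1, 0, 1, 1, 0, 1, 0]},
            index=list("abcdefg"),
        )
        groups = pd.Series([1, 1, 1, 2, 2, 2, 1], index=list("abcdefg"))
        base = cohort.km_logrank(groups, clin).statistic
        clin2 = clin.copy()
        clin2.loc["g", "time"] = 999.0
        assert cohort.km_logrank(groups, clin2).statistic == pytest.approx(
            base, abs=1e-9)

    def test_single_group_rejected(self):
        clin = pd.DataFrame({"time": [1.0, 2], "event": [1, 1]}, index=list("ab"))
        with pytest.raises(InputError):
            cohort.km_logrank(pd.Series([1, 1], index=list("ab")), clin)


class TestPrognosisPipeline:
    def _cohort(self):
        rng = np.random.default_rng(40)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        prof = pd.DataFrame(rng.normal(size=(6, n)),
                            index=[f"path:x_{i}" for i in range(6)],
                            columns=samples)
        # make subpathway 0 strongly prognostic
        risk = prof.iloc[0].to_numpy()
        time = rng.exponential(1.0 / (0.05 * np.exp(1.5 * risk)))
        clin = pd.DataFrame({"time": np.maximum(time, 1e-3),
                             "event": np.ones(n, dtype=int)}, index=samples)
        return prof, clin

    def test_planted_prognostic_subpathway_selected(self):
        prof, clin = self._cohort()
        report = cohort.prognosis_pipeline(prof, clin, split_seed=3)
        assert "path:x_0" in report["signature"]
        assert report["logrank"] is not None

    def test_report_deterministic(self):
        prof, clin = self._cohort()
        a = cohort.prognosis_pipeline(prof, clin, split_seed=3)
        b = cohort.prognosis_pipeline(prof, clin, split_seed=3)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_enrichment_overlap_block(self):
        prof, clin = self._cohort()
        enr = pd.DataFrame(
            {"p": [1e-5] * 3 + [0.5] * 3,
             "p_adjusted": [1e-4] * 3 + [0.9] * 3},
            index=prof.index,
        )
        report = cohort.prognosis_pipeline(prof, clin, split_seed=3, enrichment=enr)
        assert set(report["enrichment_overlap"]) == {"0.01", "0.001", "0.0001"}
        for block in report["enrichment_overlap"].values():
            assert 0.0 <= block["p"] <= 1.0
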