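"""Taxa-signal correlation, FDR, classification, clustering, stage comparison."""
import numpy as np
import pandas as pd
import pytest

from conftest import oracle_complete_linkage
from quorumflow.community import (
    CommunitySignalSeries,
    CorrelationAnalysis,
    TaxaClusterer,
    classify_relationships,
    cluster_taxa,
    compare_stages,
    fdr_adjust,
    pearson_matrix,
    significance_stars,
)
from quorumflow.synthetic import CommunitySimPlan, gen_community_series


def _series(taxa, ahls):
    cols = [f"w{i}" for i in range(np.asarray(taxa).shape[1])]
    return CommunitySignalSeries(
        taxa_abundance=pd.DataFrame(np.asarray(taxa, float), columns=cols),
        ahl_conc=pd.DataFrame(np.asarray(ahls, float), columns=cols),
    )


class TestPearsonMatrix:
    def test_identical_series_r_plus_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = pearson_matrix(_series([x], [x]))
        assert r.iloc[0, 0] == pytest.approx(1.0)
        assert p.iloc[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_negated_series_r_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mirrored = 2 * x.mean() - x
        r, _ = pearson_matrix(_series([x], [mirrored]))
        assert r.iloc[0, 0] == pytest.approx(-1.0)

    def test_constant_row_gives_nan_r(self):
        r, p = pearson_matrix(_series([[1.0, 1.0, 1.0, 1.0]], [[1, 2, 3, 4]]))
        assert np.isnan(r.iloc[0, 0]) and np.isnan(p.iloc[0, 0])

    def test_agrees_with_two_pass_covariance_oracle(self, rng):
        """Matrix implementation vs direct per-pair covariance formula, 50 matrices."""
        for _ in range(50):
            X = rng.uniform(0.0, 1.0, size=(4, 8))
            Y = rng.normal(size=(3, 8))
            r, p = pearson_matrix(_series(X, Y))
            for i in range(4):
                for j in range(3):
                    x, y = X[i], Y[j]
                    cov = np.mean((x - x.mean()) * (y - y.mean()))
                    expected = cov / (x.std() * y.std())
                    assert r.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_affine_invariance(self, rng):
        x = rng.uniform(0.0, 1.0, size=10)
        y = rng.normal(size=10)
        r0, _ = pearson_matrix(_series([x], [y]))
        r_scaled, _ = pearson_matrix(_series([3.0 * x + 7.0], [y]))
        r_flipped, _ = pearson_matrix(_series([-0.5 * x + 1.0], [y]))
        assert r_scaled.iloc[0, 0] == pytest.approx(r0.iloc[0, 0], abs=1e-12)
        assert r_flipped.iloc[0, 0] == pytest.approx(-r0.iloc[0, 0], abs=1e-12)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            _series([[1.0, 2.0]], [[1.0, 2.0]])


class TestFdrAdjust:
    def test_step_up_hand_example(self):
        p = pd.DataFrame([[0.01, 0.02, 0.03]])
        q = fdr_adjust(p)
        np.testing.assert_allclose(q.to_numpy()[0], [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_test_q_equals_p(self):
        q = fdr_adjust(pd.DataFrame([[0.04]]))
        assert q.iloc[0, 0] == pytest.approx(0.04)

    def test_all_ones_stay_one(self):
        q = fdr_adjust(pd.DataFrame(np.ones((3, 4))))
        assert (q.to_numpy() == 1.0).all()

    def test_q_at_least_p_and_monotone(self, rng):
        p = pd.DataFrame(rng.uniform(size=(6, 5)))
        q = fdr_adjust(p)
        assert (q.to_numpy() >= p.to_numpy() - 1e-12).all()
        flat_p, flat_q = p.to_numpy().ravel(), q.to_numpy().ravel()
        order = np.argsort(flat_p)
        assert (np.diff(flat_q[order]) >= -1e-12).all()

    def test_nan_passthrough(self):
        p = pd.DataFrame([[0.01, np.nan, 0.5]])
        q = fdr_adjust(p)
        assert np.isnan(q.iloc[0, 1])
        assert np.isfinite(q.iloc[0, 0])

    def test_complete_null_false_positive_proportion(self):
        """Empirical proportion of q < alpha under the null <= alpha (500 seeds)."""
        alpha = 0.05
        fractions = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            p = pd.DataFrame(rng.uniform(size=(8, 3)))
            q = fdr_adjust(p)
            fractions.append(np.mean(q.to_numpy() < alpha))
        assert np.mean(fractions) <= alpha


class TestClassify:
    def test_all_positive_matrix(self):
        r = pd.DataFrame(np.ones((2, 2)))
        q = pd.DataFrame(np.zeros((2, 2)))
        cls, summary = classify_relationships(r, q)
        assert (cls.to_numpy() == "positive").all()
        assert summary["positive"] == 100.0

    def test_percentages_sum_to_100(self, rng):
        r = pd.DataFrame(rng.uniform(-1, 1, size=(10, 4)))
        q = pd.DataFrame(rng.uniform(0, 1, size=(10, 4)))
        _, summary = classify_relationships(r, q)
        assert summary["positive"] + summary["negative"] + summary["neutral"] == \
            pytest.approx(100.0)

    def test_nan_r_classified_neutral(self):
        r = pd.DataFrame([[np.nan]])
        q = pd.DataFrame([[np.nan]])
        cls, _ = classify_relationships(r, q)
        assert cls.iloc[0, 0] == "neutral"

    def test_planted_split_recovered(self):
        """70% negative / 20% positive plant recovered within +-8 points."""
        rng = np.random.default_rng(99)
        n_taxa, n_ahls = 50, 2
        signs = np.zeros((n_taxa, n_ahls), dtype=int)
        for i in range(n_taxa):
            u = rng.random()
            if u < 0.7:
                signs[i, rng.integers(n_ahls)] = -1
            elif u < 0.9:
                signs[i, rng.integers(n_ahls)] = +1
        plan = CommunitySimPlan(n_taxa, 40, n_ahls,
                                tuple(map(tuple, signs)), effect_size=0.9, seed=99)
        series, truth = gen_community_series(plan)
        ana = CorrelationAnalysis().fit(series)
        planted_neg = 100.0 * np.mean(truth.to_numpy() == -1)
        planted_pos = 100.0 * np.mean(truth.to_numpy() == +1)
        assert ana.summary_["negative"] == pytest.approx(planted_neg, abs=8.0)
        assert ana.summary_["positive"] == pytest.approx(planted_pos, abs=8.0)

    def test_all_noise_series_mostly_neutral(self):
        sig_fracs = []
        for seed in range(30):
            plan = CommunitySimPlan(20, 20, 2, tuple((0, 0) for _ in range(20)),
                                    seed=seed)
            series, _ = gen_community_series(plan)
            ana = CorrelationAnalysis(alpha=0.05).fit(series)
            sig_fracs.append(ana.summary_["positive"] + ana.summary_["negative"])
        assert np.mean(sig_fracs) <= 5.0

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""


class TestClusterTaxa:
    def test_identical_rows_merge_at_height_zero(self):
        r = pd.DataFrame([[0.5, -0.5], [0.5, -0.5], [-1.0, 1.0]],
                         index=["a", "b", "c"])
        tree = cluster_taxa(r, k=2)
        assert tree.linkage[0, 2] == pytest.approx(0.0)
        assert tree.clusters["a"] == tree.clusters["b"] != tree.clusters["c"]

    def test_merge_heights_nondecreasing(self, rng):
        for _ in range(100):
            r = pd.DataFrame(rng.uniform(-1, 1, size=(6, 3)))
            tree = cluster_taxa(r)
            assert (np.diff(tree.linkage[:, 2]) >= -1e-12).all()

    def test_agrees_with_brute_force_agglomeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 7))
            r = pd.DataFrame(rng.uniform(-1, 1, size=(n, 3)))
            tree = cluster_taxa(r)
            oracle_heights = oracle_complete_linkage(r.to_numpy())
            np.testing.assert_allclose(sorted(tree.linkage[:, 2]),
                                       sorted(oracle_heights), atol=1e-10)

    def test_permutation_equivariance(self, rng):
        r = pd.DataFrame(rng.uniform(-1, 1, size=(8, 3)),
                         index=[f"t{i}" for i in range(8)])
        perm = rng.permutation(8)
        tree = cluster_taxa(r, k=3)
        tree_p = cluster_taxa(r.iloc[perm], k=3)
        # same partition of labels, up to cluster relabelling
        part = {}
        for label, c in tree.clusters.items():
            part.setdefault(c, set()).add(label)
        part_p = {}
        for label, c in tree_p.clusters.items():
            part_p.setdefault(c, set()).add(label)
        assert sorted(map(sorted, part.values())) == sorted(map(sorted, part_p.values()))

    def test_nan_imputed_as_zero(self):
        r = pd.DataFrame([[np.nan, 0.0], [0.0, 0.0], [1.0, 1.0]])
        tree = cluster_taxa(r, k=2)
        assert tree.clusters.iloc[0] == tree.clusters.iloc[1]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_taxa(pd.DataFrame([[1.0, 0.0]]))

    def test_estimator_wrapper(self):
        r = pd.DataFrame(np.eye(4))
        clusterer = TaxaClusterer(k=2).fit(r)
        assert len(clusterer.labels_) == 4
        assert clusterer.get_params() == {"k": 2}


class TestCompareStages:
    def _result(self, positive, negative):
        n = 10
        r = pd.DataFrame(np.zeros((n, 1)))
        q = pd.DataFrame(np.ones((n, 1)))
        from quorumflow.community import CorrelationResult
        summary = {"positive": positive, "negative": negative,
                   "neutral": 100 - positive - negative, "n_pairs": n}
        return CorrelationResult(r=r, p_raw=q, q=q, classification=r.astype(str),
                                 summary=summary)

    def test_reported_fold_change_flagged(self):
        report = compare_stages(self._result(20, 72), self._result(54, 38),
                                {"3OC8-HSL": 25.0}, {"3OC8-HSL": 85.0})
        row = report.ahl_fold_change.iloc[0]
        assert row.fold_change == pytest.approx(3.4)
        assert row.flagged

    def test_class_shift_deltas(self):
        report = compare_stages(self._result(20, 72), self._result(54, 38),
                                {}, {})
        shift = report.class_shift.set_index("class")
        assert shift.loc["positive", "delta"] == pytest.approx(34.0)
        assert shift.loc["negative", "delta"] == pytest.approx(-34.0)

    def test_identical_stages_all_zero(self):
        res = self._result(20, 72)
        report = compare_stages(res, res, {"C6-HSL": 10.0}, {"C6-HSL": 10.0})
        assert (report.class_shift["delta"] == 0).all()
        assert report.ahl_fold_change["fold_change"].iloc[0] == pytest.approx(1.0)
        assert not report.ahl_fold_change["flagged"].iloc[0]

    def test_missing_ahl_reported_undefined(self):
        res = self._result(20, 72)
        report = compare_stages(res, res, {"C6-HSL": 10.0}, {})
        assert np.isnan(report.ahl_fold_change["fold_change"].iloc[0])
        assert report.ahl_fold_change["note"].iloc[0] == "absent in one stage"

    def test_planted_sign_flip_shift_recovered(self):
        """Flipping 30% of planted signs shifts the class split accordingly."""
        def make(signs, seed):
            plan = CommunitySimPlan(len(signs), 40, 1,
                                    tuple((s,) for s in signs),
                                    effect_size=0.9, seed=seed)
            series, _ = gen_community_series(plan)
            return CorrelationAnalysis().fit(series).result_
        rng = np.random.default_rng(7)
        signs_floc = [-1] * 35 + [1] * 10 + [0] * 5
        signs_gran = list(signs_floc)
        flip = rng.choice(35, size=15, replace=False)  # 30% of taxa flip to +
        for i in flip:
            signs_gran[i] = 1
        floc = make(signs_floc, seed=1)
        gran = make(signs_gran, seed=2)
        report = compare_stages(floc, gran, {}, {})
        shift = report.class_shift.set_index("class")
        assert shift.loc["positive", "delta"] == pytest.approx(30.0, abs=10.0)
        assert shift.loc["negative", "delta"] == pytest.approx(-30.0, abs=10.0)
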