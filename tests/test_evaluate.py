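import dataclasses

import numpy as np
import pandas as pd
import pytest

from panelex import (CVConfig, EvaluationError, evaluate_panel,
                     hclust_linkage, pca_coords, ttest_all, volcano_stats)
from panelex.evaluate import EvaluationReport

from conftest import make_two_group_table


class TestEvaluatePanel:
    def test_perfectly_separated_test_set(self):
        train = make_two_group_table(3, 10, seed=0, shifts={0: 50.0}, sd=1.0)
        test = make_two_group_table(3, 4, seed=1, shifts={0: 50.0}, sd=1.0)
        rep = evaluate_panel(train, ["m000"], test=test)
        assert rep.mode == "test-set"
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0
        np.testing.assert_allclose(rep.confusion, [[4, 0], [0, 4]])

    def test_repeated_cv_mode_on_separable_panel(self):
        train = make_two_group_table(3, 10, seed=2, shifts={1: 50.0}, sd=1.0)
        rep = evaluate_panel(train, ["m001"],
                             cv=CVConfig(n_folds=5, n_repeats=20, seed=0))
        assert rep.mode == "repeated-cv"
        assert rep.accuracy == 1.0
        assert rep.confusion.sum() == pytest.approx(20)

    def test_metrics_equal_brute_force_counts(self):
        train = make_two_group_table(4, 12, seed=3, shifts={0: 2.0})
        test = make_two_group_table(4, 8, seed=4, shifts={0: 2.0})
        rep = evaluate_panel(train, ["m000"], test=test)
        conf = rep.confusion
        total = conf.sum()
        tp, fp, fn = conf[1, 1], conf[0, 1], conf[1, 0]
        assert rep.accuracy == pytest.approx((conf[0, 0] + conf[1, 1]) / total)
        if tp + fp:
            assert rep.precision == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert rep.recall == pytest.approx(tp / (tp + fn))
        if rep.precision + rep.recall:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.recall / (rep.precision + rep.recall))

    def test_missing_panel_molecule_errors(self):
        train = make_two_group_table(3, 5, seed=5)
        with pytest.raises(EvaluationError):
            evaluate_panel(train, ["nope"])

    def test_report_rejects_inconsistent_metrics(self):
        with pytest.raises(EvaluationError):
            EvaluationReport(panel=["m"], mode="test-set",
                             class_labels=["a", "b"], positive_class="b",
                             accuracy=0.9, precision=1.0, recall=1.0, f1=1.0,
                             confusion=np.array([[2.0, 0.0], [0.0, 2.0]]))


class TestPCA:
    def test_two_clusters_on_one_molecule(self):
        t = make_two_group_table(1, 10, seed=6, shifts={0: 100.0}, sd=0.5)
        coords, evr = pca_coords(t, ["m000"])
        a = coords.loc[coords["condition"] == "a", "PC1"]
        b = coords.loc[coords["condition"] == "b", "PC1"]
        assert (a.max() < b.min()) or (b.max() < a.min())
        assert evr[0] == pytest.approx(1.0)
        assert evr[1] == pytest.approx(0.0)

    def test_explained_variance_fractions_bounded(self, planted_dataset):
        panel = planted_dataset.table.molecule_ids[:5]
        _, evr = pca_coords(planted_dataset.table, panel)
        assert 0.0 <= evr[1] <= evr[0] <= 1.0
        assert evr.sum() <= 1.0 + 1e-12

    def test_matches_reference_pca_up_to_sign(self, planted_dataset):
        sklearn_pca = pytest.importorskip("sklearn.decomposition")
        table = planted_dataset.table
        panel = table.molecule_ids[:8]
        coords, evr = pca_coords(table, panel)
        X = table.samples_by_molecules(panel, fill=0.0).to_numpy()
        ref = sklearn_pca.PCA(n_components=2).fit(X)
        ref_coords = ref.transform(X)
        for c in range(2):
            ours = coords.iloc[:, c].to_numpy()
            theirs = ref_coords[:, c]
            agree = np.allclose(ours, theirs, atol=1e-8) \
                or np.allclose(ours, -theirs, atol=1e-8)
            assert agree
        np.testing.assert_allclose(evr, ref.explained_variance_ratio_,
                                   atol=1e-10)

    def test_too_few_samples_errors(self):
        t = make_two_group_table(2, 1, seed=7)
        with pytest.raises(EvaluationError):
            pca_coords(t, ["m000"])


class TestHclust:
    def test_two_samples_single_merge_at_euclidean_distance(self):
        t = make_two_group_table(2, 1, seed=8)
        t.values.iloc[:, 0] = [0.0, 0.0]
        t.values.iloc[:, 1] = [3.0, 4.0]
        link, samples = hclust_linkage(t, ["m000", "m001"])
        assert link.shape == (1, 4)
        assert link[0, 2] == pytest.approx(5.0)

    def test_three_collinear_points_merge_closest_first(self):
        df = pd.DataFrame([[0.0, 1.0, 10.0]], index=["m"],
                          columns=["a_1", "a_2", "b_1"])
        from panelex import QuantTable
        t = QuantTable(df, {"a_1": "a", "a_2": "a", "b_1": "b"})
        link, _ = hclust_linkage(t, ["m"])
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}
        assert link[0, 2] == pytest.approx(1.0)
        assert (np.diff(link[:, 2]) >= 0).all()

    def test_average_linkage_matches_naive_agglomeration(self):
        """Five samples, hand-rolled average-linkage agglomeration."""
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 3))
        df = pd.DataFrame(X.T, index=["m0", "m1", "m2"],
                          columns=["a_1", "a_2", "a_3", "b_1", "b_2"])
        from panelex import QuantTable
        t = QuantTable(df - df.min().min() + 1.0,
                       {c: c.split("_")[0] for c in df.columns})
        link, _ = hclust_linkage(t, ["m0", "m1", "m2"])

        # naive O(n^3) average-linkage on pairwise Euclidean distances
        pts = t.samples_by_molecules(["m0", "m1", "m2"]).to_numpy()
        clusters = {i: [i] for i in range(5)}
        heights = []
        next_id = 5
        while len(clusters) > 1:
            best = None
            for i in sorted(clusters):
                for j in sorted(clusters):
                    if i >= j:
                        continue
                    d = np.mean([np.linalg.norm(pts[p] - pts[q])
                                 for p in clusters[i] for q in clusters[j]])
                    if best is None or d < best[0]:
                        best = (d, i, j)
            d, i, j = best
            heights.append(d)
            clusters[next_id] = clusters.pop(i) + clusters.pop(j)
            next_id += 1
        np.testing.assert_allclose(link[:, 2], heights, rtol=1e-10)


class TestVolcano:
    def test_fold_change_and_significance_scales(self):
        t = make_two_group_table(2, 20, seed=10)
        t.values.iloc[0] = np.r_[np.full(20, 4.0), np.full(20, 8.0)]
        stats = ttest_all(t)
        entries = {v.molecule_id: v for v in volcano_stats(stats, ["m000"])}
        assert entries["m000"].log2_fold_change == pytest.approx(1.0)
        assert entries["m000"].in_panel and not entries["m001"].in_panel

    def test_neg_log10_matches_recomputation(self, planted_dataset):
        stats = ttest_all(planted_dataset.table)
        for v, s in zip(volcano_stats(stats), stats):
            assert v.neg_log10_p == pytest.approx(-np.log10(max(s.p_value,
                                                                1e-300)))
            m1, m2 = s.mean_group1, s.mean_group2
            if m1 > 0 and m2 > 0:
                assert v.log2_fold_change == pytest.approx(np.log2(m2 / m1))

    def test_bh_adjustment_matches_hand_formula(self, planted_dataset):
        stats = ttest_all(planted_dataset.table)
        entries = volcano_stats(stats)
        pvals = np.array([s.p_value for s in stats])
        n = len(pvals)
        order = np.argsort(pvals)
        ranked = pvals[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        hand = np.empty(n)
        hand[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose([e.adjusted_p for e in entries], hand,
                                   rtol=1e-10)
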