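import warnings

import numpy as np
import pandas as pd
import pytest

import panelfinder as pf
from panelfinder.core_data import IntensityMatrix, SampleSheet, ValidationError
from panelfinder.multivariate import spearman_distance, vip_scores


def make_matrix(arr, samples=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return IntensityMatrix(
        pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=samples),
        is_log2=True,
    )


def make_sheet(groups, samples=None):
    samples = samples or [f"s{i}" for i in range(len(groups))]
    return SampleSheet(pd.DataFrame({"sample_id": samples, "group": groups}))


class TestMdsEmbed:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=20)
        m = make_matrix(np.column_stack([col, col, rng.normal(size=20), rng.normal(size=20)]))
        d = spearman_distance(m)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)
        coords = pf.mds_embed(m)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-8)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(30, 6))
        d1 = spearman_distance(make_matrix(arr))
        d2 = spearman_distance(make_matrix(np.exp(arr)))  # monotone map
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)

    def test_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(30, 8))
        m = make_matrix(arr)
        perm = rng.permutation(8)
        m_perm = make_matrix(arr[:, perm], samples=[f"s{i}" for i in perm])
        d1 = spearman_distance(m)
        d2 = spearman_distance(m_perm).loc[d1.index, d1.columns]
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)

    def test_two_cluster_recovery(self, two_group_sim):
        from sklearn.metrics import silhouette_score

        m, sheet, _ = two_group_sim
        f, _ = pf.filter_group_validity(m, sheet)
        mc = pf.impute_downshifted(
            pf.normalize_median(pf.log2_transform(f)), seed=21
        )
        coords = pf.mds_embed(mc)
        labels = sheet.group_of().reindex(coords.index)
        assert silhouette_score(coords.to_numpy(), labels) > 0.5

    def test_too_few_samples_is_error(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValidationError):
            pf.mds_embed(m)


class TestPlsdaVip:
    def test_closed_form_single_component(self):
        """Weights proportional to (1, 0) with one component: VIP = (sqrt 2, 0)."""
        w = np.array([[1.0], [0.0]])
        np.testing.assert_allclose(
            vip_scores(w, np.array([1.0])), [np.sqrt(2.0), 0.0], atol=1e-12
        )

    def test_fit_recovers_informative_protein(self):
        # protein 0 carries the classes; protein 1 is constant
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        arr = np.vstack([y + 0.01 * np.arange(8), np.zeros(8)])
        m = make_matrix(arr)
        sheet = make_sheet(["control"] * 4 + ["LGG_GT"] * 4)
        model = pf.plsda_fit(m, sheet, n_components=1)
        np.testing.assert_allclose(model.vip.to_numpy(), [np.sqrt(2.0), 0.0], atol=1e-6)

    def test_vip_normalization_identity(self, four_group_complete):
        m, sheet, _ = four_group_complete
        model = pf.plsda_fit(m, sheet, n_components=3)
        assert float((model.vip**2).mean()) == pytest.approx(1.0, abs=1e-8)

    def test_marker_recovery_top_ranks(self):
        """Planted markers occupy >= 90% of the top-n_markers VIP ranks."""
        for seed in (1, 2, 3):
            cfg = pf.SimConfig(
                n_per_group={"control": 20, "LGG_GT": 20}, n_proteins=1000,
                n_markers=50, effect_log2=2.0, seed=seed,
            )
            m, sheet, truth = pf.simulate_matrix(cfg)
            f, _ = pf.filter_group_validity(m, sheet)
            mc = pf.impute_downshifted(
                pf.normalize_median(pf.log2_transform(f)), seed=seed
            )
            model = pf.plsda_fit(mc, sheet, n_components=2)
            top = set(model.vip.nlargest(50).index)
            assert len(top & set(truth)) >= 45

    def test_component_bound_enforced(self):
        m = make_matrix(np.random.default_rng(1).normal(size=(5, 6)))
        sheet = make_sheet(["control"] * 3 + ["EMB"] * 3)
        with pytest.raises(ValidationError):
            pf.plsda_fit(m, sheet, n_components=5)


class TestSvmRank:
    def separable(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(20, 16))
        arr[0, 8:] += 6.0  # one perfectly separating protein
        m = make_matrix(arr)
        sheet = make_sheet(["control"] * 8 + ["LGG_GT"] * 8)
        return m, sheet

    def test_separable_data_perfect_accuracy(self):
        m, sheet = self.separable()
        r = pf.svm_rank(m, sheet, n_splits=8, seed=2)
        assert r.cv_accuracy == 1.0
        assert r.rank.loc["p0"] == 1

    def test_seeded_determinism(self):
        m, sheet = self.separable()
        r1 = pf.svm_rank(m, sheet, n_splits=6, seed=9)
        r2 = pf.svm_rank(m, sheet, n_splits=6, seed=9)
        pd.testing.assert_series_equal(r1.rank, r2.rank)
        assert r1.cv_accuracy == r2.cv_accuracy

    def test_rank_is_permutation(self):
        m, sheet = self.separable()
        r = pf.svm_rank(m, sheet, n_splits=4, seed=3)
        assert sorted(r.rank) == list(range(1, m.shape[0] + 1))

    def test_permuted_labels_near_majority_rate(self):
        """Label-permutation null: accuracy falls to the majority-class rate."""
        rng = np.random.default_rng(31)
        arr = rng.normal(size=(30, 24))
        m = make_matrix(arr)
        groups = ["control"] * 14 + ["LGG_GT"] * 10
        accs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(20):
                perm = rng.permutation(24)
                sheet = make_sheet([groups[j] for j in perm])
                r = pf.svm_rank(m, sheet, n_splits=4, seed=i, prefilter_p=0.2)
                accs.append(r.cv_accuracy)
        majority = 14 / 24
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - majority) < max(3 * se, 0.12)

    def test_permutation_mode(self):
        # single informative protein: no redundancy, so permutation
        # importance also finds it
        m, sheet = self.separable()
        r = pf.svm_rank(m, sheet, n_splits=4, seed=4, importance="permutation")
        assert r.importance_mode == "permutation"
        assert r.rank.loc["p0"] == 1

    def test_too_few_splits_rejected(self):
        m, sheet = self.separable()
        with pytest.raises(ValidationError, match="fourfold"):
            pf.svm_rank(m, sheet, n_splits=2)


class TestConsensusPanel:
    def _model_from_vip(self, vip: pd.Series):
        return pf.PlsdaModel(
            n_components=1, classes=["a", "b"],
            scores=pd.DataFrame(), weights=pd.DataFrame(),
            explained_y_ss=np.array([1.0]), vip=vip,
        )

    def _svm_from_rank(self, rank: pd.Series):
        return pf.SvmRanking(
            rank=rank, importance=1.0 / rank, selection_freq=rank * 0 + 1.0,
            cv_accuracy=1.0, n_splits_run=4, seed=0,
        )

    def test_identical_rankings_idempotent(self):
        idx = pd.Index([f"p{i}" for i in range(20)])
        vip = pd.Series(np.linspace(2, 0.1, 20), index=idx)
        svm = self._svm_from_rank(pd.Series(np.arange(1, 21), index=idx))
        panel = pf.consensus_panel(self._model_from_vip(vip), svm, k=10)
        assert panel.members == list(idx[:10])
        assert len(panel) == 10

    def test_disjoint_topk_empty_panel_warns(self):
        idx = pd.Index([f"p{i}" for i in range(10)])
        vip = pd.Series(np.linspace(2, 0.1, 10), index=idx)
        svm = self._svm_from_rank(pd.Series(np.arange(10, 0, -1), index=idx))
        with pytest.warns(UserWarning, match="disjoint"):
            panel = pf.consensus_panel(self._model_from_vip(vip), svm, k=3)
        assert panel.members == []

    def test_k_larger_than_set_is_error(self):
        idx = pd.Index(["p0", "p1"])
        vip = pd.Series([1.0, 0.5], index=idx)
        svm = self._svm_from_rank(pd.Series([1, 2], index=idx))
        with pytest.raises(ValidationError):
            pf.consensus_panel(self._model_from_vip(vip), svm, k=3)

    def test_engineered_104_intersection(self):
        """Rankings built to agree on exactly 104 proteins yield a
        104-member panel under the intersection rule."""
        n, k = 302, 150
        idx = pd.Index([f"p{i:03d}" for i in range(n)])
        # VIP rank of p_i is i+1; SVM agrees on the first 104 and ranks the
        # remainder in reverse, so the top-150 lists overlap in exactly 104
        vip = pd.Series(np.linspace(3, 0.01, n), index=idx)
        svm_rank_s = pd.Series(
            [i + 1 if i < 104 else 406 - i for i in range(n)], index=idx
        )
        panel = pf.consensus_panel(
            self._model_from_vip(vip), self._svm_from_rank(svm_rank_s), k=k
        )
        assert len(panel) == 104
        assert set(panel.members) == {f"p{i:03d}" for i in range(104)}

    def test_mismatched_sets_rejected(self):
        vip = pd.Series([1.0], index=pd.Index(["p0"]))
        svm = self._svm_from_rank(pd.Series([1], index=pd.Index(["other"])))
        with pytest.raises(ValidationError):
            pf.consensus_panel(self._model_from_vip(vip), svm)


class TestKmeansSeparation:
    def test_four_separated_groups_high_ari(self):
        rng = np.random.default_rng(12)
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]])
        pts, groups = [], []
        names = ["control", "LGG_GT", "EMB", "other_tumor"]
        for gi, c in enumerate(centers):
            pts.append(c + rng.normal(0, 0.3, size=(10, 2)))
            groups += [names[gi]] * 10
        samples = [f"s{i}" for i in range(40)]
        scores = pd.DataFrame(np.vstack(pts), index=samples, columns=["c1", "c2"])
        sheet = make_sheet(groups, samples=samples)
        _, ari = pf.kmeans_separation(scores, sheet, k=4, seed=1)
        assert ari > 0.9

    def test_k1_single_cluster_zero_ari(self, tiny_sheet):
        scores = pd.DataFrame(
            np.random.default_rng(2).normal(size=(6, 2)),
            index=tiny_sheet.sample_ids, columns=["c1", "c2"],
        )
        assign, ari = pf.kmeans_separation(scores, tiny_sheet, k=1, seed=0)
        assert assign.nunique() == 1
        assert ari == 0.0

    def test_seeded_determinism(self, tiny_sheet):
        scores = pd.DataFrame(
            np.random.default_rng(3).normal(size=(6, 2)),
            index=tiny_sheet.sample_ids, columns=["c1", "c2"],
        )
        a1, r1 = pf.kmeans_separation(scores, tiny_sheet, k=2, seed=5)
        a2, r2 = pf.kmeans_separation(scores, tiny_sheet, k=2, seed=5)
        pd.testing.assert_series_equal(a1, a2)
        assert r1 == r2

    def test_degenerate_scores_rejected(self, tiny_sheet):
        scores = pd.DataFrame(
            np.ones((6, 2)), index=tiny_sheet.sample_ids, columns=["c1", "c2"]
        )
        with pytest.raises(ValidationError):
            pf.kmeans_separation(scores, tiny_sheet, k=2, seed=0)
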