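"""Integrative classifier: Ki67 labeling, feature fusion, forest tuning,
patient LOOCV leakage contract, external scoring and group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mtorsig as m
from mtorsig.integrative import _derive_seed

from conftest import DESK_FOREST, small_matrix


def _pheno(rows):
    return m.PhenotypeTable(pd.DataFrame(rows))


class TestLabelResponse:
    @pytest.mark.parametrize("pre,post,expected", [
        (20.0, 10.0, "responder"),      # 50% relative decrease
        (20.0, 20.0, "non_responder"),  # no change
        (50.0, 46.0, "non_responder"),  # 8% relative decrease
        (50.0, 44.0, "responder"),      # 12% relative decrease
    ])
    def test_relative_threshold_rule(self, pre, post, expected):
        labels = m.label_response(_pheno([{"sample_id": "p1", "ki67_pre": pre,
                                           "ki67_post": post}]))
        assert labels[0].label == expected

    def test_boundary_exactly_at_10pct(self):
        # a 10% decrease is NOT a response (strict >); just over 10% is
        at = m.label_response(_pheno([{"sample_id": "p", "ki67_pre": 40.0,
                                       "ki67_post": 36.0}]))[0]
        over = m.label_response(_pheno([{"sample_id": "p", "ki67_pre": 40.0,
                                         "ki67_post": 35.999}]))[0]
        assert at.label == "non_responder"
        assert over.label == "responder"

    def test_absolute_mode(self):
        labels = m.label_response(_pheno([{"sample_id": "p", "ki67_pre": 50.0,
                                           "ki67_post": 38.0}]), relative=False)
        assert labels[0].ki67_change == pytest.approx(12.0)
        assert labels[0].label == "responder"

    def test_provided_response_passes_through(self):
        labels = m.label_response(_pheno([{"sample_id": "p",
                                           "response": "responder"}]))
        assert labels[0].label == "responder"

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            m.label_response(_pheno([{"sample_id": "p", "ki67_pre": 0.0,
                                      "ki67_post": 0.0}]))


class TestBuildIntegratedFeatures:
    def test_empty_fcbf_gives_signature_intersection(self):
        out = m.build_integrated_features(["a", "b", "c"], [], ["a", "c", "z"])
        assert out.genes == ["a", "c"]
        assert set(out.provenance.values()) == {"invitro"}

    def test_inclusion_exclusion_counts(self):
        sig = [f"s{i}" for i in range(100)]
        fcbf = [f"f{i}" for i in range(9)] + ["s0", "s1", "s2"]
        platform = sig + [f"f{i}" for i in range(9)]
        out = m.build_integrated_features(sig, fcbf, platform)
        assert len(out.genes) == 109
        assert sum(v == "both" for v in out.provenance.values()) == 3

    def test_provenance_matches_set_logic(self, rng):
        universe = [f"g{i}" for i in range(50)]
        sig = list(rng.choice(universe, 20, replace=False))
        fcbf = list(rng.choice(universe, 10, replace=False))
        platform = set(rng.choice(universe, 45, replace=False)) | set(fcbf)
        out = m.build_integrated_features(sig, fcbf, platform)
        for g in out.genes:
            in_sig = g in sig and g in platform
            in_fcbf = g in fcbf
            expected = "both" if in_sig and in_fcbf else \
                "invitro" if in_sig else "fcbf"
            assert out.provenance[g] == expected

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m.build_integrated_features(["a"], [], ["z"])


class TestTuneAndTrainRF:
    def test_single_feature_forces_mtry_1(self, rng):
        X = rng.normal(size=(30, 1))
        y = (X[:, 0] > 0).astype(int)
        tuned = m.tune_and_train_rf(X, y, m.ForestConfig(n_trees=50,
                                                         inner_repeats=1))
        assert tuned.chosen_mtry == 1

    def test_separable_cohort_perfect_internal_cv(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 10))
        X[:, 0] = y * 4 + rng.normal(0, 0.1, n)
        X[:, 1] = -y * 4 + rng.normal(0, 0.1, n)
        tuned = m.tune_and_train_rf(X, y, m.ForestConfig(
            n_trees=100, mtry_grid=(2, 4, 6), inner_repeats=2))
        assert all(acc == 1.0 for acc in tuned.internal_cv_accuracy.values())

    def test_oversized_grid_values_skipped(self, rng, caplog):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        with caplog.at_level("WARNING"):
            tuned = m.tune_and_train_rf(X, y, m.ForestConfig(
                n_trees=20, mtry_grid=(2, 50), inner_repeats=1))
        assert tuned.mtry_grid == [2]

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(24, 6))
        y = (X[:, 0] + rng.normal(0, 1, 24) > 0).astype(int)
        cfg = m.ForestConfig(n_trees=50, mtry_grid=(2, 3), inner_repeats=1, seed=4)
        t1 = m.tune_and_train_rf(X, y, cfg)
        t2 = m.tune_and_train_rf(X, y, cfg)
        assert t1.chosen_mtry == t2.chosen_mtry
        assert t1.internal_cv_accuracy == t2.internal_cv_accuracy


class TestIntegrativeModel:
    def test_final_model_separates_classes_in_sample(self, patient_sim,
                                                     signature_results):
        matrix, pheno, truth = patient_sim
        std = m.standardize_genes(matrix)
        model = m.IntegrativeModel(std, m.label_response(pheno),
                                   signature_results.gene_set,
                                   m.ForestConfig(seed=17, **DESK_FOREST))
        results = model.fit()
        probs = results.fittedvalues
        y = np.array([truth.response[s] == "responder" for s in probs.index])
        assert np.all(probs[y] > 0.5)
        assert np.all(probs[~y] < 0.5)
        # feature set always contains the platform-resolved signature genes
        platform = set(std.gene_ids)
        expected_invitro = [g for g in signature_results.gene_set.genes
                            if g in platform]
        assert set(expected_invitro) <= set(results.features.genes)

    def test_same_seed_identical_serialized_model(self, patient_sim,
                                                  signature_results, tmp_path):
        matrix, pheno, _ = patient_sim
        std = m.standardize_genes(matrix)
        cfg = m.ForestConfig(n_trees=50, mtry_grid=(2, 4), inner_repeats=1, seed=5)
        labels = m.label_response(pheno)
        d1 = m.IntegrativeModel(std, labels, signature_results.gene_set, cfg).fit().to_dict()
        d2 = m.IntegrativeModel(std, labels, signature_results.gene_set, cfg).fit().to_dict()
        assert d1 == d2

    def test_loocv_fold_count_and_probability_complement(self, patient_loocv):
        assert patient_loocv.n_folds == 23
        # P(response) + P(non-response) = 1 by construction of tree votes:
        # the reported probability plus its complement covers both classes
        probs = patient_loocv.table["prob_response"]
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_loocv_training_never_sees_held_out_column(self, patient_sim,
                                                       signature_results):
        """Fold feature sets equal selection re-run on the reduced matrix."""
        matrix, pheno, _ = patient_sim
        std = m.standardize_genes(matrix)
        labels = m.label_response(pheno)
        cfg = m.ForestConfig(n_trees=30, mtry_grid=(2, 4), inner_repeats=1, seed=8)
        model = m.IntegrativeModel(std, labels, signature_results.gene_set, cfg)
        sid = std.sample_ids[5]
        report = model.loocv()
        reduced = std.drop_samples([sid])
        y_red = model.y[np.array(std.sample_ids) != sid]
        disc = m.discretize(reduced)
        fcbf = m.fcbf_select(disc, y_red, cfg.fcbf_delta)
        expected = m.build_integrated_features(signature_results.gene_set,
                                               fcbf.selected, reduced.gene_ids)
        assert report.fold_features[sid] == expected.genes

    def test_loocv_order_invariance_of_probabilities(self, patient_sim,
                                                     signature_results):
        matrix, pheno, _ = patient_sim
        std = m.standardize_genes(matrix)
        labels = m.label_response(pheno)
        cfg = m.ForestConfig(n_trees=30, mtry_grid=(2, 4), inner_repeats=1, seed=8)
        base = m.IntegrativeModel(std, labels, signature_results.gene_set, cfg)
        rng = np.random.default_rng(0)
        perm = list(np.array(std.sample_ids)[rng.permutation(std.n_samples)])
        shuffled = m.IntegrativeModel(std.select_samples(perm), labels,
                                      signature_results.gene_set, cfg)
        r1 = base.loocv().table.set_index("sample_id")["prob_response"]
        r2 = shuffled.loocv().table.set_index("sample_id")["prob_response"]
        pd.testing.assert_series_equal(r1.sort_index(), r2.sort_index())

    def test_single_class_fold_rejected(self, signature_results, rng):
        values = rng.normal(size=(150, 8))
        mat = small_matrix(values, gene_prefix="G0000")
        std = m.standardize_genes(mat)
        labels = ["non_responder"] + ["responder"] * 7
        model = m.IntegrativeModel(std, labels, [],
                                   m.ForestConfig(n_trees=10, mtry_grid=(2,),
                                                  inner_repeats=1))
        with pytest.raises(ValueError, match="loses a class"):
            model.loocv()


class TestExternalScoring:
    def test_scoring_training_cohort_matches_fitted(self, patient_sim,
                                                    signature_results):
        matrix, pheno, _ = patient_sim
        std = m.standardize_genes(matrix)
        cfg = m.ForestConfig(n_trees=50, mtry_grid=(2, 4), inner_repeats=1, seed=5)
        results = m.IntegrativeModel(std, m.label_response(pheno),
                                     signature_results.gene_set, cfg).fit()
        pred = results.predict(std)
        pd.testing.assert_series_equal(pred.probabilities, results.fittedvalues)

    def test_missing_feature_policies(self, patient_sim, signature_results):
        matrix, pheno, _ = patient_sim
        std = m.standardize_genes(matrix)
        cfg = m.ForestConfig(n_trees=30, mtry_grid=(2,), inner_repeats=1, seed=5)
        results = m.IntegrativeModel(std, m.label_response(pheno),
                                     signature_results.gene_set, cfg).fit()
        n_feat = len(results.features.genes)
        # drop 10% of model genes -> imputed with warning
        drop_few = results.features.genes[: int(0.1 * n_feat)]
        keep = [g for g in std.gene_ids if g not in set(drop_few)]
        pred = results.predict(std.select_genes(keep))
        assert len(pred.probabilities) == std.n_samples
        # drop all model genes -> error
        keep_none = [g for g in std.gene_ids
                     if g not in set(results.features.genes)]
        with pytest.raises(ValueError, match="missing"):
            results.predict(std.select_genes(keep_none))


class TestCompareGroups:
    def test_null_case_flat(self, rng):
        vals = rng.uniform(0, 1, 30)
        probs = pd.Series(np.tile(vals, 2),
                          index=[f"s{i}" for i in range(60)])
        groups = pd.Series(["a"] * 30 + ["b"] * 30, index=probs.index)
        comp = m.compare_groups(probs, groups)
        assert comp.anova_p > 0.9
        assert (comp.pairwise["p_adj"] > 0.9).all()

    def test_strong_separation_recovered(self, rng):
        means = {"low": 0.2, "mid": 0.5, "high": 0.8}
        probs, groups = [], []
        for g, mu in means.items():
            probs.extend(np.clip(rng.normal(mu, 0.05, 50), 0, 1))
            groups.extend([g] * 50)
        probs = pd.Series(probs, index=[f"s{i}" for i in range(150)])
        comp = m.compare_groups(probs, pd.Series(groups, index=probs.index))
        assert (comp.pairwise["p_adj"] < 1e-6).all()
        assert comp.group_means["low"] < comp.group_means["mid"] < comp.group_means["high"]

    def test_two_groups_equals_t_test(self, rng):
        a = rng.normal(0.4, 0.1, 25)
        b = rng.normal(0.5, 0.1, 25)
        probs = pd.Series(np.concatenate([a, b]),
                          index=[f"s{i}" for i in range(50)])
        groups = pd.Series(["a"] * 25 + ["b"] * 25, index=probs.index)
        comp = m.compare_groups(probs, groups)
        t_p = stats.ttest_ind(a, b).pvalue
        assert comp.anova_p == pytest.approx(t_p, rel=1e-9)

    def test_tukey_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        probs, groups = [], []
        for g, mu in (("a", 0.3), ("b", 0.4), ("c", 0.45)):
            probs.extend(rng.normal(mu, 0.1, 20))
            groups.extend([g] * 20)
        probs = pd.Series(probs, index=[f"s{i}" for i in range(60)])
        comp = m.compare_groups(probs, pd.Series(groups, index=probs.index))
        sm_res = pairwise_tukeyhsd(probs.to_numpy(), np.array(groups))
        sm_p = {(g1, g2): p for (g1, g2), p in
                zip([("a", "b"), ("a", "c"), ("b", "c")], sm_res.pvalues)}
        for _, row in comp.pairwise.iterrows():
            assert row["p_adj"] == pytest.approx(
                sm_p[(row["group1"], row["group2"])], abs=1e-6)

    def test_high_response_fraction(self):
        probs = pd.Series([0.9, 0.8, 0.1, 0.2], index=list("wxyz"))
        groups = pd.Series(["hi", "hi", "lo", "lo"], index=probs.index)
        comp = m.compare_groups(probs, groups, cutoff=0.75)
        assert comp.high_response_fraction == {"hi": 1.0, "lo": 0.0}

    def test_singleton_group_rejected(self):
        probs = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        groups = pd.Series(["g1", "g1", "g2"], index=probs.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            m.compare_groups(probs, groups)


def test_derived_seeds_stable_and_bounded():
    s1 = _derive_seed(17, "P001")
    assert s1 == _derive_seed(17, "P001")
    assert 0 <= s1 < 2 ** 31
    assert s1 != _derive_seed(17, "P002") != _derive_seed(18, "P001")
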