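"""Cross-validation scheme, classifier contract, ROC/AUC, fusion estimator."""

import numpy as np
import pytest
from scipy import stats

from specfuse.blocks import FTIR, RAMAN, SpectralBlock
from specfuse.configs import TABLE1
from specfuse.evaluation import (FusionModel, assemble_blocks,
                                 fit_binary_classifier, model_from_config,
                                 roc_auc, run_config, stratified_kfold)


class TestStratifiedKfold:
    def test_balanced_cohort_gives_three_plus_three_folds(self):
        y = np.repeat([0, 1], 18)
        assignment = stratified_kfold(y, k=6, seed=0)
        for fold in range(6):
            members = y[assignment == fold]
            assert members.size == 6
            assert (members == 0).sum() == 3 and (members == 1).sum() == 3

    def test_leave_one_out_degenerate_case(self):
        y = np.array([0, 1, 0, 1])
        np.testing.assert_array_equal(stratified_kfold(y, k=4), np.arange(4))

    def test_seed_determinism(self):
        y = np.repeat([0, 1], 12)
        a = stratified_kfold(y, k=6, seed=3)
        b = stratified_kfold(y, k=6, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_small_class_rejected(self):
        y = np.array([0] * 10 + [1] * 3)
        with pytest.raises(ValueError, match="stratify"):
            stratified_kfold(y, k=6)


class TestBinaryClassifier:
    def test_separable_data_fits_perfectly(self):
        X = np.r_[np.full((10, 1), -2.0), np.full((10, 1), 2.0)]
        y = np.repeat([0, 1], 10)
        clf = fit_binary_classifier(X, y)
        assert (clf.predict(X) == y).all()
        p = clf.predict_proba(X)
        assert np.all((p > 0) & (p < 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_binary_classifier(np.ones((5, 2)), np.zeros(5))

    def test_duplicated_feature_leaves_predictions_unchanged(self, rng):
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=30) > 0).astype(int)
        lone = fit_binary_classifier(X, y)
        dup = fit_binary_classifier(np.hstack([X, X[:, :1]]), y)
        p1 = lone.predict_proba(X)[:, 1]
        p2 = dup.predict_proba(np.hstack([X, X[:, :1]]))[:, 1]
        # the two copies share the weight; the ridge geometry shifts the
        # probabilities slightly but never the decisions
        np.testing.assert_allclose(p1, p2, atol=0.1)
        np.testing.assert_array_equal(p1 >= 0.5, p2 >= 0.5)
        w = dup.coef_.ravel()
        assert abs(w[0] - w[4]) < 1e-4  # symmetric split across the copies

    def test_label_permutation_scores_near_chance(self):
        accs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(36, 10))
            y = rng.permutation(np.repeat([0, 1], 18))
            assignment = stratified_kfold(y, k=6, seed=seed)
            correct = 0
            for fold in range(6):
                te = assignment == fold
                clf = fit_binary_classifier(X[~te], y[~te])
                correct += (clf.predict(X[te]) == y[te]).sum()
            accs.append(correct / 36)
        half = 2.576 * np.sqrt(0.25 / (8 * 36))
        assert abs(np.mean(accs) - 0.5) < half + 0.02


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(np.array([0.1, 0.2, 0.8, 0.9]),
                         np.array([0, 0, 1, 1]))
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc(np.full(10, 0.5), np.repeat([0, 1], 5))
        assert abs(auc - 0.5) < 1e-12

    def test_hand_example(self):
        _, auc = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]),
                         np.array([0, 0, 1, 1]))
        assert abs(auc - 0.75) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_u_statistic_identity(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.uniform(size=40), 2)  # force some ties
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        _, auc = roc_auc(scores, labels)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                               alternative="two-sided").statistic
        n1 = (labels == 1).sum()
        n0 = (labels == 0).sum()
        assert abs(auc - u / (n1 * n0)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.zeros(4))


def _toy_blocks(rng, n=36, p_r=30, p_f=20, effect=2.0):
    y = np.repeat([0, 1], n // 2)
    Xr = rng.normal(size=(n, p_r))
    Xr[:, 3] += effect * y
    Xf = rng.normal(size=(n, p_f))
    Xf[:, 7] += effect * y
    ids = [f"s{i}" for i in range(n)]
    blocks = {
        RAMAN: SpectralBlock(RAMAN, np.linspace(610, 1720, p_r), Xr, ids),
        FTIR: SpectralBlock(FTIR, np.linspace(400, 4000, p_f), Xf, ids),
    }
    return blocks, y


class TestFusionModel:
    def test_lldf_consumes_full_concatenated_width(self, default_blocks):
        blocks, _ = default_blocks
        X, sizes, _ = assemble_blocks(TABLE1[10], blocks)
        assert X.shape[1] == 2883 and sizes == (1015, 1868)
        X, sizes, _ = assemble_blocks(TABLE1[13], blocks)
        assert X.shape[1] == 1742 and sizes == (1015, 727)

    def test_scalers_fit_on_training_rows_only(self, rng):
        blocks, y = _toy_blocks(rng)
        X, sizes, _ = assemble_blocks(TABLE1[10], blocks)
        model = FusionModel(option=2, block_sizes=sizes).fit(X[:30], y[:30])
        np.testing.assert_allclose(model.unit_scalers_[0].mean_,
                                   X[:30, :sizes[0]].mean(axis=0), atol=1e-12)

    def test_hldf_with_duplicated_block_equals_single_block(self, rng):
        blocks, y = _toy_blocks(rng)
        # present the same matrix as both modality blocks
        twin = SpectralBlock(FTIR, np.linspace(400, 4000, 30),
                             blocks[RAMAN].X, blocks[RAMAN].subject_ids)
        X2 = np.hstack([blocks[RAMAN].X, twin.X])
        hldf = FusionModel(option=4, block_sizes=(30, 30)).fit(X2, y)
        single = FusionModel(option=1, block_sizes=(30,)).fit(blocks[RAMAN].X, y)
        np.testing.assert_allclose(
            hldf.predict_proba(X2)[:, 1],
            single.predict_proba(blocks[RAMAN].X)[:, 1], atol=1e-9)

    def test_predict_threshold_tie_is_positive(self):
        model = FusionModel(option=1, block_sizes=(1,))
        model.classes_ = np.array([0, 1])
        model.threshold = 0.5
        # direct check of the decision rule on synthetic probabilities
        probs = np.array([0.49, 0.5, 0.51])
        labels = np.where(probs >= model.threshold, 1, 0)
        np.testing.assert_array_equal(labels, [0, 1, 1])

    @pytest.mark.parametrize("row", [2, 11, 16, 21])
    def test_fs_rows_reduce_to_percentile_counts(self, rng, row):
        from specfuse.configs import nominal_feature_count
        blocks, y = _toy_blocks(rng, p_r=40, p_f=30)
        cfg = TABLE1[row]
        X, sizes, _ = assemble_blocks(cfg, blocks)
        model = model_from_config(cfg, sizes, fs_n_iter=3, random_state=0)
        model.fit(X, y)
        selectors = [r for r in model.reducers_ if r is not None]
        expect = nominal_feature_count(cfg, n_raman=40, n_ftir_full=30,
                                       n_ftir_fp=30)
        got = [int(s.get_support().sum()) for s in selectors]
        if cfg.option == 2:
            assert got == [expect]
        else:
            assert "/".join(str(g) for g in got) == str(expect).replace(" ", "") \
                or sum(got) == expect


class TestRunConfig:
    def test_strong_signal_recovers_high_accuracy(self, rng):
        blocks, y = _toy_blocks(rng, effect=6.0)
        result = run_config(TABLE1[10], blocks, y, n_repeats=2, seed=1)
        assert result.mean_accuracy > 0.9
        assert result.mean_auc > 0.95
        assert result.accuracies.shape == (2,)
        assert result.fold_accuracies.shape == (2, 6)
        assert result.confusion.sum() == 2 * 36

    def test_determinism_across_runs(self, rng):
        blocks, y = _toy_blocks(rng)
        a = run_config(TABLE1[1], blocks, y, n_repeats=2, seed=5)
        b = run_config(TABLE1[1], blocks, y, n_repeats=2, seed=5)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        np.testing.assert_array_equal(a.aucs, b.aucs)

    def test_se_shrinks_with_repeats(self, rng):
        """SE of the mean accuracy scales about like 1/sqrt(repeats)."""
        blocks, y = _toy_blocks(rng, effect=1.0)
        few = run_config(TABLE1[1], blocks, y, n_repeats=4, seed=2)
        many = run_config(TABLE1[1], blocks, y, n_repeats=16, seed=2)
        if few.se_accuracy > 0:
            assert many.se_accuracy < few.se_accuracy * 1.2

    def test_fr_rows_record_chosen_components(self, rng):
        blocks, y = _toy_blocks(rng, effect=3.0)
        result = run_config(TABLE1[3], blocks, y, n_repeats=1, seed=0)
        assert len(result.chosen_components) == 6  # one record per fold
        for chosen in result.chosen_components:
            assert all(1 <= c <= 10 for c in chosen)
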