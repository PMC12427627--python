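"""Metrics, ROC, folds, pipeline orchestration, ablation harness, CLI."""

import json

import numpy as np
import pytest

import neurofuse as nf
from neurofuse.evaluation import ABLATION_VARIANTS, ConfusionMatrix


class TestConfusion:
    def test_perfect_predictions(self):
        cm = nf.confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (2, 2, 0, 0)

    def test_all_wrong(self):
        cm = nf.confusion([1, 0], [0, 1])
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (0, 0, 1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nf.confusion([0, 1], [0])

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            nf.confusion([0, 2], [0, 1])


class TestMetrics:
    def test_balanced_224_subject_worked_example(self):
        """A 224-subject confusion matrix with one error per class."""
        report = nf.metrics_from_confusion(ConfusionMatrix(TP=111, TN=111,
                                                           FP=1, FN=1))
        assert report.n_correct == 222
        assert report.accuracy == pytest.approx(222 / 224)
        assert report.precision == pytest.approx(111 / 112)
        assert report.recall == pytest.approx(111 / 112)

    def test_matches_bruteforce_counting(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 40))
            yt = rng.integers(0, 2, n)
            yp = rng.integers(0, 2, n)
            if yt.sum() in (0, n):
                continue
            report = nf.metrics_from_confusion(nf.confusion(yt, yp))
            tp = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 1)
            fp = sum(1 for a, b in zip(yt, yp) if a == 0 and b == 1)
            fn = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 0)
            tn = n - tp - fp - fn
            assert report.accuracy == (tp + tn) / n
            if tp + fp:
                assert report.precision == tp / (tp + fp)
            if tp + fn:
                assert report.recall == tp / (tp + fn)
            if tn + fp:
                assert report.specificity == tn / (tn + fp)

    def test_undefined_precision_flagged_not_zeroed(self):
        with pytest.warns(UserWarning, match="precision"):
            report = nf.metrics_from_confusion(ConfusionMatrix(TP=0, TN=3,
                                                               FP=0, FN=2))
        assert np.isnan(report.precision)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            nf.metrics_from_confusion(ConfusionMatrix(0, 0, 0, 0))


class TestRoc:
    def test_scores_equal_labels_give_perfect_auc(self):
        _, auc = nf.roc_auc([0, 1, 0, 1], [0, 1, 0, 1])
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        _, auc = nf.roc_auc([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3])
        assert auc == 0.5

    def test_pairwise_concordance_example(self):
        # 4 class pairs, 3 concordant -> AUC 0.75
        _, auc = nf.roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotonicity(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        curve, _ = nf.roc_auc(y, rng.random(50))
        assert curve.fpr[0] == curve.tpr[0] == 0.0
        assert curve.fpr[-1] == curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_rank_auc_equals_trapezoid_with_and_without_ties(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 60)
            y[0], y[1] = 0, 1
            scores = np.round(rng.random(60), int(rng.integers(1, 4)))  # forces ties
            curve, auc = nf.roc_auc(y, scores)
            trapezoid = np.trapezoid(curve.tpr, curve.fpr)
            assert abs(auc - trapezoid) < 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            nf.roc_auc([1, 1], [0.2, 0.6])


class TestStratifiedKFold:
    def test_balanced_ten_subjects_one_of_each_per_fold(self):
        y = np.array([0, 1] * 5)
        folds = nf.stratified_kfold(y, 5, seed=0)
        for fold in folds:
            assert sorted(y[fold].tolist()) == [0, 1]

    def test_folds_partition_index_set(self, rng):
        y = rng.integers(0, 2, 37)
        y[:6] = [0, 0, 0, 1, 1, 1]
        folds = nf.stratified_kfold(y, 3, seed=1)
        allidx = np.sort(np.concatenate(folds))
        assert np.array_equal(allidx, np.arange(37))

    def test_same_seed_same_folds(self, rng):
        y = rng.integers(0, 2, 24)
        y[:2] = [0, 1]
        f1 = nf.stratified_kfold(y, 4, seed=9)
        f2 = nf.stratified_kfold(y, 4, seed=9)
        for a, b in zip(f1, f2):
            assert np.array_equal(a, b)

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError):
            nf.stratified_kfold(np.array([0, 0, 0, 1]), 2)


class TestPipeline:
    def test_deterministic_given_seed(self, tiny_cohort, fast_config):
        r1 = nf.run_pipeline(tiny_cohort, fast_config)
        r2 = nf.run_pipeline(tiny_cohort, fast_config)
        assert r1.metrics.to_dict() == r2.metrics.to_dict()
        assert r1.predictions.equals(r2.predictions)

    def test_learns_planted_dual_signal(self, tiny_cohort, fast_config):
        result = nf.run_pipeline(tiny_cohort, fast_config)
        assert result.metrics.accuracy >= 0.7
        assert result.confusion.total == len(result.predictions)
        assert result.metrics.n_correct == result.confusion.TP + result.confusion.TN

    def test_probabilities_normalized(self, tiny_cohort, fast_config):
        result = nf.run_pipeline(tiny_cohort, fast_config)
        rows = result.predictions[["p_control", "p_asd"]].to_numpy()
        assert np.abs(rows.sum(axis=1) - 1.0).max() < 1e-6


class TestAblation:
    def test_exactly_five_variants_with_shared_structure(self, tiny_cohort,
                                                         fast_config):
        report = nf.run_ablation(tiny_cohort, fast_config, n_folds=3)
        assert set(report.variants) == {
            "full", "no_autoencoder", "no_gami", "no_cnn_gnn", "no_hypernetwork"
        }
        for name in report.variants:
            assert len(report.fold_accuracies[name]) == 3

    def test_full_and_no_ae_differ_only_in_fusion_stage(self):
        full, no_ae = ABLATION_VARIANTS["full"], ABLATION_VARIANTS["no_autoencoder"]
        diff = {k for k in full if full[k] != no_ae[k]}
        assert diff == {"use_autoencoder"}

    def test_single_modality_variants_drop_one_branch(self):
        assert not ABLATION_VARIANTS["no_gami"]["use_gami"]
        assert not ABLATION_VARIANTS["no_cnn_gnn"]["use_mri"]
        assert not ABLATION_VARIANTS["no_hypernetwork"]["use_hypernet"]


class TestPermutationImportance:
    def test_unused_dimension_scores_exactly_zero(self, rng):
        Z = rng.standard_normal((80, 4))
        y = (Z[:, 0] > 0).astype(int)
        table = nf.permutation_importance(
            lambda M: (M[:, 0] > 0).astype(int), Z, y, n_repeats=5, seed=0
        )
        unused = table.set_index("dimension").loc[[1, 2, 3], "importance"]
        assert np.all(unused == 0.0)
        assert table.iloc[0]["dimension"] == 0

    def test_duplicated_dimension_shares_importance(self, rng):
        """Each copy of a duplicated predictor scores at most the unique copy."""
        Z = rng.standard_normal((200, 2))
        y = (Z[:, 0] > 0).astype(int)
        Zdup = np.column_stack([Z[:, 0], Z[:, 0], Z[:, 1]])

        def clf(M):
            return ((M[:, 0] + M[:, 1]) / 2 > 0).astype(int)

        unique_imp = nf.permutation_importance(
            lambda M: (M[:, 0] > 0).astype(int), Z, y, n_repeats=10, seed=1
        ).set_index("dimension").loc[0, "importance"]
        dup = nf.permutation_importance(clf, Zdup, y, n_repeats=10, seed=1)
        dup = dup.set_index("dimension")
        assert dup.loc[0, "importance"] <= unique_imp
        assert dup.loc[1, "importance"] <= unique_imp

    def test_reproducible_with_seed(self, rng):
        Z = rng.standard_normal((50, 3))
        y = rng.integers(0, 2, 50)
        fn = lambda M: (M[:, 0] > 0).astype(int)  # noqa: E731
        t1 = nf.permutation_importance(fn, Z, y, n_repeats=4, seed=3)
        t2 = nf.permutation_importance(fn, Z, y, n_repeats=4, seed=3)
        assert t1.equals(t2)
        assert np.all(np.isfinite(t1["importance"]))


class TestCli:
    def test_simulate_train_evaluate_roundtrip(self, tmp_path):
        from click.testing import CliRunner

        from neurofuse.cli import main

        runner = CliRunner()
        cohort_dir = tmp_path / "cohort"
        out_dir = tmp_path / "run"
        res = runner.invoke(main, [
            "simulate", "--n", "24", "--n-features", "6",
            "--behavioral-effect", "2.0", "--roi-effect", "1.0",
            "--shape", "4,4,4", "--n-rois", "8", "--seed", "1",
            "--out", str(cohort_dir),
        ])
        assert res.exit_code == 0, res.output
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "seed: 1\n"
            "gami: {epochs: 2, max_interactions: 1, seed: 1}\n"
            "encoder: {embed_dim: 8, gnn_hidden: 4, epochs: 2, seed: 1}\n"
            "fusion: {epochs: 2, seed: 1}\n"
            "hypernet: {epochs: 3, seed: 1}\n"
        )
        res = runner.invoke(main, [
            "train", "--cohort", str(cohort_dir), "--config", str(cfg),
            "--out", str(out_dir),
        ])
        assert res.exit_code == 0, res.output
        metrics = json.loads((out_dir / "metrics.json").read_text())
        assert 0.0 <= metrics["accuracy"] <= 1.0
        res = runner.invoke(main, [
            "evaluate", "--predictions", str(out_dir / "predictions.csv"),
        ])
        assert res.exit_code == 0, res.output
        assert json.loads(res.output)["accuracy"] == metrics["accuracy"]
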