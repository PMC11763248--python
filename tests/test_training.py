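"""Splitting, SMOTE, class weights, and fitting contracts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from parcelcam.model_graph import GraphNetConfig, build_graph_net
from parcelcam.synthetic import EffectSpec, simulate_graph_cohort
from parcelcam.training import (
    MetricsSummary, TrainConfig, class_weights, final_fit, smote_oversample,
    stratified_subject_kfold, train_model,
)


class TestKFold:
    def test_no_subject_spans_two_folds(self, small_graph_cohort):
        folds = stratified_subject_kfold(small_graph_cohort, k=5, seed=0)
        seen = {}
        for i, fold in enumerate(folds.folds):
            for sid in fold:
                sub = folds.session_to_subject[sid]
                assert seen.setdefault(sub, i) == i

    def test_balanced_cohort_splits_subjects_evenly(self):
        effect = EffectSpec(seed=1)
        cohort = simulate_graph_cohort(n_nodes=6, n_subjects=100,
                                       sessions_per_subject=1,
                                       class_ratio=0.5, effect=effect,
                                       dual_class_fraction=0.0)
        folds = stratified_subject_kfold(cohort, k=10, seed=0)
        sizes = [len({folds.session_to_subject[s] for s in f})
                 for f in folds.folds]
        assert sizes == [10] * 10

    def test_per_fold_class_ratio_tracks_global(self):
        """Measured over 20 seeds on the default imbalanced cohort."""
        effect = EffectSpec(seed=2)
        cohort = simulate_graph_cohort(n_nodes=6, n_subjects=120, effect=effect)
        table = cohort.session_table().set_index("session_id")
        global_ad = (table["label"] == "AD").mean()
        for seed in range(20):
            folds = stratified_subject_kfold(cohort, k=5, seed=seed)
            for fold in folds.folds:
                frac = (table.loc[fold, "label"] == "AD").mean()
                assert abs(frac - global_ad) < 0.15

    def test_k_larger_than_subject_count_rejected(self, small_graph_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            stratified_subject_kfold(small_graph_cohort, k=1000)


class TestSmote:
    def test_balanced_input_returned_unchanged(self, small_graph_cohort):
        graphs = [s.payload for s in small_graph_cohort.sessions]
        hc = [g for g in graphs if g.label == "HC"][:5]
        ad = [g for g in graphs if g.label == "AD"][:5]
        out = smote_oversample(hc + ad, seed=0)
        assert len(out) == 10

    def test_counts_balanced_after_oversampling(self, small_graph_cohort):
        graphs = [s.payload for s in small_graph_cohort.sessions]
        out = smote_oversample(graphs, seed=0)
        labels = pd.Series([g.label for g in out]).value_counts()
        assert labels["AD"] == labels["HC"]

    def test_two_member_minority_interpolates_on_segment(self, rng):
        from conftest import make_graph

        def sym(m):
            m = np.abs(m)
            m = m + m.T
            np.fill_diagonal(m, 0.0)
            return m

        a, b = sym(rng.standard_normal((6, 6))), sym(rng.standard_normal((6, 6)))
        majority = [make_graph(sym(rng.standard_normal((6, 6))), label="HC",
                               session_id=f"h{i}") for i in range(6)]
        out = smote_oversample(
            majority + [make_graph(a, label="AD", session_id="a"),
                        make_graph(b, label="AD", session_id="b")],
            k_neighbors=1, seed=3)
        synth = [g for g in out if g.subject_id.startswith("smote")]
        assert len(synth) == 4
        iu = np.triu_indices(6, 1)
        for g in synth:
            lam = (g.matrix[iu] - a[iu]) / np.where(b[iu] - a[iu] == 0, 1,
                                                    b[iu] - a[iu])
            lam = lam[np.abs(b[iu] - a[iu]) > 1e-12]
            assert np.allclose(lam, lam[0], atol=1e-9)
            assert -1e-9 <= lam[0] <= 1 + 1e-9

    def test_synthetic_graphs_satisfy_invariants(self, small_graph_cohort):
        from parcelcam.preprocess import validate_graph

        graphs = [s.payload for s in small_graph_cohort.sessions]
        for g in smote_oversample(graphs, seed=1):
            assert validate_graph(g).ok

    def test_minority_smaller_than_k_rejected(self, small_graph_cohort):
        graphs = [s.payload for s in small_graph_cohort.sessions]
        hc = [g for g in graphs if g.label == "HC"]
        ad = [g for g in graphs if g.label == "AD"][:3]
        with pytest.raises(ValueError, match="k"):
            smote_oversample(hc + ad, k_neighbors=5)


class TestClassWeights:
    def test_balanced_gives_unit_weights(self):
        w = class_weights(["AD", "HC"] * 10)
        assert w == {"HC": 1.0, "AD": 1.0}

    def test_inverse_frequency(self):
        w = class_weights(["HC"] * 30 + ["AD"] * 10)
        assert w["AD"] == pytest.approx(2.0)
        assert w["HC"] == pytest.approx(2.0 / 3.0)


class TestMetricsSummary:
    def test_confusion_rows_sum_to_one(self, rng):
        frames = []
        for f in range(4):
            y = rng.integers(0, 2, size=30)
            p = rng.integers(0, 2, size=30)
            frames.append(pd.DataFrame({"y_true": y, "y_pred": p}))
        ms = MetricsSummary.from_fold_frames(frames)
        assert np.allclose(ms.confusion_median.sum(axis=1), 1.0, atol=1e-9)
        assert all(v >= 0 for v in ms.iqr.values())


class TestFitting:
    CFG = TrainConfig(batch_size=16, imbalance="smote", patience=3,
                      max_epochs=5, lr=3e-3, seed=0)

    @staticmethod
    def build(seed):
        return build_graph_net(
            GraphNetConfig(n_nodes=12, gpc_channels=(4, 4, 4), fc_sizes=(8, 1)),
            seed=seed)

    def test_untrained_model_scores_near_chance_auc(self, rng):
        """AUC of an untrained network on balanced random data is ~0.5."""
        aucs = []
        for seed in range(10):
            model = self.build(seed)
            m = np.abs(rng.standard_normal((100, 1, 12, 12)))
            m = m + np.swapaxes(m, 2, 3)
            m[:, :, np.arange(12), np.arange(12)] = 0.0
            y = np.array([0, 1] * 50)
            logits = model.forward_logits(m, train=False)
            aucs.append(roc_auc_score(y, logits))
        assert 0.4 < float(np.median(aucs)) < 0.6

    def test_cross_validation_yields_fold_metrics_and_predictions(
            self, small_graph_cohort):
        folds = stratified_subject_kfold(small_graph_cohort, k=3, seed=1)
        models, summary, preds = train_model(self.build, small_graph_cohort,
                                             folds, self.CFG)
        assert len(models) == 3
        assert len(preds) == len(small_graph_cohort.sessions)
        assert set(summary.per_fold.columns) == {"fold", "tpr", "tnr",
                                                 "accuracy"}

    def test_final_fit_covers_every_session_and_flags_in_sample(
            self, small_graph_cohort):
        model, preds, info = final_fit(self.build, small_graph_cohort, self.CFG)
        assert len(preds) == len(small_graph_cohort.sessions)
        n_val = (~preds["in_sample"]).sum()
        # the held-out part is ~10% of subjects' sessions
        assert 0 < n_val < 0.3 * len(preds)

    def test_final_fit_split_is_subject_exclusive(self, small_graph_cohort):
        _, preds, _ = final_fit(self.build, small_graph_cohort, self.CFG)
        val_subjects = set(preds.loc[~preds["in_sample"], "subject_id"])
        train_subjects = set(preds.loc[preds["in_sample"], "subject_id"])
        assert not val_subjects & train_subjects

    def test_same_seed_reproduces_predictions(self, small_graph_cohort):
        _, a, _ = final_fit(self.build, small_graph_cohort, self.CFG)
        _, b, _ = final_fit(self.build, small_graph_cohort, self.CFG)
        assert np.array_equal(a["prob_ad"].to_numpy(), b["prob_ad"].to_numpy())


class TestNullCohort:
    def test_null_effect_trains_to_chance_accuracy(self):
        """With no planted effect a balanced cohort cannot be classified:
        median fold accuracy stays near 0.5."""
        effect = EffectSpec(effect_parcels=frozenset(), effect_size=0.0,
                            noise_sd=0.05, seed=42)
        cohort = simulate_graph_cohort(n_nodes=20, n_subjects=150,
                                       sessions_per_subject=1,
                                       class_ratio=0.5, effect=effect,
                                       dual_class_fraction=0.0)
        build = lambda s: build_graph_net(
            GraphNetConfig(n_nodes=20, gpc_channels=(4, 4, 4),
                           fc_sizes=(8, 1)), seed=s)
        cfg = TrainConfig(batch_size=64, imbalance="smote", patience=3,
                          max_epochs=10, lr=3e-3, seed=0)
        folds = stratified_subject_kfold(cohort, k=5, seed=0)
        _, summary, _ = train_model(build, cohort, folds, cfg)
        assert 0.35 <= summary.median["accuracy"] <= 0.65
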