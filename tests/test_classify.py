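"""Classification protocol: filtering, splits, metrics, training, fusion."""

import numpy as np
import pandas as pd
import pytest

from meltid.classify import (
    SmallCNN,
    TrainConfig,
    evaluate,
    filter_min_samples,
    fuse_models,
    get_backbone,
    gradcam,
    grid_search,
    predict,
    report_from_probs,
    retrain_full,
    stratified_split,
    train_classifier,
)
from meltid.classify.protocol import _largest_remainder, load_arrays, select_best
from meltid.imaging import RenderStyle, compute_axis_limits, render_dataset
from meltid.meltsim import MeltModelParams, make_labeled_dataset
from meltid.pipeline import process_runs


# ---- a small, well-separated rendered corpus shared by the training tests ----

@pytest.fixture(scope="module")
def toy_manifest(panel10, tmp_path_factory):
    """3 well-separated species x 10 runs, all three kinds rendered."""
    species = [panel10[5], panel10[6], panel10[8]]
    runs, _ = make_labeled_dataset(species, 10, MeltModelParams(),
                                   master_seed=11)
    curvesets = process_runs(runs)
    style = RenderStyle(axis_limits=compute_axis_limits(curvesets))
    out = tmp_path_factory.mktemp("toy_images")
    manifest = render_dataset(curvesets, out, style)
    return stratified_split(manifest, seed=11)


@pytest.fixture(scope="module")
def toy_config():
    return TrainConfig(epochs=8, learning_rates=(1e-3,), weight_decays=(0.0,),
                       seed=11)


@pytest.fixture(scope="module")
def toy_model(toy_manifest, toy_config):
    model, history, opt_acc = train_classifier(toy_manifest, "melt", toy_config)
    return model, history, opt_acc


class TestFilterMinSamples:
    def test_mixed_counts(self):
        retained, excluded, removed = filter_min_samples({"A": 5, "B": 4, "C": 10})
        assert retained == {"A", "C"} and excluded == {"B"} and removed == 4

    def test_nothing_removed(self):
        retained, excluded, removed = filter_min_samples({"A": 5, "B": 9})
        assert excluded == set() and removed == 0

    def test_all_excluded_is_error(self):
        with pytest.raises(ValueError):
            filter_min_samples({"A": 1, "B": 2})


class TestStratifiedSplit:
    @pytest.mark.parametrize("n,expected", [(5, [3, 1, 1]), (10, [6, 2, 2]),
                                            (12, [7, 3, 2])])
    def test_largest_remainder_counts(self, n, expected):
        assert _largest_remainder(n, (0.6, 0.2, 0.2)) == expected

    def test_split_counts_and_determinism(self):
        rows = [{"run_id": f"r{s}{i}", "species_label": s, "kind": "melt",
                 "image_path": "x"}
                for s in "ABC" for i in range(5)]
        manifest = pd.DataFrame(rows)
        a = stratified_split(manifest, seed=4)
        b = stratified_split(manifest, seed=4)
        assert a["split"].tolist() == b["split"].tolist()
        counts = a.groupby(["species_label", "split"]).size().unstack()
        assert (counts["train"] == 3).all()
        assert (counts["val"] == 1).all()
        assert (counts["test"] == 1).all()
        c = stratified_split(manifest, seed=5)
        assert c["split"].tolist() != a["split"].tolist()
        assert c.groupby(["species_label", "split"]).size().unstack().equals(counts)

    def test_kinds_of_one_run_share_split(self, toy_manifest):
        per_run = toy_manifest.groupby("run_id")["split"].nunique()
        assert (per_run == 1).all()

    def test_small_class_rejected(self):
        rows = [{"run_id": f"r{i}", "species_label": "A", "kind": "melt",
                 "image_path": "x"} for i in range(4)]
        with pytest.raises(ValueError, match="< 5"):
            stratified_split(pd.DataFrame(rows))


class TestMetrics:
    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_cls = rng.integers(2, 8)
            n = int(rng.integers(n_cls, 60))
            y_true = rng.integers(0, n_cls, size=n)
            y_pred = rng.integers(0, n_cls, size=n)
            probs = np.zeros((n, n_cls))
            probs[np.arange(n), y_pred] = 1.0
            rep = report_from_probs(probs, y_true, [str(i) for i in range(n_cls)])
            assert rep.recall == pytest.approx(rep.accuracy, abs=1e-12)

    def test_hand_computed_confusion_matrix(self):
        # confusion matrix [[5,0,0],[1,4,0],[0,0,5]]
        y_true = np.array([0] * 5 + [1] * 5 + [2] * 5)
        y_pred = np.array([0] * 5 + [0] + [1] * 4 + [2] * 5)
        probs = np.zeros((15, 3))
        probs[np.arange(15), y_pred] = 1.0
        rep = report_from_probs(probs, y_true, ["a", "b", "c"])
        assert rep.accuracy == pytest.approx(14 / 15)
        assert rep.recall == pytest.approx(14 / 15)
        assert rep.precision == pytest.approx((5 * (5 / 6) + 5 + 5) / 15)
        np.testing.assert_array_equal(
            rep.confusion_matrix, [[5, 0, 0], [1, 4, 0], [0, 0, 5]])

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 1])
        probs = np.eye(3)[y]
        rep = report_from_probs(probs, y, ["a", "b", "c"])
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0
        assert rep.avg_confidence == 1.0


class TestGridSearch:
    def test_tie_break_prefers_lower_lr_then_wd(self):
        table = pd.DataFrame([
            {"learning_rate": 1e-3, "weight_decay": 0.0, "optimal_val_accuracy": 0.9},
            {"learning_rate": 1e-4, "weight_decay": 1e-4, "optimal_val_accuracy": 0.9},
            {"learning_rate": 1e-4, "weight_decay": 0.0, "optimal_val_accuracy": 0.9},
        ])
        assert select_best(table) == (1e-4, 0.0)

    def test_single_cell(self):
        table = pd.DataFrame([{"learning_rate": 1e-3, "weight_decay": 0.0,
                               "optimal_val_accuracy": 0.5}])
        assert select_best(table) == (1e-3, 0.0)


class TestTraining:
    def test_history_and_separable_accuracy(self, toy_model, toy_config):
        model, history, opt_acc = toy_model
        assert len(history) == toy_config.epochs
        assert opt_acc == 1.0

    def test_deterministic_retrain(self, toy_manifest, toy_config):
        m1, _, acc1 = train_classifier(toy_manifest, "melt", toy_config)
        m2, _, acc2 = train_classifier(toy_manifest, "melt", toy_config)
        assert acc1 == acc2
        assert m1.weights_hash() == m2.weights_hash()

    def test_save_load_identical_predictions(self, toy_model, toy_manifest,
                                             tmp_path):
        model = toy_model[0]
        model.save(tmp_path / "model")
        loaded = SmallCNN.load(tmp_path / "model")
        X, _, _, _ = load_arrays(toy_manifest, "melt", "test",
                                 model.class_names, model.input_size)
        np.testing.assert_array_equal(model.predict_proba(X),
                                      loaded.predict_proba(X))

    def test_retrain_full_uses_train_plus_val_never_test(self, toy_manifest,
                                                         toy_config):
        audit: list = []
        model = retrain_full(toy_manifest, "melt", toy_config, (1e-3, 0.0),
                             audit=audit)
        runs = toy_manifest.drop_duplicates("run_id")
        expected = set(runs.loc[runs["split"].isin(["train", "val"]), "run_id"])
        test_ids = set(runs.loc[runs["split"] == "test", "run_id"])
        assert set(model.train_run_ids) == expected
        batched = {rid for batch in audit for rid in batch}
        assert batched == expected
        assert not (batched & test_ids)

    def test_evaluate_on_separable_toy(self, toy_manifest, toy_config):
        model = retrain_full(toy_manifest, "melt", toy_config, (1e-3, 0.0))
        rep = evaluate(model, toy_manifest, "melt")
        assert rep.accuracy == 1.0
        assert rep.n_test == rep.confusion_matrix.sum()

    def test_grid_search_returns_table_argmax(self, toy_manifest):
        config = TrainConfig(epochs=2, learning_rates=(1e-3, 1e-4),
                             weight_decays=(0.0,), seed=11)
        best, table = grid_search(toy_manifest, "melt", config)
        assert len(table) == 2
        assert best == select_best(table)


class TestBackbones:
    def test_unknown_backbone(self):
        with pytest.raises(ValueError, match="unknown"):
            get_backbone("alexnet", 3, 64, 0, ["a", "b", "c"])

    def test_torch_backbones_are_optional_plugins(self):
        with pytest.raises((RuntimeError, NotImplementedError), match="resnet18"):
            get_backbone("resnet18", 3, 64, 0, ["a", "b", "c"])


@pytest.fixture(scope="module")
def kind_models(toy_manifest, toy_config):
    return {kind: train_classifier(toy_manifest, kind, toy_config)[0]
            for kind in ("melt", "hrm", "derivative_hrm")}


class TestFusion:
    def test_fused_dimension_is_sum_of_latents(self, kind_models, toy_manifest):
        fused = fuse_models(kind_models, toy_manifest, seed=11)
        assert fused.input_dim == sum(m.latent_dim for m in kind_models.values())

    def test_fused_accuracy_close_to_best_single(self, kind_models,
                                                 toy_manifest):
        fused = fuse_models(kind_models, toy_manifest, seed=11)
        probs, y, _ = fused.predict_proba(toy_manifest, "test")
        fused_acc = (probs.argmax(axis=1) == y).mean()
        singles = [evaluate(m, toy_manifest, k).accuracy
                   for k, m in kind_models.items()]
        assert fused_acc >= max(singles) - 0.05

    def test_fused_deterministic(self, kind_models, toy_manifest):
        f1 = fuse_models(kind_models, toy_manifest, seed=11)
        f2 = fuse_models(kind_models, toy_manifest, seed=11)
        p1, _, _ = f1.predict_proba(toy_manifest, "test")
        p2, _, _ = f2.predict_proba(toy_manifest, "test")
        np.testing.assert_array_equal(p1, p2)

    def test_mismatched_class_lists_rejected(self, kind_models):
        from meltid.classify.protocol import FusedModel
        bad = dict(kind_models)
        bad["melt"] = SmallCNN(2, 64, 0, ["x", "y"])
        with pytest.raises(ValueError, match="class list"):
            FusedModel(bad)


class TestGradCam:
    def test_heatmap_normalized(self, toy_model, toy_manifest):
        model = toy_model[0]
        X, _, _, _ = load_arrays(toy_manifest, "melt", "test",
                                 model.class_names, model.input_size)
        heat = gradcam(model, X[0])
        assert heat.shape == (model.input_size, model.input_size)
        assert heat.min() == 0.0 and heat.max() == 1.0

    def test_constant_activations_give_zero_map(self):
        model = SmallCNN(3, input_size=64, seed=0)
        blank = np.zeros((1, 64, 64), dtype=np.float32)
        heat = gradcam(model, blank)
        assert np.all(heat == 0.0)

    def test_mass_concentrates_on_melt_transition(self, toy_model,
                                                  toy_manifest):
        model = toy_model[0]
        X, _, _, _ = load_arrays(toy_manifest, "melt", "test",
                                 model.class_names, model.input_size)
        heat = np.mean([gradcam(model, x) for x in X], axis=0)
        s = model.input_size
        # plot x-axis spans 60-90 degC over the axes box (16%..96% of width)
        def cols(t_lo, t_hi):
            lo = int(s * (0.16 + 0.80 * (t_lo - 60) / 30))
            hi = int(s * (0.16 + 0.80 * (t_hi - 60) / 30))
            return slice(lo, hi)
        transition = heat[:, cols(69, 83)].mean()
        baseline = heat[:, cols(86, 90)].mean()
        assert transition > baseline

    def test_invalid_layer(self, toy_model):
        with pytest.raises(ValueError, match="target_layer"):
            gradcam(toy_model[0], np.zeros((1, 64, 64), dtype=np.float32),
                    target_layer=7)
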