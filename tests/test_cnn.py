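import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucopipe.cnn import (
    CNNSpec,
    Conv2D,
    ConvBlockSpec,
    LabeledImages,
    ReLU,
    TrainingConfig,
    build_model,
    cross_validate,
    load_model,
    parameter_count,
    predict,
    predict_labels,
    save_model,
    softmax,
    split_dataset,
    train_model,
)

TINY_SPEC = CNNSpec(
    input_size=(16, 16, 1),
    conv_blocks=(ConvBlockSpec(4, 3, 2), ConvBlockSpec(8, 3, 2)),
    inter_block_normalization=False,
    dense_units=(16,),
    dropout_rate=0.0,
    class_count=4,
)
TINY_CLASSES = (50, 100, 150, 200)


def tiny_labeled_set(rng, n_per_class=6, side=16, n_classes=4):
    """Images whose mean intensity encodes the class; trivially learnable."""
    images, labels = [], []
    for k in range(n_classes):
        base = 60 + 40 * k
        for _ in range(n_per_class):
            img = np.clip(rng.normal(base, 2.0, (side, side)), 0, 255)
            images.append(img.astype(np.uint8))
            labels.append(k)
    return LabeledImages(np.stack(images), np.array(labels), TINY_CLASSES[:n_classes])


class TestBuildModel:
    def test_conv_layer_parameter_formula(self, rng):
        conv = Conv2D(1, 16, 3, 1, "same", rng)
        assert conv.W.size + conv.b.size == (3 * 3 * 1 + 1) * 16 == 160

    def test_rectifier(self):
        relu = ReLU()
        out = relu.forward(np.array([-3.0, 0.0, 5.0]), False, None)
        assert (out == [0.0, 0.0, 5.0]).all()

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_closed_form_matches_allocated_arrays(self, seed):
        gen = np.random.default_rng(seed)
        side = int(gen.integers(12, 48))
        spec = CNNSpec(
            input_size=(side, side, 1),
            conv_blocks=tuple(
                ConvBlockSpec(
                    int(gen.integers(2, 12)),
                    int(gen.choice([1, 3, 5])),
                    int(gen.choice([1, 2])),
                )
                for _ in range(2)
            ),
            inter_block_normalization=bool(gen.integers(0, 2)),
            dense_units=(int(gen.integers(4, 64)),),
            dropout_rate=float(gen.uniform(0, 0.9)),
            class_count=int(gen.integers(2, 16)),
        )
        model = build_model(spec, seed=seed, class_values=range(spec.class_count))
        assert model.trainable_parameter_count == parameter_count(spec)

    def test_default_profile_exceeds_75_million_parameters(self):
        assert parameter_count(CNNSpec()) > 75_000_000

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CNNSpec(class_count=0)
        with pytest.raises(ValueError):
            ConvBlockSpec(filters=8, kernel_size=0)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_softmax_outputs_normalized(self, seed):
        gen = np.random.default_rng(seed)
        logits = gen.normal(0, 10, (5, 16))
        p = softmax(logits)
        assert (p >= 0).all()
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-6


class TestSplitDataset:
    def test_balanced_1440_split(self):
        labels = np.repeat(np.arange(16), 90)
        ds = LabeledImages(np.zeros((1440, 4, 4), dtype=np.uint8), labels)
        tr, te = split_dataset(ds, TrainingConfig(seed=1))
        assert len(tr) == 1152 and len(te) == 288
        assert (np.bincount(tr.labels) == 72).all()
        assert (np.bincount(te.labels) == 18).all()

    def test_same_seed_reproduces_partition(self):
        labels = np.repeat(np.arange(4), 10)
        ds = LabeledImages(np.zeros((40, 4, 4), dtype=np.uint8), labels, TINY_CLASSES)
        a = split_dataset(ds, TrainingConfig(seed=7))
        b = split_dataset(ds, TrainingConfig(seed=7))
        assert (a[0].labels == b[0].labels).all()
        assert (a[0].images == b[0].images).all()

    def test_minimal_stratification(self):
        labels = np.repeat(np.arange(4), 2)
        ds = LabeledImages(np.zeros((8, 4, 4), dtype=np.uint8), labels, TINY_CLASSES)
        tr, te = split_dataset(ds, TrainingConfig(train_fraction=0.5, seed=0))
        assert (np.bincount(tr.labels, minlength=4) == 1).all()
        assert (np.bincount(te.labels, minlength=4) == 1).all()

    def test_singleton_class_rejected(self):
        ds = LabeledImages(
            np.zeros((3, 4, 4), dtype=np.uint8), np.array([0, 0, 1]), TINY_CLASSES
        )
        with pytest.raises(ValueError):
            split_dataset(ds, TrainingConfig(seed=0))


class TestTraining:
    @pytest.mark.parametrize("epochs", [1, 3])
    def test_history_length_equals_epochs(self, rng, epochs):
        ds = tiny_labeled_set(rng)
        cfg = TrainingConfig(epochs=epochs, batch_size=8, seed=0)
        tr, te = split_dataset(ds, cfg)
        model = build_model(TINY_SPEC, seed=0, class_values=TINY_CLASSES)
        _, hist = train_model(model, tr, te, cfg)
        assert len(hist.train_loss) == len(hist.val_loss) == epochs

    def test_memorizes_separable_data(self, rng):
        ds = tiny_labeled_set(rng, n_per_class=8)
        cfg = TrainingConfig(epochs=10, batch_size=8, learning_rate=1e-2, seed=1)
        tr, te = split_dataset(ds, cfg)
        model = build_model(TINY_SPEC, seed=1, class_values=TINY_CLASSES)
        model, hist = train_model(model, tr, te, cfg)
        assert hist.train_loss[-1] < 0.1 * hist.train_loss[0]
        pred = predict_labels(model, tr.images)
        assert (pred == tr.labels).mean() == 1.0

    def test_seeded_training_is_reproducible(self, rng):
        ds = tiny_labeled_set(rng)
        cfg = TrainingConfig(epochs=2, batch_size=8, seed=5)
        tr, te = split_dataset(ds, cfg)
        hists = []
        probas = []
        for _ in range(2):
            m = build_model(TINY_SPEC, seed=5, class_values=TINY_CLASSES)
            m, h = train_model(m, tr, te, cfg)
            hists.append(h)
            probas.append(m.predict_proba(te.images))
        assert hists[0].train_loss == hists[1].train_loss
        assert (probas[0] == probas[1]).all()

    def test_prediction_contract(self, rng):
        ds = tiny_labeled_set(rng)
        model = build_model(TINY_SPEC, seed=0, class_values=TINY_CLASSES)
        probs, label = predict(model, ds.images[0])
        assert probs.shape == (4,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert label.value == TINY_CLASSES[int(np.argmax(probs))]
        probs2, label2 = predict(model, ds.images[0])
        assert (probs == probs2).all() and label == label2

    def test_save_load_roundtrip(self, rng, tmp_path):
        ds = tiny_labeled_set(rng)
        cfg = TrainingConfig(epochs=2, batch_size=8, seed=2)
        tr, te = split_dataset(ds, cfg)
        model = build_model(TINY_SPEC, seed=2, class_values=TINY_CLASSES)
        model, _ = train_model(model, tr, te, cfg)
        save_model(model, tmp_path / "m")
        again = load_model(tmp_path / "m")
        assert (again.predict_proba(te.images) == model.predict_proba(te.images)).all()


class TestCrossValidate:
    def test_partition_conservation(self, rng):
        ds = tiny_labeled_set(rng, n_per_class=5, n_classes=2)
        cfg = TrainingConfig(epochs=1, batch_size=4, folds=2, seed=0)
        cm, folds = cross_validate(ds, dataclasses.replace(TINY_SPEC, class_count=2), cfg)
        assert cm.sum() == len(ds)
        assert sum(f["n_test"] for f in folds) == len(ds)

    def test_too_many_folds_rejected(self, rng):
        ds = tiny_labeled_set(rng, n_per_class=3)
        cfg = TrainingConfig(epochs=1, folds=4, seed=0)
        with pytest.raises(ValueError):
            cross_validate(ds, TINY_SPEC, cfg)

    def test_separable_data_recovers_diagonal(self, rng):
        ds = tiny_labeled_set(rng, n_per_class=8)
        cfg = TrainingConfig(
            epochs=10, batch_size=8, learning_rate=1e-2, folds=4, seed=3
        )
        cm, _ = cross_validate(ds, TINY_SPEC, cfg)
        assert np.trace(cm) / cm.sum() >= 0.9
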