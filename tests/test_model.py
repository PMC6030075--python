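import copy
from datetime import date, timedelta

import numpy as np
import pytest

from prognote.dataset import NEG, PAD, POS, UNDEFINED, PatientSequence
from prognote.model import (
    ModelConfig,
    SurvivalLSTM,
    predict,
    predictions_frame,
    train,
    weighted_loss,
)


def make_sequences(n, T, D, seed, signal=True):
    """Directly constructed labelled sequences: NEG visits carry a shifted
    input vector when ``signal`` is on, otherwise inputs are pure noise."""
    rng = np.random.default_rng(seed)
    seqs = []
    for i in range(n):
        k = int(rng.integers(2, T + 1))
        x = np.zeros((T, D))
        labels = np.full(T, PAD, dtype=np.int8)
        n_neg = int(rng.integers(0, max(1, k // 2)))
        for t in range(k):
            is_neg = t >= k - n_neg
            x[t] = rng.normal(size=D) + 1.0
            if signal and is_neg:
                x[t] += 3.0
            labels[t] = NEG if is_neg else POS
        seqs.append(
            PatientSequence(
                patient_id=f"P{i:03d}",
                x=x,
                labels=labels,
                visit_dates=[date(2015, 1, 1) + timedelta(days=7 * t) for t in range(k)],
                note_ids=[f"P{i:03d}-n{t:03d}" for t in range(k)],
            )
        )
    return seqs


class TestBuildModel:
    def test_layer_order(self):
        model = SurvivalLSTM(ModelConfig(input_dim=8))
        assert model.layer_order == [
            "lstm", "batchnorm", "lstm", "dropout", "time_distributed_softmax",
        ]

    def test_softmax_rows_sum_to_one(self):
        model = SurvivalLSTM(ModelConfig(input_dim=6, seed=1))
        x = np.random.default_rng(0).normal(size=(4, 7, 6))
        probs, _ = model.forward(x, training=False)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-12)

    def test_parameter_counts_match_closed_form(self):
        cfg = ModelConfig(input_dim=12, hidden1=50, hidden2=25)
        model = SurvivalLSTM(cfg)
        counts = model.parameter_count()
        assert counts["lstm_1"] == 4 * 50 * (12 + 50 + 1)
        assert counts["lstm_2"] == 4 * 25 * (50 + 25 + 1)
        # closed form equals the actual array sizes
        assert counts["lstm_1"] == (
            model.params["Wx1"].size + model.params["Wh1"].size + model.params["b1"].size
        )
        assert counts["lstm_2"] == (
            model.params["Wx2"].size + model.params["Wh2"].size + model.params["b2"].size
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_dim=4, dropout=1.0).validate()
        with pytest.raises(ValueError):
            ModelConfig(input_dim=4, hidden1=0).validate()


class TestWeightedLoss:
    def test_perfect_predictions_zero_loss(self):
        labels = np.array([[POS, NEG, PAD]])
        probs = np.eye(3)[labels]
        assert weighted_loss(labels, probs) == pytest.approx(0.0, abs=1e-12)

    def test_three_timestep_example_matches_direct_formula(self):
        labels = np.array([[POS, NEG, PAD]])
        probs = np.array([[[0.7, 0.2, 0.1], [0.3, 0.6, 0.1], [0.25, 0.25, 0.5]]])
        lam = (2.0, 1.0, 0.1)
        expected = -(2.0 * np.log(0.7) + 1.0 * np.log(0.6) + 0.1 * np.log(0.5)) / 3
        assert weighted_loss(labels, probs, lam) == pytest.approx(expected, abs=1e-12)

    def test_linear_in_class_weights(self):
        labels = np.array([[POS, NEG, PAD, POS]])
        rng = np.random.default_rng(0)
        raw = rng.random((1, 4, 3))
        probs = raw / raw.sum(axis=-1, keepdims=True)
        l1 = weighted_loss(labels, probs, (2.0, 1.0, 0.1))
        l2 = weighted_loss(labels, probs, (4.0, 2.0, 0.2))
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_undefined_timesteps_contribute_nothing(self):
        labels = np.array([[POS, UNDEFINED]])
        probs = np.array([[[1.0, 0.0, 0.0], [0.1, 0.4, 0.5]]])
        assert weighted_loss(labels, probs) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_probability_rows_rejected(self):
        labels = np.array([[POS]])
        with pytest.raises(ValueError):
            weighted_loss(labels, np.array([[[0.9, 0.9, 0.9]]]))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        cfg = ModelConfig(input_dim=4, hidden1=5, hidden2=3, dropout=0.0, seed=0)
        model = SurvivalLSTM(cfg)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 4, 4))
        y = rng.integers(0, 4, size=(2, 4))
        _, cache = model.forward(x, training=True)
        grads = model.backward(cache, y)

        def loss_fn():
            clone = copy.deepcopy(model)
            probs, _ = clone.forward(x, training=True)
            return weighted_loss(y, probs, cfg.class_weights)

        eps = 1e-6
        for key in ("Wx1", "Wh1", "b1", "gamma", "beta", "Wx2", "Wh2", "b2", "Wo", "bo"):
            flat = model.params[key].reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                down = loss_fn()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = grads[key].reshape(-1)[idx]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8), key


class TestTraining:
    def test_lr_schedule_matches_inverse_time_decay(self):
        seqs = make_sequences(8, 5, 4, seed=0)
        cfg = ModelConfig(input_dim=4, hidden1=4, hidden2=3, epochs=4,
                          batch_size=4, lr=0.01, lr_decay_per_epoch=0.5, seed=0)
        _, history = train(seqs, cfg)
        for row in history:
            assert row["lr"] == pytest.approx(0.01 / (1 + 0.5 * row["epoch"]))

    def test_learns_above_majority_baseline(self):
        seqs = make_sequences(40, 8, 6, seed=3, signal=True)
        cfg = ModelConfig(input_dim=6, hidden1=8, hidden2=5, epochs=40,
                          batch_size=8, seed=3)
        model, history = train(seqs, cfg)
        labels = np.concatenate([s.labels for s in seqs])
        real = labels[(labels == POS) | (labels == NEG)]
        majority = max((real == POS).mean(), (real == NEG).mean())
        assert history[-1]["train_acc_real"] > majority
        assert history[-1]["loss"] < history[0]["loss"]

    def test_empty_training_split_raises(self):
        with pytest.raises(ValueError):
            train([], ModelConfig(input_dim=4))

    def test_raising_pos_weight_lowers_false_negative_rate(self):
        """With a heavier Survival-positive weight the model should call
        fewer true POS visits NEG (seeded comparison, fixed data)."""
        train_seqs = make_sequences(40, 8, 6, seed=11, signal=True)
        val_seqs = make_sequences(20, 8, 6, seed=12, signal=True)

        def fn_rate(pos_weight):
            cfg = ModelConfig(input_dim=6, hidden1=8, hidden2=5, epochs=12,
                              batch_size=8, seed=5,
                              class_weights=(pos_weight, 1.0, 0.1))
            model, _ = train(train_seqs, cfg)
            preds = predict(val_seqs, model)
            fn = total = 0
            for p in preds:
                for t in range(len(p.note_ids)):
                    if p.labels[t] == POS:
                        total += 1
                        fn += p.probs[t].argmax() != POS
            return fn / total

        assert fn_rate(8.0) <= fn_rate(0.25)


class TestPredict:
    def _trained(self, seed=0):
        seqs = make_sequences(12, 6, 4, seed=seed)
        cfg = ModelConfig(input_dim=4, hidden1=6, hidden2=4, epochs=3,
                          batch_size=4, seed=seed)
        model, _ = train(seqs, cfg)
        return model, seqs

    def test_future_perturbation_leaves_past_bitwise_identical(self):
        model, seqs = self._trained()
        x = np.stack([s.x for s in seqs])
        base, _ = model.forward(x, training=False)
        rng = np.random.default_rng(0)
        for _ in range(5):
            t_cut = int(rng.integers(1, x.shape[1]))
            perturbed = x.copy()
            perturbed[:, t_cut:] += rng.normal(size=perturbed[:, t_cut:].shape)
            out, _ = model.forward(perturbed, training=False)
            assert np.array_equal(out[:, :t_cut], base[:, :t_cut])

    def test_extra_padding_does_not_change_real_predictions(self):
        model, seqs = self._trained(seed=2)
        x = np.stack([s.x for s in seqs])
        base, _ = model.forward(x, training=False)
        extended = np.concatenate([x, np.zeros((x.shape[0], 4, x.shape[2]))], axis=1)
        out, _ = model.forward(extended, training=False)
        assert np.array_equal(out[:, : x.shape[1]], base)

    def test_probability_rows_sum_to_one(self):
        model, seqs = self._trained(seed=1)
        preds = predict(seqs, model)
        for p in preds:
            np.testing.assert_allclose(p.probs.sum(axis=-1), 1.0, atol=1e-12)
            assert ((p.p_surv >= 0) & (p.p_surv <= 1)).all()

    def test_dim_mismatch_raises(self):
        model, _ = self._trained()
        bad = make_sequences(3, 6, 9, seed=4)
        with pytest.raises(ValueError):
            predict(bad, model)

    def test_save_load_roundtrip_predicts_identically(self, tmp_path):
        model, seqs = self._trained(seed=3)
        model.save(tmp_path / "run")
        loaded = SurvivalLSTM.load(tmp_path / "run")
        x = np.stack([s.x for s in seqs])
        a, _ = model.forward(x, training=False)
        b, _ = loaded.forward(x, training=False)
        np.testing.assert_array_equal(a, b)

    def test_predictions_frame_shape(self):
        model, seqs = self._trained(seed=5)
        frame = predictions_frame(predict(seqs, model))
        assert list(frame.columns) == [
            "patient_id", "visit_index", "visit_date", "note_id",
            "p_survival", "true_label",
        ]
        assert len(frame) == sum(s.n_real for s in seqs)
        assert set(frame.true_label) <= {"POS", "NEG", "PAD", "UNDEFINED"}
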