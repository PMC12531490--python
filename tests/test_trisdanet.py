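"""Decoder architecture geometry, attention/gating semantics, ablation
switches, training mechanics, and evaluation metrics."""

import numpy as np
import pytest

from hybridstd import _nn, synthio, trisdanet
from hybridstd.eegprep import STANDARD_60, build_partition
from hybridstd.trisdanet import (TrainConfig, TriSdanet, TriSdanetConfig,
                                 evaluate, metrics_from_counts, nsp_split,
                                 stratified_split, train)


@pytest.fixture(scope="module")
def partition():
    return build_partition(list(STANDARD_60))


@pytest.fixture(scope="module")
def small_data():
    return synthio.gen_eeg_dataset(20, 20, snr_scale=2.0, seed=0)


class TestNspSplit:
    def test_three_20xT_blocks(self, partition, small_data):
        blocks = nsp_split(small_data[0], partition)
        assert set(blocks) == {"T", "F", "P"}
        for b in blocks.values():
            assert b.shape == (20, 100)
        total = sum(b.size for b in blocks.values())
        assert total == small_data[0].data.size

    def test_blocks_are_a_row_permutation_of_input(self, partition, small_data):
        x = small_data[0].data
        blocks = nsp_split(x, partition)
        stacked = np.vstack([blocks[r] for r in ("T", "F", "P")])
        # every input row appears exactly once
        order = np.concatenate([partition.region_order[r] for r in "TFP"])
        np.testing.assert_array_equal(stacked, x[order])
        assert sorted(order) == list(range(60))

    def test_nsp_ablation_uses_fixed_random_groups(self):
        cfg = TriSdanetConfig(ablation=frozenset({"NSP"}))
        m1 = TriSdanet(cfg, seed=5)
        m2 = TriSdanet(cfg, seed=5)
        for r in "TFP":
            np.testing.assert_array_equal(m1._groups[r], m2._groups[r])
        all_ch = np.sort(np.concatenate([m1._groups[r] for r in "TFP"]))
        np.testing.assert_array_equal(all_ch, np.arange(60))

    def test_wrong_channel_count_rejected(self, partition):
        with pytest.raises(ValueError):
            nsp_split(np.zeros((59, 100)), partition)


class TestForwardGeometry:
    def test_rsf_spatial_stage_sizes(self, small_data):
        model = TriSdanet(seed=0)
        x = np.stack([e.data for e in small_data[:2]])
        blocks = model.split_blocks(x)
        f_t = model.spatial["T"](_nn.Tensor(blocks["T"]))
        f_f = model.spatial["F"](_nn.Tensor(blocks["F"]))
        f_p = model.spatial["P"](_nn.Tensor(blocks["P"]))
        assert f_t.shape == (2, 16, 1, 100)
        assert f_f.shape == (2, 16, 19, 100)
        assert f_p.shape == (2, 16, 8, 100)

    def test_output_is_distribution_and_eval_deterministic(self, small_data):
        model = TriSdanet(seed=1)
        x = np.stack([e.data for e in small_data[:4]])
        probs = model.predict_proba(x)
        assert probs.shape == (4, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert np.all(probs >= 0)
        np.testing.assert_array_equal(probs, model.predict_proba(x))

    def test_attention_weights_sum_to_one(self, small_data):
        model = TriSdanet(seed=2)
        x = np.stack([e.data for e in small_data[:3]])
        _, alpha = model.forward(x)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-5)
        assert np.all((alpha > 0) & (alpha < 1))

    def test_equal_attention_logits_average_scales(self, small_data):
        model = TriSdanet(seed=3)
        # zero the attention map: all logits equal -> alpha = 1/3 each
        model.daw_wa.w.data[...] = 0.0
        model.daw_wa.b.data[...] = 0.0
        x = np.stack([e.data for e in small_data[:2]])
        blocks = model.split_blocks(x)
        branch = model.rsf_forward(blocks, train=False)
        a, alpha = model.daw_forward(branch, train=False)
        np.testing.assert_allclose(alpha, 1.0 / 3.0, atol=1e-6)
        pooled = [branch[r].mean(axis=2, keepdims=True) for r in "TFP"]
        fcat = _nn.concat(pooled, axis=1)
        mean = sum(conv(fcat).data for conv in model.daw_convs) / 3.0
        np.testing.assert_allclose(a.data, mean, rtol=1e-4, atol=1e-5)

    def test_gate_initialises_to_half_inside_window(self, small_data):
        model = TriSdanet(seed=4)  # gate mask M starts at 0
        x = np.stack([e.data for e in small_data[:2]])
        blocks = model.split_blocks(x)
        a, _ = model.daw_forward(model.rsf_forward(blocks, False), False)
        g = model.tg_forward(a)
        lo, hi = 10, 50  # 100-500 ms at 100 Hz
        np.testing.assert_allclose(g.data[..., lo:hi],
                                   0.5 * a.data[..., lo:hi], rtol=1e-5,
                                   atol=1e-6)
        # outside the window the mask is frozen at 1: g = sigmoid(a) * a
        outside = a.data[..., :lo]
        expect = outside / (1.0 + np.exp(-outside))
        np.testing.assert_allclose(g.data[..., :lo], expect, rtol=1e-4,
                                   atol=1e-5)

    def test_gate_values_stay_in_unit_interval(self, small_data):
        model = TriSdanet(seed=5)
        x = np.stack([e.data for e in small_data[:2]])
        blocks = model.split_blocks(x)
        a, _ = model.daw_forward(model.rsf_forward(blocks, False), False)
        m_eff = model.gate_m.data * model._gate_mask + (1 - model._gate_mask)
        gate = 1.0 / (1.0 + np.exp(-m_eff * a.data))
        assert np.all((gate > 0) & (gate < 1))

    @pytest.mark.parametrize("ablated", ["DAW", "TG", "DSTCN", "RSF", "NSP"])
    def test_each_ablation_forward_passes(self, small_data, ablated):
        cfg = TriSdanetConfig(ablation=frozenset({ablated}))
        model = TriSdanet(cfg, seed=0)
        x = np.stack([e.data for e in small_data[:2]])
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_tg_ablation_is_identity(self, small_data):
        cfg = TriSdanetConfig(ablation=frozenset({"TG"}))
        model = TriSdanet(cfg, seed=0)
        x = np.stack([e.data for e in small_data[:2]])
        blocks = model.split_blocks(x)
        a, _ = model.daw_forward(model.rsf_forward(blocks, False), False)
        assert model.tg_forward(a) is a


class TestTraining:
    def test_split_sizes_70_10_20(self):
        labels = np.array([0] * 50 + [1] * 50)
        tr, va, te = stratified_split(labels, (0.7, 0.1, 0.2), seed=0)
        assert (len(tr), len(va), len(te)) == (70, 10, 20)
        assert not (set(tr) & set(va)) and not (set(tr) & set(te))
        # stratification: each class split 35/5/10
        assert (labels[tr] == 1).sum() == 35

    def test_gradient_flows_through_every_parameter(self, small_data):
        model = TriSdanet(seed=6)
        x = np.stack([e.data for e in small_data[:8]])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        rng = np.random.default_rng(0)
        logits, _ = model.forward(x, train=True, rng=rng)
        loss = _nn.softmax_cross_entropy(logits, y)
        loss.backward()
        for p in model.parameters():
            assert p.grad is not None
            assert np.linalg.norm(p.grad) > 0, "dead branch detected"

    def test_training_is_seed_deterministic(self, small_data):
        cfg = TrainConfig(epochs=2, seed=7)
        _, h1 = train(small_data, cfg)
        _, h2 = train(small_data, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_acc"] == h2["val_acc"]

    def test_single_class_dataset_rejected(self):
        eps = synthio.gen_eeg_dataset(10, 1, seed=0)
        only_targets = [e for e in eps if e.label == "target"] * 2
        with pytest.raises(ValueError):
            train(only_targets, TrainConfig(epochs=1))

    def test_checkpoint_round_trip(self, tmp_path, small_data):
        model, hist = train(small_data, TrainConfig(epochs=2, seed=1))
        path = str(tmp_path / "ckpt.npz")
        trisdanet.save_checkpoint(path, model, hist)
        back = trisdanet.load_checkpoint(path)
        x = np.stack([e.data for e in small_data[:4]])
        np.testing.assert_allclose(back.predict_proba(x),
                                   model.predict_proba(x), rtol=1e-5,
                                   atol=1e-6)


class TestEvaluate:
    def test_metrics_from_hand_counts(self):
        m = metrics_from_counts(tp=45, fn=5, fp=4, tn=46)
        assert m["accuracy"] == pytest.approx(0.91)
        assert m["TPR"] == pytest.approx(0.90)
        assert m["FPR"] == pytest.approx(0.08)

    def test_perfect_and_degenerate_predictors(self):
        perfect = metrics_from_counts(20, 0, 0, 20)
        assert perfect["accuracy"] == 1.0 and perfect["FPR"] == 0.0
        all_pos = metrics_from_counts(20, 0, 20, 0)
        assert all_pos["TPR"] == 1.0 and all_pos["FPR"] == 1.0
        assert all_pos["accuracy"] == 0.5

    def test_evaluate_counts_against_sklearn(self, small_data):
        from sklearn.metrics import accuracy_score, confusion_matrix
        model = TriSdanet(seed=8)
        res = evaluate(model, small_data)
        x = np.stack([e.data for e in small_data])
        y = np.array([1 if e.label == "target" else 0 for e in small_data])
        pred = model.predict_proba(x).argmax(axis=1)
        assert res["accuracy"] == pytest.approx(accuracy_score(y, pred))
        tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
        if tp + fn:
            assert res["TPR"] == pytest.approx(tp / (tp + fn))
        if fp + tn:
            assert res["FPR"] == pytest.approx(fp / (fp + tn))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        TriSdanetConfig(temporal_kernels={"T": 14, "F": 25, "P": 35})
    with pytest.raises(ValueError):
        TriSdanetConfig(dropout_p=1.0)
    with pytest.raises(ValueError):
        TriSdanetConfig(ablation=frozenset({"XYZ"}))
    with pytest.raises(ValueError):
        TrainConfig(split=(0.5, 0.2, 0.2))
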