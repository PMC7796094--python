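"""Res BCDU-Net architecture contract, BConvLSTM fusion semantics, training
determinism, and checkpointing (desk-scale input sizes)."""

import numpy as np
import pytest
from scipy.signal import correlate2d
from scipy.special import expit

from lungseg import (
    NetworkConfig,
    TrainConfig,
    build_model,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)
from lungseg import nn


def tiny_pairs(rng, n, size=32):
    pairs = []
    for _ in range(n):
        img = rng.random((size, size, 3), dtype=np.float32)
        mask = np.zeros((size, size), dtype=np.uint8)
        mask[8:24, 8:24] = 1
        pairs.append((img, mask))
    return pairs


class TestBuildModel:
    def test_forward_contract_64(self):
        model = build_model(NetworkConfig(input_size=(64, 64)), seed=0)
        x = np.random.default_rng(0).random((64, 64, 3), dtype=np.float32)
        probs, mask = predict(model, x)
        assert probs.shape == (64, 64)
        assert np.all((probs > 0) & (probs < 1))
        assert set(np.unique(mask)) <= {0, 1}

    def test_encoder_taps_and_stage_depths(self):
        model = build_model(NetworkConfig(input_size=(64, 64)), seed=0)
        enc = model.net.encoder
        assert model.skip_channels == (64, 128, 256, 512)
        assert tuple(len(s) for s in enc.stages) == (3, 4, 6, 3)
        x = nn.Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
        model.net.train(False)
        f_stem, feats = enc(x)
        assert f_stem.shape == (1, 64, 32, 32)
        assert [f.shape[1] for f in feats] == [64, 128, 256, 512]
        assert [f.shape[2] for f in feats] == [16, 8, 4, 2]

    def test_architecture_determinism(self):
        a = build_model(NetworkConfig(input_size=(32, 32)), seed=3)
        b = build_model(NetworkConfig(input_size=(32, 32)), seed=3)
        assert a.n_parameters == b.n_parameters
        np.testing.assert_array_equal(
            a.net.parameters()[0].data, b.net.parameters()[0].data
        )

    def test_invalid_configs(self):
        with pytest.raises(ValueError, match="divisible by 32"):
            build_model(NetworkConfig(input_size=(100, 64)))
        with pytest.raises(ValueError, match="double"):
            build_model(NetworkConfig(channel_schedule=(64, 96, 256, 512)))
        with pytest.raises(ValueError, match="odd"):
            build_model(NetworkConfig(bconvlstm_kernel=4))
        with pytest.raises(ValueError, match="weights"):
            build_model(NetworkConfig(encoder_pretrained=True))

    def test_pretrained_weights_load(self, tmp_path):
        donor = build_model(NetworkConfig(input_size=(32, 32)), seed=9)
        enc_params = donor.net.encoder.parameters()
        path = tmp_path / "enc.npz"
        np.savez(path, **{f"arr_{i}": p.data for i, p in enumerate(enc_params)})
        model = build_model(
            NetworkConfig(input_size=(32, 32), encoder_pretrained=True),
            seed=1,
            pretrained_weights=str(path),
        )
        np.testing.assert_array_equal(
            model.net.encoder.parameters()[0].data, enc_params[0].data
        )


def reference_conv(x, w, b):
    """Independent cross-correlation (scipy) for the recurrence oracle."""
    cout = w.shape[0]
    out = np.zeros((cout,) + x.shape[1:])
    for o in range(cout):
        acc = sum(
            correlate2d(x[c], w[o, c], mode="same") for c in range(x.shape[0])
        )
        out[o] = acc + b[o]
    return out


def reference_convlstm(sequence, w, b, hidden):
    h = np.zeros((hidden,) + sequence[0].shape[1:])
    c = np.zeros_like(h)
    for x_t in sequence:
        z = reference_conv(np.concatenate([x_t, h], axis=0), w, b)
        i, f, o, g = (z[k * hidden : (k + 1) * hidden] for k in range(4))
        i, f, o = expit(i), expit(f), expit(o)
        g = np.tanh(g)
        c = f * c + i * g
        h = o * np.tanh(c)
    return h


class TestBConvLSTM:
    def test_zero_fixed_point_is_exact(self):
        fusion = nn.BConvLSTMFusion(2, 3, rng=np.random.default_rng(0))
        for p in fusion.parameters():
            p.data[...] = 0.0
        z = nn.Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32))
        out = fusion(z, z)
        assert np.all(out.data == 0.0)

    def test_matches_hand_unrolled_recurrence(self):
        rng = np.random.default_rng(6)
        fusion = nn.BConvLSTMFusion(3, 3, rng=rng, dtype=np.float64)
        enc = rng.standard_normal((1, 3, 5, 5))
        dec = rng.standard_normal((1, 3, 5, 5))
        out = fusion(nn.Tensor(enc), nn.Tensor(dec)).data[0]
        wf = fusion.forward_lstm.conv.weight.data
        bf = fusion.forward_lstm.conv.bias.data
        wb = fusion.backward_lstm.conv.weight.data
        bb = fusion.backward_lstm.conv.bias.data
        h_fwd = reference_convlstm([enc[0], dec[0]], wf, bf, hidden=3)
        h_bwd = reference_convlstm([dec[0], enc[0]], wb, bb, hidden=3)
        np.testing.assert_allclose(
            out, np.concatenate([h_fwd, h_bwd], axis=0), atol=1e-5
        )

    def test_sequence_reversal_swaps_directions(self):
        rng = np.random.default_rng(7)
        fusion = nn.BConvLSTMFusion(2, 3, rng=rng)
        swapped = nn.BConvLSTMFusion(2, 3, rng=rng)
        swapped.forward_lstm = fusion.backward_lstm
        swapped.backward_lstm = fusion.forward_lstm
        a = nn.Tensor(rng.standard_normal((1, 2, 4, 4)).astype(np.float32))
        b = nn.Tensor(rng.standard_normal((1, 2, 4, 4)).astype(np.float32))
        ab = fusion(a, b).data
        ba = swapped(b, a).data
        np.testing.assert_array_equal(ab[:, :2], ba[:, 2:])
        np.testing.assert_array_equal(ab[:, 2:], ba[:, :2])

    def test_shape_mismatch_rejected(self):
        fusion = nn.BConvLSTMFusion(2, 3, rng=np.random.default_rng(0))
        a = nn.Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32))
        b = nn.Tensor(np.zeros((1, 2, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="equal shapes"):
            fusion(a, b)


class TestTrainPredict:
    def test_one_epoch_smoke_and_history(self):
        rng = np.random.default_rng(0)
        pairs = tiny_pairs(rng, 2)
        model = build_model(NetworkConfig(input_size=(32, 32)), seed=0)
        tc = TrainConfig(epochs=1, batch_size=2, learning_rate=1e-3, seed=0)
        model, history = train(model, pairs, pairs, tc)
        assert len(history) == 1
        for key in ("train_loss", "train_acc", "val_loss", "val_acc", "val_dice"):
            assert np.isfinite(history[0][key])

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(1)
        pairs = tiny_pairs(rng, 4)
        tc = TrainConfig(epochs=2, batch_size=2, learning_rate=1e-3, seed=5)
        losses = []
        for _ in range(2):
            model = build_model(NetworkConfig(input_size=(32, 32)), seed=5)
            _, history = train(model, pairs, None, tc)
            losses.append(history[-1]["train_loss"])
        assert losses[0] == pytest.approx(losses[1], abs=1e-7)

    def test_empty_training_set_rejected(self):
        model = build_model(NetworkConfig(input_size=(32, 32)), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, [], None, TrainConfig(epochs=1, batch_size=1))

    def test_non_finite_loss_aborts(self):
        rng = np.random.default_rng(2)
        pairs = tiny_pairs(rng, 1)
        img = pairs[0][0].copy()
        img[0, 0, 0] = np.nan
        model = build_model(NetworkConfig(input_size=(32, 32)), seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            train(model, [(img, pairs[0][1])], None,
                  TrainConfig(epochs=1, batch_size=1))

    def test_predict_threshold_monotone(self):
        model = build_model(NetworkConfig(input_size=(32, 32)), seed=2)
        x = np.random.default_rng(3).random((32, 32, 3), dtype=np.float32)
        _, loose = predict(model, x, threshold=0.01)
        _, strict = predict(model, x, threshold=0.99)
        assert np.all(strict <= loose)

    def test_predict_size_mismatch(self):
        model = build_model(NetworkConfig(input_size=(32, 32)), seed=0)
        with pytest.raises(ValueError, match="does not match"):
            predict(model, np.zeros((64, 64, 3), dtype=np.float32))

    def test_checkpoint_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        pairs = tiny_pairs(rng, 2)
        model = build_model(NetworkConfig(input_size=(32, 32)), seed=1)
        tc = TrainConfig(epochs=1, batch_size=2, learning_rate=1e-3, seed=1)
        model, _ = train(model, pairs, None, tc)
        x = rng.random((32, 32, 3), dtype=np.float32)
        probs_before, _ = predict(model, x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        probs_after, _ = predict(restored, x)
        np.testing.assert_allclose(probs_before, probs_after, atol=1e-7)
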