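"""Denoiser: SE gating, dilated bottleneck, assembly, training, PSNR."""

import math

import numpy as np
import pytest

from sonodeclutter import cae
from sonodeclutter import nn
from sonodeclutter import phantom as ph
from sonodeclutter.nn import tensor as T


class TestSeGate:
    def test_zero_input_stays_zero(self):
        out = cae.se_gate(np.zeros((4, 6, 6), dtype=np.float32), reduction=2)
        assert np.array_equal(out, np.zeros((4, 6, 6)))

    def test_forced_half_gates_scale_by_half(self):
        block = nn.SEBlock(3, 2, np.random.default_rng(0))
        for lin in (block.fc1, block.fc2):
            lin.weight.data[:] = 0.0
            lin.bias.data[:] = 0.0  # sigmoid(0) = 0.5
        x = np.random.default_rng(1).random((3, 4, 4)).astype(np.float32)
        out = cae.se_gate(x, block=block)
        assert np.allclose(out, 0.5 * x, atol=1e-6)

    def test_two_channel_example_matches_hand_computation(self):
        block = nn.SEBlock(2, 2, np.random.default_rng(0))  # bottleneck width 1
        block.fc1.weight.data = np.array([[0.5, -1.0]], dtype=np.float32)
        block.fc1.bias.data = np.array([0.1], dtype=np.float32)
        block.fc2.weight.data = np.array([[2.0], [-0.5]], dtype=np.float32)
        block.fc2.bias.data = np.array([0.0, 0.3], dtype=np.float32)
        x = np.array([[[0.8]], [[0.2]]], dtype=np.float32)  # (2, 1, 1)
        # squeeze: z = (0.8, 0.2); hidden = relu(0.5*0.8 - 1.0*0.2 + 0.1) = 0.3
        # gates = sigmoid((2.0*0.3, -0.5*0.3 + 0.3)) = sigmoid((0.6, 0.15))
        g = 1.0 / (1.0 + np.exp(-np.array([0.6, 0.15])))
        expected = x[:, 0, 0] * g
        out = cae.se_gate(x, block=block)
        assert np.allclose(out[:, 0, 0], expected, atol=1e-6)

    def test_gates_bounded_so_output_never_exceeds_input(self):
        x = np.random.default_rng(2).random((5, 8, 8)).astype(np.float32)
        out = cae.se_gate(x, reduction=4, seed=3)
        per_channel_in = np.abs(x).sum(axis=(1, 2))
        per_channel_out = np.abs(out).sum(axis=(1, 2))
        assert np.all(per_channel_out <= per_channel_in + 1e-6)


class TestDilatedBottleneck:
    def test_empty_dilation_list_rejected(self):
        with pytest.raises(ValueError):
            cae.DilatedBottleneck(4, (), np.random.default_rng(0))

    def test_spatial_size_preserved(self):
        x = np.random.default_rng(0).random((3, 12, 12)).astype(np.float32)
        out = cae.dilated_bottleneck(x, (1, 2, 4))
        assert out.shape[1:] == (12, 12)

    def test_single_dilation_degenerates_to_plain_conv_plus_fusion(self):
        mod = cae.DilatedBottleneck(2, (1,), np.random.default_rng(0))
        assert len(mod.branches) == 1
        assert mod.branches[0].dilation == 1
        x = np.random.default_rng(1).random((2, 8, 8)).astype(np.float32)
        assert cae.dilated_bottleneck(x, (1,), module=mod).shape == (4, 8, 8)

    def test_zero_input_with_biases_gives_constant_channels(self):
        mod = cae.DilatedBottleneck(1, (1, 2), np.random.default_rng(0))
        for i, branch in enumerate(mod.branches):
            branch.bias.data[:] = 0.5 + 0.25 * i
        out = cae.dilated_bottleneck(np.zeros((1, 5, 5), dtype=np.float32),
                                     (1, 2), module=mod)
        for c in range(out.shape[0]):
            assert np.allclose(out[c], out[c, 0, 0], atol=1e-6)


def _hand_count_desk_params(levels=2, base=8, reduction=16, n_dil=4) -> int:
    """Independent sum of parameter-count formulas over the declared layers."""
    def conv(cin, cout, k):
        return k * k * cin * cout + cout

    def se(c):
        hidden = max(c // reduction, 1)
        return (c * hidden + hidden) + (hidden * c + c)

    chans = [base * 2**i for i in range(levels)]
    total = 0
    cin = 1
    for c in chans:
        total += conv(cin, c, 3) + conv(c, c, 3) + se(c)
        cin = c
    deepest = chans[-1]
    total += n_dil * conv(deepest, deepest, 3) + conv(n_dil * deepest, 2 * deepest, 1)
    cin = 2 * deepest
    for c in reversed(chans):
        total += (cin * c * 4 + c)  # 2x2 transposed conv
        total += conv(c + c, c, 3) + conv(c, c, 3)
        cin = c
    total += conv(chans[0], 1, 1)
    return total


class TestBuildCae:
    def test_output_shape_and_range(self):
        net = cae.build_cae(cae.CaeArchitecture(levels=2, base_channels=8), seed=0)
        x = np.random.default_rng(0).random((1, 1, 64, 64)).astype(np.float32)
        with T.no_grad():
            y = net(T.Tensor(x))
        assert y.data.shape == (1, 1, 64, 64)
        assert 0.0 < y.data.min() and y.data.max() < 1.0

    def test_forward_deterministic(self):
        net = cae.build_cae(cae.DESK_ARCH, seed=1)
        x = T.Tensor(np.random.default_rng(1).random((1, 1, 64, 64), dtype=np.float32))
        with T.no_grad():
            a, b = net(x).data, net(x).data
        assert np.array_equal(a, b)

    def test_indivisible_size_rejected_with_message(self):
        net = cae.build_cae(cae.DESK_ARCH, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            with T.no_grad():
                net(T.Tensor(np.zeros((1, 1, 62, 62), dtype=np.float32)))

    def test_parameter_count_matches_hand_sum(self):
        net = cae.build_cae(cae.DESK_ARCH, seed=0)
        assert net.n_params() == _hand_count_desk_params()

    def test_invalid_arch_rejected(self):
        with pytest.raises(ValueError):
            cae.CaeArchitecture(levels=1)
        with pytest.raises(ValueError):
            cae.CaeArchitecture(dilations=())


class TestTraining:
    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError):
            cae.train_cae([], cae.DESK_ARCH, cae.CaeConfig())

    def test_identity_task_loss_decreases(self):
        recs = [ph.generate_phantom(label, 32, ph.record_seed(7, label, i))
                for label in ph.CLASSES for i in range(2)]
        for r in recs:  # no marks: marked == clean
            r.marked = r.clean.copy()
            r.mark_mask = np.zeros_like(r.lesion_mask)
        arch = cae.CaeArchitecture(levels=2, base_channels=4)
        model, trace = cae.train_cae(recs, arch, cae.CaeConfig(epochs=8, lr0=1e-3, seed=0))
        assert len(trace) == 8
        assert trace[-1] < trace[0]

    def test_declutter_deterministic_and_bounded(self):
        model = cae.CaeDenoiser(epochs=1, base_channels=4, seed=0)
        X = np.random.default_rng(0).random((2, 32, 32)).astype(np.float32)
        model.fit(X, X)
        img = np.zeros((32, 32), dtype=np.float32)
        a, b = cae.declutter(model, img), cae.declutter(model, img)
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a)) and 0.0 < a.min() and a.max() < 1.0

    def test_declutter_size_mismatch_rejected(self):
        model = cae.CaeDenoiser(epochs=1, base_channels=4, seed=0)
        X = np.random.default_rng(0).random((2, 32, 32)).astype(np.float32)
        model.fit(X, X)
        with pytest.raises(ValueError, match="expected 32x32"):
            cae.declutter(model, np.zeros((64, 64)))

    def test_save_load_roundtrip(self, tmp_path):
        model = cae.CaeDenoiser(epochs=2, base_channels=4, seed=3)
        X = np.random.default_rng(0).random((4, 32, 32)).astype(np.float32)
        model.fit(X, X)
        cae.save_cae(model, tmp_path / "m.npz")
        loaded = cae.load_cae(tmp_path / "m.npz")
        assert np.array_equal(loaded.transform(X), model.transform(X))
        assert loaded.loss_trace_ == model.loss_trace_


class TestPsnr:
    def test_identical_images_give_infinity(self):
        a = np.random.default_rng(0).random((8, 8))
        assert cae.psnr(a, a) == math.inf

    def test_closed_form_twenty_db(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)  # MSE = 0.01, peak 1 -> 20 dB
        assert cae.psnr(a, b) == pytest.approx(20.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((6, 6)), rng.random((6, 6))
        se = 0.0
        for i in range(6):
            for j in range(6):
                se += (a[i, j] - b[i, j]) ** 2
        expected = 10 * math.log10(1.0 / (se / 36))
        assert cae.psnr(a, b) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cae.psnr(np.zeros((3, 3)), np.zeros((4, 4)))


class TestDeskProfileProperties:
    """Properties of the trained desk-scale denoiser (shared session run)."""

    def test_mark_region_error_decreases_with_training(self, desk_cae_run):
        model = desk_cae_run["model"]
        untrained = cae.CaeDenoiser(epochs=1, lr0=0.0, seed=0)
        marked_recs = [r for r in desk_cae_run["heldout"] if r.mark_mask.any()][:10]
        X = np.stack([r.marked for r in marked_recs])
        untrained.fit(X[:2], X[:2])  # zero lr: weights stay at initialization
        inside_tr, inside_un, outside_tr = [], [], []
        for r in marked_recs:
            mask = r.mark_mask.astype(bool)
            out_tr = cae.declutter(model, r.marked)
            out_un = cae.declutter(untrained, r.marked)
            inside_tr.append(np.abs(out_tr - r.clean)[mask].mean())
            inside_un.append(np.abs(out_un - r.clean)[mask].mean())
            outside_tr.append(np.abs(out_tr - r.clean)[~mask].mean())
        assert np.mean(inside_tr) < np.mean(inside_un)
        assert np.mean(outside_tr) < np.mean(inside_un)

    def test_loss_trace_has_one_entry_per_epoch(self, desk_cae_run):
        assert len(desk_cae_run["trace"]) == 30
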