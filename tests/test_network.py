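"""Learned components against independent transcriptions of their defining
recurrences: Conv-LSTM gates, soft thresholding, channel attention fusion,
branch wiring contracts and gradient flow through the FBP layer."""

import numpy as np
import pytest

from dualct import autodiff as ad
from dualct.autodiff import Tensor
from dualct.fbp import FBPConfig, fbp_reconstruct
from dualct.geometry import (ScanGeometry, Sinogram, default_pixel_size,
                             interpolate_views)
from dualct.network import (ACSTF, MFNF, SNFM, ConvLSTMCell, DualDomainNet,
                            ModelConfig, RCU, RCUAttResblock,
                            SingleDomainNet, position_normalize)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def zero_params(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)


class TestConvLSTM:
    def test_zero_parameters_zero_state(self, rng):
        cell = ConvLSTMCell(3, rng, dtype=np.float64)
        zero_params(cell)
        x = Tensor(rng.normal(size=(3, 5, 5)))
        z = Tensor(np.zeros((3, 5, 5)))
        h, (h2, c) = cell(x, (z, z))
        # f = i = o = sigmoid(0) = 1/2, c' = tanh(0) = 0 -> c_t = h_t = 0
        np.testing.assert_allclose(c.data, 0.0)
        np.testing.assert_allclose(h.data, 0.0)

    def test_zero_parameters_nonzero_memory(self, rng):
        cell = ConvLSTMCell(2, rng, dtype=np.float64)
        zero_params(cell)
        x = Tensor(rng.normal(size=(2, 4, 4)))
        h0 = Tensor(np.zeros((2, 4, 4)))
        c0 = Tensor(rng.normal(size=(2, 4, 4)))
        h, (_, c) = cell(x, (h0, c0))
        np.testing.assert_allclose(c.data, 0.5 * c0.data, atol=1e-12)
        np.testing.assert_allclose(h.data, 0.5 * np.tanh(0.5 * c0.data),
                                   atol=1e-12)

    def test_scalar_oracle(self, rng):
        """1x1 spatial, 1 channel: the cell must match a direct scalar
        transcription of the gate recurrence."""
        cell = ConvLSTMCell(1, rng, dtype=np.float64)
        x, h0, c0 = rng.normal(size=3)
        ht, (_, ct) = cell(Tensor(np.full((1, 1, 1), x)),
                           (Tensor(np.full((1, 1, 1), h0)),
                            Tensor(np.full((1, 1, 1), c0))))

        def gate(m):
            # pointwise conv on (x, h), then the center tap of the 3x3
            # depthwise kernel (padding leaves only the center on 1x1 maps)
            pre = m.pw.weight.data[0, 0, 0, 0] * x + \
                m.pw.weight.data[0, 1, 0, 0] * h0
            return m.dw.weight.data[0, 0, 1, 1] * pre + m.dw.bias.data[0]

        f = sigmoid(gate(cell.w_f))
        i = sigmoid(gate(cell.w_i))
        o = sigmoid(gate(cell.w_o))
        c_new = np.tanh(gate(cell.w_c))
        c_ref = f * c0 + i * c_new
        h_ref = o * np.tanh(c_ref)
        assert ct.data[0, 0, 0] == pytest.approx(c_ref, abs=1e-10)
        assert ht.data[0, 0, 0] == pytest.approx(h_ref, abs=1e-10)

    def test_hidden_state_bounded(self, rng):
        cell = ConvLSTMCell(4, rng, dtype=np.float64)
        x = Tensor(rng.normal(size=(4, 6, 6)) * 50.0)
        z = Tensor(np.zeros((4, 6, 6)))
        h, _ = cell(x, (z, z))
        assert np.all(np.abs(h.data) < 1.0)

    def test_channel_mismatch_rejected(self, rng):
        cell = ConvLSTMCell(3, rng)
        bad = Tensor(np.zeros((5, 4, 4), np.float32))
        z = Tensor(np.zeros((5, 4, 4), np.float32))
        with pytest.raises(ValueError):
            cell(bad, (z, z))


class TestRCU:
    def test_shape_contract(self, rng):
        rcu = RCU(6, 10, rng)
        y, state = rcu(Tensor(np.zeros((6, 8, 12), np.float32)))
        assert y.shape == (10, 8, 12)
        assert state[0].shape == (10, 8, 12)
        rcu2 = RCU(6, 10, rng, stride=2)
        y2, _ = rcu2(Tensor(np.zeros((6, 8, 12), np.float32)))
        assert y2.shape == (10, 4, 6)

    def test_without_conv_lstm_equals_cbr_conv_path(self, rng):
        rcu = RCU(4, 6, rng, use_conv_lstm=False, dtype=np.float64)
        x = Tensor(rng.normal(size=(4, 8, 8)))
        y, state = rcu(x)
        assert state is None
        ref = rcu.out_conv(rcu.cbr(x))
        np.testing.assert_array_equal(y.data, ref.data)

    def test_state_threading_and_determinism(self, rng):
        r1 = RCU(3, 4, rng, dtype=np.float64)
        r2 = RCU(4, 8, rng, stride=2, state_channels=4, dtype=np.float64)
        x = Tensor(rng.normal(size=(3, 8, 8)))
        y1, s1 = r1(x)
        y2a, _ = r2(y1, s1)
        y2b, _ = r2(y1, s1)
        np.testing.assert_array_equal(y2a.data, y2b.data)
        # threading the state changes the output vs a zero initial state
        y2c, _ = r2(y1, None)
        assert not np.allclose(y2a.data, y2c.data)


class TestRCUAttResblock:
    def test_spatial_shape_preserved_and_finite(self, rng):
        blk = RCUAttResblock(8, rng)
        x = Tensor(rng.normal(size=(8, 6, 10)).astype(np.float32))
        y, _ = blk(x)
        assert y.shape == (8, 6, 10)
        assert np.all(np.isfinite(y.data))

    def test_zeroed_inner_transform_is_identity(self, rng):
        blk = RCUAttResblock(4, rng, dtype=np.float64)
        blk.out_conv.weight.data[:] = 0.0
        blk.out_conv.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(4, 6, 6)))
        y, _ = blk(x)
        np.testing.assert_array_equal(y.data, x.data)


class TestACSTF:
    def test_zero_input_zero_output(self, rng):
        m = ACSTF(4, rng, dtype=np.float64)
        y = m(Tensor(np.zeros((4, 5, 5))))
        np.testing.assert_allclose(y.data, 0.0)

    @pytest.mark.parametrize("x,expected", [
        (3.0, 2.0), (-3.0, -2.0), (0.5, 0.0), (1.0, 0.0), (-1.0, 0.0)])
    def test_soft_threshold_scalar_cases(self, x, expected):
        # piecewise definition at tau = 1, boundary inclusive
        t = Tensor(np.array(x))
        tau = Tensor(np.array(1.0))
        y = (t - tau).relu() - (-t - tau).relu()
        assert float(y.data) == pytest.approx(expected)

    def test_shrinkage_property(self, rng):
        m = ACSTF(6, rng, dtype=np.float64)
        x = rng.normal(size=(6, 7, 7)) * 3.0
        y = m(Tensor(x)).data
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)
        assert np.all(y * x >= -1e-12)

    def test_se_path_matches_elementwise_oracle(self, rng):
        """Full SE path on a 4-channel input against a straight-line
        transcription of the threshold rule and shrinkage."""
        m = ACSTF(4, rng, reduction=2, dtype=np.float64)
        x = rng.normal(size=(4, 3, 3))
        got = m(Tensor(x)).data

        gap = np.abs(x).mean(axis=(1, 2))                       # GAP(|x|)
        w1 = m.fc1.weight.data[:, :, 0, 0]
        w2 = m.fc2.weight.data[:, :, 0, 0]
        hid = np.maximum(w1 @ gap + m.fc1.bias.data, 0.0)
        z = w2 @ hid + m.fc2.bias.data
        tau = sigmoid(z) * gap                                  # per channel
        assert np.all(tau >= 0)
        ref = np.empty_like(x)
        for c in range(4):
            for i in range(3):
                for j in range(3):
                    v = x[c, i, j]
                    if v > tau[c]:
                        ref[c, i, j] = v - tau[c]
                    elif v < -tau[c]:
                        ref[c, i, j] = v + tau[c]
                    else:
                        ref[c, i, j] = 0.0
        np.testing.assert_allclose(got, ref, atol=1e-6)


class TestSNFM:
    def test_softmax_rows_sum_to_one(self, rng):
        m = SNFM(3, 4, rng, dtype=np.float64)
        low = Tensor(rng.normal(size=(3, 4, 4)))
        high = Tensor(rng.normal(size=(4, 4, 4)))
        xl = m.agg1(m.agg3(low))
        q = m.q_dw(xl).reshape(4, 16)
        k = m.k_dw(xl).reshape(4, 16)
        scores = (q @ k.T) * (1.0 / np.sqrt(m.d_k))
        att = ad.softmax(scores, axis=-1)
        np.testing.assert_allclose(att.data.sum(axis=1), 1.0, atol=1e-6)

    def test_position_normalization_statistics(self, rng):
        x = Tensor(rng.normal(size=(8, 5, 5)) * 3.0 + 1.0)
        y = position_normalize(x).data
        np.testing.assert_allclose(y.mean(axis=0), 0.0, atol=1e-5)
        np.testing.assert_allclose(y.std(axis=0), 1.0, atol=1e-2)

    def test_toy_tensors_match_step_by_step_oracle(self, rng):
        """2-channel 2x2 fusion against a hand transcription of the
        attention product and the normalization-modulation rule."""
        m = SNFM(2, 2, rng, dtype=np.float64)
        low = Tensor(rng.normal(size=(2, 2, 2)))
        high = Tensor(rng.normal(size=(2, 2, 2)))
        got = m(low, high).data

        xl = m.agg1(m.agg3(low)).data            # aggregated low features
        q = m.q_dw(Tensor(xl)).data.reshape(2, 4)
        k = m.k_dw(Tensor(xl)).data.reshape(2, 4)
        v = m.v_dw(high).data.reshape(2, 4)
        scores = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                scores[i, j] = (q[i] * k[j]).sum() / np.sqrt(2.0)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        a = (w @ v).reshape(2, 2, 2)
        ar = a + high.data                       # residual attention feature
        gamma = m.gamma_conv(Tensor(ar)).data
        beta = m.beta_conv(Tensor(ar)).data
        mu = xl.mean(axis=0)
        sd = np.sqrt(((xl - mu) ** 2).mean(axis=0) + 1e-5)
        ref = gamma * (xl - mu) / sd + beta
        np.testing.assert_allclose(got, ref, atol=1e-5)

    def test_spatial_mismatch_rejected(self, rng):
        m = SNFM(2, 2, rng)
        with pytest.raises(ValueError):
            m(Tensor(np.zeros((2, 4, 4), np.float32)),
              Tensor(np.zeros((2, 8, 8), np.float32)))


class TestMFNF:
    @pytest.mark.parametrize("mode", ["snfm", "sum", "concat"])
    def test_output_channel_contract(self, mode, rng):
        m = MFNF(6, 4, rng, fusion_mode=mode)
        high = Tensor(np.zeros((4, 8, 8), np.float32))
        low = Tensor(np.zeros((6, 8, 8), np.float32))
        assert m(high, low).shape == (4, 8, 8)

    def test_sum_mode_zero_low_reduces_to_high_path(self, rng):
        m = MFNF(6, 4, rng, fusion_mode="sum", use_acstf=False,
                 dtype=np.float64)
        high = Tensor(rng.normal(size=(4, 8, 8)))
        low = Tensor(np.zeros((6, 8, 8)))
        got = m(high, low)
        ref = high + m.out_conv(high.relu())
        np.testing.assert_array_equal(got.data, ref.data)

    def test_relu_replaces_acstf_when_disabled(self, rng):
        m = MFNF(3, 4, rng, fusion_mode="sum", use_acstf=False,
                 dtype=np.float64)
        assert not hasattr(m, "acstf")
        high = Tensor(rng.normal(size=(4, 6, 6)))
        low = Tensor(rng.normal(size=(3, 6, 6)))
        fused = m.low_proj(low) + high
        ref = high + m.out_conv(fused.relu())
        np.testing.assert_array_equal(m(high, low).data, ref.data)

    def test_deterministic_under_fixed_weights(self, rng):
        m = MFNF(3, 4, rng, fusion_mode="snfm")
        high = Tensor(rng.normal(size=(4, 6, 6)).astype(np.float32))
        low = Tensor(rng.normal(size=(3, 6, 6)).astype(np.float32))
        np.testing.assert_array_equal(m(high, low).data, m(high, low).data)


class TestSingleDomainNet:
    def test_identity_at_initialization(self, rng):
        """Band residuals are zero-initialized: a fresh network is an
        exact identity map."""
        net = SingleDomainNet(ModelConfig(base_channels=2, dtype="float64"),
                              np.random.default_rng(0))
        x = Tensor(rng.normal(size=(24, 32)))
        np.testing.assert_allclose(net(x).data, x.data, atol=1e-12)

    def test_shape_preserved_sinogram_format(self, rng):
        net = SingleDomainNet(ModelConfig(base_channels=2),
                              np.random.default_rng(0))
        x = Tensor(rng.normal(size=(32, 44)).astype(np.float32))
        assert net(x).shape == (32, 44)

    def test_indivisible_dimensions_rejected(self, rng):
        net = SingleDomainNet(ModelConfig(base_channels=2),
                              np.random.default_rng(0))
        with pytest.raises(ValueError):
            net(Tensor(np.zeros((30, 44), np.float32)))

    def test_deterministic_forward(self, rng):
        net = SingleDomainNet(ModelConfig(base_channels=2),
                              np.random.default_rng(0))
        x = Tensor(rng.normal(size=(16, 24)).astype(np.float32))
        np.testing.assert_array_equal(net(x).data, net(x).data)

    @pytest.mark.parametrize("kwargs", [
        {"use_conv_lstm": False, "use_acstf": False},   # ablation baseline
        {"use_conv_lstm": False},
        {"use_acstf": False},
        {"fusion_mode": "sum"},
        {"fusion_mode": "concat"},
    ])
    def test_ablation_configurations_run_finite(self, kwargs, rng):
        cfg = ModelConfig(base_channels=2, **kwargs)
        net = SingleDomainNet(cfg, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(16, 24)).astype(np.float32))
        y = net(x)
        assert y.shape == (16, 24)
        assert np.all(np.isfinite(y.data))


class TestDualDomainNet:
    def _setup(self, n_views=32, n_det=40, img=16, C=2, dtype="float32"):
        geom = ScanGeometry(n_views_full=n_views, n_detectors=n_det,
                            detector_pitch=2.0)
        px = default_pixel_size(geom, img)
        cfg = FBPConfig(image_size=img, pixel_size=px)
        model_cfg = ModelConfig(base_channels=C, init_seed=3, dtype=dtype)
        return geom, cfg, model_cfg

    def test_identity_stub_equals_fbp_of_interpolated(self, rng):
        geom, fcfg, mcfg = self._setup()
        model = DualDomainNet(mcfg, geom, fcfg, stub=True)
        sparse = Sinogram(rng.uniform(0, 2, (8, 40)).astype(np.float32),
                          geom.view_angles[::4], geom.with_views(8))
        s_out, img_out = model(sparse)
        ref = fbp_reconstruct(interpolate_views(sparse, 32), geom, fcfg)
        np.testing.assert_array_equal(img_out.data.astype(np.float32),
                                      ref.pixels)
        np.testing.assert_array_equal(
            s_out.data.astype(np.float32),
            interpolate_views(sparse, 32).values)

    def test_paper_scale_output_shapes(self, rng):
        """Full acquisition geometry: (512, 720) sinogram in and out,
        square image out (stub mode keeps this affordable)."""
        geom = ScanGeometry()
        px = default_pixel_size(geom, 512)
        model = DualDomainNet(ModelConfig(base_channels=1), geom,
                              FBPConfig(image_size=512, pixel_size=px),
                              stub=True)
        sparse = Sinogram(
            rng.uniform(0, 1, (64, 720)).astype(np.float32),
            geom.view_angles[::8], geom.with_views(64))
        s_out, img_out = model(sparse)
        assert s_out.shape == (512, 720)
        assert img_out.shape == (512, 512)

    def test_geometry_mismatch_rejected(self, rng):
        geom, fcfg, mcfg = self._setup()
        model = DualDomainNet(mcfg, geom, fcfg)
        other = ScanGeometry(n_views_full=8, n_detectors=30,
                             detector_pitch=2.0)
        bad = Sinogram(np.zeros((8, 30), np.float32), other.view_angles,
                       other)
        with pytest.raises(ValueError):
            model(bad)

    def test_sdnet_gradient_matches_finite_differences(self, rng):
        """Gradient of the image-domain loss with respect to an SDNet
        parameter, propagated through the FBP embedding layer, against
        central finite differences."""
        geom, fcfg, mcfg = self._setup(dtype="float64")
        model = DualDomainNet(mcfg, geom, fcfg)
        sparse = Sinogram(rng.uniform(0.2, 2, (8, 40)).astype(np.float32),
                          geom.view_angles[::4], geom.with_views(8))
        target = rng.normal(size=(16, 16))

        def loss_value():
            _, img = model(sparse)
            return ((img - Tensor(target)) ** 2).mean()

        loss = loss_value()
        model.zero_grad()
        loss.backward()
        p = model.sdnet.trunk1.cbr.conv.weight
        idx = (0, 0, 1, 1)
        analytic = p.grad[idx]
        h = 1e-6
        p.data[idx] += h
        lp = float(loss_value().data)
        p.data[idx] -= 2 * h
        lm = float(loss_value().data)
        p.data[idx] += h
        fd = (lp - lm) / (2 * h)
        assert analytic == pytest.approx(fd, rel=1e-3)
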