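import numpy as np
import pytest

from conftest import SMALL_MODEL, TINY_MODEL, tiny_config
from n2g import nn
from n2g.autograd import Tensor
from n2g.model import (CANONICAL_VARIANTS, VARIANTS, GaitRegressor,
                       ModelConfig, RelativeDivision, SqueezeExcite,
                       bias_audit, build_model, load_checkpoint,
                       save_checkpoint)


class TestModelConfig:
    def test_default_time_steps(self):
        cfg = ModelConfig()
        assert cfg.n_time_steps == (1055 - 53) // 11 + 1 == 92

    def test_odd_filters_with_div_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ModelConfig(n_filters_per_channel=7)

    def test_unknown_variant_lists_names(self):
        with pytest.raises(ValueError) as err:
            ModelConfig.for_variant("FExt+Div")
        for name in CANONICAL_VARIANTS:
            assert name in str(err.value)

    @pytest.mark.parametrize("name,flags", [
        ("N2GNet", (True, True, True)),
        ("FExt-Div+SE+Bi", (False, True, True)),
        ("FExt", (True, False, False)),
        ("FExt-Div", (False, False, False)),
        ("FExt+SE", (True, True, False)),
        ("FExt+Bi", (True, False, True)),
    ])
    def test_variant_flags(self, name, flags):
        cfg = ModelConfig.for_variant(name)
        assert (cfg.use_div, cfg.use_se, cfg.use_bi) == flags


class TestFeatureExtraction:
    def test_zero_input_finite_constant(self):
        net = GaitRegressor(tiny_config())
        net.eval()
        out = net.fext(Tensor(np.zeros((1, 2, 60))))
        assert np.all(np.isfinite(out.data))
        # constant across time (running-stat shift only)
        np.testing.assert_allclose(
            out.data, np.broadcast_to(out.data[:, :, :1], out.shape),
            atol=1e-12)

    def test_square_homogeneity_with_bn_bypassed(self):
        cfg = tiny_config(variant_flags=(False, False, False))
        net = GaitRegressor(cfg)
        net.eval()
        net.fext.bypass_bn = True
        t = np.arange(60) / 211.0
        x = np.sin(2 * np.pi * 20 * t)[None, None] * np.ones((1, 2, 1))
        out1 = net.fext(Tensor(x)).data
        out2 = net.fext(Tensor(2 * x)).data
        np.testing.assert_allclose(out2, 4 * out1, rtol=1e-9)

    def test_pooled_squares_nonnegative_when_bn_bypassed(self, rng):
        net = GaitRegressor(tiny_config(variant_flags=(False, False, False)))
        net.eval()
        net.fext.bypass_bn = True
        out = net.fext(Tensor(rng.standard_normal((2, 2, 60))))
        assert np.all(out.data >= 0)

    def test_wrong_shape_rejected(self, rng):
        net = GaitRegressor(tiny_config())
        with pytest.raises(ValueError, match="expected input"):
            net(rng.standard_normal((1, 2, 61)))


class TestRelativeDivision:
    def test_hand_example(self):
        div = RelativeDivision(n_leads=1, per_lead=4, eps=0.0)
        x = Tensor(np.array([4.0, 9.0, 2.0, 3.0]).reshape(1, 4, 1))
        out = div(x).data.reshape(-1)
        np.testing.assert_allclose(out, [4.0, 9.0, 2.0, 3.0])

    def test_joint_scaling_leaves_ratios(self, rng):
        div = RelativeDivision(n_leads=2, per_lead=4, eps=1e-6)
        x = rng.uniform(0.5, 2.0, (1, 8, 3))
        out1 = div(Tensor(x)).data
        out2 = div(Tensor(5.0 * x)).data
        # original halves scale by 5, relative halves are invariant
        for lead in range(2):
            orig = slice(4 * lead, 4 * lead + 2)
            rel = slice(4 * lead + 2, 4 * lead + 4)
            np.testing.assert_allclose(out2[:, orig], 5.0 * out1[:, orig])
            np.testing.assert_allclose(out2[:, rel], out1[:, rel], rtol=1e-5)

    def test_zero_denominator_finite(self):
        div = RelativeDivision(n_leads=1, per_lead=2, eps=1e-6)
        x = Tensor(np.array([3.0, 0.0]).reshape(1, 2, 1))
        out = div(x).data.reshape(-1)
        assert np.all(np.isfinite(out))
        assert out[1] == pytest.approx(3.0 / 1e-6)

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            RelativeDivision(n_leads=1, per_lead=3, eps=1e-6)


class TestSqueezeExcite:
    def test_gate_shrinks_magnitudes(self, rng):
        se = SqueezeExcite(8, 4, np.random.default_rng(0))
        x = rng.standard_normal((2, 8, 5))
        out = se(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    def test_identical_timesteps_identical_gates(self, rng):
        se = SqueezeExcite(8, 4, np.random.default_rng(0))
        col = rng.standard_normal((1, 8, 1))
        x = np.repeat(col, 4, axis=2)
        out = se(Tensor(x)).data
        np.testing.assert_allclose(
            out, np.broadcast_to(out[:, :, :1], out.shape), atol=1e-12)

    def test_zero_input_zero_output(self):
        se = SqueezeExcite(8, 4, np.random.default_rng(0))
        out = se(Tensor(np.zeros((1, 8, 3)))).data
        np.testing.assert_allclose(out, 0.0)

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError):
            SqueezeExcite(9, 4, np.random.default_rng(0))


class TestBiLSTM:
    def test_default_output_shape(self, rng):
        cfg = ModelConfig(**SMALL_MODEL)
        lstm = nn.BiLSTM(cfg.n_features, 64, 3, bias=False,
                         rng=np.random.default_rng(0))
        out = lstm(Tensor(rng.standard_normal((1, cfg.n_features, 92))))
        assert out.shape == (1, 2 * 64, 92)

    def test_tied_weights_time_reversal_symmetry(self, rng):
        lstm = nn.BiLSTM(3, 4, 1, bias=False, rng=np.random.default_rng(0))
        lstm.bwd0.w_ih.data = lstm.fwd0.w_ih.data.copy()
        lstm.bwd0.w_hh.data = lstm.fwd0.w_hh.data.copy()
        x = rng.standard_normal((1, 3, 7))
        out = lstm(Tensor(x)).data
        out_rev = lstm(Tensor(x[:, :, ::-1].copy())).data
        # forward half on reversed input == time-reverse of backward half
        np.testing.assert_allclose(out_rev[:, :4], out[:, 4:, ::-1],
                                   atol=1e-12)

    def test_constant_input_stable(self):
        lstm = nn.BiLSTM(2, 3, 3, bias=False, rng=np.random.default_rng(1))
        x = np.ones((1, 2, 50))
        out = lstm(Tensor(x)).data
        assert np.all(np.isfinite(out))


class TestBuildModel:
    def test_all_variants_build_with_bias_audit(self):
        for name in CANONICAL_VARIANTS:
            handle = build_model(name, **TINY_MODEL)
            audit = handle.structural_report["bias_audit"]
            assert audit["ok"], name
            if handle.config.use_se:
                assert len(audit["bias_parameters"]) == 2
            else:
                assert audit["bias_parameters"] == []

    def test_div_counterparts_equal_parameters(self):
        pairs = [("N2GNet", "FExt-Div+SE+Bi"), ("FExt", "FExt-Div"),
                 ("FExt+SE", "FExt-Div+SE"), ("FExt+Bi", "FExt-Div+Bi")]
        for a, b in pairs:
            pa = build_model(a, **TINY_MODEL).n_parameters
            pb = build_model(b, **TINY_MODEL).n_parameters
            assert pa == pb, (a, b)

    def test_full_model_has_most_parameters(self):
        full = build_model("N2GNet", **TINY_MODEL).n_parameters
        assert full > build_model("FExt+SE", **TINY_MODEL).n_parameters
        assert full > build_model("FExt+Bi", **TINY_MODEL).n_parameters

    def test_forward_scalar_nonnegative(self, rng):
        handle = build_model("N2GNet", **TINY_MODEL)
        pred = handle.network.predict(rng.standard_normal((1, 2, 60)))
        assert pred.shape == (1,)
        assert pred[0] >= 0

    def test_prediction_is_relu_of_preactivation(self, rng):
        handle = build_model("N2GNet", **TINY_MODEL)
        x = rng.standard_normal((64, 2, 60))
        pre, pred = handle.network.predict(x, return_pre=True)
        np.testing.assert_allclose(pred, np.maximum(pre, 0.0), atol=0)

    def test_forward_determinism(self, rng):
        x = rng.standard_normal((2, 2, 60))
        a = build_model("N2GNet", seed=5, **TINY_MODEL).network.predict(x)
        b = build_model("N2GNet", seed=5, **TINY_MODEL).network.predict(x)
        np.testing.assert_array_equal(a, b)

    def test_alias_n2gnet_flags(self):
        assert VARIANTS["N2GNet"] == (True, True, True)


class TestTrainingStep:
    def test_single_example_loss_decreases(self, rng):
        handle = build_model("N2GNet", **TINY_MODEL)
        net = handle.network
        x = Tensor(rng.standard_normal((1, 2, 60)))
        y = Tensor(np.array([0.8]))
        opt = nn.Adam(net.parameters(), lr=1e-5)
        net.train()

        def loss():
            return (net(x) - y).abs().mean()

        l0 = loss()
        opt.zero_grad()
        l0.backward()
        opt.step()
        l1 = loss()
        assert float(l1.data) <= float(l0.data) + 1e-5


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, rng):
        handle = build_model("N2GNet", **TINY_MODEL)
        x = rng.standard_normal((3, 2, 60))
        before = handle.network.predict(x)
        save_checkpoint(handle, tmp_path / "ckpt")
        loaded = load_checkpoint(tmp_path / "ckpt")
        after = loaded.network.predict(x)
        np.testing.assert_array_equal(before, after)
        assert loaded.config == handle.config


def test_bias_audit_flags_intruder():
    handle = build_model("FExt", **TINY_MODEL)
    net = handle.network
    net.head.dense.bias = nn.Parameter(np.zeros(1), is_bias=True)
    audit = bias_audit(net)
    assert not audit["ok"]
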