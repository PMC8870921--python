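import numpy as np
import pytest

from lesionquant import (UNetConfig, build_unet, count_parameters, forward,
                         load_checkpoint, save_checkpoint)
from lesionquant.training import _sigmoid


def small_cfg(**kw):
    base = dict(depth=2, base_channels=2, max_channels=8, in_shape=(16, 16))
    base.update(kw)
    return UNetConfig(**base)


class TestConfig:
    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            UNetConfig(depth=5, in_shape=(250, 250))

    def test_depth_five_accepts_256(self):
        cfg = UNetConfig(depth=5, in_shape=(256, 256))
        # five pooling halvings: 256 -> 8 at the bottleneck
        assert cfg.in_shape[0] // 2 ** cfg.depth == 8

    def test_width_doubling_capped(self):
        cfg = UNetConfig(depth=5, base_channels=16, max_channels=256)
        assert [cfg.width(d) for d in range(6)] == [16, 32, 64, 128, 256, 256]


class TestBuild:
    def test_same_seed_identical_parameters(self):
        a = build_unet(small_cfg(), seed=9)
        b = build_unet(small_cfg(), seed=9)
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_different_seed_differs(self):
        a = build_unet(small_cfg(), seed=1)
        b = build_unet(small_cfg(), seed=2)
        assert any(not np.array_equal(pa.value, pb.value)
                   for pa, pb in zip(a.params, b.params))

    @pytest.mark.parametrize("cfg", [
        small_cfg(),
        small_cfg(batch_norm=False),
        small_cfg(depth=3, base_channels=3, max_channels=100),
        small_cfg(depth=1, base_channels=5),
    ])
    def test_closed_form_count_matches_model(self, cfg):
        model = build_unet(cfg, seed=0)
        assert count_parameters(cfg) == model.n_parameters()

    def test_hand_computed_count_minimal_net(self):
        # depth 1, base 1, no BN: enc0 two 3x3 convs 1->1 (10 each);
        # bottleneck 1->2 (20) and 2->2 (38); decoder 3->1 (28) and 1->1 (10);
        # head 1x1 1->1 (2) => 118
        cfg = small_cfg(depth=1, base_channels=1, max_channels=64,
                        batch_norm=False, in_shape=(8, 8))
        assert count_parameters(cfg) == 118

    def test_doubling_base_roughly_quadruples(self):
        small = count_parameters(small_cfg(base_channels=8, max_channels=1024))
        big = count_parameters(small_cfg(base_channels=16, max_channels=1024))
        assert 3.0 < big / small < 4.5


class TestForward:
    def test_output_shape_and_open_interval(self, rng):
        m = build_unet(small_cfg(), seed=0)
        x = rng.normal(size=(3, 16, 16)).astype(np.float32)
        out = forward(m, x)
        assert out.shape == (3, 16, 16)
        assert out.min() > 0.0 and out.max() < 1.0

    def test_wrong_slice_shape_rejected(self, rng):
        m = build_unet(small_cfg(), seed=0)
        with pytest.raises(ValueError, match="expects"):
            forward(m, rng.normal(size=(2, 8, 8)).astype(np.float32))

    def test_duplicated_slice_identical_outputs(self, rng):
        m = build_unet(small_cfg(), seed=0)
        sl = rng.normal(size=(16, 16)).astype(np.float32)
        out = forward(m, np.stack([sl, sl]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_eval_forward_deterministic(self, rng):
        m = build_unet(small_cfg(), seed=0)
        x = rng.normal(size=(2, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(forward(m, x), forward(m, x))

    def test_prior_sets_initial_output_level(self, rng):
        m = build_unet(small_cfg(batch_norm=False, foreground_prior=0.01), seed=0)
        x = rng.normal(size=(2, 16, 16)).astype(np.float32)
        # mean initial membership tracks the configured foreground prior
        assert forward(m, x).mean() < 0.1


class TestGradients:
    def test_directional_derivative_matches_backprop(self, rng):
        """Backprop against a numeric directional derivative of the summed BCE.

        ReLU/max-pool kinks make per-element checks unreliable in float32, so
        the check is along one random direction in parameter space, where the
        kink set has measure ~0.
        """
        cfg = small_cfg(batch_norm=False, in_shape=(8, 8))
        m = build_unet(cfg, seed=3)
        params = m.params
        # nudge biases off zero: with zero biases, dead receptive fields put
        # pre-activations exactly on the ReLU kink where the two-sided
        # numeric difference disagrees with the one-sided convention
        for p in params:
            if p.name.endswith(".b"):
                p.value = p.value + rng.normal(0.05, 0.02,
                                               p.value.shape).astype(np.float32)
        x = rng.normal(size=(3, 8, 8)).astype(np.float32)
        y = (rng.random((3, 8, 8)) > 0.6).astype(np.float32)

        def loss():
            z = m.forward_logits(x, train=True).astype(np.float64)
            p = np.clip(1.0 / (1.0 + np.exp(-z)), 1e-12, 1 - 1e-12)
            yy = y[..., None]
            return float(-(yy * np.log(p) + (1 - yy) * np.log(1 - p)).sum())

        for p in params:
            p.grad[...] = 0.0
        z = m.forward_logits(x, train=True)
        m.backward((_sigmoid(z) - y[..., None]).astype(np.float32))

        direction = [rng.normal(size=p.value.shape).astype(np.float32)
                     for p in params]
        norm = np.sqrt(sum(float((d * d).sum()) for d in direction))
        direction = [d / norm for d in direction]
        analytic = sum(float((p.grad * d).sum())
                       for p, d in zip(params, direction))
        h = 1e-2
        saved = [p.value.copy() for p in params]
        for p, d, s in zip(params, direction, saved):
            p.value = s + h * d
        lp = loss()
        for p, d, s in zip(params, direction, saved):
            p.value = s - h * d
        lm = loss()
        for p, s in zip(params, saved):
            p.value = s
        numeric = (lp - lm) / (2 * h)
        assert analytic == pytest.approx(numeric, rel=1e-3)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, rng):
        m = build_unet(small_cfg(), seed=4)
        x = rng.normal(size=(2, 16, 16)).astype(np.float32)
        before = forward(m, x)
        path = tmp_path / "model.npz"
        save_checkpoint(m, path)
        loaded = load_checkpoint(path)
        assert loaded.cfg == m.cfg
        np.testing.assert_array_equal(forward(loaded, x), before)
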