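"""Architecture accounting, geometry head, losses, metrics, training loop."""

import numpy as np
import pytest

from diffraqc.geometry import radius_at_resolution
from diffraqc.model import (ArchitectureSpec, TrainConfig, accuracy_overlap,
                            accuracy_resolution, build_model,
                            count_parameters, count_parameters_for_depth,
                            geometry_head, geometry_head_grad, load_checkpoint,
                            loss_overlap, loss_resolution, save_checkpoint,
                            sigmoid, toy_train_config, train)
from diffraqc import nn

LAMBDA = 0.9795


class TestParameterAccounting:
    """Exact trainable-scalar counts per model stage."""

    def test_fc_head_counts_fixed_for_every_depth(self):
        for depth in ("toy", 18, 34, 50):
            counts = (count_parameters(build_model(ArchitectureSpec(depth=depth)))
                      if depth == "toy" else count_parameters_for_depth(depth))
            assert counts.fc1 == 100_100          # 100 + 10^5
            assert counts.fc2 == 101              # 1 + 10^2

    def test_resolution_backbone_depth50(self):
        counts = count_parameters_for_depth(50)
        assert counts.backbone == 25_550_760
        assert counts.total == 25_650_961

    def test_overlap_backbone_depth34(self):
        counts = count_parameters_for_depth(34)
        assert counts.backbone == 21_791_400
        assert counts.total == 21_891_601

    def test_built_resnet18_matches_shape_table(self):
        # the instantiated network counts exactly what the table predicts
        model = build_model(ArchitectureSpec(depth=18))
        assert count_parameters(model).backbone == count_parameters_for_depth(18).backbone

    def test_total_is_sum_of_stages(self):
        c = count_parameters(build_model(ArchitectureSpec(depth="toy")))
        assert c.total == c.backbone + c.fc1 + c.fc2

    def test_unknown_depth_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(depth=27)
        with pytest.raises(ValueError):
            ArchitectureSpec(head="banana")


class TestForwardShapes:
    def test_toy_forward_on_128_input(self):
        model = build_model(ArchitectureSpec(depth="toy", head="sigmoid_overlap"))
        x = np.random.default_rng(0).random((3, 128, 128)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (3,)

    def test_toy_forward_on_quadrant_input(self):
        model = build_model(ArchitectureSpec(depth="toy"))
        x = np.zeros((2, 512, 512), dtype=np.float32)
        geom = {"wavelength_A": LAMBDA, "p_eff_mm": 1.0, "distance_mm": 250.0}
        out = model.forward(x, geom=geom)
        assert out.shape == (2,)
        assert np.all(out >= 0)

    def test_resolution_head_requires_geometry(self):
        model = build_model(ArchitectureSpec(depth="toy"))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 128, 128)))


class TestGeometryHead:
    def test_zero_scalar_maps_to_zero(self):
        assert geometry_head(0.0, LAMBDA, 1.0, 250.0) == 0.0
        assert geometry_head(-3.0, LAMBDA, 1.0, 250.0) == 0.0

    def test_closed_form_45_degrees(self):
        # s * p_eff = D puts the effective radius at 2theta = 45 deg
        out = geometry_head(250.0, LAMBDA, 1.0, 250.0)
        assert out == pytest.approx(2 * np.sin(np.radians(22.5)) / LAMBDA,
                                    rel=1e-12)

    def test_exactly_inverts_radius_at_resolution(self):
        # s chosen as r(d) / p_eff returns 1/d to 1e-9
        p_eff, D = 0.344, 265.0
        for d in (1.4, 2.0, 3.3, 4.5):
            s = radius_at_resolution(d, D, LAMBDA) / p_eff
            assert geometry_head(s, LAMBDA, p_eff, D) == pytest.approx(
                1.0 / d, rel=1e-9)

    def test_monotone_in_s(self):
        s = np.linspace(1.0, 500.0, 200)
        out = geometry_head(s, LAMBDA, 1.0, 250.0)
        assert np.all(np.diff(out) > 0)

    def test_gradient_matches_finite_difference(self):
        s = np.array([5.0, 80.0, 300.0])
        g = geometry_head_grad(s, LAMBDA, 1.0, 250.0)
        eps = 1e-6
        num = (geometry_head(s + eps, LAMBDA, 1.0, 250.0)
               - geometry_head(s - eps, LAMBDA, 1.0, 250.0)) / (2 * eps)
        np.testing.assert_allclose(g, num, rtol=1e-6)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            geometry_head(1.0, -1.0, 1.0, 250.0)


class TestLosses:
    def test_resolution_loss_values(self):
        assert loss_resolution([0.5], [0.5], "mse")[0] == 0.0
        assert loss_resolution([0.5], [0.4], "mse")[0] == pytest.approx(0.01)
        assert loss_resolution([0.5], [0.4], "mae")[0] == pytest.approx(0.1)

    def test_batch_loss_is_mean_of_items(self):
        preds = np.array([0.5, 0.3, 0.7])
        labels = np.array([0.4, 0.3, 0.2])
        per_item = [loss_resolution([p], [l], "mse")[0]
                    for p, l in zip(preds, labels)]
        assert loss_resolution(preds, labels, "mse")[0] == pytest.approx(
            np.mean(per_item))

    def test_bce_closed_forms(self):
        assert loss_overlap([0.0], [1.0])[0] == pytest.approx(np.log(2))
        assert loss_overlap([30.0], [1.0])[0] == pytest.approx(0.0, abs=1e-9)
        # sigmoid symmetry: loss(z, 1) = loss(-z, 0)
        assert loss_overlap([1.7], [1.0])[0] == pytest.approx(
            loss_overlap([-1.7], [0.0])[0])

    def test_loss_gradients_match_finite_difference(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=5)
        y = (rng.random(5) > 0.5).astype(float)
        for fn, args in ((loss_overlap, (y,)),
                         (lambda p, y: loss_resolution(p, y, "mse"), (y,))):
            _, grad = fn(z, *args)
            eps = 1e-6
            for i in range(5):
                zp, zm = z.copy(), z.copy()
                zp[i] += eps
                zm[i] -= eps
                num = (fn(zp, *args)[0] - fn(zm, *args)[0]) / (2 * eps)
                assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-9)


class TestAccuracy:
    def test_perfect_and_threshold(self):
        assert accuracy_resolution([0.5, 0.3], [0.5, 0.3]) == 1.0
        assert accuracy_resolution([0.50], [0.58]) == 0.0
        assert accuracy_resolution([0.50], [0.57]) == 1.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        preds = rng.random(100)
        labels = rng.random(100)
        expect = sum(abs(p - l) <= 0.07 for p, l in zip(preds, labels)) / 100
        assert accuracy_resolution(preds, labels) == pytest.approx(expect)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            accuracy_resolution([], [])
        with pytest.raises(ValueError):
            accuracy_overlap([], [])


class TestLayerGradients:
    """Numerical gradient checks of the layer library on tiny tensors."""

    @staticmethod
    def _check(layer, x, train=True, rtol=2e-3):
        rng = np.random.default_rng(0)
        out = layer.forward(x.astype(np.float64), train=train)
        gout = rng.normal(size=out.shape)
        for p in layer.params():
            p.grad[...] = 0.0
        gx = layer.backward(gout)

        def total(xv):
            return float(np.sum(layer.forward(xv, train=False) * gout))

        # input gradient (eval-mode forward for layers whose train pass is
        # stochastic or stateful is handled per-case by callers)
        eps = 1e-4
        flat = x.reshape(-1)
        idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            up = total(x)
            flat[i] = orig - eps
            dn = total(x)
            flat[i] = orig
            assert gx.reshape(-1)[i] == pytest.approx((up - dn) / (2 * eps),
                                                      rel=rtol, abs=1e-5)

    def test_conv_gradients(self):
        rng = np.random.default_rng(3)
        conv = nn.Conv2d(2, 3, 3, stride=2, pad=1, bias=True, rng=rng)
        x = rng.normal(size=(2, 2, 7, 7))
        self._check(conv, x)
        # weight gradient
        out = conv.forward(x)
        gout = np.ones_like(out)
        for p in conv.params():
            p.grad[...] = 0.0
        conv.backward(gout)
        w = conv.weight
        eps = 1e-4
        orig = w.value[1, 0, 1, 1]
        w.value[1, 0, 1, 1] = orig + eps
        up = conv.forward(x).sum()
        w.value[1, 0, 1, 1] = orig - eps
        dn = conv.forward(x).sum()
        w.value[1, 0, 1, 1] = orig
        assert w.grad[1, 0, 1, 1] == pytest.approx((up - dn) / (2 * eps),
                                                   rel=1e-3)

    def test_linear_maxpool_meanpool_gradients(self):
        rng = np.random.default_rng(4)
        self._check(nn.Linear(6, 4, rng=rng), rng.normal(size=(3, 6)))
        self._check(nn.BlockMeanPool(2), rng.normal(size=(2, 1, 6, 6)))
        x = rng.normal(size=(1, 2, 6, 6))
        x += 0.05 * np.arange(x.size).reshape(x.shape)  # break max ties
        self._check(nn.MaxPool2d(3, stride=2, pad=1), x)


class TestTraining:
    def _tiny_dataset(self, n=16, seed=0):
        rng = np.random.default_rng(seed)
        # images whose bright-disk radius encodes the label, on a 128 grid
        labels = rng.uniform(0.25, 0.65, size=n)
        imgs = np.zeros((n, 128, 128), dtype=np.float32)
        yy, xx = np.mgrid[:128, :128]
        for i, lab in enumerate(labels):
            r = radius_at_resolution(1.0 / lab, 250.0, LAMBDA)
            imgs[i] = 30.0 * (np.hypot(yy, xx) * 4.0 <= r)
        geom = {"wavelength_A": np.full(n, LAMBDA),
                "p_eff_mm": np.full(n, 1.0),
                "distance_mm": np.full(n, 250.0)}
        return {"images": imgs, "labels": labels, "geometry": geom}

    def test_loss_trajectory_is_deterministic(self):
        ds = self._tiny_dataset()
        spec = ArchitectureSpec(depth="toy")
        cfg = toy_train_config("resolution", epochs=2, seed=7, batch_size=8)
        r1, s1, _ = train(ds, spec, cfg)
        r2, s2, _ = train(ds, spec, cfg)
        assert [(r.train_loss, r.test_loss) for r in r1] == \
               [(r.train_loss, r.test_loss) for r in r2]
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_training_reduces_loss(self):
        ds = self._tiny_dataset(n=48, seed=1)
        spec = ArchitectureSpec(depth="toy")
        cfg = toy_train_config("resolution", epochs=10, seed=3, batch_size=16)
        records, _, _ = train(ds, spec, cfg)
        assert records[-1].train_loss < records[0].train_loss

    def test_head_config_mismatch_rejected(self):
        ds = self._tiny_dataset()
        spec = ArchitectureSpec(depth="toy", head="sigmoid_overlap")
        cfg = toy_train_config("resolution", epochs=1)
        with pytest.raises(ValueError):
            train(ds, spec, cfg)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(test_fraction=0.0)
        with pytest.raises(ValueError):
            TrainConfig(task="banana")


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = build_model(ArchitectureSpec(depth="toy", head="sigmoid_overlap",
                                             fc1_dropout=True), seed=5)
        x = np.random.default_rng(6).random((2, 128, 128)).astype(np.float32)
        p0 = model.predict(x)
        path = tmp_path / "ck.npz"
        save_checkpoint(path, model, meta={"note": "test"})
        again, meta = load_checkpoint(path)
        assert meta["note"] == "test"
        np.testing.assert_allclose(again.predict(x), p0, rtol=1e-6)
        assert np.all((p0 >= 0) & (p0 <= 1))

    def test_sigmoid_is_stable_and_symmetric(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(800.0) == pytest.approx(1.0)
        assert sigmoid(-800.0) == pytest.approx(0.0)
        z = np.linspace(-5, 5, 11)
        np.testing.assert_allclose(sigmoid(z) + sigmoid(-z), 1.0, rtol=1e-12)
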