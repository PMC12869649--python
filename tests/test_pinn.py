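import numpy as np
import pytest

from qrai.grid import Grid, PressureVolume
from qrai.acoustics import AcousticMedium
from qrai.beams import make_pulse
from qrai.twin import TransducerArray, ImpulseResponse, TwinConfig, TwinOperator
from qrai.pinn import (
    NetworkConfig,
    TrainConfig,
    TrainingSample,
    pressure_loss,
    sinogram_loss,
    sinogram_loss_grad,
    total_loss,
    train,
    enhance,
    save_model,
    load_model,
)
from conftest import gaussian_blob


def tiny_twin(grid_n=8, ndim=3):
    g = Grid((grid_n,) * ndim, (1e-3,) * ndim)
    med = AcousticMedium(g, c=1500.0)
    center = [(grid_n - 2) * 1e-3] + [(grid_n - 1) / 2.0 * 1e-3] * (ndim - 1)
    arr = TransducerArray.matrix(
        rows=2, cols=1 if ndim == 2 else 2, pitch=3e-3, center=center,
        normal=(-1.0,) + (0.0,) * (ndim - 1),
        element_size=(2e-3, 2e-3), sub_pitch=1e-3,
    )
    cfg = TwinConfig(
        pulse=make_pulse("box", 6e-7, 2e-7),
        array=arr,
        ir=ImpulseResponse(kind="damped-sinusoid", f0=1e6, q=2.0),
        medium=med,
        duration=1.2e-5,
        pml_width=2,
    )
    return TwinOperator(cfg)


class TestLosses:
    def test_pressure_loss_identity_and_offset(self, grid2d, rng):
        a = PressureVolume(grid2d, rng.random(grid2d.shape), role="p_pred")
        assert pressure_loss(a, a) == 0.0
        b = PressureVolume(grid2d, a.values + 1.0, role="p_pred")
        assert pressure_loss(b, a) == pytest.approx(1.0)

    def test_pressure_loss_hand_case(self):
        g = Grid((2, 1), (1e-3, 1e-3))
        a = PressureVolume(g, np.array([[0.0], [0.0]]), role="p_pred")
        b = PressureVolume(g, np.array([[3.0], [4.0]]), role="p_pred")
        assert pressure_loss(a, b) == pytest.approx(12.5)

    def test_pressure_loss_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            pressure_loss(rng.random((4, 4)), rng.random((5, 5)))

    def test_sinogram_loss_self_consistency(self, rng):
        op = tiny_twin()
        pred = rng.random(op.cfg.medium.grid.shape)
        s_m = op.to_sinogram(op.apply(pred))
        assert sinogram_loss(pred, s_m, op) == pytest.approx(0.0, abs=1e-20)

    def test_sinogram_loss_zero_prediction(self, rng):
        op = tiny_twin()
        s_m = op.to_sinogram(rng.standard_normal((op.n_elements, op.n_steps)))
        expected = float(np.mean(s_m.data**2))
        zero = np.zeros(op.cfg.medium.grid.shape)
        assert sinogram_loss(zero, s_m, op) == pytest.approx(expected)

    def test_sinogram_gradient_matches_finite_difference(self, rng):
        """Adjoint-computed gradient of Ls vs central differences on 8^3."""
        op = tiny_twin(grid_n=8, ndim=3)
        pred = rng.random(op.cfg.medium.grid.shape)
        s_m_data = op.apply(rng.random(op.cfg.medium.grid.shape))
        _, grad = sinogram_loss_grad(pred, s_m_data, op)
        s_m = op.to_sinogram(s_m_data)
        for _ in range(3):
            idx = tuple(rng.integers(s) for s in pred.shape)
            eps = 1e-6
            pp = pred.copy()
            pp[idx] += eps
            lp = sinogram_loss(pp, s_m, op)
            pm = pred.copy()
            pm[idx] -= eps
            lm = sinogram_loss(pm, s_m, op)
            fd = (lp - lm) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-12)

    def test_total_loss_weighting(self):
        assert total_loss(2.0, 3.0, 1.0, 2.0) == pytest.approx(8.0)
        assert total_loss(2.0, 3.0, 1.0, 0.0) == pytest.approx(2.0)
        assert total_loss(2.0, 3.0, 0.0, 2.0) == pytest.approx(6.0)


def make_dataset(op, n, rng, labeled=True):
    g = op.cfg.medium.grid
    out = []
    for _ in range(n):
        center = rng.integers(2, np.array(g.shape) - 2)
        p0 = gaussian_blob(g, center, sigma_vox=1.2, amplitude=1.0)
        s_m = op.to_sinogram(op.apply(p0.values))
        p_rec = PressureVolume(
            g, 0.6 * p0.values + 0.15 * rng.standard_normal(g.shape), role="p_rec"
        )
        out.append(
            TrainingSample(p_rec=p_rec, p0=p0 if labeled else None, s_m=s_m)
        )
    return out


class TestTraining:
    def test_loss_decreases_and_identity_holds(self, rng):
        op = tiny_twin()
        ds = make_dataset(op, 4, rng)
        net_cfg = NetworkConfig(ndim=3, depth=2, base_channels=2)
        model, recs = train(
            ds, net_cfg, TrainConfig(epochs=8, seed=3, lambda2=None), twin=op
        )
        assert recs[-1].total < recs[0].total
        for r in recs:
            assert r.total == pytest.approx(
                r.lambda1 * r.loss_p + r.lambda2 * r.loss_s, rel=1e-12
            )

    def test_determinism(self, rng):
        op = tiny_twin()
        ds = make_dataset(op, 3, rng)
        cfg = NetworkConfig(ndim=3, depth=2, base_channels=2)
        _, r1 = train(ds, cfg, TrainConfig(epochs=4, seed=7, lambda2=None), twin=op)
        _, r2 = train(ds, cfg, TrainConfig(epochs=4, seed=7, lambda2=None), twin=op)
        assert [(r.loss_p, r.loss_s) for r in r1] == [(r.loss_p, r.loss_s) for r in r2]

    def test_lambda2_zero_is_supervised_baseline(self, rng):
        """With lambda2=0 the physics term does not influence the records."""
        op = tiny_twin()
        ds = make_dataset(op, 3, rng)
        cfg = NetworkConfig(ndim=3, depth=2, base_channels=2)
        _, with_op = train(ds, cfg, TrainConfig(epochs=4, seed=5, lambda2=0.0), twin=op)
        _, without = train(ds, cfg, TrainConfig(epochs=4, seed=5, lambda2=0.0))
        assert [r.loss_p for r in with_op] == [r.loss_p for r in without]

    def test_self_supervised_reduces_sinogram_loss(self, rng):
        """lambda1=0 training on unlabeled samples still drives Ls down."""
        op = tiny_twin()
        ds = make_dataset(op, 4, rng, labeled=False)
        cfg = NetworkConfig(ndim=3, depth=2, base_channels=2)
        _, recs = train(
            ds, cfg, TrainConfig(lambda1=0.0, lambda2=1.0, epochs=10, seed=2), twin=op
        )
        assert recs[-1].loss_s < recs[0].loss_s

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], NetworkConfig(), TrainConfig())

    def test_auto_lambda2_balances_terms(self, rng):
        op = tiny_twin()
        ds = make_dataset(op, 3, rng)
        cfg = NetworkConfig(ndim=3, depth=2, base_channels=2)
        _, recs = train(ds, cfg, TrainConfig(epochs=2, seed=1, lambda2=None), twin=op)
        r0 = recs[0]
        ratio = (r0.lambda2 * r0.loss_s) / (r0.lambda1 * r0.loss_p)
        assert 0.5 <= ratio <= 2.0


class TestEnhance:
    def test_shape_scale_and_nonneg(self, rng):
        op = tiny_twin()
        ds = make_dataset(op, 2, rng)
        cfg = NetworkConfig(ndim=3, depth=2, base_channels=2)
        model, _ = train(ds, cfg, TrainConfig(epochs=2, seed=0, lambda2=0.0))
        out = enhance(ds[0].p_rec, model)
        assert out.values.shape == ds[0].p_rec.values.shape
        assert out.role == "p_pred"
        assert out.values.min() >= 0.0

    def test_checkpoint_round_trip(self, rng, tmp_path):
        op = tiny_twin()
        ds = make_dataset(op, 2, rng)
        cfg = NetworkConfig(ndim=3, depth=2, base_channels=2)
        model, _ = train(ds, cfg, TrainConfig(epochs=2, seed=0, lambda2=0.0))
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        a = enhance(ds[0].p_rec, model)
        b = enhance(ds[0].p_rec, back)
        np.testing.assert_array_equal(a.values, b.values)
        assert back.train_cfg.normalization == model.train_cfg.normalization
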