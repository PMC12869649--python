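"""Physics-informed enhancement of time-reversal reconstructions.

A U-Net ``N`` maps the limited-view reconstruction ``p_rec`` to a predicted
initial pressure ``p_pred``. Training minimizes

    L = lambda1 * Lp + lambda2 * Ls ,
    Lp = mean |N(p_rec) - p0|^2            (image-domain supervision),
    Ls = mean |F(N(p_rec)) - S_m|^2        (sinogram-domain physics loss),

where F is the non-trainable digital-twin forward operator. Because F is
linear, the gradient of Ls is propagated to the image domain by the exact
adjoint of F — no surrogate model is involved. Samples without a ground-truth
``p0`` (as for in vivo data, where the initial pressure is inaccessible)
contribute only the self-supervised sinogram term; setting ``lambda2 = 0``
recovers a plain supervised U-Net baseline.

Each sample's ``p_rec`` is max-normalized, with the scale stored and
re-applied after inference so predictions stay on the physical scale of the
input reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .grid import PressureVolume
from .twin import Sinogram, TwinConfig, TwinOperator
from .nn import UNet, Adam

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TrainingSample",
    "LossRecord",
    "PinnModel",
    "pressure_loss",
    "sinogram_loss",
    "total_loss",
    "train",
    "enhance",
    "save_model",
    "load_model",
]


@dataclass
class NetworkConfig:
    """U-Net hyperparameters; input extents must divide by 2^(depth-1)."""

    ndim: int = 3
    depth: int = 3
    base_channels: int = 8
    final_activation: str = "nonneg"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.final_activation not in ("nonneg", "linear"):
            raise ValueError("final_activation must be 'nonneg' or 'linear'")


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``lambda2 = None`` auto-balances the physics term once, at the first
    epoch, so both loss terms start at comparable magnitude. ``normalization``
    is the per-sample scale policy applied to p_rec (and consistently to p0
    and S_m, all of which are linear in p_rec's scale).
    """

    lambda1: float = 1.0
    lambda2: float | None = None
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 1
    seed: int = 0
    normalization: str = "max"

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or (self.lambda2 is not None and self.lambda2 < 0):
            raise ValueError("loss weights must be non-negative")
        if self.lambda1 == 0 and self.lambda2 == 0:
            raise ValueError("lambda1 and lambda2 cannot both be zero")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.normalization not in ("max", "none"):
            raise ValueError("normalization must be 'max' or 'none'")


@dataclass
class TrainingSample:
    """One training triple (p_rec, optional p0, measured sinogram)."""

    p_rec: PressureVolume
    s_m: Sinogram
    p0: PressureVolume | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.p0 is not None and self.p0.grid != self.p_rec.grid:
            raise ValueError("p_rec and p0 must share a grid")


@dataclass
class LossRecord:
    epoch: int
    loss_p: float
    loss_s: float
    lambda1: float
    lambda2: float

    @property
    def total(self) -> float:
        return self.lambda1 * self.loss_p + self.lambda2 * self.loss_s


@dataclass
class PinnModel:
    """Trained enhancement model: network + configs + normalization policy."""

    net: UNet
    net_cfg: NetworkConfig
    train_cfg: TrainConfig


# ---------------------------------------------------------------------------
# losses


def pressure_loss(pred, target) -> float:
    """Mean squared voxel difference between predicted and true pressure."""
    pred_v = pred.values if isinstance(pred, PressureVolume) else np.asarray(pred)
    tgt_v = target.values if isinstance(target, PressureVolume) else np.asarray(target)
    if pred_v.shape != tgt_v.shape:
        raise ValueError(f"shape mismatch: {pred_v.shape} vs {tgt_v.shape}")
    return float(np.mean((pred_v - tgt_v) ** 2))


def sinogram_loss(pred, s_m: Sinogram, twin: TwinConfig | TwinOperator) -> float:
    """Mean squared difference between F(pred) and the measured sinogram."""
    op = twin if isinstance(twin, TwinOperator) else TwinOperator(twin)
    pred_v = pred.values if isinstance(pred, PressureVolume) else np.asarray(pred)
    sim = op.apply(pred_v)
    if sim.shape != s_m.data.shape:
        raise ValueError(
            f"twin geometry produces sinogram {sim.shape}, measured is {s_m.data.shape}"
        )
    return float(np.mean((sim - s_m.data) ** 2))


def sinogram_loss_grad(
    pred_values: np.ndarray, s_m_data: np.ndarray, op: TwinOperator
) -> tuple[float, np.ndarray]:
    """Value and exact gradient of the sinogram loss w.r.t. the prediction."""
    resid = op.apply(pred_values) - s_m_data
    loss = float(np.mean(resid**2))
    grad = op.adjoint(2.0 * resid / resid.size)
    return loss, grad


def total_loss(loss_p: float, loss_s: float, lambda1: float, lambda2: float) -> float:
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("loss weights must be non-negative")
    return lambda1 * loss_p + lambda2 * loss_s


# ---------------------------------------------------------------------------
# training


def _normalize(sample: TrainingSample, policy: str):
    """Per-sample scale; p0 and S_m share p_rec's scale (all linear in it)."""
    if policy == "max":
        scale = float(np.max(np.abs(sample.p_rec.values)))
        scale = scale if scale > 0 else 1.0
    else:
        scale = 1.0
    x = sample.p_rec.values / scale
    tgt = None if sample.p0 is None else sample.p0.values / scale
    sino = sample.s_m.data / scale
    return x, tgt, sino, scale


def train(
    dataset: list[TrainingSample],
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    twin: TwinConfig | TwinOperator | None = None,
) -> tuple[PinnModel, list[LossRecord]]:
    """Jointly optimize image fidelity and sinogram-domain physics consistency.

    Deterministic given ``train_cfg.seed`` (network init and batch order).
    ``twin`` may be omitted only when ``lambda2 == 0`` (supervised baseline).
    Returns the model and the per-epoch loss history; the logged identity
    ``total = lambda1 * loss_p + lambda2 * loss_s`` holds exactly at every
    epoch.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    shape = dataset[0].p_rec.values.shape
    for s in dataset:
        if s.p_rec.values.shape != shape:
            raise ValueError("all training samples must share one grid shape")
    lam2_known = train_cfg.lambda2 is not None
    lam2 = train_cfg.lambda2 if lam2_known else 0.0
    need_physics = (not lam2_known) or lam2 > 0
    op: TwinOperator | None = None
    if need_physics:
        if twin is None:
            raise ValueError("physics loss requested but no twin operator given")
        op = twin if isinstance(twin, TwinOperator) else TwinOperator(twin)
    if any(s.p0 is None for s in dataset) and train_cfg.lambda1 > 0 and not need_physics:
        raise ValueError("samples without p0 require a physics (sinogram) loss")

    rng = np.random.default_rng(train_cfg.seed)
    net = UNet(
        ndim=net_cfg.ndim,
        depth=net_cfg.depth,
        base_channels=net_cfg.base_channels,
        final_activation=net_cfg.final_activation,
        rng=rng,
    )
    net.check_shape(shape)
    opt = Adam(net.params, net.grads, lr=train_cfg.lr)

    prepared = [_normalize(s, train_cfg.normalization) for s in dataset]
    for s, (_, _, _, scale) in zip(dataset, prepared):
        s.scale = scale

    records: list[LossRecord] = []
    lam1 = train_cfg.lambda1
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(prepared))
        sum_p, n_p, sum_s, n_s = 0.0, 0, 0.0, 0
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start : start + train_cfg.batch_size]
            net.zero_grad()
            for j in batch:
                x, tgt, sino, _ = prepared[j]
                pred = net.forward(x[None, None])
                grad = np.zeros_like(pred)
                if tgt is not None and lam1 > 0:
                    lp = float(np.mean((pred[0, 0] - tgt) ** 2))
                    grad[0, 0] += lam1 * 2.0 * (pred[0, 0] - tgt) / tgt.size
                    sum_p += lp
                    n_p += 1
                if need_physics:
                    ls, gs = sinogram_loss_grad(pred[0, 0], sino, op)
                    sum_s += ls
                    n_s += 1
                    if lam2 > 0:
                        grad[0, 0] += lam2 * gs
                if not np.all(np.isfinite(grad)):
                    raise FloatingPointError(
                        f"non-finite gradient at epoch {epoch}; "
                        "reduce the learning rate or check the inputs"
                    )
                net.backward(grad)
            opt.step()
        loss_p = sum_p / n_p if n_p else 0.0
        loss_s = sum_s / n_s if n_s else 0.0
        if not np.isfinite(loss_p) or not np.isfinite(loss_s):
            raise FloatingPointError(f"loss diverged at epoch {epoch}")
        if not lam2_known:
            # one-time balance: physics term starts at the image term's level
            lam2 = lam1 * loss_p / loss_s if loss_s > 0 else 0.0
            lam2_known = True
        records.append(
            LossRecord(epoch=epoch, loss_p=loss_p, loss_s=loss_s, lambda1=lam1, lambda2=lam2)
        )
    final_cfg = TrainConfig(
        lambda1=lam1,
        lambda2=lam2,
        lr=train_cfg.lr,
        epochs=train_cfg.epochs,
        batch_size=train_cfg.batch_size,
        seed=train_cfg.seed,
        normalization=train_cfg.normalization,
    )
    return PinnModel(net=net, net_cfg=net_cfg, train_cfg=final_cfg), records


def enhance(p_rec: PressureVolume, model: PinnModel) -> PressureVolume:
    """Apply the trained network; output on p_rec's physical scale."""
    x = p_rec.values
    if model.train_cfg.normalization == "max":
        scale = float(np.max(np.abs(x)))
        scale = scale if scale > 0 else 1.0
    else:
        scale = 1.0
    pred = model.net.forward((x / scale)[None, None])[0, 0] * scale
    return PressureVolume(p_rec.grid, pred, role="p_pred")


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: PinnModel, path) -> None:
    """Bundle weights + configs + normalization policy into one .npz file."""
    path = Path(path)
    meta = {
        "net_cfg": asdict(model.net_cfg),
        "train_cfg": asdict(model.train_cfg),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.net.state_dict())


def load_model(path) -> PinnModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        net_cfg = NetworkConfig(**meta["net_cfg"])
        train_cfg = TrainConfig(**meta["train_cfg"])
        rng = np.random.default_rng(0)
        net = UNet(
            ndim=net_cfg.ndim,
            depth=net_cfg.depth,
            base_channels=net_cfg.base_channels,
            final_activation=net_cfg.final_activation,
            rng=rng,
        )
        net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return PinnModel(net=net, net_cfg=net_cfg, train_cfg=train_cfg)
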