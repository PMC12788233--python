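"""Reconstruction networks and the training loop.

Three architectures share one contract — input a 1 x 512 Lead I window (plus
a D-dimensional one-hot metadata vector), output an 11 x 512 matrix of the
remaining leads in the order II, III, aVR, aVL, aVF, V1-V6, all in mV:

* ``DualBranchNet`` (the proposed model): a two-layer 1-D CNN front-end
  (32 filters, kernel 5, ReLU) feeding a BiLSTM; the metadata pass through a
  three-layer fully connected branch whose output is broadcast along the 512
  time steps and concatenated with the BiLSTM features (late fusion).
  Dropout (rate 0.2) sits after the BiLSTM block and after the concatenation
  block — these two layers are also the Monte-Carlo dropout sites kept
  active at inference for uncertainty estimation.
* ``EarlyFusionNet``: the identical CNN-BiLSTM backbone, but the metadata
  enter by channel repetition at the input (a (D+1) x 512 tensor); no
  separate feature branch.
* ``UNet1d``: a depth-3 1-D encoder-decoder with skip connections over the
  same channel-repeated input.

Signals are trained in raw mV (no normalization) so reported RMSE is in mV.
Training uses Adam on MSE with per-epoch shuffling; validation runs every
``validation_interval_epochs`` epochs (and always at the final epoch) and
the parameters with the lowest validation loss are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .synth import ParameterError

#: hyperparameter search ranges explored upstream of the final defaults
#: (documentation only; no search is performed here)
SEARCH_RANGES = {
    "bilstm_units": (128, 1024),
    "conv_filters": (16, 128),
    "kernel_size": (3, 9),
    "dropout_rate": (0.1, 0.3),
    "learning_rate": (0.001, 0.005),
}


@dataclass
class ModelConfig:
    """Final architecture/training configuration (defaults as published)."""

    conv_layers: int = 2
    conv_filters: int = 32
    kernel_size: int = 5
    bilstm_units: int = 512
    dropout_rate: float = 0.2
    feature_fc_layers: int = 3
    feature_fc_width: int = 32
    fusion_fc_widths: tuple[int, ...] = (256,)
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    validation_interval_epochs: int = 20
    seed: int = 0
    # U-Net baseline scale
    unet_depth: int = 3
    unet_base_filters: int = 16

    def __post_init__(self) -> None:
        for name in ("conv_layers", "conv_filters", "kernel_size", "bilstm_units",
                     "feature_fc_layers", "feature_fc_width", "epochs",
                     "batch_size", "validation_interval_epochs"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be a positive count")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        self.fusion_fc_widths = tuple(self.fusion_fc_widths)


class DualBranchNet:
    """Late-fusion CNN-BiLSTM; ``metadata_dim=0`` gives the time-series-only
    variant (no feature branch, concatenation degenerates to identity)."""

    def __init__(self, cfg: ModelConfig, metadata_dim: int, in_channels: int = 1):
        if metadata_dim < 0:
            raise ParameterError("metadata_dim must be >= 0")
        rng = np.random.default_rng(cfg.seed)
        f, k, h = cfg.conv_filters, cfg.kernel_size, cfg.bilstm_units
        self.cfg = cfg
        self.metadata_dim = metadata_dim
        self.in_channels = in_channels
        self.convs = []
        cin = in_channels
        for i in range(cfg.conv_layers):
            self.convs.append(nn.Conv1d(rng, cin, f, k, name=f"conv{i}"))
            cin = f
        self.conv_relus = [nn.ReLU() for _ in self.convs]
        self.bilstm = nn.BiLSTM(rng, f, h)
        self.drop_lstm = nn.Dropout(cfg.dropout_rate, mc_site=True)
        self.feature_fcs = []
        self.feature_relus = []
        if metadata_dim > 0:
            fin = metadata_dim
            for i in range(cfg.feature_fc_layers):
                self.feature_fcs.append(
                    nn.Dense(rng, fin, cfg.feature_fc_width, name=f"featfc{i}"))
                self.feature_relus.append(nn.ReLU())
                fin = cfg.feature_fc_width
        self.drop_fuse = nn.Dropout(cfg.dropout_rate, mc_site=True)
        fused = 2 * h + (cfg.feature_fc_width if metadata_dim > 0 else 0)
        self.head = []
        self.head_relus = []
        hin = fused
        for i, w in enumerate(cfg.fusion_fc_widths):
            self.head.append(nn.Dense(rng, hin, w, name=f"head{i}"))
            self.head_relus.append(nn.ReLU())
            hin = w
        self.out = nn.Dense(rng, hin, 11, name="out")
        self._t = None

    # -- plumbing -----------------------------------------------------------
    def layers(self) -> list[nn.Layer]:
        return (self.convs + self.conv_relus + [self.bilstm, self.drop_lstm]
                + self.feature_fcs + self.feature_relus + [self.drop_fuse]
                + self.head + self.head_relus + [self.out])

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, m: np.ndarray | None = None,
                mode: str = "eval", rng: np.random.Generator | None = None
                ) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ParameterError(
                f"expected input (batch, {self.in_channels}, T), got {x.shape}")
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        if m is not None:
            m = np.ascontiguousarray(m, dtype=nn.DTYPE)
        b, _, t = x.shape
        self._t = t
        a = x
        for conv, relu in zip(self.convs, self.conv_relus):
            a = relu.forward(conv.forward(a))
        seq = a.transpose(0, 2, 1)  # (B, T, F)
        hs = self.bilstm.forward(seq)
        hs = self.drop_lstm.forward(hs, mode, rng)
        if self.metadata_dim > 0:
            if m is None or m.shape != (b, self.metadata_dim):
                raise ParameterError(
                    f"expected metadata (batch, {self.metadata_dim})")
            fvec = m
            for fc, relu in zip(self.feature_fcs, self.feature_relus):
                fvec = relu.forward(fc.forward(fvec))
            fb = np.broadcast_to(fvec[:, None, :], (b, t, fvec.shape[-1]))
            z = np.concatenate([hs, fb], axis=2)
        else:
            z = hs
        z = self.drop_fuse.forward(z, mode, rng)
        for fc, relu in zip(self.head, self.head_relus):
            z = relu.forward(fc.forward(z))
        y = self.out.forward(z)  # (B, T, 11)
        return y.transpose(0, 2, 1)

    def backward(self, gy: np.ndarray) -> None:
        g = gy.transpose(0, 2, 1)
        g = self.out.backward(g)
        for fc, relu in zip(reversed(self.head), reversed(self.head_relus)):
            g = fc.backward(relu.backward(g))
        g = self.drop_fuse.backward(g)
        if self.metadata_dim > 0:
            h2 = 2 * self.cfg.bilstm_units
            g_hs, g_fb = g[:, :, :h2], g[:, :, h2:]
            gf = g_fb.sum(axis=1)  # undo the broadcast along time
            for fc, relu in zip(reversed(self.feature_fcs),
                                reversed(self.feature_relus)):
                gf = fc.backward(relu.backward(gf))
            g = g_hs
        g = self.drop_lstm.backward(g)
        g = self.bilstm.backward(g)
        g = g.transpose(0, 2, 1)
        for conv, relu in zip(reversed(self.convs), reversed(self.conv_relus)):
            g = conv.backward(relu.backward(g))


class EarlyFusionNet:
    """Same backbone as the dual branch; metadata repeated along time and
    concatenated with the waveform at the input (no feature branch)."""

    def __init__(self, cfg: ModelConfig, metadata_dim: int):
        self.metadata_dim = metadata_dim
        self.cfg = cfg
        self.backbone = DualBranchNet(cfg, metadata_dim=0,
                                      in_channels=1 + metadata_dim)

    def params(self):
        return self.backbone.params()

    def zero_grad(self):
        self.backbone.zero_grad()

    def _fuse_input(self, x: np.ndarray, m: np.ndarray | None) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        if self.metadata_dim == 0:
            return x
        b, _, t = x.shape
        if m is None or m.shape != (b, self.metadata_dim):
            raise ParameterError(f"expected metadata (batch, {self.metadata_dim})")
        m = np.ascontiguousarray(m, dtype=nn.DTYPE)
        mrep = np.broadcast_to(m[:, :, None], (b, self.metadata_dim, t))
        return np.concatenate([x, mrep], axis=1)

    def forward(self, x, m=None, mode="eval", rng=None):
        return self.backbone.forward(self._fuse_input(x, m), None, mode, rng)

    def backward(self, gy):
        self.backbone.backward(gy)


class UNet1d:
    """Depth-3 1-D U-Net over a channel-repeated (1+D) x 512 input."""

    def __init__(self, cfg: ModelConfig, metadata_dim: int):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.metadata_dim = metadata_dim
        k = cfg.kernel_size
        base = cfg.unet_base_filters
        cin = 1 + metadata_dim
        widths = [base * 2 ** i for i in range(cfg.unet_depth)]  # e.g. 16,32,64
        self.enc = []
        self.enc_relu = []
        self.pools = []
        c = cin
        for w in widths:
            self.enc.append(nn.Conv1d(rng, c, w, k, name=f"enc{w}"))
            self.enc_relu.append(nn.ReLU())
            self.pools.append(nn.MaxPool1d())
            c = w
        self.mid = nn.Conv1d(rng, c, 2 * c, k, name="mid")
        self.mid_relu = nn.ReLU()
        self.drop_mid = nn.Dropout(cfg.dropout_rate, mc_site=True)
        self.ups = []
        self.dec = []
        self.dec_relu = []
        c = 2 * widths[-1]
        for w in reversed(widths):
            self.ups.append(nn.Upsample1d())
            self.dec.append(nn.Conv1d(rng, c + w, w, k, name=f"dec{w}"))
            self.dec_relu.append(nn.ReLU())
            c = w
        self.out = nn.Conv1d(rng, c, 11, 1, name="out")
        self._skip_channels = list(reversed(widths))

    def layers(self):
        return (self.enc + self.enc_relu + self.pools
                + [self.mid, self.mid_relu, self.drop_mid]
                + self.ups + self.dec + self.dec_relu + [self.out])

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for layer in self.layers():
            layer.zero_grad()

    def _fuse_input(self, x, m):
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        if self.metadata_dim == 0:
            return x
        b, _, t = x.shape
        if m is None or m.shape != (b, self.metadata_dim):
            raise ParameterError(f"expected metadata (batch, {self.metadata_dim})")
        m = np.ascontiguousarray(m, dtype=nn.DTYPE)
        mrep = np.broadcast_to(m[:, :, None], (b, self.metadata_dim, t))
        return np.concatenate([x, mrep], axis=1)

    def forward(self, x, m=None, mode="eval", rng=None):
        a = self._fuse_input(x, m)
        skips = []
        for conv, relu, pool in zip(self.enc, self.enc_relu, self.pools):
            a = relu.forward(conv.forward(a))
            skips.append(a)
            a = pool.forward(a)
        a = self.mid_relu.forward(self.mid.forward(a))
        a = self.drop_mid.forward(a, mode, rng)
        for up, conv, relu, skip in zip(self.ups, self.dec, self.dec_relu,
                                        reversed(skips)):
            a = up.forward(a)
            a = np.concatenate([a, skip], axis=1)
            a = relu.forward(conv.forward(a))
        return self.out.forward(a)

    def backward(self, gy):
        g = self.out.backward(gy)
        skip_grads = []
        # walk the decoder backwards, splitting off skip-connection gradients
        for i in range(len(self.dec) - 1, -1, -1):
            g = self.dec[i].backward(self.dec_relu[i].backward(g))
            n_up = g.shape[1] - self._skip_channels[i]
            g_up, g_skip = g[:, :n_up], g[:, n_up:]
            skip_grads.append(g_skip)
            g = self.ups[i].backward(g_up)
        g = self.drop_mid.backward(g)
        g = self.mid.backward(self.mid_relu.backward(g))
        skip_grads = skip_grads[::-1]  # now indexed like self.enc
        for i in range(len(self.enc) - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[len(self.enc) - 1 - i]
            g = self.enc[i].backward(self.enc_relu[i].backward(g))


_ARCHS = {"dual": DualBranchNet, "earlyfusion": EarlyFusionNet, "unet": UNet1d}


@dataclass
class TrainedModel:
    """A network plus its config snapshot and training history."""

    net: object
    config: ModelConfig
    metadata_dim: int
    arch: str
    history: dict = field(default_factory=lambda: {"train_loss": [], "val": []})
    best_epoch: int | None = None
    best_val_loss: float | None = None

    def state(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.net.params()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for p in self.net.params():
            p.value[...] = state[p.name]

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: npz of parameters + json sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state())
        meta = {
            "arch": self.arch,
            "metadata_dim": self.metadata_dim,
            "config": asdict(self.config),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = meta["config"]
        cfg_dict["fusion_fc_widths"] = tuple(cfg_dict["fusion_fc_widths"])
        cfg = ModelConfig(**cfg_dict)
        model = build_model(meta["arch"], cfg, meta["metadata_dim"])
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state({k: data[k] for k in data.files})
        model.history = meta["history"]
        model.best_epoch = meta["best_epoch"]
        model.best_val_loss = meta["best_val_loss"]
        return model


def build_model(arch: str, cfg: ModelConfig, metadata_dim: int) -> TrainedModel:
    if arch not in _ARCHS:
        raise ParameterError(f"unknown architecture {arch!r}; pick from {sorted(_ARCHS)}")
    net = _ARCHS[arch](cfg, metadata_dim)
    return TrainedModel(net=net, config=cfg, metadata_dim=metadata_dim, arch=arch)


def build_dual_branch(cfg: ModelConfig, metadata_dim: int) -> TrainedModel:
    return build_model("dual", cfg, metadata_dim)


def build_early_fusion_baseline(cfg: ModelConfig, metadata_dim: int) -> TrainedModel:
    return build_model("earlyfusion", cfg, metadata_dim)


def build_unet_baseline(cfg: ModelConfig, metadata_dim: int) -> TrainedModel:
    return build_model("unet", cfg, metadata_dim)


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def _batch_eval(model: TrainedModel, x, m, y, batch_size: int) -> float:
    total = 0.0
    n = x.shape[0]
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        pred = model.net.forward(x[lo:hi], m[lo:hi] if m.shape[1] else None, "eval")
        total += float(np.sum((pred - y[lo:hi]) ** 2))
    return total / (n * y.shape[1] * y.shape[2])


def train(model: TrainedModel,
          train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
          cfg: ModelConfig | None = None) -> TrainedModel:
    """Train with Adam on MSE; retain the lowest-validation-loss parameters.

    ``train_data``/``val_data`` are (X, M, Y) stacks as produced by
    ``preprocess.stack_pairs``.  Shuffling, dropout and initialization all
    derive from ``cfg.seed``, so identical calls give identical histories.
    """
    cfg = cfg or model.config
    xt, mt, yt = (np.ascontiguousarray(a, dtype=nn.DTYPE) for a in train_data)
    xv, mv, yv = (np.ascontiguousarray(a, dtype=nn.DTYPE) for a in val_data)
    if xt.shape[0] == 0 or xv.shape[0] == 0:
        raise ParameterError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.net.params(), lr=cfg.learning_rate)
    best_state = None
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(xt.shape[0])
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb = xt[idx], yt[idx]
            mb = mt[idx] if mt.shape[1] else None
            model.net.zero_grad()
            pred = model.net.forward(xb, mb, "train", rng)
            loss = mse(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}; aborting")
            gy = 2.0 * (pred - yb) / pred.size
            model.net.backward(gy)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.history["train_loss"].append(epoch_loss / n_batches)
        if epoch % cfg.validation_interval_epochs == 0 or epoch == cfg.epochs:
            vloss = _batch_eval(model, xv, mv, yv, cfg.batch_size)
            model.history["val"].append([epoch, vloss])
            if model.best_val_loss is None or vloss < model.best_val_loss:
                model.best_val_loss = vloss
                model.best_epoch = epoch
                best_state = model.state()
    if best_state is not None:
        model.load_state(best_state)
    return model


def predict(model: TrainedModel, lead1: np.ndarray,
            meta: np.ndarray | None = None) -> np.ndarray:
    """Deterministic reconstruction (dropout inactive).

    Accepts (512,), (1, 512) single inputs or (n, 1, 512) batches; returns
    (11, 512) or (n, 11, 512) correspondingly.
    """
    x = np.asarray(lead1, dtype=float)
    single = x.ndim < 3
    if x.ndim == 1:
        x = x[None, None, :]
    elif x.ndim == 2:
        x = x[None, :, :]
    m = None
    if model.metadata_dim > 0:
        m = np.asarray(meta, dtype=float)
        if m.ndim == 1:
            m = m[None, :]
    y = model.net.forward(x, m, "eval")
    return y[0] if single else y
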