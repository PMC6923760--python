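"""Convolutional autoencoder compressing window images to latent codes.

The network is intentionally small, sized for stacks of a few thousand
8 x 12 images: a single convolutional layer of ``n_filters`` kernels
spanning the full feature width (so the kernel slides only along time,
with valid padding and no pooling), a dense bottleneck of ``latent_dim``
units, and a mirrored decoder (dense -> one transposed convolution) with
a sigmoid output keeping reconstructions inside the [0, 1] data range.
It is trained with Adam on the L2-regularized mean squared
reconstruction error. The implementation is plain numpy with hand-coded
backpropagation, which keeps training fully deterministic under a fixed
seed and fast on a single CPU (the whole model has a few thousand
parameters).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .errors import TrainingError, ValidationError
from .imaging import WindowConfig

_GRID_AXES = ("learning_rate", "discount", "kernel_height", "n_filters", "latent_dim")


@dataclass(frozen=True)
class CAEConfig:
    """Hyperparameters of the autoencoder.

    Defaults follow the grid-search optimum for 8 x 12 inputs: 30 filters
    of height 3 (full 12-feature width), a 15-dimensional code, Adam at
    1e-4. ``activation`` applies to the hidden conv/dense layers
    ('relu' or 'linear'); the latent layer itself is linear and
    ``output_activation`` ('sigmoid' or 'linear') bounds reconstructions.
    """

    n_filters: int = 30
    kernel_height: int = 3
    latent_dim: int = 15
    learning_rate: float = 1e-4
    l2_weight: float = 1e-4
    epochs: int = 500
    batch_size: int = 64
    seed: int = 0
    activation: str = "relu"
    output_activation: str = "sigmoid"
    early_stopping: bool = True
    patience: int = 25
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_filters < 1 or self.latent_dim < 1 or self.kernel_height < 1:
            raise ValidationError("n_filters, latent_dim, kernel_height must be >= 1")
        if self.activation not in ("relu", "linear"):
            raise ValidationError(f"unknown activation {self.activation!r}")
        if self.output_activation not in ("sigmoid", "linear"):
            raise ValidationError(f"unknown output_activation {self.output_activation!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else z


def _act_grad(z: np.ndarray, kind: str) -> np.ndarray:
    return (z > 0).astype(z.dtype) if kind == "relu" else np.ones_like(z)


def _out_act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return z


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ConvAutoencoder:
    """One-conv-layer autoencoder for (win_size, n_features) images."""

    WEIGHT_KEYS = ("Wc", "We", "Wd", "Wt")
    BIAS_KEYS = ("bc", "be", "bd", "bo")

    def __init__(self, config: CAEConfig, win_size: int, n_features: int):
        if config.kernel_height > win_size:
            raise ValidationError(
                f"kernel_height {config.kernel_height} exceeds window size {win_size}"
            )
        self.config = config
        self.win_size = win_size
        self.n_features = n_features
        self.t_out = win_size - config.kernel_height + 1
        self.hidden = self.t_out * config.n_filters
        rng = np.random.default_rng(config.seed)
        kh, nf, lat, f = config.kernel_height, config.n_filters, config.latent_dim, n_features
        ksz = kh * f
        self.params = {
            "Wc": _glorot(rng, ksz, nf, (nf, ksz)),
            "bc": np.zeros(nf),
            "We": _glorot(rng, self.hidden, lat, (self.hidden, lat)),
            "be": np.zeros(lat),
            "Wd": _glorot(rng, lat, self.hidden, (lat, self.hidden)),
            "bd": np.zeros(self.hidden),
            "Wt": _glorot(rng, nf, ksz, (nf, kh, f)),
            "bo": np.zeros(f),
        }

    # ---- forward pieces -------------------------------------------------
    def _patches(self, x: np.ndarray) -> np.ndarray:
        """(N, T, F) -> (N, t_out, kh*F) sliding patches along time."""
        kh = self.config.kernel_height
        v = np.lib.stride_tricks.sliding_window_view(x, kh, axis=1)  # (N, t_out, F, kh)
        return v.transpose(0, 1, 3, 2).reshape(x.shape[0], self.t_out, kh * self.n_features)

    def _forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        cfg = self.config
        patches = self._patches(x)
        z1 = patches @ p["Wc"].T + p["bc"]
        a1 = _act(z1, cfg.activation)
        h = a1.reshape(x.shape[0], self.hidden)
        latent = h @ p["We"] + p["be"]
        zd = latent @ p["Wd"] + p["bd"]
        g = _act(zd, cfg.activation)
        gmat = g.reshape(x.shape[0], self.t_out, cfg.n_filters)
        y_pre = np.tile(p["bo"], (x.shape[0], self.win_size, 1))
        for j in range(cfg.kernel_height):
            y_pre[:, j:j + self.t_out, :] += gmat @ p["Wt"][:, j, :]
        yhat = _out_act(y_pre, cfg.output_activation)
        return dict(patches=patches, z1=z1, h=h, latent=latent, zd=zd,
                    gmat=gmat, y_pre=y_pre, yhat=yhat)

    def encode(self, x: np.ndarray) -> np.ndarray:
        self._check_shape(x)
        return self._forward(x)["latent"]

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        self._check_shape(x)
        return self._forward(x)["yhat"]

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 3 or x.shape[1:] != (self.win_size, self.n_features):
            raise ValidationError(
                f"expected images of shape (N, {self.win_size}, {self.n_features}), "
                f"got {x.shape}"
            )

    # ---- losses and gradients ------------------------------------------
    def _weight_norm(self) -> float:
        return float(sum(np.sum(self.params[k] ** 2) for k in self.WEIGHT_KEYS))

    def loss(self, x: np.ndarray) -> tuple[float, float]:
        """(regularized loss, plain reconstruction MSE) per image-pixel mean."""
        yhat = self._forward(x)["yhat"]
        mse = float(np.mean((yhat - x) ** 2))
        return mse + self.config.l2_weight * self._weight_norm(), mse

    def _backward(self, x: np.ndarray, cache: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        p, cfg = self.params, self.config
        n = x.shape[0]
        dy = 2.0 * (cache["yhat"] - x) / cache["yhat"].size
        if cfg.output_activation == "sigmoid":
            dy = dy * cache["yhat"] * (1.0 - cache["yhat"])
        grads: dict[str, np.ndarray] = {}
        grads["bo"] = dy.sum(axis=(0, 1))
        dwt = np.empty_like(p["Wt"])
        dgmat = np.zeros_like(cache["gmat"])
        for j in range(cfg.kernel_height):
            dy_j = dy[:, j:j + self.t_out, :]
            dwt[:, j, :] = np.einsum("nsk,nsf->kf", cache["gmat"], dy_j)
            dgmat += dy_j @ p["Wt"][:, j, :].T
        grads["Wt"] = dwt
        dzd = dgmat.reshape(n, self.hidden) * _act_grad(cache["zd"], cfg.activation)
        grads["Wd"] = cache["latent"].T @ dzd
        grads["bd"] = dzd.sum(axis=0)
        dlat = dzd @ p["Wd"].T
        grads["We"] = cache["h"].T @ dlat
        grads["be"] = dlat.sum(axis=0)
        dh = dlat @ p["We"].T
        dz1 = dh.reshape(n, self.t_out, cfg.n_filters) * _act_grad(cache["z1"], cfg.activation)
        grads["Wc"] = np.einsum("nsk,nsp->kp", dz1, cache["patches"])
        grads["bc"] = dz1.sum(axis=(0, 1))
        for k in self.WEIGHT_KEYS:
            grads[k] = grads[k] + 2.0 * cfg.l2_weight * p[k]
        return grads


@dataclass
class TrainedCAE:
    """Fitted model plus its per-epoch loss trace."""

    model: ConvAutoencoder
    loss_history: list[float]           # regularized loss per epoch (full data)
    recon_history: list[float]          # plain reconstruction MSE per epoch
    config: CAEConfig
    stopped_epoch: int = 0

    def encode(self, images: np.ndarray) -> np.ndarray:
        return self.model.encode(images)

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        return self.model.reconstruct(images)

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]

    def save(self, path) -> None:
        meta = json.dumps({"config": asdict(self.config),
                           "win_size": self.model.win_size,
                           "n_features": self.model.n_features,
                           "loss_history": self.loss_history,
                           "recon_history": self.recon_history,
                           "stopped_epoch": self.stopped_epoch})
        np.savez(path, meta=np.array(meta), **self.model.params)

    @classmethod
    def load(cls, path) -> "TrainedCAE":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        config = CAEConfig(**meta["config"])
        model = ConvAutoencoder(config, meta["win_size"], meta["n_features"])
        for k in list(model.params):
            model.params[k] = data[k]
        return cls(model, meta["loss_history"], meta["recon_history"], config,
                   meta["stopped_epoch"])


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_cae(images: np.ndarray, config: CAEConfig) -> TrainedCAE:
    """Fit the autoencoder with mini-batch Adam.

    The per-epoch regularized loss is recorded on the full image stack.
    With early stopping enabled, a 10% validation split is monitored and
    the parameters with the best validation loss are restored; otherwise
    training runs for exactly ``config.epochs`` epochs. Deterministic
    given the config seed.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise ValidationError("images must be a 3-D stack (N, win, features)")
    n = images.shape[0]
    if n < config.batch_size:
        raise ValidationError(f"need at least batch_size={config.batch_size} images, got {n}")
    model = ConvAutoencoder(config, images.shape[1], images.shape[2])
    rng = np.random.default_rng(config.seed + 1)

    n_val = int(round(n * config.val_fraction)) if config.early_stopping else 0
    n_val = min(n_val, n - config.batch_size) if n_val else 0
    perm = rng.permutation(n)
    val, train = images[perm[:n_val]], images[perm[n_val:]]

    opt = _Adam(model.params, config.learning_rate)
    loss_hist: list[float] = []
    recon_hist: list[float] = []
    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    strikes = 0
    epoch = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(train.shape[0])
        for i in range(0, train.shape[0], config.batch_size):
            batch = train[order[i:i + config.batch_size]]
            cache = model._forward(batch)
            grads = model._backward(batch, cache)
            opt.step(model.params, grads)
        reg_loss, mse = model.loss(images)
        if not np.isfinite(reg_loss):
            raise TrainingError(
                f"loss became non-finite at epoch {epoch}; "
                f"last finite epoch {len(loss_hist)} "
                f"(loss {loss_hist[-1]:.4g})" if loss_hist else
                f"loss became non-finite at epoch {epoch}"
            )
        loss_hist.append(reg_loss)
        recon_hist.append(mse)
        if n_val:
            val_loss, _ = model.loss(val) if len(val) else (reg_loss, mse)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in model.params.items()}
                strikes = 0
            else:
                strikes += 1
                if strikes >= config.patience:
                    break
    if best_params is not None:
        model.params = best_params
    return TrainedCAE(model, loss_hist, recon_hist, config, stopped_epoch=epoch)


def encode(trained: TrainedCAE, images: np.ndarray) -> np.ndarray:
    codes = trained.encode(np.asarray(images, dtype=float))
    if not np.isfinite(codes).all():
        raise TrainingError("latent codes contain non-finite values")
    return codes


def reconstruct(trained: TrainedCAE, images: np.ndarray) -> np.ndarray:
    return trained.reconstruct(np.asarray(images, dtype=float))


def grid_search(panels: dict[str, np.ndarray], window_config: WindowConfig,
                base_config: CAEConfig,
                grid: dict[str, list]) -> tuple[CAEConfig, WindowConfig, pd.DataFrame]:
    """Exhaustive search over {learning_rate, discount, kernel_height,
    n_filters, latent_dim}; the discount axis re-runs imaging. Returns the
    winning CAE config, the winning window config, and the full loss table
    (diverged combinations recorded with infinite loss)."""
    from .imaging import assemble_dataset

    if not grid:
        raise ValidationError("empty grid")
    unknown = set(grid) - set(_GRID_AXES)
    if unknown:
        raise ValidationError(f"unknown grid axes: {sorted(unknown)}")
    axes = [a for a in _GRID_AXES if a in grid]
    rows = []
    best = (np.inf, None, None)
    for combo in product(*(grid[a] for a in axes)):
        setting = dict(zip(axes, combo))
        wcfg = (replace(window_config, discount=setting.pop("discount"))
                if "discount" in setting else window_config)
        ccfg = replace(base_config, **setting)
        stack = assemble_dataset(panels, wcfg)
        try:
            trained = train_cae(stack.images, ccfg)
            final = trained.final_loss
        except TrainingError:
            final = np.inf
        rows.append({a: dict(zip(axes, combo))[a] for a in axes} | {"final_loss": final})
        if final < best[0]:
            best = (final, ccfg, wcfg)
    table = pd.DataFrame(rows)
    if best[1] is None:
        raise TrainingError("every grid combination diverged")
    return best[1], best[2], table
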