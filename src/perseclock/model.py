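"""The PerSEClock network: channel attention over blocked CpG loci + MLP head.

The model reshapes a length-L beta-value vector into a block tensor of shape
``block_rows x block_cols x channels`` (consecutive loci land in consecutive
channels), squeezes each channel to its mean, passes the channel means
through a two-layer excitation bottleneck ending in a sigmoid, rescales each
channel by its gate, flattens, and regresses age with a multilayer
perceptron (LeakyReLU / batch-norm / dropout hidden layers, one linear
output).  The reference geometry is 3 x 6 x 1,362 = 24,516 loci, the CpG set
shared by the Illumina 27K/450K/850K platforms.  A plain-MLP baseline (the
same head without the attention block) is provided for comparison.

The main surface is two scikit-learn-style estimators,
:class:`PerSEClockRegressor` and :class:`MLPClockRegressor`; the module-level
functions expose the individual tensor operations for testing and reuse.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from ._network import (
    Adam, BatchNorm1d, Dropout, Layer, LeakyReLU, Linear, Network,
    SqueezeExcite, _sigmoid,
)

logger = logging.getLogger(__name__)

VARIANTS = ("perseclock", "plain_mlp")


@dataclass
class ClockConfig:
    """Architecture geometry and head hyperparameters.

    Defaults are the published architecture: blocks of 3 x 6 beta values per
    channel, 1,362 channels (24,516 loci), a 4-layer MLP head of width 32
    with LeakyReLU, BatchNorm1d(32) and Dropout(0.1).  ``channels=None``
    infers the channel count from the input length at fit time.
    """

    block_rows: int = 3
    block_cols: int = 6
    channels: int | None = 1362
    se_reduction: int = 16
    hidden_width: int = 32
    hidden_depth: int = 4
    dropout_rate: float = 0.1
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        for name in ("block_rows", "block_cols", "se_reduction",
                     "hidden_width", "hidden_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.channels is not None and self.channels < 1:
            raise ValueError("channels must be a positive integer or None")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be positive")
        if self.channels is not None and self.se_reduction > self.channels:
            raise ValueError("se_reduction must not exceed channels")

    @property
    def positions(self) -> int:
        """Beta values per channel (block_rows * block_cols; 18 in the reference geometry)."""
        return self.block_rows * self.block_cols

    @property
    def input_length(self) -> int | None:
        return None if self.channels is None else self.positions * self.channels

    def resolve_channels(self, n_features: int) -> int:
        """Channel count for an input of ``n_features`` loci (hard error if indivisible)."""
        if self.channels is not None:
            if self.positions * self.channels != n_features:
                raise ValueError(
                    f"input length {n_features} != block_rows*block_cols*channels "
                    f"= {self.positions * self.channels}")
            return self.channels
        if n_features % self.positions != 0:
            raise ValueError(
                f"input length {n_features} is not divisible by "
                f"block_rows*block_cols = {self.positions}")
        return n_features // self.positions


# --- functional tensor operations -----------------------------------------

def reshape_to_blocks(x: np.ndarray, cfg: ClockConfig) -> np.ndarray:
    """Reshape a length-L beta vector into (block_rows, block_cols, channels).

    Element i goes to channel ``i % channels`` at within-channel position
    ``i // channels`` (row-major over the block), so adjacent loci occupy
    different channels.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D beta vector")
    ch = cfg.resolve_channels(x.size)
    return x.reshape(cfg.block_rows, cfg.block_cols, ch)


def flatten_blocks(t: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reshape_to_blocks`."""
    return np.asarray(t).reshape(-1)


def global_average_pool(t: np.ndarray) -> np.ndarray:
    """Mean of the block_rows*block_cols values in each channel -> (channels,)."""
    t = np.asarray(t, dtype=float)
    if t.ndim != 3:
        raise ValueError("expected a 3-D block tensor")
    return t.mean(axis=(0, 1))


def scale(t: np.ndarray, gates: np.ndarray) -> np.ndarray:
    """Multiply every value in channel c by gates[c]."""
    t = np.asarray(t, dtype=float)
    gates = np.asarray(gates, dtype=float).reshape(-1)
    if t.shape[-1] != gates.size:
        raise ValueError(
            f"gate length {gates.size} != channel count {t.shape[-1]}")
    return t * gates


def excitation(pooled: np.ndarray, model: "PerSEClockRegressor") -> np.ndarray:
    """Excitation gates for a pooled channel vector, via a fitted model's SE block."""
    check_is_fitted(model)
    se = model._se_block()
    if se is None:
        raise ValueError("model variant has no excitation block")
    pooled = np.asarray(pooled, dtype=float).reshape(1, -1)
    if pooled.shape[1] != se.channels:
        raise ValueError(
            f"pooled length {pooled.shape[1]} != channels {se.channels}")
    h = np.maximum(se.fc1.forward(pooled, False), 0.0)
    return _sigmoid(se.fc2.forward(h, False)).ravel()


def forward(x: np.ndarray, model: "_BaseClockRegressor") -> float:
    """Single-sample forward pass (evaluation mode) -> predicted age in years."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input vector")
    return float(model.predict(x.reshape(1, -1))[0])


def build_network(n_features: int, cfg: ClockConfig, variant: str,
                  seed) -> Network:
    """Construct an initialized network; reproducible from ``seed``."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    channels = cfg.resolve_channels(n_features)
    if variant == "perseclock" and cfg.se_reduction > channels:
        raise ValueError("se_reduction must not exceed channels")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    if variant == "perseclock":
        layers.append(SqueezeExcite(cfg.positions, channels, cfg.se_reduction, rng))
    width_in = n_features
    for _ in range(cfg.hidden_depth):
        layers += [
            Linear(width_in, cfg.hidden_width, rng),
            LeakyReLU(cfg.leaky_slope),
            BatchNorm1d(cfg.hidden_width),
            Dropout(cfg.dropout_rate),
        ]
        width_in = cfg.hidden_width
    layers.append(Linear(width_in, 1, rng))
    return Network(layers)


@dataclass
class TrainHistory:
    """Per-epoch MSE losses (years^2) with the early-stopping bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0          # 1-based epoch attaining the minimum val loss
    best_val_loss: float = float("inf")

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


# --- estimators ------------------------------------------------------------

class _BaseClockRegressor(RegressorMixin, BaseEstimator):
    """Shared fit/predict machinery for the clock variants.

    Training minimizes MSE with Adam on raw (unstandardized) beta values,
    monitors validation MSE every epoch, stops after ``patience`` epochs
    without improvement, and restores the parameters of the epoch with the
    lowest validation loss.  Batch-norm running statistics are frozen at
    prediction time, so single-sample prediction is supported.
    """

    _variant = ""

    def __init__(self, block_rows=3, block_cols=6, channels=None,
                 se_reduction=16, hidden_width=32, hidden_depth=4,
                 dropout_rate=0.1, leaky_slope=0.01,
                 learning_rate=0.05, batch_size=512, max_epochs=150,
                 patience=20, validation_fraction=0.1, random_state=None,
                 verbose=0):
        self.block_rows = block_rows
        self.block_cols = block_cols
        self.channels = channels
        self.se_reduction = se_reduction
        self.hidden_width = hidden_width
        self.hidden_depth = hidden_depth
        self.dropout_rate = dropout_rate
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    def _clock_config(self) -> ClockConfig:
        return ClockConfig(
            block_rows=self.block_rows, block_cols=self.block_cols,
            channels=self.channels, se_reduction=self.se_reduction,
            hidden_width=self.hidden_width, hidden_depth=self.hidden_depth,
            dropout_rate=self.dropout_rate, leaky_slope=self.leaky_slope,
        )

    def _se_block(self):
        for layer in self.network_.layers:
            if isinstance(layer, SqueezeExcite):
                return layer
        return None

    def _eval_mse(self, X: np.ndarray, y: np.ndarray) -> float:
        pred = self._predict_array(X)
        return float(np.mean((pred - y) ** 2))

    def _predict_array(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        step = max(int(self.batch_size), 1)
        for start in range(0, X.shape[0], step):
            chunk = X[start:start + step]
            out[start:start + step] = self.network_.forward(chunk, training=False).ravel()
        return out

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on (X, y); validation data is split off internally unless given.

        Parameters
        ----------
        X : array-like of shape (n_samples, n_loci)
            Beta values in [0, 1], fully imputed (no NaN).
        y : array-like of shape (n_samples,)
            Chronological ages in years.
        X_val, y_val : optional explicit validation set; when omitted,
            ``validation_fraction`` of the training data is held out.
        """
        X, y = validate_data(self, X, y, y_numeric=True, dtype=np.float64)
        y = y.astype(float)
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        cfg = self._clock_config()
        self.channels_ = cfg.resolve_channels(X.shape[1])
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            if not 0.0 < self.validation_fraction < 1.0:
                raise ValueError(
                    "validation_fraction must be in (0, 1) when no explicit "
                    "validation set is given")
            n_val = max(1, int(np.floor(self.validation_fraction * X.shape[0])))
            if n_val >= X.shape[0]:
                raise ValueError("not enough samples to hold out validation data")
            perm = rng.permutation(X.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_tr, y_tr = X[tr_idx], y[tr_idx]
            X_val, y_val = X[val_idx], y[val_idx]
        else:
            X_tr, y_tr = X, y
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float).ravel()
            if X_val.shape[0] == 0:
                raise ValueError("validation set is empty")

        net = build_network(X.shape[1], cfg, self._variant,
                            rng.integers(0, 2**31 - 1))
        self.network_ = net
        opt = Adam(net.parameters(), lr=self.learning_rate)
        history = TrainHistory()
        best_state = net.get_state()
        warned_bs1 = False

        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(X_tr.shape[0])
            epoch_losses, epoch_sizes = [], []
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                if len(idx) == 1:
                    if not warned_bs1:
                        logger.warning("skipping training batch of size 1 "
                                       "(batch-norm needs >= 2 samples)")
                        warned_bs1 = True
                    continue
                xb, yb = X_tr[idx], y_tr[idx]
                pred = net.forward(xb, training=True, rng=rng).ravel()
                resid = pred - yb
                loss = float(np.mean(resid ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}")
                net.backward((2.0 * resid / len(idx)).reshape(-1, 1))
                opt.step(net.gradients())
                epoch_losses.append(loss)
                epoch_sizes.append(len(idx))
            train_loss = float(np.average(epoch_losses, weights=epoch_sizes))
            val_loss = self._eval_mse(X_val, y_val)
            if not np.isfinite(val_loss):
                raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
            history.train_loss.append(train_loss)
            history.val_loss.append(val_loss)
            if val_loss < history.best_val_loss:
                history.best_val_loss = val_loss
                history.best_epoch = epoch
                best_state = net.get_state()
            if self.verbose:
                logger.info("epoch %d: train MSE %.4f, val MSE %.4f",
                            epoch, train_loss, val_loss)
            if epoch - history.best_epoch >= self.patience:
                break

        net.set_state(best_state)
        self.history_ = history
        self.best_epoch_ = history.best_epoch
        self.best_val_loss_ = history.best_val_loss
        return self

    def predict(self, X):
        """Predicted chronological age (years) for each row of X, eval mode."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=np.float64)
        return self._predict_array(X)


class PerSEClockRegressor(_BaseClockRegressor):
    """Channel-attention perceptron age predictor (squeeze-excite + MLP head)."""

    _variant = "perseclock"

    def channel_gates(self, X) -> np.ndarray:
        """Excitation gates in (0, 1), shape (n_samples, channels).

        High gates mark channels the model treats as informative for age.
        """
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=np.float64)
        return self._se_block().gates(X)


class MLPClockRegressor(_BaseClockRegressor):
    """Plain multilayer-perceptron baseline: the same head, no attention block."""

    _variant = "plain_mlp"


def build_model(cfg: ClockConfig, variant: str = "perseclock",
                seed=None) -> _BaseClockRegressor:
    """Construct an unfitted estimator from a :class:`ClockConfig`."""
    cls = PerSEClockRegressor if variant == "perseclock" else MLPClockRegressor
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    return cls(random_state=seed, **asdict(cfg))


# --- checkpoints ------------------------------------------------------------

def save_checkpoint(model: _BaseClockRegressor, path,
                    locus_ids: list[str] | None = None) -> None:
    """Save a fitted model: config as JSON plus parameter arrays (.npz)."""
    check_is_fitted(model)
    config = {
        "variant": model._variant,
        "params": model.get_params(),
        "n_features_in": int(model.n_features_in_),
        "channels": int(model.channels_),
        "locus_ids": locus_ids,
        "best_epoch": int(model.best_epoch_),
        "best_val_loss": float(model.best_val_loss_),
        "history": {"train_loss": model.history_.train_loss,
                    "val_loss": model.history_.val_loss},
    }
    state = model.network_.get_state()
    arrays = {f"arr_{i}": a for i, a in enumerate(state)}
    np.savez(str(path), config=np.array(json.dumps(config)), **arrays)


def load_checkpoint(path, expected_params: dict | None = None
                    ) -> _BaseClockRegressor:
    """Load a checkpoint; refuses one whose config conflicts with ``expected_params``."""
    with np.load(str(path), allow_pickle=False) as data:
        config = json.loads(str(data["config"]))
        state = [data[f"arr_{i}"]
                 for i in range(sum(1 for k in data.files if k.startswith("arr_")))]
    if expected_params:
        saved = config["params"]
        for key, want in expected_params.items():
            if key in saved and saved[key] != want:
                raise ValueError(
                    f"checkpoint config conflict: {key} is {saved[key]!r} in the "
                    f"checkpoint but {want!r} was requested")
    cls = PerSEClockRegressor if config["variant"] == "perseclock" else MLPClockRegressor
    model = cls(**config["params"])
    model.n_features_in_ = config["n_features_in"]
    model.channels_ = config["channels"]
    cfg = model._clock_config()
    net = build_network(config["n_features_in"], cfg, config["variant"], 0)
    net.set_state(state)
    model.network_ = net
    model.history_ = TrainHistory(
        train_loss=list(config["history"]["train_loss"]),
        val_loss=list(config["history"]["val_loss"]),
        best_epoch=config["best_epoch"],
        best_val_loss=config["best_val_loss"],
    )
    model.best_epoch_ = config["best_epoch"]
    model.best_val_loss_ = config["best_val_loss"]
    model.locus_ids_ = config.get("locus_ids")
    return model
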