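"""Dataset splitting, the optimization loop, and batch prediction.

The optimization loop itself lives in the estimators
(:class:`~perseclock.model._BaseClockRegressor.fit`); this module provides
the shuffle-then-split partitioning, a thin training entry point working on
:class:`~perseclock.meth_io.BetaMatrix` + metadata, and prediction with
safety checks (no missing values, locus order agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import PredictionResult
from .meth_io import BetaMatrix
from .model import (
    ClockConfig, MLPClockRegressor, PerSEClockRegressor, TrainHistory,
    _BaseClockRegressor,
)

__all__ = [
    "TrainConfig", "TrainHistory", "split_dataset", "train", "fit_clock",
    "predict",
]


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the published training recipe.

    ``split_fractions`` (0.81, 0.09, 0.10) reproduce the reference
    8,577 / 953 / 1,059 train/validation/test partition of 10,589 samples
    under floor-floor-remainder sizing.
    """

    learning_rate: float = 0.05
    batch_size: int = 512
    max_epochs: int = 150
    patience: int = 20
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.81, 0.09, 0.10)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if not 1 <= self.patience <= self.max_epochs:
            raise ValueError("patience must be in [1, max_epochs]")
        f = self.split_fractions
        if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("split_fractions must be 3 non-negative reals summing to 1")


def split_dataset(n: int, fractions=(0.81, 0.09, 0.10), seed=0):
    """Shuffle indices 0..n-1 and split into train/validation/test index arrays.

    Sizes are floor(n*f_train), floor(n*f_val), and the remainder for test;
    the three sets are disjoint and cover all indices.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    f = tuple(fractions)
    if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 non-negative reals summing to 1")
    n_train = int(np.floor(n * f[0]))
    n_val = int(np.floor(n * f[1]))
    if n_train == 0:
        raise ValueError("fractions produce an empty training set")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def train(model: _BaseClockRegressor, X_train, y_train, X_val, y_val
          ) -> tuple[_BaseClockRegressor, TrainHistory]:
    """Fit ``model`` on the given train/validation arrays; returns (model, history).

    The returned parameters are those of the epoch with minimum validation
    MSE (checkpoint-restore semantics).
    """
    model.fit(X_train, y_train, X_val=X_val, y_val=y_val)
    return model, model.history_


def fit_clock(bm: BetaMatrix, meta: pd.DataFrame, variant: str = "perseclock",
              clock_cfg: ClockConfig | None = None,
              train_cfg: TrainConfig | None = None):
    """End-to-end: split a cohort, fit a clock, and return everything needed downstream.

    Returns
    -------
    model : fitted estimator (with ``locus_ids_`` recording the panel order)
    splits : dict with 'train'/'val'/'test' index arrays into ``bm``
    """
    if bm.mask.any():
        raise ValueError("beta matrix contains missing values; run imputation first")
    clock_cfg = clock_cfg or ClockConfig(channels=None)
    train_cfg = train_cfg or TrainConfig()
    ages = _ages_for(bm, meta)
    tr, va, te = split_dataset(bm.n_samples, train_cfg.split_fractions,
                               train_cfg.seed)
    cls = PerSEClockRegressor if variant == "perseclock" else MLPClockRegressor
    if variant not in ("perseclock", "plain_mlp"):
        raise ValueError(f"unknown variant {variant!r}")
    model = cls(
        block_rows=clock_cfg.block_rows, block_cols=clock_cfg.block_cols,
        channels=clock_cfg.channels, se_reduction=clock_cfg.se_reduction,
        hidden_width=clock_cfg.hidden_width, hidden_depth=clock_cfg.hidden_depth,
        dropout_rate=clock_cfg.dropout_rate, leaky_slope=clock_cfg.leaky_slope,
        learning_rate=train_cfg.learning_rate, batch_size=train_cfg.batch_size,
        max_epochs=train_cfg.max_epochs, patience=train_cfg.patience,
        random_state=train_cfg.seed,
    )
    model.fit(bm.values[tr], ages[tr], X_val=bm.values[va], y_val=ages[va])
    model.locus_ids_ = list(bm.locus_ids)
    return model, {"train": tr, "val": va, "test": te}


def predict(model: _BaseClockRegressor, bm: BetaMatrix,
            meta: pd.DataFrame | None = None) -> PredictionResult:
    """Predict ages for every sample of a fully imputed beta matrix.

    Evaluation-mode semantics: dropout off, batch-norm running statistics;
    predictions are independent of inference batch size, and a single-sample
    matrix is fine.
    """
    if bm.mask.any():
        n_bad = int(bm.mask.any(axis=1).sum())
        raise ValueError(
            f"{n_bad} sample(s) contain missing beta values; impute first "
            "(perseclock.meth_io.impute_missing)")
    panel = getattr(model, "locus_ids_", None)
    if panel is not None and list(bm.locus_ids) != list(panel):
        raise ValueError(
            "locus order of the beta matrix does not match the order the "
            "model was trained on; intersect against the model's panel first")
    pred = model.predict(bm.values)
    if meta is not None:
        ages = _ages_for(bm, meta)
    else:
        ages = np.full(bm.n_samples, np.nan)
    return PredictionResult(list(bm.sample_ids), pred, ages)


def _ages_for(bm: BetaMatrix, meta: pd.DataFrame) -> np.ndarray:
    lookup = meta.set_index("sample_id")["age"]
    missing = [s for s in bm.sample_ids if s not in lookup.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:10]}")
    return lookup.loc[bm.sample_ids].to_numpy(dtype=float)
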