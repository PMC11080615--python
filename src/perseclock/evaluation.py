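"""Accuracy metrics for age prediction and per-group error summaries.

Four metrics summarize predicted vs chronological age over m samples:

* R^2 = 1 - SSE/SST, with SSE = sum_i (preAge_i - chrAge_i)^2 and
  SST = sum_i (chrAge_i - mean(chrAge))^2;
* MAE = mean |preAge_i - chrAge_i| (years);
* MSE = mean (preAge_i - chrAge_i)^2 (years^2);
* Med = median |preAge_i - chrAge_i| (years) — median absolute error, the
  robust headline metric for epigenetic clocks.

Per-tissue (or per-dataset) tables additionally report the mean *signed*
error preAge - chrAge, the age-acceleration summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PredictionResult:
    """Paired predicted and actual ages for a set of samples."""

    sample_ids: list[str]
    pre_age: np.ndarray
    chr_age: np.ndarray

    def __post_init__(self) -> None:
        self.pre_age = np.asarray(self.pre_age, dtype=float).ravel()
        self.chr_age = np.asarray(self.chr_age, dtype=float).ravel()
        m = len(self.sample_ids)
        if m < 1:
            raise ValueError("need at least one sample")
        if self.pre_age.size != m or self.chr_age.size != m:
            raise ValueError("sample_ids, pre_age and chr_age lengths differ")
        if not np.all(np.isfinite(self.pre_age)):
            raise ValueError("non-finite predicted ages")

    @property
    def m(self) -> int:
        return len(self.sample_ids)

    @property
    def errors(self) -> np.ndarray:
        """Signed errors preAge - chrAge (years)."""
        return self.pre_age - self.chr_age

    def _require_actual(self) -> None:
        if not np.all(np.isfinite(self.chr_age)):
            raise ValueError("actual ages unavailable or non-finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids,
                             "predicted_age": self.pre_age,
                             "age": self.chr_age})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PredictionResult":
        actual = (df["age"].to_numpy(dtype=float) if "age" in df.columns
                  else np.full(len(df), np.nan))
        return cls([str(s) for s in df["sample_id"]],
                   df["predicted_age"].to_numpy(dtype=float), actual)


@dataclass
class MetricsReport:
    """The four summary metrics for one prediction set."""

    r_squared: float
    mae: float
    mse: float
    med: float
    n: int

    def to_dict(self) -> dict:
        return {"r_squared": self.r_squared, "mae": self.mae,
                "mse": self.mse, "med": self.med, "n": self.n}


def r_squared(p: PredictionResult) -> float:
    """Coefficient of determination 1 - SSE/SST (errors against actual age)."""
    p._require_actual()
    sst = float(np.sum((p.chr_age - p.chr_age.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("all actual ages identical: SST = 0, R^2 undefined")
    sse = float(np.sum((p.pre_age - p.chr_age) ** 2))
    return 1.0 - sse / sst


def mae(p: PredictionResult) -> float:
    """Mean absolute error in years."""
    p._require_actual()
    return float(np.mean(np.abs(p.errors)))


def mse(p: PredictionResult) -> float:
    """Mean squared error in years^2."""
    p._require_actual()
    return float(np.mean(p.errors ** 2))


def med_abs_error(p: PredictionResult) -> float:
    """Median absolute error in years (even m: mean of the two central values)."""
    p._require_actual()
    return float(np.median(np.abs(p.errors)))


def compute_metrics(p: PredictionResult) -> MetricsReport:
    return MetricsReport(r_squared(p), mae(p), mse(p), med_abs_error(p), p.m)


def per_group_error_summary(p: PredictionResult, meta: pd.DataFrame,
                            group_key: str = "tissue") -> pd.DataFrame:
    """Per-group error table: (group, n, mean signed error, Med, MAE).

    Signed error is preAge - chrAge, so a positive mean means the group is
    predicted older than it is.
    """
    p._require_actual()
    if group_key not in meta.columns:
        raise ValueError(f"metadata has no column {group_key!r}")
    lookup = meta.set_index("sample_id")[group_key]
    missing = [s for s in p.sample_ids if s not in lookup.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:10]}")
    groups = lookup.loc[p.sample_ids].to_numpy()
    err = p.errors
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        rows.append({
            group_key: g,
            "n": int(sel.sum()),
            "mean_signed_error": float(err[sel].mean()),
            "med": float(np.median(np.abs(err[sel]))),
            "mae": float(np.mean(np.abs(err[sel]))),
        })
    return pd.DataFrame(rows)
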